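"""Readers, writers and validation for ASV count tables, sequences and metadata.

In-memory convention: count matrices are samples x ASVs.  BIOM files store
observations (ASVs) x samples and are transposed on load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


class ValidationError(ValueError):
    """Raised when input files are inconsistent or violate table invariants."""


@dataclass
class AsvTable:
    """Nonnegative integer count matrix (samples x ASVs) with identifiers.

    ``group`` is optional until metadata is attached; when present it must
    contain exactly two levels, each with at least two samples.
    """

    counts: np.ndarray
    sample_ids: list[str]
    asv_ids: list[str]
    group: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (samples x ASVs)")
        n_samples, n_asvs = self.counts.shape
        if len(self.sample_ids) != n_samples:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n_samples} count rows"
            )
        if len(self.asv_ids) != n_asvs:
            raise ValidationError(
                f"{len(self.asv_ids)} ASV ids for {n_asvs} count columns"
            )
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("duplicate sample ids")
        if len(set(self.asv_ids)) != n_asvs:
            raise ValidationError("duplicate ASV ids")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("non-integer counts")
            self.counts = np.round(self.counts).astype(np.int64)
        totals = self.counts.sum(axis=1)
        if np.any(totals == 0):
            bad = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValidationError(f"samples with zero total count: {bad}")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if self.group.shape != (n_samples,):
                raise ValidationError("group labels must align with samples")
            levels, counts_per = np.unique(self.group.astype(str), return_counts=True)
            if len(levels) != 2:
                raise ValidationError(
                    f"expected exactly two group levels, got {list(levels)}"
                )
            if np.any(counts_per < 2):
                raise ValidationError(
                    "each group level needs at least 2 samples; "
                    f"sizes {dict(zip(levels, counts_per))}"
                )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def drop_empty_asvs(self) -> "AsvTable":
        """Return a table without all-zero ASV columns (logged if any)."""
        keep = self.counts.sum(axis=0) > 0
        n_dropped = int((~keep).sum())
        if n_dropped == 0:
            return self
        dropped = [a for a, k in zip(self.asv_ids, keep) if not k]
        logger.warning("dropping %d all-zero ASV column(s): %s", n_dropped, dropped)
        return replace(
            self,
            counts=self.counts[:, keep],
            asv_ids=[a for a, k in zip(self.asv_ids, keep) if k],
        )

    def with_group(self, labels: dict[str, str]) -> "AsvTable":
        """Attach per-sample group labels keyed by sample id."""
        missing = [s for s in self.sample_ids if s not in labels]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        group = np.array([labels[s] for s in self.sample_ids], dtype=object)
        return replace(self, group=group)


@dataclass
class ResultRecord:
    """Per-ASV test outcome row.

    ``direction`` is +1 for enrichment in the first group level (sorted
    order), -1 for the second, 0 when not detected.
    """

    asv_id: str
    detected: bool
    direction: int
    iteration_detected: Optional[int]
    da_final: float
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.direction == 0) == self.detected:
            raise ValidationError("direction must be 0 iff not detected")
        if (self.iteration_detected is not None) != self.detected:
            raise ValidationError("iteration_detected present iff detected")
        if not -1.0 <= self.da_final <= 1.0:
            raise ValidationError("da_final outside [-1, 1]")


def read_counts(path, fmt: str = "auto") -> AsvTable:
    """Read a count table from TSV (samples x ASVs) or BIOM (v1 JSON / v2.1 HDF5).

    All-zero ASV columns are dropped with a warning.  The returned table has
    no group labels attached.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "biom" if path.suffix.lower() == ".biom" else "tsv"
    if fmt == "tsv":
        table = _read_counts_tsv(path)
    elif fmt == "biom":
        table = _read_counts_biom(path)
    else:
        raise ValueError(f"unknown count-table format {fmt!r}")
    return table.drop_empty_asvs()


def _read_counts_tsv(path: Path) -> AsvTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"cannot parse count TSV {path}: {exc}") from exc
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValidationError(f"missing value in count TSV {path}, sample {row!r}")
    values = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce")
    if numeric.isna().any():
        bad = values.ravel()[numeric.isna().to_numpy()][0]
        raise ValidationError(f"non-numeric count {bad!r} in {path}")
    counts = numeric.to_numpy(dtype=float).reshape(values.shape)
    if np.any(counts < 0):
        raise ValidationError(f"negative count in {path}")
    if not np.array_equal(counts, np.round(counts)):
        raise ValidationError(f"non-integer count in {path}")
    return AsvTable(
        counts=counts.astype(np.int64),
        sample_ids=[str(s) for s in df.index],
        asv_ids=[str(a) for a in df.columns],
    )


def _read_counts_biom(path: Path) -> AsvTable:
    # v2.1 files are HDF5; v1 is JSON. Both store observations x samples.
    if h5py.is_hdf5(path):
        return _read_biom_hdf5(path)
    return _read_biom_json(path)


def _read_biom_hdf5(path: Path) -> AsvTable:
    with h5py.File(path, "r") as f:
        asv_ids = [x.decode() if isinstance(x, bytes) else str(x)
                   for x in f["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x)
                      for x in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        data = grp["data"][:]
        indices = grp["indices"][:]
        indptr = grp["indptr"][:]
    from scipy.sparse import csr_matrix

    mat = csr_matrix(
        (data, indices, indptr), shape=(len(asv_ids), len(sample_ids))
    ).toarray()
    return AsvTable(counts=mat.T, sample_ids=sample_ids, asv_ids=asv_ids)


def _read_biom_json(path: Path) -> AsvTable:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"cannot parse BIOM JSON {path}: {exc}") from exc
    try:
        asv_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        n_obs, n_samp = doc["shape"]
        mat = np.zeros((n_obs, n_samp))
        if doc["matrix_type"] == "dense":
            mat[:] = np.asarray(doc["data"], dtype=float)
        else:
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed BIOM JSON {path}: {exc}") from exc
    return AsvTable(counts=mat.T, sample_ids=sample_ids, asv_ids=asv_ids)


def read_fasta_sequences(path) -> dict[str, str]:
    """Read FASTA into ``{record_id: uppercase sequence}``.

    Record id is the token before the first whitespace.  Duplicate ids and
    characters outside {A,C,G,T,N} raise :class:`ValidationError`.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValidationError(f"duplicate FASTA record id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValidationError(
                f"record {record.id!r} contains invalid characters {sorted(bad)}"
            )
        sequences[record.id] = seq
    return sequences


def check_sequences_cover_table(table: AsvTable, sequences: dict[str, str]) -> None:
    """Ensure every ASV in the table has a sequence; extras are ignored."""
    missing = [a for a in table.asv_ids if a not in sequences]
    if missing:
        raise ValidationError(f"ASVs missing from FASTA: {missing}")


def read_metadata(path, group_column: str) -> dict[str, str]:
    """Read a sample-metadata TSV (first column = sample id) and return the
    requested group column as ``{sample_id: label}``.

    Restriction to the samples of a count table and the two-level check
    happen in :func:`attach_groups`, once the table is known.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if group_column not in df.columns:
        raise ValidationError(
            f"group column {group_column!r} not in metadata columns {list(df.columns)}"
        )
    return {str(s): str(v) for s, v in df[group_column].items()}


def attach_groups(table: AsvTable, labels: dict[str, str]) -> AsvTable:
    """Restrict metadata labels to the table's samples and attach them.

    Raises unless exactly two levels remain, each with >= 2 samples.
    """
    return table.with_group(labels)


def read_taxonomy(path) -> dict[str, dict[str, str]]:
    """Optional taxonomy TSV (first column ASV id); used only to label output."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    return {str(a): {str(c): str(v) for c, v in row.items()} for a, row in df.iterrows()}


RESULT_COLUMNS = ["asv_id", "detected", "direction", "iteration_detected", "da_final"]


def write_results(records: list[ResultRecord], path) -> None:
    """Write results as TSV in input order; taxonomy ranks appended as columns."""
    tax_ranks: list[str] = []
    for rec in records:
        for rank in rec.taxonomy:
            if rank not in tax_ranks:
                tax_ranks.append(rank)
    rows = []
    for rec in records:
        row = {
            "asv_id": rec.asv_id,
            "detected": rec.detected,
            "direction": rec.direction,
            "iteration_detected": (
                "" if rec.iteration_detected is None else rec.iteration_detected
            ),
            "da_final": repr(rec.da_final),
        }
        for rank in tax_ranks:
            row[rank] = rec.taxonomy.get(rank, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS + tax_ranks)
    df.to_csv(path, sep="\t", index=False)


def read_results(path) -> list[ResultRecord]:
    """Parse a TSV written by :func:`write_results` back into records."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    tax_ranks = [c for c in df.columns if c not in RESULT_COLUMNS]
    for _, row in df.iterrows():
        detected = row["detected"] == "True"
        records.append(
            ResultRecord(
                asv_id=row["asv_id"],
                detected=detected,
                direction=int(row["direction"]),
                iteration_detected=(
                    int(row["iteration_detected"]) if detected else None
                ),
                da_final=float(row["da_final"]),
                taxonomy={r: row[r] for r in tax_ranks if row[r] != ""},
            )
        )
    return records
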