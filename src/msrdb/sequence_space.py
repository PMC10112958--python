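"""Metric-space embedding of ASV sequences.

Sequences are embedded as k-mer frequency profiles (default k=5) and compared
with Euclidean distance, which is alignment-free and satisfies the metric
axioms.  The embedding lives behind this module so an alternative metric can
be swapped in without touching the aggregation or testing code.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

DEFAULT_KMER_K = 5


def kmer_order(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order (profile coordinate order)."""
    return ["".join(p) for p in product("ACGT", repeat=k)]


def kmer_profile(sequence: str, k: int = DEFAULT_KMER_K) -> np.ndarray:
    """k-mer frequency vector of a DNA string over the 4^k lexicographic k-mers.

    Windows containing ``N`` are skipped.  The vector sums to 1 when at least
    one valid window exists.

    Raises
    ------
    ValueError
        If the sequence is shorter than ``k``.
    """
    if k < 1:
        raise ValueError("k must be positive")
    sequence = sequence.upper()
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} < k={k}")
    counts = np.zeros(4**k)
    # rolling base-4 encoding; restart after any N
    code = 0
    valid = 0  # number of consecutive valid bases ending here
    mask = 4 ** (k - 1)
    for base in sequence:
        idx = _BASE_INDEX.get(base)
        if idx is None:
            code, valid = 0, 0
            continue
        code = (code % mask) * 4 + idx
        valid += 1
        if valid >= k:
            counts[code] += 1
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


@dataclass
class DistanceIndex:
    """Pairwise distances plus per-ASV full sorted neighbor lists.

    ``neighbor_order[i]`` holds the indices of all other ASVs sorted by
    increasing distance to ASV ``i``, ties broken by ASV-id lexicographic
    order for bit-reproducibility.
    """

    asv_ids: list[str]
    distance: np.ndarray
    neighbor_order: np.ndarray

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def index_of(self, asv_id: str) -> int:
        try:
            return self.asv_ids.index(asv_id)
        except ValueError:
            raise KeyError(asv_id) from None


def build_distance_index(profiles: dict[str, np.ndarray]) -> DistanceIndex:
    """Build the full Euclidean distance matrix and sorted neighbor lists."""
    asv_ids = list(profiles)
    if len(asv_ids) < 2:
        raise ValueError("need at least 2 ASVs to build a distance index")
    mat = np.asarray([profiles[a] for a in asv_ids], dtype=float)
    if mat.ndim != 2:
        raise ValueError("profiles must share one dimension")
    dist = squareform(pdist(mat, metric="euclidean"))
    # lexicographic rank of each id, used as the secondary sort key
    id_rank = np.argsort(np.argsort(np.array(asv_ids, dtype=object)))
    n = len(asv_ids)
    order = np.empty((n, n - 1), dtype=np.int64)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        keys = np.lexsort((id_rank[others], dist[i, others]))
        order[i] = others[keys]
    return DistanceIndex(asv_ids=asv_ids, distance=dist, neighbor_order=order)


def neighborhood(index: DistanceIndex, asv_id: str, k: int) -> tuple[list[str], float]:
    """The ``k`` nearest ASVs to ``asv_id`` (excluding itself) and the radius
    (distance to the k-th neighbor)."""
    if not 1 <= k <= index.n_asvs - 1:
        raise ValueError(f"k={k} out of range [1, {index.n_asvs - 1}]")
    i = index.index_of(asv_id)
    nn = index.neighbor_order[i, :k]
    radius = float(index.distance[i, nn[-1]])
    return [index.asv_ids[j] for j in nn], radius


def cluster_asvs(
    index: DistanceIndex,
    subset: list[str],
    linkage_cutoff: float | None = None,
) -> dict[str, int]:
    """Average-linkage clustering of a subset of ASVs, cut at ``linkage_cutoff``.

    Default cutoff is the median pairwise distance within the subset.  Labels
    are consecutive integers starting at 1, ordered by cluster size
    descending (ties by first member position).
    """
    if not subset:
        raise ValueError("subset must be nonempty")
    if len(subset) == 1:
        return {subset[0]: 1}
    idx = [index.index_of(a) for a in subset]
    sub = index.distance[np.ix_(idx, idx)]
    condensed = squareform(sub, checks=False)
    if linkage_cutoff is None:
        linkage_cutoff = float(np.median(condensed))
    Z = linkage(condensed, method="average")
    raw = fcluster(Z, t=linkage_cutoff, criterion="distance")
    # relabel by size descending, ties by earliest member
    labels = np.unique(raw)
    first_pos = {lab: int(np.argmax(raw == lab)) for lab in labels}
    ordered = sorted(labels, key=lambda lab: (-int((raw == lab).sum()), first_pos[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(ordered)}
    return {a: remap[lab] for a, lab in zip(subset, raw)}


def profiles_for(sequences: dict[str, str], k: int = DEFAULT_KMER_K) -> dict[str, np.ndarray]:
    """k-mer profiles for a map of sequences, preserving input order."""
    return {a: kmer_profile(s, k) for a, s in sequences.items()}
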