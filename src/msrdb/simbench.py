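"""Synthetic clustered ASV data with planted signal, plus a benchmark harness.

Generation model: cluster ancestor sequences are uniform random DNA; each ASV
is its cluster ancestor with i.i.d. per-base substitutions.  Baseline absolute
abundances are log-normal; truth ASVs are multiplied by a fold change in
group 2; optional per-ASV log-normal measurement bias multiplies both groups
identically.  Sample totals are Poisson around the target depth (scaled by
``depth_ratio`` in group 2) and counts are multinomial.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .asv_io import AsvTable
from .pipeline import PipelineOutput, run_test
from .ps_aggregation import PSConfig
from .weighted_rdb import RDBConfig, TestResult

_BASES = np.array(list("ACGT"))

GROUP_LABELS = ("g1", "g2")


@dataclass
class SimulationConfig:
    n_asv: int = 100
    n_clusters: int = 10
    seq_length: int = 250
    mutation_rate: float = 0.02
    n_per_group: tuple[int, int] = (50, 50)
    depth: float = 10_000.0
    depth_ratio: float = 1.0
    base_abundance: float = 1.0
    da_clusters: tuple[int, ...] = (1, 2)
    da_fraction_within: float = 1.0
    fold_change: float = 4.0
    fold_change_per_cluster: dict[int, float] = field(default_factory=dict)
    bias_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asv < self.n_clusters:
            raise ValueError("n_asv must be >= n_clusters")
        if self.fold_change <= 0 or any(
            f <= 0 for f in self.fold_change_per_cluster.values()
        ):
            raise ValueError("fold changes must be > 0")
        if not 0 < self.da_fraction_within <= 1:
            raise ValueError("da_fraction_within must be in (0, 1]")
        if not set(self.da_clusters) <= set(range(1, self.n_clusters + 1)):
            raise ValueError("da_clusters must be within 1..n_clusters")

    def fold_for(self, cluster: int) -> float:
        return self.fold_change_per_cluster.get(cluster, self.fold_change)


@dataclass
class SimulatedDataset:
    table: AsvTable
    sequences: dict[str, str]
    truth: set[str]
    truth_direction: dict[str, int]
    cluster_of: dict[str, int]


def _asv_id(i: int) -> str:
    return f"asv{i + 1:04d}"


def simulate_sequences(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], dict[str, int]]:
    """Clustered random sequences: per-cluster ancestor plus point mutations.

    ASVs are assigned to clusters round-robin (cluster ids 1-based).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ancestors = rng.integers(0, 4, size=(cfg.n_clusters, cfg.seq_length))
    sequences: dict[str, str] = {}
    cluster_of: dict[str, int] = {}
    for i in range(cfg.n_asv):
        c = i % cfg.n_clusters
        seq = ancestors[c].copy()
        mutate = rng.random(cfg.seq_length) < cfg.mutation_rate
        # substitute to a uniformly random *different* base
        shifts = rng.integers(1, 4, size=int(mutate.sum()))
        seq[mutate] = (seq[mutate] + shifts) % 4
        asv = _asv_id(i)
        sequences[asv] = "".join(_BASES[seq])
        cluster_of[asv] = c + 1
    return sequences, cluster_of


def _truth_set(cfg: SimulationConfig, cluster_of: dict[str, int]) -> set[str]:
    truth: set[str] = set()
    for c in cfg.da_clusters:
        members = [a for a, cl in cluster_of.items() if cl == c]
        n_da = int(round(cfg.da_fraction_within * len(members)))
        truth.update(members[:n_da])
    return truth


def simulate_counts(
    cfg: SimulationConfig,
    sequences: dict[str, str],
    cluster_of: dict[str, int],
    rng: Optional[np.random.Generator] = None,
) -> SimulatedDataset:
    """Draw compositional counts with the configured planted signal."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    asv_ids = list(sequences)
    n = len(asv_ids)
    baseline = rng.lognormal(mean=0.0, sigma=cfg.base_abundance, size=n)
    truth = _truth_set(cfg, cluster_of)

    fold = np.ones(n)
    for j, a in enumerate(asv_ids):
        if a in truth:
            fold[j] = cfg.fold_for(cluster_of[a])
    if cfg.fold_change == 1.0 and not cfg.fold_change_per_cluster:
        truth = set()  # fold 1 plants no signal: global null
        fold[:] = 1.0

    abund1 = baseline.copy()
    abund2 = baseline * fold
    if cfg.bias_sigma > 0:
        bias = rng.lognormal(mean=0.0, sigma=cfg.bias_sigma, size=n)
        abund1 = abund1 * bias
        abund2 = abund2 * bias
    prob1 = abund1 / abund1.sum()
    prob2 = abund2 / abund2.sum()

    n1, n2 = cfg.n_per_group
    counts = np.zeros((n1 + n2, n), dtype=np.int64)
    sample_ids = []
    group = []
    for i in range(n1 + n2):
        in_g2 = i >= n1
        depth = cfg.depth * (cfg.depth_ratio if in_g2 else 1.0)
        total = 0
        while total == 0:  # zero-total samples are invalid upstream
            total = rng.poisson(depth)
        counts[i] = rng.multinomial(total, prob2 if in_g2 else prob1)
        sample_ids.append(f"S{i + 1:04d}")
        group.append(GROUP_LABELS[1] if in_g2 else GROUP_LABELS[0])
    table = AsvTable(
        counts=counts,
        sample_ids=sample_ids,
        asv_ids=asv_ids,
        group=np.array(group, dtype=object),
    ).drop_empty_asvs()
    # truth direction: fold > 1 enriches group 2 => group1 - group2 < 0
    direction = {
        a: (-1 if cfg.fold_for(cluster_of[a]) > 1 else 1) for a in truth
    }
    truth = truth & set(table.asv_ids)
    return SimulatedDataset(
        table=table,
        sequences={a: sequences[a] for a in table.asv_ids},
        truth=truth,
        truth_direction={a: d for a, d in direction.items() if a in truth},
        cluster_of=cluster_of,
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Sequences plus counts from one config, fully determined by cfg.seed."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_seq, rng_cnt = (np.random.default_rng(s) for s in ss.spawn(2))
    sequences, cluster_of = simulate_sequences(cfg, rng_seq)
    return simulate_counts(cfg, sequences, cluster_of, rng_cnt)


def apply_column_bias(table: AsvTable, factors: np.ndarray) -> np.ndarray:
    """Relative abundances after per-ASV multiplicative measurement bias.

    The same factor scales an ASV's counts in every sample (extraction/PCR
    efficiency), so fold changes between groups are untouched.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (table.n_asvs,) or np.any(factors <= 0):
        raise ValueError("need one positive factor per ASV")
    scaled = table.counts * factors[None, :]
    return scaled / scaled.sum(axis=1, keepdims=True)


def evaluate(result: TestResult, truth: set[str]) -> dict[str, float]:
    """Empirical FDR and power of one test result against planted truth."""
    detected = result.detected
    fdr = len(detected - truth) / max(len(detected), 1)
    power = len(detected & truth) / max(len(truth), 1)
    return {"fdr": fdr, "power": power, "n_detected": float(len(detected))}


SCENARIOS: dict[str, SimulationConfig] = {
    # global null: no planted signal
    "null": SimulationConfig(fold_change=1.0),
    # whole clusters differentially abundant, moderate signal
    "homogeneous": SimulationConfig(
        n_per_group=(20, 20), depth=2000.0, fold_change=1.4
    ),
    # half of each signal cluster's members carry the signal
    "interleaved": SimulationConfig(da_fraction_within=0.5, fold_change=4.0),
    # per-ASV multiplicative measurement bias, identical across samples
    "biased": SimulationConfig(
        n_per_group=(20, 20), depth=2000.0, fold_change=1.4, bias_sigma=1.0
    ),
    # group 2 sequenced at half depth
    "unbalanced_depth": SimulationConfig(
        n_per_group=(20, 20), depth=2000.0, fold_change=1.4, depth_ratio=0.5
    ),
}


def scenario_config(name: str, **overrides) -> SimulationConfig:
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    return replace(SCENARIOS[name], **overrides)


_METHOD_RE = re.compile(r"^(msrdb|rdb|knn)(\d+)?$")


def method_config(method: str) -> PSConfig:
    """Parse a method name like ``msrdb``, ``rdb``, ``knn20`` into a PSConfig."""
    m = _METHOD_RE.match(method)
    if not m:
        raise ValueError(f"unknown method {method!r}")
    mode, k = m.group(1), m.group(2)
    k_max = int(k) if k else 10
    return PSConfig(mode=mode, k_max=k_max)


def rep_seed(master_seed: int, rep: int) -> int:
    """Deterministic per-replicate seed derived from the master seed."""
    return int(
        np.random.SeedSequence([master_seed, rep]).generate_state(1, np.uint32)[0]
    )


def run_methods_on(
    ds: SimulatedDataset, methods: list[str], alpha: float = 0.05
) -> dict[str, PipelineOutput]:
    out = {}
    for method in methods:
        out[method] = run_test(
            ds.table,
            ds.sequences,
            ps_cfg=method_config(method),
            rdb_cfg=RDBConfig(alpha=alpha),
        )
    return out


def run_benchmark(
    scenario: str | SimulationConfig,
    methods: list[str],
    reps: int,
    seed: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tidy table of per-replicate FDR/power for each method on one scenario."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = scenario_config(scenario) if isinstance(scenario, str) else scenario
    name = scenario if isinstance(scenario, str) else "custom"
    rows = []
    for rep in range(reps):
        ds = simulate_dataset(replace(cfg, seed=rep_seed(seed, rep)))
        outputs = run_methods_on(ds, methods, alpha=alpha)
        for method, out in outputs.items():
            metrics = evaluate(out.result, ds.truth)
            rows.append(
                {"scenario": name, "method": method, "rep": rep, **metrics}
            )
    return pd.DataFrame(rows)


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Means with Monte-Carlo standard errors per (scenario, method)."""
    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        return pd.Series(
            {
                "reps": n,
                "fdr_mean": g["fdr"].mean(),
                "fdr_se": g["fdr"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "power_mean": g["power"].mean(),
                "power_se": g["power"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )

    return (
        df.groupby(["scenario", "method"])[["fdr", "power"]]
        .apply(_agg)
        .reset_index()
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Write counts.tsv, sequences.fasta, metadata.tsv and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        ds.table.counts, index=ds.table.sample_ids, columns=ds.table.asv_ids
    ).rename_axis("sample_id").to_csv(out / "counts.tsv", sep="\t")
    with open(out / "sequences.fasta", "w") as fh:
        for a, s in ds.sequences.items():
            fh.write(f">{a}\n{s}\n")
    pd.DataFrame(
        {"sample_id": ds.table.sample_ids, "group": list(ds.table.group)}
    ).to_csv(out / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "asv_id": ds.table.asv_ids,
            "is_da": [a in ds.truth for a in ds.table.asv_ids],
            "direction": [ds.truth_direction.get(a, 0) for a in ds.table.asv_ids],
            "cluster": [ds.cluster_of[a] for a in ds.table.asv_ids],
        }
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
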