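"""Multiscale adaptive aggregation weights (propagation-separation stage).

For each ASV s and each neighbor s' within its current k-NN, the raw weight is

    w(s; s') = Ks(d(s, s') / r_s) * Ka(|DA(s) - DA(s')| / h)

where Ks is a spatial kernel on sequence distance with per-ASV adaptive
radius r_s (the distance to the k-th neighbor), Ka is an adaptive kernel on
the difference of estimated differential-abundance levels, and

    DA(s) = (P1w(s) - P2w(s)) / (P1w(s) + P2w(s))

is a robust fold-change coefficient computed from weighted group means of
relative abundance.  Weights and DA depend on each other, so they are updated
together over a geometrically growing schedule of neighborhood sizes; only
ASVs with similar DA levels end up aggregated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse

from .asv_io import AsvTable
from .sequence_space import DistanceIndex

logger = logging.getLogger(__name__)

Mode = Literal["msrdb", "rdb", "knn"]

# tiny radius inflation so the k-th neighbor keeps a ~0 but defined
# triangular weight and duplicate sequences (r == 0) avoid 0/0
_RADIUS_EPS = 1e-9


@dataclass
class PSConfig:
    """Tuning parameters of the aggregation stage.

    ``mode='rdb'`` degenerates to identity weights (vanilla test);
    ``mode='knn'`` keeps spatial weights but disables the adaptive kernel.
    """

    k_max: int = 10
    growth: float = 1.25
    # Bandwidth of the adaptive kernel on the DA-difference scale.  Must be
    # well below the DA gap between signal and null ASVs: aggregated DA is an
    # abundance-weighted mean, so even a percent of leaked weight onto a
    # high-abundance neighbor with different DA cascades across scales.
    h: float = 0.1
    spatial_kernel: Literal["triangular", "epanechnikov"] = "triangular"
    adaptive_kernel: Literal["gaussian", "exponential"] = "gaussian"
    mode: Mode = "msrdb"

    def __post_init__(self) -> None:
        if self.mode == "rdb":
            self.k_max = 1
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.growth <= 1:
            raise ValueError("growth must be > 1")
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.spatial_kernel not in ("triangular", "epanechnikov"):
            raise ValueError(f"unknown spatial kernel {self.spatial_kernel!r}")
        if self.adaptive_kernel not in ("gaussian", "exponential"):
            raise ValueError(f"unknown adaptive kernel {self.adaptive_kernel!r}")
        if self.mode not in ("msrdb", "rdb", "knn"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def schedule(self, n_asvs: int) -> list[int]:
        """Strictly increasing neighbor counts k_1=1 < ... <= k_max.

        k_{t+1} = min(k_max, ceil(k_t * growth)); counts are capped at
        n_asvs - 1 neighbors.
        """
        cap = min(self.k_max, n_asvs - 1)
        if self.k_max > n_asvs - 1:
            logger.warning(
                "k_max=%d exceeds n_asvs-1=%d; clipping", self.k_max, n_asvs - 1
            )
        if self.mode == "rdb":
            return []
        if self.mode == "knn":
            # spatial weights do not depend on DA, so one scale suffices
            return [cap]
        ks = [1]
        while ks[-1] < cap:
            ks.append(min(cap, math.ceil(ks[-1] * self.growth)))
        return ks


@dataclass
class IterationTrace:
    """Per-scale diagnostics of the PS loop."""

    k: list[int] = field(default_factory=list)
    mean_row_entropy: list[float] = field(default_factory=list)
    da_quantiles: list[tuple[float, float, float]] = field(default_factory=list)


def relative_abundance(table: AsvTable) -> np.ndarray:
    """Per-sample relative abundances; each row sums to 1."""
    counts = np.asarray(table.counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("sample with zero total count")
    return counts / totals


def group_masks(group: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Boolean masks for the two group levels, in sorted level order."""
    group = np.asarray(group).astype(str)
    levels = sorted(set(group))
    if len(levels) != 2:
        raise ValueError(f"expected two group levels, got {levels}")
    return group == levels[0], group == levels[1], levels


def group_means(relabund: np.ndarray, group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean relative abundance per ASV within each group."""
    m1, m2, _ = group_masks(group)
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError("both groups must be nonempty")
    return relabund[m1].mean(axis=0), relabund[m2].mean(axis=0)


def weighted_group_mean(weights: sparse.spmatrix, pbar: np.ndarray) -> np.ndarray:
    """Row-stochastic propagation of a per-ASV vector: out[s] = sum_s' w(s;s') pbar[s']."""
    pbar = np.asarray(pbar, dtype=float)
    if weights.shape[1] != pbar.shape[0]:
        raise ValueError(
            f"weight matrix {weights.shape} incompatible with vector {pbar.shape}"
        )
    return np.asarray(weights @ pbar).ravel()


def da_statistic(p1w: np.ndarray, p2w: np.ndarray) -> np.ndarray:
    """Robust fold-change coefficient (p1w - p2w) / (p1w + p2w) in [-1, 1].

    Defined as 0 where both inputs are 0.
    """
    p1w = np.asarray(p1w, dtype=float)
    p2w = np.asarray(p2w, dtype=float)
    if np.any(p1w < 0) or np.any(p2w < 0):
        raise ValueError("group means must be nonnegative")
    denom = p1w + p2w
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = (p1w[nz] - p2w[nz]) / denom[nz]
    return out


def _spatial_kernel(u: np.ndarray, kind: str) -> np.ndarray:
    if kind == "triangular":
        return np.clip(1.0 - u, 0.0, None)
    return np.clip(1.0 - u**2, 0.0, None)  # epanechnikov (unscaled)


def _adaptive_kernel(u: np.ndarray, kind: str) -> np.ndarray:
    if kind == "gaussian":
        return np.exp(-(u**2))
    return np.exp(-u)


def identity_weights(n: int) -> sparse.csr_matrix:
    return sparse.identity(n, format="csr")


def compute_weights(
    index: DistanceIndex,
    da: np.ndarray,
    k_t: int,
    cfg: PSConfig,
) -> sparse.csr_matrix:
    """Row-normalized weight matrix over each ASV's k_t nearest neighbors.

    The self-weight is Ks(0)*Ka(0) = 1 before normalization, so it never
    vanishes.  ``mode='knn'`` sets the adaptive kernel to 1 everywhere.
    """
    n = index.n_asvs
    if k_t < 1:
        raise ValueError("k_t must be >= 1")
    if k_t > n - 1:
        logger.warning("k_t=%d clipped to %d", k_t, n - 1)
        k_t = n - 1
    da = np.asarray(da, dtype=float)
    if da.shape != (n,):
        raise ValueError("DA profile must cover all ASVs")

    nbr = index.neighbor_order[:, :k_t]  # (n, k_t)
    rows_idx = np.repeat(np.arange(n), k_t)
    d = index.distance[rows_idx, nbr.ravel()].reshape(n, k_t)
    radius = d[:, -1:] + _RADIUS_EPS
    ks = _spatial_kernel(d / radius, cfg.spatial_kernel)
    if cfg.mode == "knn":
        ka = np.ones_like(ks)
    else:
        dd = np.abs(da[:, None] - da[nbr])
        ka = _adaptive_kernel(dd / cfg.h, cfg.adaptive_kernel)
    raw = ks * ka

    # assemble rows: self weight 1 plus neighbor weights, then normalize
    cols = np.concatenate([np.arange(n)[:, None], nbr], axis=1)
    vals = np.concatenate([np.ones((n, 1)), raw], axis=1)
    vals /= vals.sum(axis=1, keepdims=True)
    mat = sparse.csr_matrix(
        (vals.ravel(), (np.repeat(np.arange(n), k_t + 1), cols.ravel())),
        shape=(n, n),
    )
    mat.sum_duplicates()
    return mat


def _row_entropy(weights: sparse.csr_matrix) -> float:
    vals = weights.data[weights.data > 0]
    rows = np.repeat(
        np.arange(weights.shape[0]), np.diff(weights.indptr)
    )[weights.data > 0]
    ent = np.zeros(weights.shape[0])
    np.add.at(ent, rows, -vals * np.log(vals))
    return float(ent.mean())


def ps_iterate(
    table: AsvTable,
    index: DistanceIndex,
    cfg: PSConfig,
    group: np.ndarray | None = None,
) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray, IterationTrace]:
    """Run the PS loop; returns (final weights, weighted table, final DA, trace).

    The weighted table propagates each sample's relative-abundance row
    through the final weights: q_i(s) = sum_s' w(s; s') p_i(s').
    """
    if group is None:
        group = table.group
    if group is None:
        raise ValueError("group labels required")
    if index.asv_ids != table.asv_ids:
        raise ValueError("distance index ASV order must match the count table")
    return ps_iterate_from_relabund(relative_abundance(table), index, cfg, group)


def ps_iterate_from_relabund(
    p: np.ndarray,
    index: DistanceIndex,
    cfg: PSConfig,
    group: np.ndarray,
) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray, IterationTrace]:
    """PS loop on an already-normalized samples x ASVs matrix."""
    p = np.asarray(p, dtype=float)
    n = p.shape[1]
    pbar1, pbar2 = group_means(p, group)
    da = da_statistic(pbar1, pbar2)
    weights = identity_weights(n)
    trace = IterationTrace()
    for k_t in cfg.schedule(n):
        weights = compute_weights(index, da, k_t, cfg)
        da = da_statistic(
            weighted_group_mean(weights, pbar1),
            weighted_group_mean(weights, pbar2),
        )
        q10, q50, q90 = np.quantile(da, [0.1, 0.5, 0.9])
        trace.k.append(k_t)
        trace.mean_row_entropy.append(_row_entropy(weights))
        trace.da_quantiles.append((float(q10), float(q50), float(q90)))
    weighted_table = np.asarray((weights @ p.T).T)
    return weights, weighted_table, da, trace
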