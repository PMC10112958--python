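"""Glue from validated inputs to per-ASV results."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .asv_io import AsvTable, ResultRecord, check_sequences_cover_table
from .ps_aggregation import (
    IterationTrace,
    PSConfig,
    ps_iterate_from_relabund,
    relative_abundance,
)
from .sequence_space import DEFAULT_KMER_K, build_distance_index, profiles_for
from .weighted_rdb import RDBConfig, TestResult, rdb_iterate


@dataclass
class PipelineOutput:
    result: TestResult
    da_final: np.ndarray
    trace: IterationTrace
    asv_ids: list[str]

    def to_records(
        self, taxonomy: Optional[dict[str, dict[str, str]]] = None
    ) -> list[ResultRecord]:
        records = []
        for j, asv in enumerate(self.asv_ids):
            det = asv in self.result.detected
            records.append(
                ResultRecord(
                    asv_id=asv,
                    detected=det,
                    direction=self.result.direction.get(asv, 0),
                    iteration_detected=self.result.iteration_detected.get(asv),
                    da_final=float(np.clip(self.da_final[j], -1.0, 1.0)),
                    taxonomy=(taxonomy or {}).get(asv, {}),
                )
            )
        return records


def run_test(
    table: AsvTable,
    sequences: dict[str, str],
    ps_cfg: Optional[PSConfig] = None,
    rdb_cfg: Optional[RDBConfig] = None,
    kmer_k: int = DEFAULT_KMER_K,
) -> PipelineOutput:
    """Full pipeline: embed sequences, run PS aggregation, run the test."""
    if table.group is None:
        raise ValueError("table must carry group labels")
    check_sequences_cover_table(table, sequences)
    return run_test_from_relabund(
        relative_abundance(table),
        sequences,
        table.asv_ids,
        table.group,
        ps_cfg=ps_cfg,
        rdb_cfg=rdb_cfg,
        kmer_k=kmer_k,
    )


def run_test_from_relabund(
    relabund: np.ndarray,
    sequences: dict[str, str],
    asv_ids: list[str],
    group: np.ndarray,
    ps_cfg: Optional[PSConfig] = None,
    rdb_cfg: Optional[RDBConfig] = None,
    kmer_k: int = DEFAULT_KMER_K,
) -> PipelineOutput:
    """Pipeline entry for an already-normalized samples x ASVs matrix."""
    ps_cfg = ps_cfg or PSConfig()
    rdb_cfg = rdb_cfg or RDBConfig()
    profiles = profiles_for({a: sequences[a] for a in asv_ids}, kmer_k)
    index = build_distance_index(profiles)
    _, weighted, da, trace = ps_iterate_from_relabund(relabund, index, ps_cfg, group)
    result = rdb_iterate(weighted, group, asv_ids, rdb_cfg)
    return PipelineOutput(result=result, da_final=da, trace=trace, asv_ids=asv_ids)
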