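"""End-to-end orchestration shared by the CLI, tests and scripts."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .adjacency import (
    AdjacencyResult,
    ScoringConfig,
    adjacency_score,
    build_descending_matrix,
)
from .motif_io import FrequencyMatrix
from .peaks_windows import PeakRecord, SequenceWindow, extract_windows
from .synthetic_data import SyntheticDataset

__all__ = [
    "score_windows",
    "score_genome",
    "windows_from_dataset",
    "results_frame",
]

log = logging.getLogger(__name__)


def score_windows(
    windows: Sequence[SequenceWindow],
    motifs: Sequence[FrequencyMatrix],
    cfg: ScoringConfig,
) -> list[AdjacencyResult]:
    """Adjacency score of every motif over a shared window set."""
    if not motifs:
        raise ValueError("no motifs to score")
    results = []
    for motif in motifs:
        bsm = build_descending_matrix(windows, motif, cfg)
        results.append(adjacency_score(bsm, cfg, motif_id=motif.motif_id))
    return results


def score_genome(
    genome: Mapping[str, object],
    peaks: Sequence[PeakRecord],
    motifs: Sequence[FrequencyMatrix],
    cfg: ScoringConfig,
) -> list[AdjacencyResult]:
    """Extract flanked ±m windows and score all motifs.

    The flank equals the longest motif, so every placement whose center lies
    within the ±m span is scored and all distance bins fill evenly.
    """
    if not motifs:
        raise ValueError("no motifs to score")
    flank = max(m.length for m in motifs)
    windows = extract_windows(genome, peaks, m=cfg.m, flank=flank)
    if not windows:
        raise ValueError("no usable windows: all peaks skipped")
    return score_windows(windows, motifs, cfg)


def windows_from_dataset(ds: SyntheticDataset, cfg: ScoringConfig):
    """Flanked windows for an in-memory synthetic dataset."""
    genome = {ds.spec.chrom: ds.contig}
    peaks = [PeakRecord(ds.spec.chrom, p) for p in ds.peak_positions]
    flank = max(m.length for m in ds.motifs)
    return extract_windows(genome, peaks, m=cfg.m, flank=flank)


def results_frame(results: Sequence[AdjacencyResult]) -> pd.DataFrame:
    """Score table: motif_id, S, S1, S2, t_star, r, b, n — descending S."""
    df = pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in results],
            "S": [r.score for r in results],
            "S1": [r.s1 for r in results],
            "S2": [r.s2 for r in results],
            "t_star": [r.t_star for r in results],
            "r": [r.r for r in results],
            "b": [r.b for r in results],
            "n": [r.n for r in results],
        }
    )
    return df.sort_values(["S", "motif_id"], ascending=[False, True], ignore_index=True)
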