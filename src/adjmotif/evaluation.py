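"""Motif ranking and ROC/AUC evaluation against binary motif labels.

Candidate motifs are ranked by their adjacency score S.  Given a labelling
of motifs (or motif families) as positive / negative for the ChIPed factor,
the ranked list is evaluated with the area under the ROC curve; ties in S
count 1/2, the Mann-Whitney convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .adjacency import AdjacencyResult

__all__ = [
    "MotifRanking",
    "LabelSet",
    "rank_motifs",
    "roc_auc",
    "roc_points",
    "group_by_family",
    "family_auc",
    "read_labels",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifRanking:
    """Motifs in non-increasing score order; ties break lexicographically."""

    motif_ids: tuple[str, ...]
    scores: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.motif_ids)

    def rank_of(self, motif_id: str) -> int:
        """1-based rank of a motif in the list."""
        return self.motif_ids.index(motif_id) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "motif_id": self.motif_ids,
                "score": self.scores,
            }
        )


@dataclass(frozen=True)
class LabelSet:
    """Binary labels (True = positive) and optional family per motif."""

    labels: Mapping[str, bool]
    families: Mapping[str, str] | None = None

    def family_of(self, motif_id: str) -> str:
        if self.families and self.families.get(motif_id):
            return self.families[motif_id]
        return motif_id  # unannotated motifs are their own singleton family


def rank_motifs(results: Sequence[AdjacencyResult | tuple[str, float]]) -> MotifRanking:
    """Stable descending sort by adjacency score; ties by motif id."""
    if not results:
        raise ValueError("cannot rank an empty result list")
    pairs = [
        (r.motif_id, float(r.score)) if isinstance(r, AdjacencyResult) else (r[0], float(r[1]))
        for r in results
    ]
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate motif ids in ranking input: {dupes}")
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return MotifRanking(
        motif_ids=tuple(p[0] for p in pairs),
        scores=tuple(p[1] for p in pairs),
    )


def _scores_and_truth(ranking: MotifRanking, labels: LabelSet):
    y_true, y_score, dropped = [], [], []
    lab = labels.labels
    for mid, s in zip(ranking.motif_ids, ranking.scores):
        if mid in lab:
            y_true.append(bool(lab[mid]))
            y_score.append(s)
        else:
            dropped.append(mid)
    if dropped:
        log.warning("%d ranked motif(s) without labels were excluded", len(dropped))
    if not any(y_true) or all(y_true):
        raise ValueError(
            "AUC undefined: need at least one positive and one negative labeled motif"
        )
    return np.asarray(y_true, dtype=int), np.asarray(y_score, dtype=float)


def roc_auc(ranking: MotifRanking, labels: LabelSet) -> float:
    """Area under the ROC curve of the ranking (ties count 1/2)."""
    y_true, y_score = _scores_and_truth(ranking, labels)
    return float(roc_auc_score(y_true, y_score))


def roc_points(ranking: MotifRanking, labels: LabelSet) -> pd.DataFrame:
    """Empirical ROC curve points: FPR, TPR, threshold."""
    y_true, y_score = _scores_and_truth(ranking, labels)
    fpr, tpr, thr = roc_curve(y_true, y_score)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def group_by_family(ranking: MotifRanking, labels: LabelSet) -> pd.DataFrame:
    """Best (smallest) rank and best score per motif family.

    Motifs without a family annotation form singleton families under their
    own id.  The returned frame also carries the family label when every
    member agrees (mixed families are labelled positive if any member is).
    """
    rows = []
    for rank0, (mid, s) in enumerate(zip(ranking.motif_ids, ranking.scores)):
        rows.append(
            {
                "motif_id": mid,
                "family": labels.family_of(mid),
                "rank": rank0 + 1,
                "score": s,
                "positive": labels.labels.get(mid),
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("family", sort=False)
        .agg(
            best_rank=("rank", "min"),
            best_score=("score", "max"),
            n_motifs=("motif_id", "size"),
            positive=("positive", lambda s: bool(s.any()) if s.notna().any() else None),
        )
        .reset_index()
        .sort_values("best_rank", ignore_index=True)
    )
    return out


def family_auc(ranking: MotifRanking, labels: LabelSet) -> float:
    """AUC over families, each represented by its best member score."""
    fam = group_by_family(ranking, labels).dropna(subset=["positive"])
    y = fam["positive"].astype(bool)
    if y.nunique() < 2:
        raise ValueError("family AUC undefined: need positive and negative families")
    return float(roc_auc_score(y.astype(int), fam["best_score"]))


def read_labels(path) -> LabelSet:
    """Read a label TSV: motif_id, family, label in {pos, neg}.

    A two-column file (motif_id, label) is accepted; family defaults to the
    motif id.
    """
    labels: dict[str, bool] = {}
    families: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if lineno == 1 and fields[0].lower() in ("motif_id", "motif"):
                continue
            if len(fields) == 2:
                mid, fam, lab = fields[0], "", fields[1]
            elif len(fields) >= 3:
                mid, fam, lab = fields[0], fields[1], fields[2]
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
            lab_norm = lab.strip().lower()
            if lab_norm in ("pos", "positive", "1", "true"):
                value = True
            elif lab_norm in ("neg", "negative", "0", "false"):
                value = False
            else:
                raise ValueError(f"{path}:{lineno}: unknown label {lab!r}")
            if mid in labels:
                raise ValueError(f"{path}:{lineno}: duplicate motif id {mid!r}")
            labels[mid] = value
            if fam:
                families[mid] = fam
    return LabelSet(labels=labels, families=families or None)
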