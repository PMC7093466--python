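"""Benchmarking interaction metrics against gold-standard labels.

Implements the headline procedures of the analysis: ROC / precision–
recall curves and AUC per metric, calibration of the distance cutoff
achieving a target false-discovery rate among labeled complex-member
pairs, novel-interaction calling (close in the embedding yet weakly
correlated, so invisible to the classical PCC approach), per-complex
co-clustering concordance, and overlap between two clusterings.

ROC and PR are built from first principles so the tie convention is
pinned and oracle-testable: tied scores form a single curve step, and
the trapezoidal AUC then equals the Mann–Whitney estimator with ties
counted half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster import ClusterAssignment
from .dataio import ComplexCatalog
from .score import LabeledPairs

__all__ = [
    "ROCResult",
    "PRResult",
    "FDRCutoff",
    "ConcordanceReport",
    "OverlapReport",
    "roc",
    "pr_curve",
    "fdr_cutoff",
    "call_novel",
    "complex_concordance",
    "clustering_overlap",
]

LOWER = "lower_is_hit"  # distances: small score = predicted interaction
HIGHER = "higher_is_hit"  # correlations: large score = predicted interaction


def direction_for(metric: str) -> str:
    """Conventional direction: distances are lower-is-hit, pcc higher."""
    return HIGHER if metric == "pcc" else LOWER


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    metric: str
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass
class PRResult:
    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    area: float
    metric: str
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "recall": self.recall,
                "precision": self.precision,
            }
        )


@dataclass
class FDRCutoff:
    """Loosest distance threshold keeping labeled-pair FDR <= alpha."""

    alpha: float
    threshold: float | None  # None when no threshold qualifies
    achieved_fdr: float | None
    n_called: int

    @property
    def found(self) -> bool:
        return self.threshold is not None


def _hit_scores(
    pairs: LabeledPairs, metric: str, direction: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labeled scores oriented so that larger = predicted interaction."""
    if direction not in (LOWER, HIGHER):
        raise ValueError(f"direction must be {LOWER!r} or {HIGHER!r}")
    labeled = pairs.labeled()
    ok = labeled[metric].notna()
    labeled = labeled[ok]
    raw = labeled[metric].to_numpy(float)
    y = labeled["label"].astype(bool).to_numpy()
    oriented = -raw if direction == LOWER else raw
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError(
            f"metric {metric!r}: need at least one positive and one negative"
        )
    return oriented, raw, y


def _curve_counts(oriented: np.ndarray, y: np.ndarray):
    """Cumulative TP/FP at each distinct threshold, loosening left→right."""
    order = np.argsort(-oriented, kind="stable")
    scores = oriented[order]
    hits = y[order].astype(int)
    # last index of each tie block
    distinct = np.nonzero(np.diff(scores))[0]
    block_ends = np.r_[distinct, len(scores) - 1]
    tp = np.cumsum(hits)[block_ends]
    fp = (block_ends + 1) - tp
    return scores[block_ends], tp, fp


def roc(pairs: LabeledPairs, metric: str, direction: str | None = None) -> ROCResult:
    """ROC curve and trapezoidal AUC for one metric.

    The curve has one point per distinct score; tied positives and
    negatives share a step, so the trapezoid across a tie block
    contributes half — the AUC equals the Mann–Whitney U estimator
    with ties half-weighted.
    """
    direction = direction or direction_for(metric)
    oriented, _, y = _hit_scores(pairs, metric, direction)
    thr_oriented, tp, fp = _curve_counts(oriented, y)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.r_[np.nan, -thr_oriented if direction == LOWER else thr_oriented]
    return ROCResult(thresholds, fpr, tpr, auc, metric, n_pos, n_neg)


def pr_curve(
    pairs: LabeledPairs, metric: str, direction: str | None = None
) -> PRResult:
    """Precision/recall at every distinct threshold, step-wise area.

    Area is the step integral Σ (R_i − R_{i−1})·P_i over the curve
    from strictest to loosest threshold (average-precision form);
    recall reaches 1.0 at the loosest threshold.
    """
    direction = direction or direction_for(metric)
    oriented, _, y = _hit_scores(pairs, metric, direction)
    thr_oriented, tp, fp = _curve_counts(oriented, y)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    recall = tp / n_pos
    precision = tp / (tp + fp)
    area = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    thresholds = -thr_oriented if direction == LOWER else thr_oriented
    return PRResult(thresholds, recall, precision, area, metric, n_pos, n_neg)


def fdr_cutoff(
    pairs: LabeledPairs, metric: str = "umap_dist", alpha: float = 0.05
) -> FDRCutoff:
    """Distance threshold achieving FDR <= alpha among labeled pairs.

    Candidate thresholds are the observed labeled distances; at each
    t, FDR(t) = FP / (TP + FP) over labeled pairs called at distance
    <= t. Returns the largest qualifying t. Calibration uses labeled
    pairs only; unlabeled candidates are scored against the resulting
    threshold elsewhere but never enter it.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    oriented, raw, y = _hit_scores(pairs, metric, LOWER)
    order = np.argsort(raw, kind="stable")
    d = raw[order]
    hits = y[order].astype(int)
    distinct = np.nonzero(np.diff(d))[0]
    block_ends = np.r_[distinct, len(d) - 1]
    tp = np.cumsum(hits)[block_ends]
    called = block_ends + 1
    fdr = (called - tp) / called
    ok = np.nonzero(fdr <= alpha)[0]
    if len(ok) == 0:
        return FDRCutoff(alpha=alpha, threshold=None, achieved_fdr=None, n_called=0)
    best = ok[-1]
    return FDRCutoff(
        alpha=alpha,
        threshold=float(d[block_ends[best]]),
        achieved_fdr=float(fdr[best]),
        n_called=int(called[best]),
    )


def call_novel(
    pairs: LabeledPairs,
    threshold: float,
    metric: str = "umap_dist",
    pcc_max: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Pairs close in the embedding yet weakly correlated.

    A pair is called when its distance is <= `threshold` (closed, the
    FDR-calibrated cutoff) and its profile correlation is < `pcc_max`
    (open) — interactions the classical pairwise-correlation approach
    would not have confidently called. Pairs with missing PCC are
    excluded and counted. Returns the called rows (with their label
    status) and summary counts.
    """
    table = pairs.table
    has_pcc = table["pcc"].notna()
    called = table[
        has_pcc & (table[metric] <= threshold) & (table["pcc"] < pcc_max)
    ].copy()
    genes = sorted(set(called.gene_a) | set(called.gene_b))
    label = called["label"]
    summary = {
        "n_called": int(len(called)),
        "n_unique_genes": len(genes),
        "n_called_labeled_true": int((label == True).sum()),  # noqa: E712
        "n_called_labeled_false": int((label == False).sum()),  # noqa: E712
        "n_called_unlabeled": int(label.isna().sum()),
        "n_missing_pcc": int((~has_pcc).sum()),
    }
    return called.reset_index(drop=True), summary


@dataclass
class ConcordanceReport:
    """Per-complex co-clustering of members, plus totals.

    A complex is eligible when >= 2 members are in the strain
    universe, and co-clustered when some cluster contains >= 2 of its
    members. `member_fraction` is members-in-best-cluster over
    members-in-universe (the per-complex annotation fraction).
    """

    per_complex: pd.DataFrame
    n_eligible: int
    n_co_clustered: int

    @property
    def fraction_co_clustered(self) -> float:
        return self.n_co_clustered / self.n_eligible if self.n_eligible else 0.0


def complex_concordance(
    catalog: ComplexCatalog,
    assignment: ClusterAssignment,
    universe: list[str] | set[str] | None = None,
    level: str = "sub",
) -> ConcordanceReport:
    """Which complexes have >= 2 members sharing a cluster.

    `level` selects main clusters or the finest (sub) level.
    """
    if level not in ("main", "sub"):
        raise ValueError("level must be 'main' or 'sub'")
    labels = (
        assignment.main_labels() if level == "main" else assignment.sub_labels()
    )
    universe = set(universe) if universe is not None else set(labels)
    rows = []
    n_eligible = n_co = 0
    for cid in sorted(catalog.members):
        present = sorted(g for g in catalog.members[cid] if g in universe and g in labels)
        if len(present) < 2:
            rows.append((cid, len(present), 0, False, None, np.nan))
            continue
        n_eligible += 1
        counts: dict = {}
        for g in present:
            counts[labels[g]] = counts.get(labels[g], 0) + 1
        best_cluster, best = max(counts.items(), key=lambda kv: (kv[1], str(kv[0])))
        co = best >= 2
        n_co += co
        rows.append(
            (cid, len(present), best, co, best_cluster, best / len(present))
        )
    per_complex = pd.DataFrame(
        rows,
        columns=[
            "complex_id",
            "members_in_universe",
            "max_in_one_cluster",
            "co_clustered",
            "best_cluster",
            "member_fraction",
        ],
    )
    return ConcordanceReport(per_complex, n_eligible, n_co)


@dataclass
class OverlapReport:
    """Best-match containment of clustering A's clusters in B's.

    For each A-cluster, the best-matching B-cluster maximizes
    |A_i ∩ B_j| and the overlap fraction is that intersection over
    |A_i| ("perfect" = 1.0, A-cluster wholly inside one B-cluster);
    the Jaccard index with the same best match is reported alongside,
    and the adjusted Rand index summarizes the whole pair of
    partitions.
    """

    per_cluster: pd.DataFrame
    n_perfect: int
    n_half: int  # clusters with overlap fraction >= 0.5
    ari: float


def clustering_overlap(
    A: ClusterAssignment, B: ClusterAssignment
) -> OverlapReport:
    """Compare two clusterings of the same strain universe."""
    if set(A.strains) != set(B.strains):
        raise ValueError("clusterings cover different strain universes")
    a_labels = A.main_labels()
    b_labels = B.main_labels()
    strains = sorted(a_labels)
    a_members: dict[int, set[str]] = {}
    for s, lab in a_labels.items():
        a_members.setdefault(lab, set()).add(s)
    b_members: dict[int, set[str]] = {}
    for s, lab in b_labels.items():
        b_members.setdefault(lab, set()).add(s)
    rows = []
    for lab in sorted(a_members):
        members = a_members[lab]
        best_lab, best_inter = None, -1
        for blab in sorted(b_members):
            inter = len(members & b_members[blab])
            if inter > best_inter:
                best_lab, best_inter = blab, inter
        fraction = best_inter / len(members)
        jaccard = best_inter / len(members | b_members[best_lab])
        rows.append((lab, len(members), best_lab, fraction, jaccard))
    per_cluster = pd.DataFrame(
        rows,
        columns=["cluster", "size", "best_match", "overlap_fraction", "jaccard"],
    )
    ari = float(
        adjusted_rand_score(
            [a_labels[s] for s in strains], [b_labels[s] for s in strains]
        )
    )
    return OverlapReport(
        per_cluster=per_cluster,
        n_perfect=int((per_cluster.overlap_fraction >= 1.0).sum()),
        n_half=int((per_cluster.overlap_fraction >= 0.5).sum()),
        ari=ari,
    )
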