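"""Transcriptional divergence of paralog pairs.

Duplicated genes may retain redundant function (revealed by a
negative genetic interaction between the deletions) while diverging
in their downstream transcriptional effects. The embedding distance
between the two deletion strains of a paralog pair quantifies that
transcriptional divergence; this module relates it to externally
supplied divergence metrics and genetic-interaction (GI) scores, and
flags discordant "divergent-yet-redundant" pairs: strong negative GI
but far apart in the embedding.

Thresholds for "strong negative GI" (`gi_threshold`) and "far apart"
(`distance_quantile` of all paralog distances) are explicit
conventions, not literature values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ParalogTable
from .reduce import Embedding
from .score import pair_embedding_distance, pair_profile_correlation

__all__ = [
    "ParalogReport",
    "paralog_distances",
    "metric_correlation",
    "flag_divergent_redundant",
    "build_report",
]

DEFAULT_GI_THRESHOLD = -0.5
DEFAULT_DISTANCE_QUANTILE = 0.75


@dataclass
class ParalogReport:
    """Per-pair distances, correlations and the divergent-redundant flag."""

    table: pd.DataFrame  # gene_a, gene_b, umap_dist [, pcc, divergence_metric,
    #                      gi_score, divergent_redundant]
    dropped: int = 0

    def __len__(self) -> int:
        return len(self.table)


def paralog_distances(
    embedding: Embedding, paralogs: ParalogTable
) -> tuple[pd.Series, int]:
    """Embedded Euclidean distance per paralog pair (absent pairs counted)."""
    return pair_embedding_distance(embedding, paralogs.pairs)


def metric_correlation(
    distances: pd.Series, metric_values: pd.Series
) -> tuple[float, int]:
    """Pearson R between paralog distances and an external divergence metric.

    Only pairs with both values contribute; fewer than 3 complete
    pairs is an error (the correlation would be meaningless).
    """
    distances = pd.Series(distances).astype(float)
    metric_values = pd.Series(metric_values).astype(float)
    complete = distances.notna() & metric_values.notna()
    n = int(complete.sum())
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, got {n}")
    r = stats.pearsonr(distances[complete], metric_values[complete]).statistic
    return float(r), n


def flag_divergent_redundant(
    report: pd.DataFrame,
    gi_threshold: float = DEFAULT_GI_THRESHOLD,
    distance_quantile: float = DEFAULT_DISTANCE_QUANTILE,
    distance_col: str = "umap_dist",
) -> pd.Series:
    """Flag pairs with strong negative GI yet large embedded distance.

    A pair is flagged when gi_score <= `gi_threshold` AND its distance
    exceeds the `distance_quantile` quantile of all paralog distances
    with data. Raising the quantile can only shrink the flag set.
    Pairs missing either value are never flagged.
    """
    if "gi_score" not in report.columns:
        raise ValueError("report has no gi_score column")
    dist = report[distance_col].astype(float)
    gi = report["gi_score"].astype(float)
    cutoff = dist.dropna().quantile(distance_quantile)
    return (gi <= gi_threshold) & (dist > cutoff) & dist.notna() & gi.notna()


def build_report(
    embedding: Embedding,
    paralogs: ParalogTable,
    X=None,
    gi_threshold: float = DEFAULT_GI_THRESHOLD,
    distance_quantile: float = DEFAULT_DISTANCE_QUANTILE,
) -> ParalogReport:
    """Assemble the full per-pair paralog report.

    Columns: embedded distance, profile PCC (when `X` given), any
    external divergence metric and GI score carried on the input
    table, and the divergent-redundant flag (only when GI scores are
    present).
    """
    table = paralogs.pairs.copy()
    dist, dropped = paralog_distances(embedding, paralogs)
    table[f"{embedding.method}_dist"] = dist
    if X is not None:
        table["pcc"], _ = pair_profile_correlation(X, table)
    if paralogs.has_gi:
        table["divergent_redundant"] = flag_divergent_redundant(
            table,
            gi_threshold=gi_threshold,
            distance_quantile=distance_quantile,
            distance_col=f"{embedding.method}_dist",
        )
    table = table[dist.notna()].reset_index(drop=True)
    return ParalogReport(table=table, dropped=dropped)
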