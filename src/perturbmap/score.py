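"""Per-pair interaction scores and the labeled pair table.

For every candidate gene pair the benchmark needs (a) Euclidean
distance between the two strains in each embedding and (b) the
Pearson correlation of their full deletion transcriptomes — the
classical interaction metric the embedding distance is compared
against. This module computes those scores and assembles the labeled
pair table that all benchmarking consumes.

Pairs whose strains are absent from an embedding or matrix are
dropped and counted, never silently; missing metric values propagate
as NaN, never as 0 (a zero distance means "co-located", the opposite
of unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, InteractionSet
from .reduce import Embedding

__all__ = [
    "LabeledPairs",
    "pair_embedding_distance",
    "pair_profile_correlation",
    "assemble_labeled_pairs",
    "all_pairs",
    "profile_correlation_matrix",
    "read_labeled_pairs",
    "write_labeled_pairs",
]

#: pair-table label values: True/False for gold-standard pairs, NaN for
#: unlabeled candidates appended for novel-interaction calling
LABEL_COLUMN = "label"


@dataclass
class LabeledPairs:
    """One row per canonical gene pair with label and metric columns.

    `label` is boolean (True/False) for labeled pairs and NaN for
    unlabeled candidates. Metric columns are named `<method>_dist`
    (Euclidean embedding distances, >= 0) plus `pcc` in [-1, 1].
    `dropped` counts pairs excluded per metric because a strain was
    absent.
    """

    table: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not {"gene_a", "gene_b"}.issubset(self.table.columns):
            raise ValueError("pair table needs gene_a, gene_b")
        self.table = self.table.sort_values(["gene_a", "gene_b"]).reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def metrics(self) -> list[str]:
        return [
            c
            for c in self.table.columns
            if c not in ("gene_a", "gene_b", LABEL_COLUMN)
        ]

    def labeled(self) -> pd.DataFrame:
        return self.table[self.table[LABEL_COLUMN].notna()]

    def unlabeled(self) -> pd.DataFrame:
        return self.table[self.table[LABEL_COLUMN].isna()]


def all_pairs(strain_ids: list[str]) -> pd.DataFrame:
    """All unordered strain pairs in canonical order."""
    ids = sorted(strain_ids)
    i, j = np.triu_indices(len(ids), k=1)
    arr = np.asarray(ids, dtype=object)
    return pd.DataFrame({"gene_a": arr[i], "gene_b": arr[j]})


def pair_embedding_distance(
    embedding: Embedding, pairs: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Euclidean distance between each pair's embedded coordinates.

    Returns a Series aligned with `pairs` (NaN where a strain is
    absent from the embedding) and the count of dropped pairs.
    """
    idx = embedding.strain_index()
    ia = pairs["gene_a"].map(idx)
    ib = pairs["gene_b"].map(idx)
    present = ia.notna() & ib.notna()
    out = pd.Series(np.nan, index=pairs.index, dtype=float)
    if present.any():
        a_idx = ia[present].astype(int).to_numpy()
        b_idx = ib[present].astype(int).to_numpy()
        out[present] = _gathered_distances(embedding.coords, a_idx, b_idx)
    return out, int((~present).sum())


def _gathered_distances(
    coords: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray
) -> np.ndarray:
    """Euclidean distances for index pairs under a fixed memory budget.

    For few pairs (or low dimension) the coordinate differences are
    gathered in blocks sized to ~16M floats; when the pair list is
    dense relative to the strain count and the dimension is high, the
    full strain × strain distance matrix is computed once instead.
    Never materializes an (n_pairs × dims) intermediate.
    """
    n, d = coords.shape
    if len(a_idx) * d > n * n and d > 2:
        from scipy.spatial.distance import pdist, squareform

        full = squareform(pdist(coords))
        return full[a_idx, b_idx]
    block = max(1, int(16_000_000 // max(d, 1)))
    out = np.empty(len(a_idx))
    for start in range(0, len(a_idx), block):
        sl = slice(start, start + block)
        diff = coords[a_idx[sl]] - coords[b_idx[sl]]
        out[sl] = np.linalg.norm(diff, axis=1)
    return out


def profile_correlation_matrix(X: ExpressionMatrix) -> np.ndarray:
    """Strain × strain Pearson correlation of expression profiles.

    Rows with zero variance get NaN correlations. Works on the
    strains × genes matrix directly (never materializes genes × genes
    intermediates), so memory is O(n_strains²).
    """
    values = X.values
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = norms.copy()
    safe[safe == 0] = 1.0
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[norms == 0, :] = np.nan
    corr[:, norms == 0] = np.nan
    return np.clip(corr, -1.0, 1.0, out=corr)


def pair_profile_correlation(
    X: ExpressionMatrix, pairs: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Pearson correlation of the two strains' profiles, per pair.

    Zero-variance profiles yield NaN (undefined correlation); absent
    strains are dropped and counted.
    """
    idx = X.strain_index()
    ia = pairs["gene_a"].map(idx)
    ib = pairs["gene_b"].map(idx)
    present = ia.notna() & ib.notna()
    out = pd.Series(np.nan, index=pairs.index, dtype=float)
    if present.any():
        corr = profile_correlation_matrix(X)
        out[present] = corr[
            ia[present].astype(int).to_numpy(), ib[present].astype(int).to_numpy()
        ]
    return out, int((~present).sum())


def assemble_labeled_pairs(
    interactions: InteractionSet,
    embeddings: list[Embedding],
    X: ExpressionMatrix | None = None,
    unlabeled_pairs: pd.DataFrame | None = None,
) -> LabeledPairs:
    """Join labels with every available metric into one pair table.

    Labeled pairs come from `interactions`; `unlabeled_pairs`
    (canonical gene_a/gene_b frame) may be appended for
    novel-interaction calling with label NaN. Each embedding
    contributes a `<method>_dist` column; `X` contributes `pcc`.
    Output order is canonical, independent of input order.
    """
    labeled = interactions.pairs[["gene_a", "gene_b", "label"]].copy()
    labeled["label"] = labeled["label"].astype(object)
    frames = [labeled]
    if unlabeled_pairs is not None and len(unlabeled_pairs):
        extra = unlabeled_pairs[["gene_a", "gene_b"]].copy()
        if (extra.gene_a == extra.gene_b).any():
            raise ValueError("self-pair among unlabeled candidates")
        swap = extra.gene_a > extra.gene_b
        extra.loc[swap, ["gene_a", "gene_b"]] = extra.loc[
            swap, ["gene_b", "gene_a"]
        ].to_numpy()
        extra = extra.drop_duplicates(subset=["gene_a", "gene_b"])
        extra = extra.merge(
            labeled[["gene_a", "gene_b"]],
            on=["gene_a", "gene_b"],
            how="left",
            indicator=True,
        )
        extra = extra[extra["_merge"] == "left_only"].drop(columns="_merge")
        extra["label"] = np.nan
        frames.append(extra)
    table = pd.concat(frames, ignore_index=True)

    dropped: dict[str, int] = {}
    n_metrics = 0
    for emb in embeddings:
        col = f"{emb.method}_dist"
        table[col], dropped[col] = pair_embedding_distance(emb, table)
        n_metrics += 1
    if X is not None:
        table["pcc"], dropped["pcc"] = pair_profile_correlation(X, table)
        n_metrics += 1
    if n_metrics == 0:
        raise ValueError("no metric provided (no embeddings and no matrix)")
    metric_cols = [c for c in table.columns if c.endswith("_dist") or c == "pcc"]
    all_missing = table[metric_cols].isna().all(axis=1)
    table = table[~all_missing].reset_index(drop=True)
    return LabeledPairs(table, dropped=dropped)


def write_labeled_pairs(pairs: LabeledPairs, path: str | Path) -> None:
    out = pairs.table.copy()
    out[LABEL_COLUMN] = out[LABEL_COLUMN].map(
        {True: "true", False: "false", np.nan: "unlabeled"}
    )
    out[LABEL_COLUMN] = out[LABEL_COLUMN].fillna("unlabeled")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_labeled_pairs(path: str | Path) -> LabeledPairs:
    df = pd.read_csv(path, sep="\t")
    mapping = {"true": True, "false": False, "unlabeled": np.nan}
    df[LABEL_COLUMN] = df[LABEL_COLUMN].map(mapping)
    return LabeledPairs(df)
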