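"""On-disk formats and validated in-memory containers.

Every table the pipeline touches is plain TSV (tab-separated, UTF-8,
'.' decimal, no quoting). Readers validate and reject malformed input
rather than coercing it; write→read round-trips are identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ComplexCatalog",
    "InteractionSet",
    "ParalogTable",
    "ParseError",
    "canonical_pair",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_complex_catalog",
    "write_complex_catalog",
    "read_pair_labels",
    "write_pair_labels",
    "read_paralog_table",
    "write_paralog_table",
    "catalog_to_pairs",
]


class ParseError(ValueError):
    """Raised when an on-disk table violates its contract."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered gene pair lexicographically.

    All modules store and exchange pairs in this canonical order, so a
    pair has exactly one representation throughout the pipeline.
    """
    if a == b:
        raise ParseError(f"self-pair not allowed: ({a}, {b})")
    return (a, b) if a < b else (b, a)


@dataclass
class ExpressionMatrix:
    """Strains (deleted genes) × measured genes, log-ratio scale.

    Rows are single-gene deletion strains identified by the deleted
    gene; columns are measured transcripts. Values are unitless
    expression effects (log ratios vs wild type).
    """

    strain_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # shape (n_strains, n_genes), float

    def __post_init__(self) -> None:
        self.strain_ids = list(self.strain_ids)
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ParseError("duplicate strain ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ParseError("duplicate gene ids")
        if len(self.strain_ids) < 2 or len(self.gene_ids) < 2:
            raise ParseError("need at least 2 strains and 2 genes")
        if self.values.shape != (len(self.strain_ids), len(self.gene_ids)):
            raise ParseError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.strain_ids)} strains × {len(self.gene_ids)} genes"
            )
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite value at strain {self.strain_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def strain_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.strain_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.strain_ids, columns=self.gene_ids
        )

    def subset(self, strains: list[str]) -> "ExpressionMatrix":
        idx = self.strain_index()
        rows = [idx[s] for s in strains]
        return ExpressionMatrix(strains, self.gene_ids, self.values[rows])


@dataclass
class ComplexCatalog:
    """Protein-complex catalog: complex id → member gene ids.

    Membership sets may overlap across complexes (a gene can sit in
    several complexes); every complex is nonempty.
    """

    members: dict[str, set[str]]

    def __post_init__(self) -> None:
        for cid, genes in self.members.items():
            if not genes:
                raise ParseError(f"complex {cid!r} has no members")
            self.members[cid] = set(genes)

    def __len__(self) -> int:
        return len(self.members)

    def genes(self) -> set[str]:
        return set().union(*self.members.values()) if self.members else set()


@dataclass
class InteractionSet:
    """Unordered gene pairs with boolean interaction labels.

    Pairs are stored canonically (lexicographic order), one row per
    pair, no self-pairs. `source` tags where the labels came from
    (e.g. a gold-standard database or the synthetic ground truth).
    """

    pairs: pd.DataFrame  # columns: gene_a, gene_b, label(bool)
    source: str = "unknown"

    def __post_init__(self) -> None:
        df = self.pairs.reset_index(drop=True)
        required = {"gene_a", "gene_b", "label"}
        if not required.issubset(df.columns):
            raise ParseError(f"pair table needs columns {sorted(required)}")
        canon = [canonical_pair(a, b) for a, b in zip(df.gene_a, df.gene_b)]
        df = df.assign(
            gene_a=[p[0] for p in canon], gene_b=[p[1] for p in canon]
        )
        dup = df.duplicated(subset=["gene_a", "gene_b"])
        if dup.any():
            a, b = df.loc[dup.idxmax(), ["gene_a", "gene_b"]]
            raise ParseError(f"duplicate pair after canonicalization: ({a}, {b})")
        df["label"] = df["label"].astype(bool)
        self.pairs = df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_positive(self) -> int:
        return int(self.pairs.label.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.pairs.label).sum())


@dataclass
class ParalogTable:
    """Paralogous gene pairs with optional divergence / GI columns.

    `divergence_metric` is any externally supplied numeric divergence
    estimate; `gi_score` is a genetic-interaction score where negative
    values indicate a synthetic-lethal-like (redundant) relationship.
    Either column may be absent — absent means "not provided", never
    zero-filled.
    """

    pairs: pd.DataFrame  # columns: gene_a, gene_b [, divergence_metric, gi_score]

    def __post_init__(self) -> None:
        df = self.pairs.reset_index(drop=True)
        if not {"gene_a", "gene_b"}.issubset(df.columns):
            raise ParseError("paralog table needs columns gene_a, gene_b")
        canon = [canonical_pair(a, b) for a, b in zip(df.gene_a, df.gene_b)]
        df = df.assign(
            gene_a=[p[0] for p in canon], gene_b=[p[1] for p in canon]
        )
        if df.duplicated(subset=["gene_a", "gene_b"]).any():
            raise ParseError("duplicate paralog pair after canonicalization")
        for col in ("divergence_metric", "gi_score"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="raise")
        self.pairs = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def has_gi(self) -> bool:
        return "gi_score" in self.pairs.columns

    @property
    def has_divergence(self) -> bool:
        return "divergence_metric" in self.pairs.columns


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a strain × gene TSV (header = gene ids, first column = strain ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate strain id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            raise ParseError(
                f"{path}: non-numeric or missing value {bad.iloc[0]!r} at "
                f"strain {row!r}, gene {col!r}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: missing value at strain {df.index[i]!r}, gene {df.columns[j]!r}"
        )
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression_matrix(X: ExpressionMatrix, path: str | Path) -> None:
    X.to_frame().to_csv(path, sep="\t", index_label="strain")


def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    """Read a two-column TSV (complex_id, gene_id) with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
    if df.isna().any().any():
        raise ParseError(f"{path}: missing value in catalog")
    members: dict[str, set[str]] = {}
    for cid, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        members.setdefault(cid, set()).add(gene)
    return ComplexCatalog(members)


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    rows = [
        (cid, g)
        for cid in sorted(catalog.members)
        for g in sorted(catalog.members[cid])
    ]
    pd.DataFrame(rows, columns=["complex_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


_LABEL_TOKENS = {"true": True, "false": False, "1": True, "0": False}


def read_pair_labels(path: str | Path, source: str = "file") -> InteractionSet:
    """Read a three-column TSV (gene_a, gene_b, label) with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 3:
        raise ParseError(f"{path}: expected 3 columns, got {df.shape[1]}")
    df.columns = ["gene_a", "gene_b", "label"]
    labels = []
    for tok in df["label"]:
        key = str(tok).strip().lower()
        if key not in _LABEL_TOKENS:
            raise ParseError(f"{path}: unknown label token {tok!r}")
        labels.append(_LABEL_TOKENS[key])
    df["label"] = labels
    return InteractionSet(df, source=source)


def write_pair_labels(interactions: InteractionSet, path: str | Path) -> None:
    out = interactions.pairs.copy()
    out["label"] = out["label"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


def read_paralog_table(path: str | Path) -> ParalogTable:
    """Read paralog pairs: gene_a, gene_b [, divergence_metric, gi_score]."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise ParseError(f"{path}: need header columns gene_a, gene_b")
    keep = ["gene_a", "gene_b"] + [
        c for c in ("divergence_metric", "gi_score") if c in df.columns
    ]
    return ParalogTable(df[keep])


def write_paralog_table(table: ParalogTable, path: str | Path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def catalog_to_pairs(
    catalog: ComplexCatalog,
    universe: list[str] | set[str],
    negatives_from_full_universe: bool = False,
) -> InteractionSet:
    """Turn a complex catalog into labeled gene pairs over a strain universe.

    Positives are all within-complex pairs whose two genes are both in
    `universe`. Negatives default to all remaining pairs among genes
    that carry at least one complex annotation (and are in `universe`);
    set `negatives_from_full_universe` to draw negatives from every
    universe gene instead. Restricting negatives to annotated genes
    avoids labeling never-studied genes as non-interacting.
    """
    universe = set(universe)
    annotated = catalog.genes() & universe
    positives: set[tuple[str, str]] = set()
    for genes in catalog.members.values():
        present = sorted(genes & universe)
        positives.update(
            canonical_pair(a, b) for a, b in itertools.combinations(present, 2)
        )
    negative_pool = sorted(universe if negatives_from_full_universe else annotated)
    rows = [(a, b, True) for a, b in sorted(positives)]
    for a, b in itertools.combinations(negative_pool, 2):
        if (a, b) not in positives:
            rows.append((a, b, False))
    if not annotated:
        import warnings

        warnings.warn("complex catalog has no genes in the universe", stacklevel=2)
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"])
    return InteractionSet(df, source="complex_catalog")
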