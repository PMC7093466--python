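"""Dimensionality reduction of the strain × gene matrix.

The interaction metric downstream is Euclidean distance between
strains in a low-dimensional embedding, so every reduction method
compared by the benchmark lives here behind one `Embedding` contract:
UMAP on PCA scores (the primary method), tSNE, raw PCA coordinates, a
seeded random orthonormal projection (Johnson–Lindenstrauss baseline),
and an identity "highdim" view that lets the scoring code treat raw
gene space uniformly.

UMAP and tSNE are library primitives (umap-learn, scikit-learn); this
module pins their parameters, seeding and output contracts rather than
re-implementing the optimizers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dataio import ExpressionMatrix

__all__ = [
    "ReduceParams",
    "Embedding",
    "pca_scores",
    "embed_umap",
    "embed_tsne",
    "embed_random_projection",
    "highdim_view",
    "read_embedding",
    "write_embedding",
]


@dataclass
class ReduceParams:
    """Embedding parameters.

    Defaults follow the reference analysis: 100 principal components
    feed UMAP (25 for sub-clustering), cosine metric, n_neighbors=10,
    min_dist=0.05, 2-D output.
    """

    n_pcs_main: int = 100
    n_pcs_sub: int = 25
    umap_metric: str = "cosine"
    n_neighbors: int = 10
    min_dist: float = 0.05
    out_dims: int = 2
    tsne_perplexity: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.out_dims < 1:
            raise ValueError("out_dims must be >= 1")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")


@dataclass
class Embedding:
    """Per-strain coordinates under a named reduction method."""

    strain_ids: list[str]
    coords: np.ndarray  # (n_strains, out_dims)
    method: str  # umap | tsne | pca | random_projection | highdim

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.strain_ids):
            raise ValueError("coords must be (n_strains, out_dims)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite embedding coordinate")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def out_dims(self) -> int:
        return self.coords.shape[1]

    def strain_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.strain_ids)}


def pca_scores(
    X: ExpressionMatrix, n_components: int, scale: bool = False
) -> Embedding:
    """Principal-component scores of the gene-centered matrix.

    Components are ordered by decreasing explained variance. The sign
    of each component is fixed (largest-magnitude loading positive) so
    repeated runs are deterministic. Input is gene-centered but, by
    default, not scaled: expression effects already share a common
    log-ratio scale.
    """
    max_rank = min(X.n_strains - 1, X.n_genes)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds rank bound {max_rank} "
            f"for {X.n_strains} strains × {X.n_genes} genes"
        )
    values = X.values
    if scale:
        sd = values.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=0)) / sd
    svd_solver = "randomized" if min(X.n_strains, X.n_genes) > 500 else "full"
    pca = PCA(n_components=n_components, svd_solver=svd_solver, random_state=0)
    scores = pca.fit_transform(values)
    # sign convention: flip so each component's largest-|loading| is positive
    flip = np.sign(
        pca.components_[
            np.arange(n_components), np.abs(pca.components_).argmax(axis=1)
        ]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    return Embedding(list(X.strain_ids), scores, method="pca")


def embed_umap(scores: Embedding, params: ReduceParams) -> Embedding:
    """UMAP projection of PCA scores to `out_dims` dimensions.

    Seeded via `params.seed`; with a fixed seed, umap-learn runs
    single-threaded and coordinates are reproducible on the same
    platform and library version.
    """
    import umap  # deferred: numba compilation makes this import heavy

    if scores.n_strains < params.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={params.n_neighbors + 1} strains, "
            f"got {scores.n_strains}"
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn")
        reducer = umap.UMAP(
            n_components=params.out_dims,
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            metric=params.umap_metric,
            random_state=params.seed,
        )
        coords = reducer.fit_transform(scores.coords)
    return Embedding(list(scores.strain_ids), np.asarray(coords, float), "umap")


def embed_tsne(scores: Embedding, params: ReduceParams) -> Embedding:
    """tSNE projection of PCA scores (perplexity capped below n/3)."""
    from sklearn.manifold import TSNE

    if scores.n_strains < params.n_neighbors + 1:
        raise ValueError("too few strains for tSNE")
    perplexity = min(params.tsne_perplexity, (scores.n_strains - 1) / 3.0)
    tsne = TSNE(
        n_components=params.out_dims,
        perplexity=perplexity,
        init="pca",
        random_state=params.seed,
    )
    coords = tsne.fit_transform(scores.coords)
    return Embedding(list(scores.strain_ids), np.asarray(coords, float), "tsne")


def embed_random_projection(
    X: ExpressionMatrix, out_dims: int, seed: int
) -> Embedding:
    """Random orthonormal projection (Johnson–Lindenstrauss baseline).

    Coordinates are X·R where R (genes × out_dims) has orthonormal
    columns obtained by QR-factorizing a seeded Gaussian matrix.
    """
    if out_dims < 1:
        raise ValueError("out_dims must be >= 1")
    if out_dims > X.n_genes:
        raise ValueError("out_dims exceeds number of genes")
    rng = np.random.default_rng(seed)
    gaussian = rng.normal(size=(X.n_genes, out_dims))
    R, _ = np.linalg.qr(gaussian)
    return Embedding(list(X.strain_ids), X.values @ R, "random_projection")


def highdim_view(X: ExpressionMatrix) -> Embedding:
    """Identity wrapper: raw gene space treated as an embedding.

    Lets the benchmark compare low-dimensional distances against plain
    high-dimensional Euclidean distance through one interface.
    """
    return Embedding(list(X.strain_ids), X.values.copy(), "highdim")


def write_embedding(embedding: Embedding, path: str | Path) -> None:
    cols = (
        ["x", "y"]
        if embedding.out_dims == 2
        else [f"dim{k}" for k in range(embedding.out_dims)]
    )
    df = pd.DataFrame(embedding.coords, columns=cols)
    df.insert(0, "strain", embedding.strain_ids)
    df.to_csv(path, sep="\t", index=False)


def read_embedding(path: str | Path, method: str) -> Embedding:
    df = pd.read_csv(path, sep="\t")
    if "strain" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns strain, x, y[, ...]")
    coords = df.drop(columns="strain").to_numpy(float)
    return Embedding(list(df["strain"].astype(str)), coords, method)
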