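"""Shared fixtures: seeded synthetic runs reused across the suite.

The reference study conditions (40 complexes of 3–6 members, 200
background strains, 2000 genes, σ = 0.5) are expensive to embed, so
one session-scoped fixture runs generation → PCA → UMAP → clustering →
scoring for five seeds and every test reads from it. The paralog
planting includes discordant pairs (strong negative genetic
interaction, orthogonal signatures) so the divergence analyses are
exercised on known ground truth.
"""

from __future__ import annotations

import numpy as np
import pytest

from perturbmap.bench import complex_concordance, roc
from perturbmap.cluster import (
    ClusterParams,
    build_knn_graph,
    louvain_cluster,
    subcluster,
)
from perturbmap.reduce import ReduceParams, embed_umap, highdim_view, pca_scores
from perturbmap.score import assemble_labeled_pairs
from perturbmap.synthio import SynthConfig, generate_deleteome

SEEDS = (0, 1, 2, 3, 4)

# paralog planting: 4 discordant pairs (orthogonal signatures, strong
# negative GI), 4 redundant concordant pairs (identical signatures,
# strong negative GI), 12 pairs spread over moderate divergence with
# GI concordant with divergence
DISCORDANT = [(np.pi / 2, 1.0)] * 4
CONCORDANT_REDUNDANT = [(0.0, 1.0)] * 4
SPREAD = [(t, 1.0 - t / (np.pi / 2)) for t in np.linspace(0.1, np.pi / 3, 12)]
PLANTED_PARALOGS = DISCORDANT + CONCORDANT_REDUNDANT + SPREAD


def reference_config(seed: int) -> SynthConfig:
    """Default study conditions with the planted paralog set."""
    return SynthConfig(
        divergence_angles=tuple(t for t, _ in PLANTED_PARALOGS),
        gi_overlap=tuple(r for _, r in PLANTED_PARALOGS),
        seed=seed,
    )


def run_reference_pipeline(seed: int) -> dict:
    """Generate, embed, cluster and score one seeded replicate."""
    config = reference_config(seed)
    X, truth = generate_deleteome(config)
    reduce_params = ReduceParams(seed=seed + 1)
    scores = pca_scores(X, reduce_params.n_pcs_main)
    emb = embed_umap(scores, reduce_params)
    cluster_params = ClusterParams(seed=seed + 2)
    graph = build_knn_graph(emb, cluster_params.k_neighbors)
    assignment = louvain_cluster(graph, cluster_params.resolution, cluster_params.seed)
    assignment = subcluster(X, assignment, cluster_params, reduce_params)
    interactions = truth.interactions(X.strain_ids)
    pairs = assemble_labeled_pairs(
        interactions, [emb, highdim_view(X)], X
    )
    return {
        "config": config,
        "X": X,
        "truth": truth,
        "embedding": emb,
        "assignment": assignment,
        "pairs": pairs,
        "auc_umap": roc(pairs, "umap_dist").auc,
        "auc_highdim": roc(pairs, "highdim_dist").auc,
        "concordance": complex_concordance(
            truth.catalog(), assignment, X.strain_ids, level="sub"
        ),
    }


@pytest.fixture(scope="session")
def reference_runs() -> dict[int, dict]:
    """Five seeded replicates of the reference synthetic pipeline."""
    return {seed: run_reference_pipeline(seed) for seed in SEEDS}


@pytest.fixture(scope="session")
def reference_run(reference_runs) -> dict:
    """A single replicate for tests that need just one."""
    return reference_runs[SEEDS[0]]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
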