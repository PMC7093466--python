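"""End-to-end orchestration: simulate → embed → cluster → score → bench.

`run_all` executes every stage of the analysis on either a synthetic
compendium (planted ground truth) or user-supplied TSV inputs, writing
each intermediate as a documented TSV artifact so any stage can be
re-run from disk. All randomness derives from one master seed; a rerun
with the same config reproduces the deterministic artifacts
bit-identically (embedding coordinates additionally require the same
platform and library versions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bench, diffex, paralog
from .cluster import (
    ClusterAssignment,
    ClusterParams,
    build_knn_graph,
    louvain_cluster,
    subcluster,
    write_assignment,
)
from .dataio import (
    ComplexCatalog,
    ExpressionMatrix,
    InteractionSet,
    ParalogTable,
    catalog_to_pairs,
    read_complex_catalog,
    read_expression_matrix,
    read_pair_labels,
    read_paralog_table,
    write_expression_matrix,
    write_pair_labels,
)
from .reduce import (
    Embedding,
    ReduceParams,
    embed_random_projection,
    embed_tsne,
    embed_umap,
    highdim_view,
    pca_scores,
    write_embedding,
)
from .score import all_pairs, assemble_labeled_pairs, write_labeled_pairs
from .synthio import SynthConfig, generate_deleteome, write_ground_truth

__all__ = ["RunConfig", "StageError", "run_all", "summarize"]

logger = logging.getLogger("perturbmap")

DEFAULT_METHODS = ("umap", "tsne", "pca", "random_projection", "highdim")


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are preserved."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """One run's full configuration.

    Exactly one of `synth` (simulate inputs) or `matrix_path` (load
    user TSVs) must be set. Sub-seeds for every stochastic stage are
    derived from `seed` by fixed offsets.
    """

    outdir: str | Path = "perturbmap_run"
    seed: int = 0
    synth: SynthConfig | None = None
    matrix_path: str | Path | None = None
    catalog_path: str | Path | None = None
    pairs_path: str | Path | None = None
    paralogs_path: str | Path | None = None
    methods: tuple[str, ...] = DEFAULT_METHODS
    reduce_params: ReduceParams | None = None
    cluster_params: ClusterParams | None = None
    alpha: float = 0.05  # target FDR for the distance cutoff
    pcc_max: float = 0.5  # novel calls require pcc below this
    novel_universe: str = "all"  # 'all' or 'labeled' candidate pairs
    de_level: str = "main"  # DE per main cluster ('main') or also subs ('sub')
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.matrix_path is None):
            raise ValueError("set exactly one of synth / matrix_path")
        unknown = set(self.methods) - set(DEFAULT_METHODS)
        if unknown:
            raise ValueError(f"unknown embedding methods: {sorted(unknown)}")
        if "umap" not in self.methods:
            raise ValueError("the umap method is required (primary metric)")
        if self.synth is not None:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)
        self.reduce_params = self.reduce_params or ReduceParams(seed=self.seed + 1)
        self.cluster_params = self.cluster_params or ClusterParams(
            seed=self.seed + 2
        )

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        out["outdir"] = str(self.outdir)
        for key in ("matrix_path", "catalog_path", "pairs_path", "paralogs_path"):
            if out[key] is not None:
                out[key] = str(out[key])
        return out


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise StageError(name, exc) from exc
        logger.info("stage %-12s done in %.1fs", name, time.perf_counter() - t0)
        return result

    return wrap


def run_all(config: RunConfig) -> Path:
    """Run the whole pipeline; returns the artifact directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    # ---- inputs -----------------------------------------------------------
    truth = None
    if config.synth is not None:
        X, truth = _stage("simulate")(generate_deleteome, config.synth)
        write_expression_matrix(X, outdir / "matrix.tsv")
        write_ground_truth(truth, outdir)
        catalog = truth.catalog()
        interactions = truth.interactions(X.strain_ids)
        paralogs = truth.paralog_table()
    else:
        X = _stage("load")(read_expression_matrix, config.matrix_path)
        catalog = (
            read_complex_catalog(config.catalog_path)
            if config.catalog_path
            else None
        )
        if config.pairs_path:
            interactions = read_pair_labels(config.pairs_path)
        elif catalog is not None:
            interactions = catalog_to_pairs(catalog, X.strain_ids)
        else:
            raise StageError("load", ValueError("need pairs_path or catalog_path"))
        paralogs = (
            read_paralog_table(config.paralogs_path)
            if config.paralogs_path
            else None
        )

    # ---- embeddings -------------------------------------------------------
    rp = config.reduce_params
    n_pcs = min(rp.n_pcs_main, X.n_strains - 1, X.n_genes)
    pca_full = _stage("pca")(pca_scores, X, n_pcs)
    embeddings: dict[str, Embedding] = {}
    if "pca" in config.methods:
        embeddings["pca"] = Embedding(
            pca_full.strain_ids, pca_full.coords[:, : rp.out_dims], "pca"
        )
    if "umap" in config.methods:
        embeddings["umap"] = _stage("umap")(embed_umap, pca_full, rp)
    if "tsne" in config.methods:
        embeddings["tsne"] = _stage("tsne")(embed_tsne, pca_full, rp)
    if "random_projection" in config.methods:
        embeddings["random_projection"] = _stage("randproj")(
            embed_random_projection, X, rp.out_dims, config.seed + 3
        )
    if "highdim" in config.methods:
        embeddings["highdim"] = highdim_view(X)
    for name, emb in embeddings.items():
        if name != "highdim":  # highdim == matrix.tsv, not duplicated on disk
            write_embedding(emb, outdir / f"embedding_{name}.tsv")

    # ---- clustering -------------------------------------------------------
    cp = config.cluster_params
    graph = _stage("knn")(build_knn_graph, embeddings["umap"], cp.k_neighbors)
    assignment = _stage("louvain")(
        louvain_cluster, graph, cp.resolution, cp.seed
    )
    assignment = _stage("subcluster")(
        subcluster, X, assignment, cp, config.reduce_params
    )
    write_assignment(assignment, outdir / "clusters.tsv")

    # ---- scored pairs -----------------------------------------------------
    unlabeled = (
        all_pairs(X.strain_ids) if config.novel_universe == "all" else None
    )
    pairs = _stage("score")(
        assemble_labeled_pairs,
        interactions,
        list(embeddings.values()),
        X,
        unlabeled,
    )
    write_labeled_pairs(pairs, outdir / "scored_pairs.tsv")

    # ---- benchmarking -----------------------------------------------------
    auc_rows = []
    for metric in pairs.metrics:
        roc_res = _stage("roc")(bench.roc, pairs, metric)
        pr_res = _stage("pr")(bench.pr_curve, pairs, metric)
        roc_res.to_frame().to_csv(
            outdir / f"roc_{metric}.tsv", sep="\t", index=False
        )
        pr_res.to_frame().to_csv(
            outdir / f"pr_{metric}.tsv", sep="\t", index=False
        )
        auc_rows.append((metric, roc_res.auc, pr_res.area, roc_res.n_pos, roc_res.n_neg))
    pd.DataFrame(
        auc_rows, columns=["metric", "roc_auc", "pr_area", "n_pos", "n_neg"]
    ).to_csv(outdir / "auc_summary.tsv", sep="\t", index=False)

    cutoff = _stage("fdr")(bench.fdr_cutoff, pairs, "umap_dist", config.alpha)
    with open(outdir / "fdr_cutoff.json", "w") as fh:
        json.dump(
            {
                "alpha": cutoff.alpha,
                "threshold": cutoff.threshold,
                "achieved_fdr": cutoff.achieved_fdr,
                "n_called": cutoff.n_called,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    if cutoff.found:
        novel, novel_summary = _stage("novel")(
            bench.call_novel, pairs, cutoff.threshold, "umap_dist", config.pcc_max
        )
    else:
        novel, novel_summary = pd.DataFrame(), {"n_called": 0, "n_unique_genes": 0}
    novel.to_csv(outdir / "novel_calls.tsv", sep="\t", index=False)
    with open(outdir / "novel_summary.json", "w") as fh:
        json.dump(novel_summary, fh, indent=2, sort_keys=True)

    if catalog is not None:
        report = _stage("concordance")(
            bench.complex_concordance, catalog, assignment, X.strain_ids, "sub"
        )
        report.per_complex.to_csv(
            outdir / "complex_concordance.tsv", sep="\t", index=False
        )
        with open(outdir / "concordance_summary.json", "w") as fh:
            json.dump(
                {
                    "n_eligible": report.n_eligible,
                    "n_co_clustered": report.n_co_clustered,
                    "fraction_co_clustered": report.fraction_co_clustered,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    # overlap of the UMAP-space clustering with a PCA-space clustering
    if "pca" in embeddings:
        pca_graph = build_knn_graph(embeddings["pca"], cp.k_neighbors)
        pca_assignment = louvain_cluster(pca_graph, cp.resolution, cp.seed)
        overlap = _stage("overlap")(
            bench.clustering_overlap, assignment, pca_assignment
        )
        overlap.per_cluster.to_csv(
            outdir / "cluster_overlap.tsv", sep="\t", index=False
        )
        with open(outdir / "overlap_summary.json", "w") as fh:
            json.dump(
                {
                    "n_clusters": len(overlap.per_cluster),
                    "n_perfect": overlap.n_perfect,
                    "n_half": overlap.n_half,
                    "ari": overlap.ari,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    # ---- differential expression ------------------------------------------
    de_frames = []
    lambda_rows = []
    for cid in sorted(assignment.table.main_cluster.unique()):
        members = assignment.members(int(cid))
        if len(members) < 2 or len(members) >= X.n_strains:
            continue
        res = _stage("diffex")(diffex.cluster_de, X, assignment, int(cid))
        frame = res.table.copy()
        frame.insert(0, "cluster", cid)
        de_frames.append(frame)
        lambda_rows.append((cid, res.lambda_gc))
    if de_frames:
        pd.concat(de_frames, ignore_index=True).to_csv(
            outdir / "diffex.tsv", sep="\t", index=False, float_format="%.6g"
        )
        pd.DataFrame(lambda_rows, columns=["cluster", "lambda_gc"]).to_csv(
            outdir / "lambda_gc.tsv", sep="\t", index=False
        )

    # ---- paralogs ---------------------------------------------------------
    if paralogs is not None and len(paralogs):
        preport = _stage("paralog")(
            paralog.build_report, embeddings["umap"], paralogs, X
        )
        preport.table.to_csv(
            outdir / "paralog_report.tsv", sep="\t", index=False
        )
        psummary: dict = {"n_pairs": len(preport), "dropped": preport.dropped}
        if paralogs.has_divergence:
            try:
                r, n = paralog.metric_correlation(
                    preport.table["umap_dist"],
                    preport.table["divergence_metric"],
                )
                psummary["divergence_pearson_r"] = r
                psummary["divergence_pearson_n"] = n
            except ValueError:
                pass
        if "divergent_redundant" in preport.table.columns:
            psummary["n_divergent_redundant"] = int(
                preport.table.divergent_redundant.sum()
            )
        with open(outdir / "paralog_summary.json", "w") as fh:
            json.dump(psummary, fh, indent=2, sort_keys=True)

    # ---- manifest + summary -----------------------------------------------
    import networkx
    import scipy
    import sklearn
    import umap as umap_lib

    manifest = {
        "config": config.to_jsonable(),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "umap-learn": umap_lib.__version__,
            "networkx": networkx.__version__,
        },
        "artifacts": sorted(
            {p.name for p in outdir.iterdir() if p.is_file()}
            | {"manifest.json", "summary.md"}
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (outdir / "summary.md").write_text(summarize(outdir))
    return outdir


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing artifact: {path.name}")
    return path


def summarize(artifact_dir: str | Path) -> str:
    """Human-readable summary of a completed run's artifacts."""
    outdir = Path(artifact_dir)
    lines = ["# Run summary", ""]

    auc = pd.read_csv(_require(outdir / "auc_summary.tsv"), sep="\t")
    lines.append("## Interaction benchmark (labeled pairs)")
    for _, row in auc.iterrows():
        lines.append(
            f"- {row.metric}: ROC AUC = {row.roc_auc:.3f}, "
            f"PR area = {row.pr_area:.3f} "
            f"({int(row.n_pos)} positives / {int(row.n_neg)} negatives)"
        )
    lines.append("")

    with open(_require(outdir / "fdr_cutoff.json")) as fh:
        cutoff = json.load(fh)
    if cutoff["threshold"] is not None:
        lines.append(
            f"FDR cutoff (alpha={cutoff['alpha']}): umap_dist <= "
            f"{cutoff['threshold']:.4f} (achieved FDR "
            f"{cutoff['achieved_fdr']:.4f}, {cutoff['n_called']} labeled calls)"
        )
    else:
        lines.append(f"FDR cutoff (alpha={cutoff['alpha']}): no threshold qualifies")
    with open(_require(outdir / "novel_summary.json")) as fh:
        novel = json.load(fh)
    lines.append(
        f"Novel calls (close in UMAP, PCC below cutoff): "
        f"{novel['n_called']} pairs, {novel['n_unique_genes']} unique genes"
    )
    lines.append("")

    clusters = pd.read_csv(
        _require(outdir / "clusters.tsv"), sep="\t", dtype={"sub_cluster": str}
    )
    lines.append(
        f"Clusters: {clusters.main_cluster.nunique()} main, "
        f"{clusters.sub_cluster.nunique()} total at the finest level, "
        f"{len(clusters)} strains"
    )
    conc_path = outdir / "concordance_summary.json"
    if conc_path.exists():
        with open(conc_path) as fh:
            conc = json.load(fh)
        lines.append(
            f"Complex co-clustering: {conc['n_co_clustered']}/{conc['n_eligible']} "
            f"eligible complexes ({conc['fraction_co_clustered']:.1%})"
        )
    ov_path = outdir / "overlap_summary.json"
    if ov_path.exists():
        with open(ov_path) as fh:
            ov = json.load(fh)
        lines.append(
            f"UMAP vs PCA clustering overlap: {ov['n_perfect']}/{ov['n_clusters']} "
            f"perfect, {ov['n_half']}/{ov['n_clusters']} >=50% "
            f"(ARI {ov['ari']:.3f})"
        )
    lines.append("")

    de_path = outdir / "diffex.tsv"
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t")
        lines.append("## Top differentially expressed genes per cluster")
        for cid, group in de.groupby("cluster"):
            top = group.sort_values(["q", "p_corrected"]).head(5)
            genes = ", ".join(top.gene)
            lines.append(f"- cluster {cid}: {genes}")
        lines.append("")

    pl_path = outdir / "paralog_summary.json"
    if pl_path.exists():
        with open(pl_path) as fh:
            pl = json.load(fh)
        lines.append(f"Paralog pairs scored: {pl['n_pairs']}")
        if "divergence_pearson_r" in pl:
            lines.append(
                f"Distance vs external divergence: R = "
                f"{pl['divergence_pearson_r']:.3f} (n={pl['divergence_pearson_n']})"
            )
        if "n_divergent_redundant" in pl:
            lines.append(
                f"Divergent-yet-redundant pairs flagged: "
                f"{pl['n_divergent_redundant']}"
            )
    return "\n".join(lines) + "\n"
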