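"""Synthetic deletion-compendium generator with planted ground truth.

Emulates the statistical structure a deletion-transcriptome compendium
is assumed to have: strains deleted for members of the same protein
complex share a downstream expression "signature" (scaled per member,
plus Gaussian noise), background strains are pure noise, and paralog
pairs carry signatures mixed by a divergence angle. Everything needed
to score recovery — complex membership, signatures, positive pairs,
paralog parameters — is emitted as ground truth, so every downstream
stage of the pipeline is testable without external downloads.

The generator is a modeling artifact: the compendium it imitates is
real data with no known generative model, so all distributional
choices here are documented conventions, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    ComplexCatalog,
    ExpressionMatrix,
    InteractionSet,
    ParalogTable,
    canonical_pair,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_deleteome",
    "generate_paralogs",
    "write_ground_truth",
]

# fixed offsets for deriving per-component child seeds from the master seed
_SEED_OFFSETS = {
    "sizes": 0,
    "signatures": 1,
    "strengths": 2,
    "noise": 3,
    "paralogs": 4,
    "background": 5,
}


class ConfigError(ValueError):
    """Raised when a SynthConfig violates its invariants."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic deletion compendium.

    Defaults describe the reference study conditions used throughout
    the test suite: 40 complexes of 3–6 members, 200 background
    strains, 2000 measured genes, sparse signatures of 50 target genes
    with N(0, τ²) effects (τ = 1), per-member strength ~N(1, 0.1²),
    and per-gene noise σ = 0.5.
    """

    n_genes: int = 2000
    n_complexes: int = 40
    complex_size_range: tuple[int, int] = (3, 6)
    n_background_strains: int = 200
    signature_targets: int = 50
    signature_scale: float = 1.0  # τ: sd of nonzero signature entries
    member_strength_sd: float = 0.1  # sd of per-member scalar a_i around 1
    noise_sd: float = 0.5  # σ: per-gene Gaussian noise sd
    n_paralog_pairs: int = 20
    divergence_angles: tuple[float, ...] | None = None  # θ per pair, [0, π/2]
    gi_overlap: tuple[float, ...] | None = None  # r per pair, [0, 1]
    mark_deleted_gene: bool = False  # set a strain's own gene strongly negative
    deleted_gene_value: float = -5.0
    background_weak_signatures: bool = False  # unique weak (τ/4) signatures
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ConfigError(f"bad complex_size_range {self.complex_size_range}")
        for name in (
            "n_genes",
            "n_complexes",
            "n_background_strains",
            "signature_targets",
            "n_paralog_pairs",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.signature_targets > self.n_genes:
            raise ConfigError("signature_targets exceeds n_genes")
        if self.divergence_angles is None:
            self.divergence_angles = tuple(
                np.linspace(0.0, np.pi / 2, self.n_paralog_pairs)
                if self.n_paralog_pairs
                else ()
            )
        self.divergence_angles = tuple(float(t) for t in self.divergence_angles)
        if len(self.divergence_angles) != self.n_paralog_pairs:
            raise ConfigError("divergence_angles length != n_paralog_pairs")
        for theta in self.divergence_angles:
            if not 0.0 <= theta <= np.pi / 2 + 1e-12:
                raise ConfigError(f"divergence angle {theta} outside [0, pi/2]")
        if self.gi_overlap is None:
            # default: redundancy concordant with divergence (r = 1 - θ/(π/2)),
            # the null expectation; discordant pairs are planted explicitly
            self.gi_overlap = tuple(
                1.0 - t / (np.pi / 2) for t in self.divergence_angles
            )
        self.gi_overlap = tuple(float(r) for r in self.gi_overlap)
        if len(self.gi_overlap) != self.n_paralog_pairs:
            raise ConfigError("gi_overlap length != n_paralog_pairs")
        for r in self.gi_overlap:
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"gi_overlap {r} outside [0, 1]")
        max_strains = (
            self.n_complexes * self.complex_size_range[1]
            + self.n_background_strains
            + 2 * self.n_paralog_pairs
        )
        if max_strains > self.n_genes:
            raise ConfigError(
                f"strain budget exceeded: up to {max_strains} strains but only "
                f"{self.n_genes} genes to delete"
            )

    def child_rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component generator derived from the master seed."""
        return np.random.default_rng([self.seed, _SEED_OFFSETS[component]])


@dataclass
class GroundTruth:
    """Everything the simulator planted, for scoring recovery."""

    complexes: dict[str, list[str]]  # complex_id -> member strain ids
    signatures: dict[str, np.ndarray]  # complex_id -> gene-indexed vector
    positive_pairs: set[tuple[str, str]]  # canonical same-complex pairs
    paralog_pairs: list[dict]  # strain_a, strain_b, theta, r, gi_score
    seed: int

    def __post_init__(self) -> None:
        strains = [s for members in self.complexes.values() for s in members]
        if len(strains) != len(set(strains)):
            raise ValueError("a strain belongs to two complexes")
        expected = {
            canonical_pair(a, b)
            for members in self.complexes.values()
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        }
        if self.positive_pairs != expected:
            raise ValueError("positive_pairs != union of within-complex pairs")

    def catalog(self) -> ComplexCatalog:
        return ComplexCatalog({c: set(m) for c, m in self.complexes.items()})

    def interactions(self, universe: list[str] | set[str]) -> InteractionSet:
        from .dataio import catalog_to_pairs

        return catalog_to_pairs(self.catalog(), universe)

    def paralog_table(self) -> ParalogTable:
        df = pd.DataFrame(
            [
                {
                    "gene_a": p["strain_a"],
                    "gene_b": p["strain_b"],
                    "divergence_metric": p["theta"],
                    "gi_score": p["gi_score"],
                }
                for p in self.paralog_pairs
            ],
            columns=["gene_a", "gene_b", "divergence_metric", "gi_score"],
        )
        return ParalogTable(df)


def _sparse_signature(
    rng: np.random.Generator, n_genes: int, n_targets: int, scale: float
) -> np.ndarray:
    """Sparse signature: `n_targets` genes with N(0, scale²) effects."""
    sig = np.zeros(n_genes)
    targets = rng.choice(n_genes, size=n_targets, replace=False)
    sig[targets] = rng.normal(0.0, scale, size=n_targets)
    return sig


def generate_deleteome(config: SynthConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the synthetic compendium and its planted ground truth.

    Strain layout (row order): complex members, then background
    strains, then paralog strains. Each strain is named after its
    deleted gene; deleted genes are assigned sequentially from the
    measured-gene list, so strain ids are a subset of gene ids.
    Identical config + seed yields bit-identical output.
    """
    n_digits = max(4, len(str(config.n_genes)))
    gene_ids = [f"g{i:0{n_digits}d}" for i in range(config.n_genes)]

    rng_sizes = config.child_rng("sizes")
    rng_sig = config.child_rng("signatures")
    rng_strength = config.child_rng("strengths")
    rng_noise = config.child_rng("noise")

    lo, hi = config.complex_size_range
    sizes = rng_sizes.integers(lo, hi + 1, size=config.n_complexes)

    rows: list[np.ndarray] = []
    strain_ids: list[str] = []
    complexes: dict[str, list[str]] = {}
    signatures: dict[str, np.ndarray] = {}
    cursor = 0

    for c, size in enumerate(sizes):
        cid = f"C{c:03d}"
        sig = _sparse_signature(
            rng_sig, config.n_genes, config.signature_targets, config.signature_scale
        )
        signatures[cid] = sig
        members = []
        for _ in range(int(size)):
            strain = gene_ids[cursor]
            cursor += 1
            a_i = 1.0 + rng_strength.normal(0.0, 1.0) * config.member_strength_sd
            noise = rng_noise.normal(0.0, 1.0, config.n_genes) * config.noise_sd
            rows.append(a_i * sig + noise)
            members.append(strain)
            strain_ids.append(strain)
        complexes[cid] = members

    rng_bg = config.child_rng("background")
    for _ in range(config.n_background_strains):
        strain = gene_ids[cursor]
        cursor += 1
        noise = rng_noise.normal(0.0, 1.0, config.n_genes) * config.noise_sd
        row = noise
        if config.background_weak_signatures:
            row = row + _sparse_signature(
                rng_bg,
                config.n_genes,
                config.signature_targets,
                config.signature_scale / 4.0,
            )
        rows.append(row)
        strain_ids.append(strain)

    paralog_rows, paralog_strains, paralog_records = generate_paralogs(
        config, gene_ids, cursor
    )
    rows.extend(paralog_rows)
    strain_ids.extend(paralog_strains)

    values = np.vstack(rows) if rows else np.zeros((0, config.n_genes))
    if config.mark_deleted_gene:
        gene_pos = {g: j for j, g in enumerate(gene_ids)}
        for i, strain in enumerate(strain_ids):
            values[i, gene_pos[strain]] = config.deleted_gene_value

    positive_pairs = {
        canonical_pair(a, b)
        for members in complexes.values()
        for i, a in enumerate(members)
        for b in members[i + 1 :]
    }
    truth = GroundTruth(
        complexes=complexes,
        signatures=signatures,
        positive_pairs=positive_pairs,
        paralog_pairs=paralog_records,
        seed=config.seed,
    )
    matrix = ExpressionMatrix(strain_ids, gene_ids, values)
    return matrix, truth


def generate_paralogs(
    config: SynthConfig, gene_ids: list[str], cursor: int = 0
) -> tuple[list[np.ndarray], list[str], list[dict]]:
    """Paralog strain profiles and their planted records.

    Pair members carry signatures s and cos(θ)·s + sin(θ)·s⊥, where s⊥
    is an independent signature orthogonalized against s and rescaled
    to ‖s‖, so θ is exactly the angle between the two noiseless
    profiles. The simulated genetic-interaction score is −r plus small
    noise, independent of θ, which makes divergence-vs-redundancy
    discordance plantable.
    """
    rng = config.child_rng("paralogs")
    rows: list[np.ndarray] = []
    strains: list[str] = []
    records: list[dict] = []
    for k in range(config.n_paralog_pairs):
        theta = config.divergence_angles[k]
        r = config.gi_overlap[k]
        s = _sparse_signature(
            rng, config.n_genes, config.signature_targets, config.signature_scale
        )
        t = _sparse_signature(
            rng, config.n_genes, config.signature_targets, config.signature_scale
        )
        s_norm2 = float(s @ s)
        perp = t - (t @ s) / s_norm2 * s if s_norm2 > 0 else t
        perp_norm = np.linalg.norm(perp)
        if perp_norm > 0:
            perp = perp * (np.sqrt(s_norm2) / perp_norm)
        sig_b = np.cos(theta) * s + np.sin(theta) * perp
        strain_a, strain_b = gene_ids[cursor], gene_ids[cursor + 1]
        cursor += 2
        for sig in (s, sig_b):
            noise = rng.normal(0.0, 1.0, config.n_genes) * config.noise_sd
            rows.append(sig + noise)
        gi_score = -r + rng.normal(0.0, 0.05)
        strains.extend([strain_a, strain_b])
        records.append(
            {
                "strain_a": strain_a,
                "strain_b": strain_b,
                "theta": float(theta),
                "r": float(r),
                "gi_score": float(gi_score),
            }
        )
    return rows, strains, records


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write ground-truth tables (complexes, positive pairs, paralogs, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["complexes"] = outdir / "truth_complexes.tsv"
    pd.DataFrame(
        [(c, s) for c in sorted(truth.complexes) for s in truth.complexes[c]],
        columns=["complex_id", "strain_id"],
    ).to_csv(paths["complexes"], sep="\t", index=False)

    paths["positive_pairs"] = outdir / "truth_positive_pairs.tsv"
    pd.DataFrame(
        sorted(truth.positive_pairs), columns=["strain_a", "strain_b"]
    ).to_csv(paths["positive_pairs"], sep="\t", index=False)

    paths["paralogs"] = outdir / "truth_paralogs.tsv"
    pd.DataFrame(
        truth.paralog_pairs,
        columns=["strain_a", "strain_b", "theta", "r", "gi_score"],
    ).to_csv(paths["paralogs"], sep="\t", index=False)

    paths["manifest"] = outdir / "truth_manifest.txt"
    with open(paths["manifest"], "w") as fh:
        fh.write(f"seed={truth.seed}\n")
        fh.write(f"n_complexes={len(truth.complexes)}\n")
        fh.write(f"n_positive_pairs={len(truth.positive_pairs)}\n")
        fh.write(f"n_paralog_pairs={len(truth.paralog_pairs)}\n")
    return paths
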