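# Methods

`perturbmap` infers physical and functional relationships between genes
from a compendium of single-gene-deletion transcriptomes: strains whose
deletions perturb the same complex or pathway mount similar downstream
expression responses, so proximity between strains in a low-dimensional
embedding of their profiles is used as an interaction score. This note
records the models, conventions and numerical choices behind each stage,
what the synthetic compendium does and does not emulate, and the known
limitations.

## The synthetic compendium

Real deletion compendia have no known generative model, so the simulator
is an explicit modeling artifact. Its assumptions:

- **Complex signatures.** Each planted complex *c* has a sparse signature
  vector *s_c*: `signature_targets` genes (default 50 of 2000) drawn
  without replacement, with effects ~ N(0, τ²), τ = `signature_scale`
  (default 1, log-ratio units). Sparsity mimics pathway-specific
  transcriptional responses; distinct complexes have largely disjoint
  target sets.
- **Member profiles.** Deleting member *i* of complex *c* yields the row
  *a_i·s_c + ε*, with per-member strength *a_i* ~ N(1, 0.1²) and i.i.d.
  per-gene noise ε ~ N(0, σ²), σ = `noise_sd` (default 0.5). All members
  share the signature up to a scalar — the central structural assumption
  the whole analysis relies on.
- **Background strains** (default 200) are pure noise: deletions with no
  coherent downstream program. A flag gives them weak unique signatures
  (τ/4) instead; the default is pure noise so that planted positives are
  the only structure.
- **Paralog pairs.** Pair members carry signatures *s* and
  cos(θ)·s + sin(θ)·s⊥, where s⊥ is an independent signature
  orthogonalized against *s* and rescaled to ‖s‖, making θ exactly the
  angle between the noiseless profiles (θ = 0: fully shared response;
  θ = π/2: fully diverged). The simulated genetic-interaction score is
  −r + N(0, 0.05²), where r ∈ [0, 1] is the planted redundancy —
  deliberately independent of θ, so divergence-vs-redundancy discordance
  can be planted. Default per-pair angles are evenly spaced on [0, π/2]
  with r = 1 − θ/(π/2) (the concordant null); tests plant discordant
  pairs explicitly.
- **Strain naming.** Every strain is named after its deleted gene, with
  deleted genes assigned sequentially from the measured-gene list, so
  strain ids form a subset of gene ids and the catalog/pair machinery
  can treat them interchangeably.
- **Seeding.** One master seed; each component (sizes, signatures,
  strengths, noise, paralogs, background) derives a child generator from
  `(seed, fixed offset)`, so output is bit-identical for equal config +
  seed and insensitive to the order in which components consume draws.

Not emulated: microarray dye/batch effects, growth-rate coupling,
missing values, correlated (non-i.i.d.) noise, overlapping complex
membership, and regulatory cascades between complexes. Passing tests
therefore demonstrate that the pipeline recovers the *kind* of structure
it assumes — shared scaled signatures plus Gaussian noise — not that it
would achieve the same operating characteristics on real compendia.

## Embeddings

- **PCA.** Gene-centered, unscaled (profiles already share a log-ratio
  scale; a `scale` flag exists). Scores are deterministic: each
  component's sign is fixed so its largest-magnitude loading is
  positive. Randomized SVD is used above 500×500, with a fixed internal
  seed.
- **UMAP** (primary): cosine metric, `n_neighbors = 10`,
  `min_dist = 0.05`, 2-D, on the top 100 PCs (25 for sub-clustering,
  capped at subset size − 1). Seeded; with a fixed seed umap-learn runs
  single-threaded and is reproducible on one platform + library
  version.
- **tSNE** baseline: perplexity 30 capped below n/3, PCA
  initialization, seeded.
- **Random projection** baseline: X·R with R the Q factor of a seeded
  Gaussian genes × d matrix (orthonormal columns; Johnson–Lindenstrauss
  regime).
- **High-dimensional view**: the identity embedding, so raw gene-space
  Euclidean distance flows through the same scoring interface.

## Clustering

A k-nearest-neighbor graph (k = 3, Euclidean in the 2-D embedding,
symmetrized union, unweighted, distance ties broken by strain order) is
partitioned by Louvain modularity optimization. The default resolution
is 1e-4: at that granularity merging is almost always favourable and
communities coincide with the connected components of the sparse graph,
which is the regime that yields tens of clusters from ~10³ strains. The
resolution is an ordinary modularity resolution parameter and is fully
tunable; the cluster granularity, not the literal value, is what
matters. Labels are dense integers ordered by decreasing cluster size
(ties by smallest member id).

Main clusters larger than `subcluster_min_size` (default 25 strains)
are re-embedded from their own expression submatrix (fresh PCA with up
to 25 components, fresh UMAP) and re-clustered with identical
parameters; sub-labels are "main.sub" strings so sub-clusters nest
within mains by construction. The size trigger is used rather than any
fixed list of cluster ids, since it transfers across datasets.

Within-cluster structure for heatmap display uses the pairwise embedded
distance matrix with average-linkage hierarchical clustering; the
returned leaf order places tight sub-groups (e.g. heterodimers)
adjacently.

## Pair scoring and benchmarking

Labels come from a complex catalog: positives are all within-complex
pairs present in the strain universe; negatives are, by default, all
remaining pairs among *complex-annotated* genes only — labeling genes
that were never assigned to a complex as non-interacting would poison
the negative set (a flag widens negatives to the full universe).
Pairs are canonical (lexicographic); metric values for pairs whose
strains are absent are dropped and counted, and missing values
propagate as missing, never as zero (zero distance means co-located).

ROC and PR curves are built from first principles so tie handling is
pinned: tied scores form one curve step, and the trapezoidal AUC then
equals the Mann–Whitney U estimator with ties counted half. This
equivalence is property-tested against a brute-force oracle. PR area is
the step integral Σ(R_i − R_{i−1})·P_i.

The interaction-calling cutoff is the largest distance t whose
false-discovery rate among *labeled* pairs called at d ≤ t is at most α
(default 0.05); candidates are the observed labeled distances and
unlabeled pairs never enter calibration. When no t qualifies the result
says so explicitly rather than degrading to 0. Novel calls are pairs
with d ≤ t (closed) and profile Pearson correlation < 0.5 (open) —
interactions invisible to the classical correlation approach.

Cluster/complex concordance counts a complex as co-clustered when ≥ 2
of its in-universe members share a (sub-)cluster label, with the
members-in-best-cluster fraction reported per complex. Overlap between
two clusterings reports, per cluster of A, the containment fraction
|A_i ∩ B_j*|/|A_i| of its best match (1.0 = "perfect"), together with
the Jaccard index of that match and the adjusted Rand index of the
whole pair of partitions — containment alone is trivially perfect when
B is coarse, which the ARI exposes.

## Differential expression

Per cluster and gene, a Gaussian likelihood-ratio test compares a
cluster-membership-indicator mean model against the intercept-only
model over all strains (equivalent to an equal-variance two-sample
contrast): LR = n·ln(RSS₀/RSS₁), referred to χ²(1). Zero-variance genes
get statistic 0 and p = 1 by convention. Inflation is corrected with
the genomic-control factor λ = median(LR)/0.4549 (the χ²(1) median),
computed **per cluster**, and applied only when λ > 1 — genomic control
never inflates significance. Benjamini–Hochberg q-values follow
(via statsmodels). The reported effect is the cluster-minus-background
mean difference. A one-sided hypergeometric over-representation test on
user-supplied term → gene annotations stands in for GO enrichment; no
ontology structure is used.

## Paralog divergence

Each paralog pair's transcriptional divergence is its embedded
distance; `metric_correlation` relates it to any external numeric
divergence estimate (Pearson, complete pairs only, ≥ 3 required).
A pair is flagged *divergent-yet-redundant* when its GI score is at or
below `gi_threshold` (default −0.5, i.e. strong negative interaction)
**and** its distance exceeds the `distance_quantile` (default 0.75)
quantile of all paralog distances. Both defaults are conventions, not
literature values, and are exposed as parameters.

## Problem sizes used by the test suite

Chosen as the package's reference conditions: the default synthetic
compendium (40 complexes of 3–6, 200 background, 2000 genes, σ = 0.5)
across five seeds for recovery checks; a 50-strain planted cluster over
a pure-noise background for the DE power check (3–6-member clusters
cannot reach high signature recovery because the weakest N(0, τ²)
signature entries are statistically undetectable at that group size —
50 strains matches the larger main clusters real compendia produce);
and one compendium-scale run (90 complexes of 4–20 members, ≈1484
strains × 6170 genes) exercising the full pipeline, including an exact
rerun for bit-identity.

## Known limitations

- **Isolated 2-strain groups embed unreliably.** A paralog pair
  contributes too little variance for its signature direction to
  survive the 100-PC projection at default noise (sample noise
  eigenvalues exceed a 2-strain direction's variance), so the UMAP
  placement of pair members is dominated by their background
  neighbors: fully diverged pairs occasionally co-locate inside the
  background mass and identical pairs occasionally straddle it. The
  flagged-fraction contrast between discordant and concordant planted
  pairs holds on average, but per-pair flagging of singletons is noisy.
  Divergence conclusions are correspondingly more trustworthy for genes
  embedded inside multi-strain clusters.
- With many more planted complexes than retained principal components,
  signature directions mix and embedding recovery degrades; the PC
  budget should be scaled with the expected number of expression
  programs.
- λ_GC assumes the bulk of genes are null for the cluster contrast;
  clusters whose deletions remodel a large fraction of the
  transcriptome deflate true signals.
- The FDR calibration is exact only with respect to the supplied
  labels; label noise in a real gold standard propagates directly.
- UMAP/tSNE coordinates are reproducible only for a fixed platform and
  library version; all downstream artifacts are deterministic given the
  coordinates.
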