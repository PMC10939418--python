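# Methods

## Model

`sgae` treats a spatial transcriptomics slide as an attributed graph
G = (V, E): spots are nodes with expression features X ∈ ℝ^{N×d}, edges come
from spatial proximity. The goal is an embedding H ∈ ℝ^{N×q} whose K-means
partition recovers contiguous, expression-coherent spatial domains. The
model is a Siamese graph autoencoder trained by self-supervision on two
distorted views of the same graph; no labels enter training.

### Graph construction

- **SNN**: Euclidean kNN over coordinates, symmetrized by union (an edge
  survives if either endpoint selects the other). Union keeps isolated-spot
  counts low on irregular spot layouts. Exact distance ties break toward
  the lower spot index, making gridded layouts reproducible. Default
  k = 6 matches the 6 first-order neighbors of hexagonal/array platforms.
- **Cell-type-aware pruning** (on by default): expression preclusters
  (Leiden, resolution 1.0, on a 15-NN feature graph; seeded K-means with
  K = n_clusters below 500 spots, where Leiden communities become unstable)
  define pseudo-labels; every SNN edge joining different pseudo-labels is
  deleted outright. Down-weighting instead of deletion was considered and
  rejected for simplicity; deletion is also the stricter reading of
  "pruning". Refinement and Moran's I always use the *unpruned* SNN.
- **Normalization**: Â = D̂^{−1/2}(A+I)D̂^{−1/2} with D̂ the degree matrix of
  A+I. The row-stochastic variant D^{−1}(A+I) is not used anywhere; the
  symmetric form keeps the operator's spectrum in [−1, 1], which both the
  diffusion inverse and gradient stability rely on. For every distorted or
  diffused adjacency the degree matrix is recomputed from the matrix being
  normalized (plus I), never reused from the clean graph — this preserves
  spectral radius ≤ 1 after edge deletion, and makes view 2's operator
  (Â_d from A^d + I) bounded even though A^d is dense.

### Distortion

- **Feature corruption**: X̃ = X ⊙ N, N i.i.d. Gaussian with mean 1. The
  spread parameter is interpreted as a standard deviation (0.1); the two
  views draw independent noise from per-epoch subseeds.
- **Edge removal**: undirected edges are ranked by cosine similarity of
  their endpoints' latent rows and the lowest floor(0.1·|E|) are deleted
  (one decision per unordered pair; ties resolve in lexicographic edge
  order; zero-norm rows get similarity 0). The "latent space" is the fused
  embedding of the most recent epoch — raw input features bootstrap the
  first epoch — and the ranking is recomputed every epoch
  (`freeze_edge_mask` disables this).
- **PPR diffusion**: A^d = α(I − (1−α)Â)⁻¹ with teleport α = 0.2, computed
  once per run by dense solve (N ≤ 5000) or sparse LU beyond; it depends
  only on the clean graph. Note A^d rows sum to 1 only when Â is
  row-stochastic, i.e. on regular graphs; the property tests use a ring
  lattice for that invariant.

### Network and losses

Encoder layers follow the two-branch rule
H^(l) = σ(Â_view H^(l−1) W₁^(l)) + σ(H^(l−1) W₂^(l) + b^(l)) — a graph
convolution plus a biased dense "residual" branch — with one parameter set
shared by both views. Defaults: d → 256 → 64, ReLU hidden, linear output;
the decoder mirrors the encoder as a plain GCN on the clean Â. Fusion is
the fixed average H = ½H₁ + ½H₂.

- L_REC−F = ‖ÂX − Ĥ‖²_F / 2N. The target is the *neighbor-aggregated*
  feature matrix; Â (not raw binary A) keeps target and reconstruction on
  the same scale. A flag restores the raw-A target.
- L_REC−A = ‖A − σ(HHᵀ)‖²_F / 2N against the binary adjacency without
  self-loops; the logistic squashing puts the reconstruction in (0,1).
- L_RR: node-level S_N (pairwise row cosines of H₁ vs H₂, N×N) and
  feature-level S_F (pairwise column cosines, q×q, i.e. Z_v := H_vᵀ) are
  penalized by size-normalized squared distance to identity,
  ‖S_N − I‖²_F/N² + ‖S_F − I‖²_F/q². Cosine (per-row) normalization is used
  so that S is a bounded similarity matrix comparable to I.
- L_C = KL(P‖Q)/N with q_ij ∝ (1 + ‖h_i − μ_j‖²/ν)^{−(ν+1)/2}, ν = 1, and
  p_ij = (q_ij²/Σ_i q_ij) / Σ_{j′}(…). P is treated as a constant
  (recomputed every 5 epochs from the current Q); q is floored at 10⁻¹²
  inside the log. An optional second KL term anchoring Q to the frozen
  pretrained cluster structure (target built from the pretraining-end soft
  assignment) is available via the `kl_pretrained` loss weight, 0 by
  default.

Total loss: unweighted sum of the four terms; per-term weights exist as an
ablation hook. The adjacency term numerically dominates on larger graphs
(it scales with N), which in practice supplies most of the embedding's
spatial structure; the weights were deliberately left at 1.

### Optimization

In-repo reverse-mode automatic differentiation over numpy provides exact
gradients (verified against central finite differences at 10⁻⁴ relative
error). Adaptive-moment gradient descent, lr 10⁻³, full batch.
Pretraining (default 100 epochs) minimizes L_REC + L_RR (a flag drops
L_RR); K-means (k-means++, 20 restarts, centers sorted by first coordinate
for determinism) on the pretrained fused embedding initializes the cluster
centers, which then train jointly by gradient through Q (standard for
DEC-style objectives) for 200 epochs. Divergence (non-finite loss) raises
with the offending epoch and term. Inference is a single clean forward
pass (no noise, no edge removal); by default final labels come from
K-means on the inferred embedding (matching the stated inference flow),
with argmax-Q available via `final_kmeans=False`.

All randomness flows from one integer seed through `SeedSequence` spawns
(epoch noise, K-means restarts, Leiden); identical config + seed
reproduces labels and loss histories bitwise within a fixed software
environment.

## Preprocessing

Counts are scaled per spot to a common library size — the median spot
total by default, since the normalization constant is otherwise arbitrary —
then log1p-transformed; zero-total spots are dropped with a warning. PCA
to 50 components (exact solver up to min(N,D) = 2000, seeded randomized
beyond; component signs fixed by the largest-magnitude-loading convention)
gives the default encoder input; a flag feeds full log-expression instead.
No gene filtering is applied by default.

## Evaluation metrics

ARI, NMI, FMI, and AMI are computed directly from the contingency table
(AMI's E[MI] by the exact hypergeometric sum); natural logarithms
throughout. ARI is the chance-adjusted pair-counting index; the unadjusted
Rand index is exposed separately as `rand_index`. Moran's I uses the
binary SNN adjacency as weights without row standardization (a flag
row-standardizes); per-domain spatial coherence is Moran's I of each
cluster's indicator vector, with expectation −1/(n−1) under the
permutation null. The test suite validates every index against brute-force
pair enumeration / direct formula oracles and against scikit-learn.

## Synthetic data

The generator emulates what the method needs from real data — spatially
contiguous domains with domain-specific programs over noisy counts — not
any particular platform. A grid of spots is partitioned by vertical bands,
quadrants, or seeded Voronoi cells; each domain owns a disjoint block of
marker genes (disjointness makes ground truth identifiable by
construction). Counts are negative binomial in the standard RNA-seq
parameterization (mean m, dispersion d, variance m + d·m²) with
independent dropout zeroing. Named fixtures freeze the study conditions:

- `tiny` (5×5, K=2, fold 8): unit-test scale, trivially separable;
- `bands3` (30×30, K=3, 100 genes, 10 markers/domain, base mean 2,
  fold 4, dispersion 0.5, dropout 0.2): the end-to-end recovery
  conditions. Base mean 2 and 10 markers per domain reflect a
  moderately expressed, moderately redundant gene program — enough signal
  that domains are recoverable, enough noise that per-gene evidence is
  weak;
- `hard` (30×30, K=5 Voronoi, fold 2): stress conditions with no recovery
  guarantee.

What passing on these fixtures does **not** show: robustness to
platform-specific artifacts (bead sharing, permeabilization gradients,
segmentation errors), batch effects, rare domains smaller than the kNN
neighborhood, or continuous expression gradients without sharp domain
boundaries — none of which the generator emulates.

## Problem sizes and numerical choices

The shipped end-to-end checks run the bands3 conditions (900 spots, 100
genes, 100 + 200 epochs, five seeds) — small enough to iterate on a
laptop, large enough that expression-only K-means is separated from the
full model (median ARI ≈ 0.88 vs ≈ 0.92). Dense N×N work (PPR solve,
S_N, HHᵀ) makes memory quadratic in spots; full-batch CPU training is
practical to a few thousand spots, and the architecture targets ≤ ~50k
spots before mini-batching would be needed (out of scope). Tolerances:
finite-difference gradient checks 10⁻⁴ relative; PPR vs truncated power
series 10⁻⁶; row-sum checks 10⁻⁹; loss decomposition 10⁻⁶. Degenerate
inputs (all-zero spots, isolated nodes, coincident centers, constant
Moran vectors, single-cluster partitions) follow the documented
conventions in the relevant docstrings.

## Known limitations

- The adjacency reconstruction loss grows linearly with N relative to the
  other terms; on much larger graphs the unweighted sum may need the
  ablation weights.
- Pruning with poor preclusters can isolate spots (they keep self-loops
  and still receive the residual branch, but lose spatial smoothing).
- Determinism is guaranteed within one BLAS/numpy build, not across
  builds.
- Multi-slice integration, histology-informed graphs, and GPU execution
  are out of scope.
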