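# sgae — Siamese graph autoencoder for spatial-domain clustering

Spatially resolved transcriptomics measures gene expression at known
positions in a tissue section. A central analysis task is **spatial domain
identification**: partitioning the spots into contiguous regions with
coherent expression programs (cortical layers, tumor niches, anatomical
structures). Plain expression clustering ignores where the spots are;
`sgae` is for analysts who want domains that respect both expression and
tissue geometry, without any labels.

## Method

Spots form a graph: the **spatial neighbor network (SNN)** is the
union-symmetrized Euclidean k-nearest-neighbor graph over spot coordinates
(default k = 6), optionally made *cell-type aware* by deleting edges whose
endpoints fall in different expression preclusters (Leiden on a feature-space
kNN graph). Expression is library-size normalized, log1p-transformed, and
reduced to the top 50 principal components X ∈ ℝ^{N×50}.

Two distorted views of the graph feed a pair of **parameter-shared
encoders**:

- view 1: X₁ = X ⊙ N with N ~ 𝒩(1, 0.1²), adjacency Â_m with the 10 % of
  edges of lowest latent-space cosine similarity removed;
- view 2: an independent corruption X₂ with the **Personalized PageRank
  diffusion** A^d = α(I − (1−α)Â)⁻¹, α = 0.2, which exposes higher-order
  neighborhoods.

Each encoder layer is a two-branch graph convolution
H^(l) = σ(Â H^(l−1) W₁^(l)) + σ(H^(l−1) W₂^(l) + b^(l)); the two view
embeddings H₁, H₂ are fused as H = ½H₁ + ½H₂. A GCN decoder reconstructs
neighbor-aggregated features (L_REC−F = ‖ÂX − Ĥ‖²_F / 2N) and the inner
product σ(HHᵀ) reconstructs the adjacency (L_REC−A = ‖A − Â‖²_F / 2N).
A Barlow-Twins-style **redundancy-reduction** loss pushes the node-level
(N×N) and feature-level (q×q) cross-view cosine-correlation matrices toward
identity, preventing representation collapse. A **clustering-guidance**
term sharpens the embedding around K-means-initialized centers: Q is the
Student's-t soft assignment, P its squared-and-renormalized target, and
L_C = KL(P‖Q)/N. Training minimizes

L = L_REC−F + L_REC−A + L_RR + L_C

full-batch (in-repo reverse-mode autodiff; adaptive-moment updates,
lr 10⁻³; 100 pretraining epochs without L_C, then 200 joint epochs).
Inference is one clean forward pass; K-means on the fused embedding gives
the domains, with an optional neighbor-majority refinement pass for
low-resolution array platforms. Evaluation metrics (ARI, NMI, FMI, AMI,
per-cluster Moran's I) are implemented from their contingency-table /
spatial-weight definitions.

## Worked example

```python
from sgae import SGAE
from sgae.simulate import make_fixture

ds = make_fixture("bands3")        # 30x30 grid, 3 band domains, 100 genes
model = SGAE.from_synthetic(ds)    # defaults: SNN k=6, pruning, PCA-50
res = model.fit(seed=0)
print(res.summary())
```

prints

```
Siamese graph autoencoder — spatial domain clustering
========================================================
spots: 900   latent dim: 64   clusters: 3
epochs: 100 pretrain + 200 joint
final losses: rec_f=0.6966 rec_a=143.6306 rr=0.3352 clustering=0.1177
median per-cluster Moran's I: 0.8526
vs ground truth: ARI=0.9151 NMI=0.8653 FMI=0.9433 AMI=0.8650
```

The 900 simulated spots carry three vertical-band domains with
negative-binomial counts (fold change 4 on 10 marker genes per domain,
dispersion 0.5, 20 % dropout). The fitted model recovers the bands at
ARI 0.92 — an expression-only K-means on the same preprocessed matrix
reaches ≈ 0.88 — and every recovered domain is spatially coherent
(per-cluster Moran's I far above the −1/(n−1) ≈ −0.001 permutation null).
`res.save(outdir)` writes `labels.csv`, `embedding.csv`,
`loss_history.csv`, `run_config.json`, and `metrics.json`;
`res.plot_domains(path)` draws the domain map.

The same pipeline is available from the shell:

```bash
sgae simulate --fixture bands3 --out data/
sgae run --counts data/counts.csv --coords data/coords.csv \
         --labels data/truth.csv --n-clusters 3 --seed 0 --out out/
```

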