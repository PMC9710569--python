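# Methods

## Model and procedure

The package corrects transcript loss in imaging-based spatial
transcriptomics. Input is a spot table (one row per detected mRNA: id,
gene, x, y) and a cell segmentation (integer label mask or per-cell
polygons). Spots falling inside a labeled pixel are counted into the
cell-by-gene matrix; the remainder are *dangling*.

Per-cluster expression is modeled as multivariate Gaussian in a normalized
space. The normalization (library-size scaling to the median cell total,
`log1p`, per-gene z-score) is the standard single-cell default; the fitted
transform (median total, per-gene means/SDs) is recorded so that mock-cell
vectors can be mapped into exactly the space the moments were learned in.
Counts themselves are integers; the Gaussian is an approximation justified
by the large number of transcripts per cell, and the simulator deliberately
generates discrete Dirichlet-multinomial counts so the tests exercise that
approximation rather than assuming it.

Each iteration re-clusters the current matrix, re-estimates moments,
classifies every remaining dangling spot through its mock cell and commits
all assignments synchronously. Batch commitment makes an iteration's
decisions depend only on the state at its start, hence independent of spot
processing order (spot-id order is fixed anyway to pin tie-breaks). The
loop runs a fixed number of iterations (default 3) and stops early when an
iteration assigns nothing.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `radius` (r) | 2 × median equivalent-disk radius of segmented cells | mock-cell neighborhood, in coordinate units; tying it to observed cell scale keeps it unit-free |
| `delta` | 1.0 unit | length scale of the neighbor weight w(d) = 1/(1 + d/δ) |
| `max_assign_dist` (D) | 4 r | cap on spot-to-centroid distance; beyond it a spot stays dangling |
| `min_loglik_margin` | 0 (off) | minimum best-minus-runner-up log-likelihood to commit an assignment |
| `max_iterations` | 3 | fixed iteration budget |
| `lambda_frac` | 1e-2 | ridge on cluster covariances, scaled by the mean pooled variance (unit floor when members coincide) |

The weight function is a +1-shifted inverse distance: a plain 1/d diverges
at the spot itself (d = 0), so w(d) = 1/(1 + d/δ) gives the centered spot
weight 1 and decays hyperbolically. Mock cells include *all* spots in the
neighborhood — inside, already-assigned and still-dangling — so later
iterations see earlier context; the mock vector itself is
status-independent, and iterations differ through the evolving clustering
and moments. Classification is pure likelihood with no cluster-size prior;
the margin gate and the distance cap are the explicit, tunable forms of
conservatism (false negatives over false positives).

## Clustering

`cluster_graph` builds a Euclidean kNN graph, re-weights edges by the
Jaccard overlap of neighbor sets, and optimizes modularity with Leiden
(RB-configuration, resolution 1.0). `k_neighbors` defaults to 30 but is
capped at n/5: on a small FoV (say 80 cells in 5 types) a 30-neighbor
neighborhood necessarily spans several cell types and the communities
merge; the cap keeps neighborhoods inside plausible communities. Singleton
communities are folded into the nearest community by centroid distance.
Because kNN graphs are scale-free, modularity can also split one dense blob
into sub-communities regardless of how tight it is geometrically; a final
agglomerative pass therefore merges community pairs whose mean cross-pair
Jaccard weight is at least 10% of their mean within-pair weight — split
halves of one blob stay heavily interconnected, while genuinely distinct
clusters share almost no Jaccard edges.

`cluster_dpmm` is a Dirichlet-process Gaussian mixture with a conjugate
Normal–Inverse-Wishart base (m0 = data mean, k0 = 0.01, ν0 = d + 2,
S0 = diagonal empirical variances, α = 1) fit by collapsed Gibbs sampling;
the labels of the maximum-a-posteriori sweep are returned, and inputs wider
than 50 features are first reduced by PCA. The sampler starts from the
all-singletons partition: with the weak k0 the prior predictive is far
broader than the data, so from a merged start a first singleton can
essentially never win a Gibbs move, whereas merges from the singleton start
are easy. Known limitation: on data whose PCA space is dominated by noise
dimensions (e.g. the default FoV, 140 genes → 50 PCs of which ~45 carry no
cluster signal) the NIW evidence rewards chance substructure and the
sampler fragments true clusters; the graph clusterer is the default for
FoV-sized inputs, and the DPMM is reliable on low-dimensional or strongly
separated data.

## Synthetic fields of view

The simulator generates the statistical regime the model assumes, so every
stage is testable without external data. Defaults: 80 cells, 140 genes,
5 clusters with uniform proportions; per-cluster gene programs are
Dirichlet(0.1) draws (sparse, well-separated); per-cell totals are negative
binomial with mean 300 and size 10 (CV ≈ 0.33, a realistic per-cell depth
spread); genes are i.i.d. from the cell's program; positions are isotropic
Gaussian (σ = 5 units) around cell centers placed by rejection sampling
with 24-unit minimum spacing on a 512×512 field; the segmentation is a
6-unit disk per nucleus. With radius 6 and σ = 5 the expected inside mass
is 1 − exp(−(6/5)²/2) ≈ 0.51, so about half the transcripts dangle —
matching conservative nuclear segmentations of real FoVs. The geometry was
calibrated once from this closed form. A single seeded generator with
documented draw order (programs → cluster labels → centers → totals → per
cell genes then positions) makes outputs byte-reproducible.

What the simulator does *not* emulate: cell morphology (axons, anisotropy),
optical noise and decoding errors, doublets, 3D tissue, and any dependence
of transcript position on gene identity. Consequently, passing tests show
that the statistical machinery recovers the generative structure it
assumes; they do not certify performance on morphologically complex real
tissue, where position–gene dependence and segmentation artifacts matter.
Because gene identity and position are independent here, the uncorrected
matrix is an unbiased thinning of the truth, making the evaluation
direction (corrected profiles closer to truth) a genuine test of
assignment quality rather than of bias removal.

## Coordinates and numerical choices

Spots live in continuous 2D; label masks are indexed `mask[ix, iy]` (axis 0
= x) and pixel (i, j) covers the half-open square [i, i+1) × [j, j+1), with
no epsilon tolerance at boundaries. Centroids are means of member pixel
indices. Mask dilation grows each label by a Euclidean disk; contested
pixels go to the nearest original label, distance ties to the lower label
id, and original pixels never flip. Likelihoods are evaluated through
cached Cholesky factors; MLE ties break to the lower cluster id, nearest
cell ties to the lower cell id. The Loewner order is classified by
eigenvalue checks at tolerance 1e-8 (eigenvalues, not Cholesky, so
*incomparable* is distinguishable from *not PSD in one direction*). Box's M
uses the chi-square approximation, M(1−c) with
df = p(p+1)(g−1)/2, appropriate for the group sizes used here; groups with
n ≤ p or a rank-deficient covariance get diagonal shrinkage with a warning.
Cluster-profile matrices (z-scored within each source, after depth
normalization, so sources of different depth are comparable) carry one
structurally null direction — the cell-count-weighted rows sum to zero — so
the profile-based Box's M in `compare_runs` uses a visible 1e-3 ridge.

## Problem sizes

The default test and acceptance workloads use the default FoV (~24k spots,
80 cells, 140 genes; a full 3-iteration run takes a few seconds), 180-cell
blob benchmarks for clustering, 1000 replicates for Box's M calibration,
and a 30-cell FoV for byte-determinism runs — sizes chosen to exercise
every code path at interactive speed while matching the per-FoV scale the
method targets.

## Known limitations

- Mock cells are circular and 2D; elongated morphologies will mix
  neighborhoods.
- The MLE operates in the full gene space with a ridge; with few cells per
  cluster the covariances are heavily regularized and classification is
  driven mostly by cluster means.
- DPMM fragility in noise-dominated high-dimensional spaces (above).
- Polygon segmentations support containment-free workflows (centroids,
  validation) but counting and dilation require a label mask.
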