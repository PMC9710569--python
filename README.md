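# sparcle

Iterative maximum-likelihood reassignment of "dangling" mRNA spots to cells
in multiplexed FISH images.

## The problem

Imaging-based spatial transcriptomics (MERFISH, smFISH, pciSeq, STARmap, …)
detects individual mRNA molecules as spots, but quantification requires
assigning each spot to a cell. Segmentations built by dilating nuclear
(DAPI) boundaries are conservative: in brain tissue roughly half of all
transcripts fall outside every cell boundary and are discarded, biasing the
cell-by-gene count matrix and everything downstream (cell typing, gene
programs). This package reassigns those dangling transcripts to neighboring
cells using gene covariation, and ships a ground-truth field-of-view (FoV)
simulator plus the covariance statistics used to evaluate the correction.

## The model

Cells of a cluster (cell type) $k$ are modeled as draws from a multivariate
Gaussian over normalized expression, $\mathcal N(\mu_k, \Sigma_k)$ — the
large transcript count per cell justifies the Gaussian by the central limit
theorem. Each iteration:

1. **Cluster** the current cell-by-gene matrix (Phenograph-style
   kNN/Jaccard/Leiden graph clustering, or a Dirichlet-process mixture with
   a Normal–Inverse-Wishart base fit by collapsed Gibbs sampling — neither
   needs the number of clusters in advance).
2. **Estimate moments** $(\mu_k, \Sigma_k)$ per cluster, with a small ridge
   $\lambda I$ keeping $\Sigma_k$ positive definite.
3. For every dangling spot, build a circular weighted **mock cell** of
   radius $r$: every spot within $r$ contributes weight
   $w(d) = 1/(1 + d/\delta)$ to its gene's entry.
4. **Classify** the mock cell by maximum likelihood,
   $\hat k = \arg\max_k \log\mathcal N(v;\mu_k,\Sigma_k)$, and assign the
   spot to the nearest cell carrying label $\hat k$ within a distance cap
   $D$; no candidate cell (or a too-small likelihood margin) leaves the spot
   dangling — the procedure is deliberately conservative.
5. **Update** the count matrix with all assignments at once and repeat
   (3 iterations by default).

Evaluation compares cluster expression profiles against a reference
(ground-truth programs or a paired scRNA-seq atlas) via K×K Gramian and
cross-covariance matrices, Frobenius distances, Box's M test, Loewner
(positive-semidefinite) ordering and Pearson correlation blocks.

## Worked example

```sh
sparcle simulate --seed 0 --out demo/sim
# simulated 23758 spots over 80 cells; dangling fraction 0.492

sparcle run --spots demo/sim/spots.csv --mask demo/sim/mask.tif \
            --iterations 3 --seed 0 --out demo/run
# assigned 11685 spots over 3 iteration(s); K=5 clusters
```

`demo/run/iterations.csv` then contains:

```
iteration,n_assigned,fraction_of_total,n_remaining_dangling,K
1,11622,0.48918259112719925,66,5
2,56,0.002357100766057749,10,5
3,7,0.0002946375957572186,3,5
```

The simulator leaves 49.2% of 23,758 transcripts dangling (the conservative
nuclear-segmentation regime); the run recovers nearly all of them, most in
the first iteration with a strictly decaying tail, while the clustering of
the corrected matrix finds the 5 simulated cell types. `demo/run/` also
holds the corrected matrix (`counts.mtx` + `barcodes.tsv`/`genes.tsv`,
`counts.csv`), per-spot assignment provenance (`assignments.csv`), per-cell
cluster labels (`clusters.csv`) and convex-hull cell boundaries
(`boundaries.csv`). `sparcle evaluate --pre … --post … --reference …`
produces the covariance comparison report.

The same pipeline is available as a library (`sparcle.simulate_fov`,
`sparcle.run_sparcle`, `sparcle.compare_runs`, …) for use on real spot
tables and label masks.

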