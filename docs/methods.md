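# Methods

## The φ (RUD) matrix

For each gene with at least two poly(A) sites annotated to its 3′ UTR
(a *3′ UTR-APA gene*), sites are ordered proximal → distal along the
direction of transcription: on the plus strand the distal site has the
larger genomic coordinate, on the minus strand the smaller one (BED
coordinates, 0-based half-open).  Genes whose 3′ UTR sites fall on both
strands are ambiguous and dropped with a warning.  The usage value is

φ(g, c) = distal-most site reads / Σ reads over all of g's 3′ UTR sites,

computed per cell; for genes with more than two sites the denominator runs
over *all* 3′ UTR sites so φ stays in [0, 1] regardless of site count.
Sites outside the 3′ UTR never contribute.  An entry is **missing** when
the denominator is below `min_total` (default 1: any read defines φ).
Missingness is an explicit mask, never 0 — φ = 0 is a legitimate value
(all reads proximal) and conflating the two would corrupt imputation.

## WNN iterative imputation

Model assumptions: cells of the same (unknown) state share φ profiles;
state is reflected in both the expression matrix G and the φ matrix, each
possibly partially; missingness is driven by read depth plus chance, so G
carries information about *which* entries are missing but the observed φ
values themselves are unbiased for the underlying usage.

**Embeddings.** G is library-size normalized to the median depth, log1p
transformed, gene-standardized, and reduced by PCA (deterministic full
SVD; per-component sign fixed so the largest-magnitude loading is
positive).  The φ modality is embedded the same way from the current
filled matrix, with per-gene centering only — φ is already bounded and
comparable across genes, and unit scaling would inflate the noise of
near-constant genes.  Default dimensionality `d = 30` per modality, capped
at min(n, p) − 1.

**Per-cell modality weights.** Following the Seurat-v4 weighted-nearest-
neighbor construction: for each modality, a cell's embedding is predicted
by the average of its 20 nearest within-modality neighbors and, cross-wise,
of its 20 nearest neighbors from the other modality.  The gap between
cross- and within-modality prediction errors, scaled by the cell's local
neighborhood band (k-th minus 1st neighbor distance), is softmaxed across
the two modalities into weights (w_expr, w_apa) summing to 1.  The fused
similarity of cells i, j is the weighted sum of per-modality exponential
kernels with the same per-cell bandwidth; the `k = 20` most similar cells
form the neighbor set.  kNN ties break by ascending cell index, so the
whole construction is deterministic.

**Iteration.** Missing entries are initialised with gene-wise observed
means (genes observed nowhere are dropped with a warning).  Each sweep
re-embeds the current φ matrix, recomputes weights and the fused graph,
and re-imputes every originally-missing entry; sweeps stop when the
largest change over imputed entries falls below `tol = 1e-3` or after
`max_iter = 10` sweeps (flagged, not an error).  Three choices in this
loop matter and are deliberate:

1. *The first sweep anchors the graph on expression alone.*  Before any
   imputation the φ embedding reflects only the fill pattern, not biology;
   learned weights would reward its spurious self-consistency.  From the
   second sweep onward the dual-modality weights are learned as above.
2. *Sweeps after the first are harmonic smoothing*: previously imputed
   values also propagate through the graph while observed entries stay
   pinned (each sweep iterates the neighbor average to its fixed point for
   the current graph).  A single kNN average over observed values pools at
   most k·(1 − dropout) noisy observations per entry; the harmonic fixed
   point pools across the whole connected neighborhood and is what lets
   the iteration denoise meaningfully beyond a gene-mean fill.
3. *Kernel weights inside the neighbor set are kept nearly flat*
   (bandwidth widened 4×).  A sharply decaying kernel concentrates the
   average on one or two cells and defeats the pooling; the neighbor
   *selection* still uses the unwidened kernel.

**Calibration.** Neighbor averages overstate what they know when data are
very sparse.  After the iteration, imputed deviations from the gene means
are rescaled by a slope fitted on an internal validation set: 10% of the
observed entries are held out, the full iteration is rerun on the reduced
matrix, and the held-out values are regressed through the origin on their
imputed estimates (both as deviations from gene means).  The slope is the
attenuation the data support — near 1 when neighbors predict held-out
values faithfully, well below 1 at extreme dropout — and the final imputed
value is gene_mean + slope · (estimate − gene_mean), clipped to [0, 1].
The fit is deterministic given the seed and leakage-free by construction.
Entries never reachable through any neighbor keep the gene mean and are
counted in the run report.

Observed entries are returned bit-for-bit unchanged.  Every imputed value
is a convex combination of the gene's observed values and its mean, hence
inside the gene's observed range and inside [0, 1].

## Sparse PLS-DA feature selection

Labels are one-hot encoded; X (cells × genes, complete — impute first) is
column-centered but not variance-scaled, since φ is bounded and directly
comparable across genes.  Components are extracted NIPALS-style: iterate
`a ← soft-threshold(Xᵀu)` keeping the top-`keepX` entries by magnitude
(threshold = the (keepX+1)-th largest magnitude, mixOmics convention; ties
at the boundary resolve by ascending index, and an all-tied boundary falls
back to hard selection), renormalize ‖a‖₂ = 1, update the Y side, and on
convergence deflate X and Y by regression on the score t = Xa.  Scores of
successive components are therefore orthogonal.  Signs are fixed per
component (largest-magnitude loading positive).  Prediction uses the
max-distance rule: project onto the rotation W(PᵀW)⁻¹, reconstruct the
one-hot response, take the argmax class.

**Tuning** is sequential per component with stratified k-fold CV
(default 10 folds, reduced with a warning when the smallest class is
smaller): with earlier components fixed, every `keepX` in the grid
(default {5, 10, 20, 30, 50, 100, 200, 300}) is scored by mean balanced
error rate; ties prefer the smaller `keepX`, and a component is retained
only while it improves the error by more than 0.01 (parsimony).  Maximum
components default to K + 1.  Fold assignment is seeded and reported.

Each component is a *meta-gene*; its class annotation is the class with
the most extreme score median (sign-invariant; flagged "none" when the
medians are indistinguishable).  meta-φ(h, c) is the unweighted mean of
φ⁺ over the component's selected genes — a bounded [0, 1] per-cell summary
suitable for spatial mapping.  The non-redundant feature set is the union
of per-component selections ranked by max |loading|.

## Visualization

Unsupervised: PCA (d = 30) then UMAP (n_neighbors 30, min_dist 0.3,
seeded; common single-cell defaults).  Semisupervised `spls+umap`: sPLS-DA
is fitted separately on normalized expression and on φ⁺, the two score
matrices are standardized per column (so neither modality dominates by
scale) and concatenated, and UMAP embeds the concatenation.  `pls+umap`
(dense loadings) and `spls-only` (first two components directly) are the
same machinery behind one `--scheme` flag.  Spatial maps fix the color
scale to [0, 1] for φ-valued panels and warn + autoscale otherwise.

## Evaluation protocol

*Profile PCC*: per cell, the Pearson correlation between its φ profile and
the gene-wise mean of observed raw φ over its own class, across genes
non-missing in both; undefined (NaN) below 3 shared genes.

*Silhouette*: mean silhouette over cells, Euclidean metric, computed on a
stated representation (PCA scores or a 2-D embedding); singleton classes
score 0 with a warning.

*Masking*: a uniformly random `floor(rate · n_observed)` subset of the
observed φ entries is set missing, and the same (gene, cell) entries of G
are zeroed, so both modalities lose the same information; the original
matrix is the gold standard for recovery.

*DEAPA*: per gene and class pair, a two-sided Wilcoxon rank-sum test on
observed φ; BH adjustment across genes within the pair; significant =
adjusted p < 0.05 (configurable).  Direction is the class with the higher
median φ (longer 3′ UTR).  For group sizes ≤ 8 the p-value is an exact
enumeration over all group assignments on midranks, two-sided as
P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|), which handles ties exactly; between
9 and 25 without ties, the classical exact distribution; otherwise the
normal approximation with tie correction.  Recovery of DEAPA genes is
scored as precision/recall/F1 of the recovered significant set against the
unmasked reference set, per class pair.

**A caveat the protocol exposes.**  Running a rank-sum test on a densely
imputed matrix treats smoothed values as independent observations.  They
are not: imputed entries of a class share observed donors, so even a gene
with no true class difference acquires a small but consistent shift
between classes (of order σ·√(2/n_donors)) with artificially tight
within-class spread, and the test calls it significant.  At the scale of
the bundled synthetic data this pseudo-replication dominates: DEAPA calls
from an imputed matrix over-call heavily relative to the unmasked
reference (precision ≈ 0.25 at recall ≈ 1), while the masked matrix
*without* imputation keeps calibrated precision and only loses recall —
so its F1 against the reference is higher at moderate masking.  Restricting
the recovered test to the reference's observed support softens but does
not remove the effect.  The imputed matrix is the right input for
embedding, visualization and feature selection; for calibrated
differential testing, test the observed values (or treat imputed entries
as estimates, not replicates).

## Synthetic data generator

The generator emulates the statistical shape of 3′-tag single-cell data as
seen from the APA layer.  Defaults define the reference conditions; all
draws come from one seeded `numpy` Generator.

| parameter | default | meaning / rationale |
|---|---|---|
| `n_cells`, `n_classes` | 300, 3 | equal-proportion cell types |
| `n_genes` | 2000 | expression genes in G |
| `n_apa_genes` | 500 | genes with a 2-site 3′ UTR (rows of ∅); a subset of G, as in real transcriptomes |
| `apa_variable_frac` | 0.3 | fraction of APA genes with true type-linked φ differences — DEAPA genes are a minority in real data |
| `type_concentration` | 2.5 | beta precision of per-type means around the gene base (per-type SD ≈ 0.2) for the variable fraction |
| `n_planted`, `delta_phi` | 20, 0.3 | planted DEAPA genes with an exact φ gap between a designated "long" type and the rest |
| `concentration` | 30 | beta precision of per-cell φ around the type mean (SD ≈ 0.09): biological cell-to-cell APA variability |
| `expr_signal_frac`, `expr_signal_log2_sd` | 0.2, 0.8 | genes with type-dependent expression fold changes — the expression modality's share of the class signal |
| `depth_log_mean`, `depth_log_sd`, `nb_size` | ln 3, 1.0, 2.0 | lognormal gene depth and NB dispersion typical of shallow 3′-tag counts |
| `dropout_rate` | 0.6 | target φ missingness; ∅ ends up far sparser than G (G's zero fraction ≈ 0.2) |
| `mcar_weight` | 0.3 | MCAR share of the extra dropout; the rest is count-dependent (logistic in log depth, low-depth entries vanish first), the structure WNN exploits |

Site reads are the gene's expression counts split binomially by the true
φ, so RUD computed from the site counts is unbiased for the truth; the
alternating-strand two-site annotation exercises the strand logic of the
φ module.  Dropout zeroes both sites of selected entries, with the count
of dropped entries chosen to hit the target missingness exactly (error if
the target is below the natural zero rate).  The spatial variant lays
cells on a square grid with classes as contiguous horizontal bands.

What the generator does **not** emulate: batch effects, doublets,
ambient contamination, >2 poly(A) sites per gene, continuous developmental
trajectories, within-class spatial gradients, or expression–φ coupling
beyond shared cell type.  Passing tests therefore demonstrate correctness
of the machinery and the qualitative behaviour of the method under
controlled dropout, not performance on any real tissue.

## Numerical conventions

PCA uses the deterministic full SVD; all kNN and similarity ties break by
ascending cell index; sPLS-DA and PCA signs are fixed by the
largest-magnitude-loading-positive rule; NIPALS converges at relative
1e-8 (cap 500 iterations); harmonic smoothing iterates to max-change
< 1e-4 (cap 50 sweeps) per graph; imputation outer tolerance 1e-3, cap 10
sweeps.  Every CLI command is deterministic given `--seed` — identical
inputs produce byte-identical outputs.

## Problem sizes

The bundled protocols run at 500 APA genes (2000 expression genes) × 300
cells with three types, the scale at which every stage — simulation,
imputation, cross-validated tuning, embedding and the masking experiments
— completes in a few minutes on a single CPU.

## Known limitations

Imputation assumes discrete, well-separated cell states; continuous
trajectories would be over-smoothed toward local neighborhoods.  At
extreme sparsity (≳ 85% missing) recovery approaches the information
limit: even an oracle neighbor graph barely improves on a gene-mean fill,
and the holdout-calibrated shrinkage correctly collapses imputed values
toward gene means.  The DEAPA pseudo-replication caveat above applies to
any dense imputation, not just this one.  sPLS-DA is linear; strongly
nonlinear class structure is only captured downstream by UMAP, not by the
feature selection itself.
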