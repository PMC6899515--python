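# Methods

## Model and assumptions

For one image and one target gene, the (processed) expression vector `y`
over `N` cells is modeled as a zero-mean Gaussian process with additive
covariance

```
K(θ) = σ²_int K_int + σ²_env K_env + σ²_c-c K_c-c + σ²_ε I_N .
```

The three structured kernels encode the three hypotheses about where a
gene's across-cell variance comes from. The intrinsic kernel `X Xᵀ` is the
covariance of a Bayesian linear regression of the target on the cell's own
remaining expression profile; the target gene is excluded from `X` both to
avoid a trivial self-effect and to keep signal spillover between channels
from masquerading as interaction. The environmental kernel is a
squared-exponential in the inter-cell distances and deliberately
unspecific: it absorbs any smooth spatial structure — metabolic gradients,
tissue-region effects, acquisition drift — that would otherwise be
misattributed to neighbors. The interaction kernel `Z X Xᵀ Zᵀ` is the
linear kernel on each cell's *neighborhood composition* `Z X`, the
distance-weighted average of all other cells' states, with `Z` a
zero-diagonal Gaussian-decay weight matrix sharing the environmental length
scale. Modeling assumptions worth keeping in mind: effects are additive
(no environment-by-neighborhood interactions), residuals are Gaussian
(hence the preprocessing below), and each gene is modeled independently.

## Preprocessing

Counts are variance-stabilized with the Anscombe-type transform for
negative-binomial data, `y = log(x + 1/(2φ))`. The printed source form of
this transform is typographically ambiguous ("1/2φ"); it is read as
`1/(2φ)`, the standard NB stabilizer. The dispersion `φ` (in
`var = μ + φ μ²`) is fitted globally per image by least squares of per-gene
variance on mean — the objective is quadratic in `φ`, so the closed-form
minimizer is used rather than an iterative optimizer; one global `φ` is
more stable than per-gene fits when only ~26 channels are available. The
log of the per-cell total signal (sum of raw counts over genes) is then
regressed out of every gene with an intercept, removing per-cell
"brightness" batch effects. The full matrix gets stabilization + total
regression + per-gene standardization (this is `X`); the target gene is
additionally rank-Gaussianized (probit of `r/(N+1)`, average ranks on ties)
for robustness to outliers. Already-continuous inputs (e.g. simulated
fields) skip stabilization. Whether state-matrix columns should also be
rank-Gaussianized is an open choice; here they are only standardized, which
keeps the linear kernel's gene weighting interpretable.

## Normalization and inference

Every structured kernel is divided by its own Gower factor
`G(K) = tr(PKP)/(N−1)`, `P = I − 11ᵀ/N`, before its scale multiplies it.
`G(K)` is the expected sample variance of a draw from `N(0, K)` (so
`G(I) = 1`, `G(11ᵀ) = 0`), which makes the fitted `σ²` directly comparable
variance contributions and the signature fractions
`G(σ²_eff K_eff)/Σ G` exact by construction. A kernel whose Gower factor is
numerically zero (e.g. an all-zero interaction kernel when `Z = 0`) is left
unnormalized and flagged degenerate.

Scales are optimized as `log σ²` (positivity by construction, bounded in
`[−30, 30]` against overflow) with analytic gradients under L-BFGS;
convergence at relative tolerance 1e-6, at most 500 iterations. The default
is one deterministic start (equal split of the target's variance) plus two
seeded random restarts; the previous grid point's optimum is reused as a
warm start. The shared length scale is chosen by grid search over 8
log-spaced values from 0.05× to 1.0× the image's median pairwise cell
distance — spanning "a couple of cell diameters" to "the image scale" —
with ties broken toward the smaller (more local) scale. A jitter of
1e-6 × mean diagonal is added before every Cholesky factorization; the log
marginal likelihood is always computed through the factorization, never an
explicit inverse.

Prediction for held-out cells uses the GP posterior mean
`K_* (K + σ²_ε I)⁻¹ y`. Cross-covariance blocks reuse the training
normalizations, and a held-out cell's neighborhood is built from training
cells only, so the prediction cannot leak the held-out cells' own target
values through `Z`. Cross-validation folds are uniform random partitions
under a fixed seed; preprocessing statistics (standardization, rank
transform) are computed once per image so folds stay commensurable.

## Significance

The interaction test statistic is `LLR = 2(logL_full − logL_reduced)`,
clipped at zero. Under the null the tested scale sits on the boundary of
its parameter space, so instead of the asymptotic χ²₁ the null is
simulated: draws from the fitted null covariance are processed like
observed data and both models are refitted on each draw (100 draws by
default). The refit protocol matches the observed statistic's protocol —
in particular, if the observed fit maximized over a length-scale grid, the
null refits maximize over the same grid; an asymmetric protocol (grid for
the observed fit, fixed scale for the null refits) makes the test
anti-conservative and is the main calibration pitfall. A mixture
`π₀ δ₀ + (1−π₀) χ²(df)` is fitted to the simulated LLRs (`π₀` = observed
zero fraction, `df` by maximum likelihood on the positive part; an optional
scale parameter is supported but off by default), and p-values are its
upper tail. If all simulated LLRs are zero the p-value falls back to the
add-one empirical exceedance. Benjamini-Hochberg adjustment is applied
jointly across all (image, gene) tests, and per-gene counts of significant
images use a 1% FDR threshold by default.

## Synthetic data

The image generator replaces empirical acquisitions: positions are uniform
in a square *with a minimum centroid spacing* of 0.4× the mean
nearest-neighbor distance of a uniform scatter (segmented cells have
physical extent; without the spacing floor, near-coincident pairs give
unphysical inverse-square neighbor weights that dominate the linear
simulator). Per-gene log intensity is a latent-factor mixture (correlated
cell states) plus a squared-exponential spatial field plus iid noise,
standardized to log-sd 0.5 and exponentiated around a mean count of 20;
counts are negative-binomial at dispersion 0.5. Defaults (500 cells, 26
genes, 3 latent factors) echo the shape of a breast-cancer IMC panel. The
generator emulates the statistical structure the model assumes — it has no
tissue morphology, no cell types, no segmentation masks, and *no built-in
interaction effect*, so passing tests demonstrate internal consistency and
robustness, not biological discovery on real tissue.

Two simulators create ground-truth interaction signal. The generative
simulator rescales a base model's interaction kernel by
`k_sim = [x/(1−x)] · G(K_int + K_env + σ²_ε I) / G(K_c-c)` and draws from
the resulting normal, so the simulated cell-cell Gower fraction equals `x`
exactly (the numerator is the Gower mass of the terms that accompany the
rescaled kernel; including the base interaction term there would make the
realized fraction only approximately `x`). Base terms default to kernels
built at 0.1× the median pairwise distance — an interaction range of a few
cell diameters, the scale at which juxtacrine and short-range paracrine
effects act; much wider neighborhoods make interaction draws empirically
indistinguishable from environmental fields. The linear simulator builds
`Y = √η_cc · b + √(1−η_cc) · a` where `b` is the standardized
interaction block `Z X β_c-c` (`Z`: inverse-square-distance weights on the
`N_nn` nearest neighbors, ties broken by index) and `a` the standardized
sum of a unit-variance intrinsic block `X β_I` and standard Gaussian noise;
`b` is orthogonalized against `a` before scaling so the empirical
interaction share equals `η_cc` exactly. Mis-segmentation mixes each cell's
target value and full profile with the mean of 2 partner cells sampled
without replacement with probabilities `∝ 1/d²` at share `η_mis`.

## Baselines

Three ridge regressions share the intrinsic block (all genes but the
target, standardized) and differ in the interaction block: inverse-square
weights over all cells, the plain mean of the 5 nearest neighbors, or their
inverse-square-weighted average. The penalty is chosen by internal 5-fold
CV over 13 log-spaced values 1e-3…1e3. Ridge models have no native variance
decomposition; their cell-cell attribution is defined here as the empirical
variance of the fitted interaction-block contribution divided by the
variance of the target — the most direct analogue of the GP fraction, and
an assumption to keep in mind when comparing numbers. The fourth baseline
is the same GP without the environmental term.

## Downstream analyses

Signatures are stacked into an images × (gene, component) matrix (genes
missing from any image are dropped with a warning) and summarized by PCA of
the column-centered matrix — columns are not rescaled because fractions are
already commensurate — with a deterministic sign convention. Category
enrichment ranks genes by a component's size and uses the unweighted
(rank-only) running-sum statistic, maximum height of the one-sided trace,
because categories are tested for *large* components; p-values are add-one
permutation estimates over gene-label shuffles, BH-adjusted across
categories, and categories need more than five genes. Two-class separation
projects PC scores on the centroid-connecting line and maximizes
`1 − √((1−spec)² + (1−sens)²)` over thresholds and both orientations, with
a label-permutation p-value.

## Problem sizes and numerical notes

Exact-likelihood GP inference is cubic in the cell count, so validation
experiments run at a few hundred cells: the acceptance script uses 10
images of 300–500 cells with 20 replicates per mis-segmentation setting;
the test suite uses 100–300-cell images, a 3–5-point length grid and single
starts where the quantity under test is an average over replicates. Null
calibration refits re-optimize scales over the same length grid as the
observed fits (see Significance). Single-draw variance estimates at a few
hundred cells carry sampling noise of ±0.05–0.15 in a fraction; claims are
therefore always about means or medians over seeds.

## Known limitations

Environmental and interaction effects are only partially identifiable —
with a wide neighborhood scale the interaction kernel converges to a smooth
spatial kernel, and the reduced model without the environmental term
measurably absorbs contamination into its interaction estimate. The model
is univariate (genes are fitted independently), assumes Gaussian residuals
after preprocessing, treats the two spatial terms as sharing one length
scale, and uses no sparse approximations, which limits single images to a
few thousand cells in practice.
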