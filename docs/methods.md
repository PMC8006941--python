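# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments do and do not establish.

## Spatial model and estimator

Cell positions are treated as marked point patterns in µm, restricted to
the annotated tumor region.  For each hexagonal tile the cross-type Ripley
K is estimated from the tumor-cell perspective:

K̂_ij(r) = A/(n_i·n_j) · Σ_{u∈i} Σ_{v∈j} 1{0 < ‖u−v‖ ≤ r} · e(u,v),

with A the tile's *effective* area (clipped hexagon minus excluded sparse
sub-hexagons) and e(u,v) the isotropic edge-correction weight: the
reciprocal of the fraction of the circle centred at u with radius ‖u−v‖
whose circumference lies inside the effective window.  The estimator is
evaluated from the i-side (u), per the conditional-expectation definition,
and is therefore not exactly symmetric in (i, j); the pipeline always uses
i = tumor.  The type-j intensity uses the effective area (n_j /
area_effective) for internal consistency with the weighting window.

The circle fraction is computed by discretizing the circle into 720 arcs
(0.5°) and testing the arc midpoints for containment, rather than by exact
circular-arc/polygon intersection; the error is below 0.15% of the weight
and the analytic half-plane case (weight 2) is reproduced to 0.5%.  For
convex hole-free windows the containment test is vectorized half-plane
arithmetic; otherwise it falls back to general point-in-polygon tests.
Circles entirely inside the window shortcut to weight 1.  Weights are
capped at 720 (one arc) with a warning, which stabilizes near-degenerate
sliver windows.  r_max is fixed at 338 µm (about 90% of the tile size)
even for clipped tiles, where the cap acts as the guard.

## Tessellation choices

Flat-top hexagons, grid anchored at the window bounding-box lower-left
corner plus a configurable offset; the anchoring is not meaningful
scientifically but makes every run reproducible.  Tiles clipped by the
region boundary are retained: their effective window is the clipped region
minus sparse sub-hexagons, and the edge correction handles the geometry.
Cells on shared tile edges are assigned to the lowest tile id (a
measure-zero event; determinism matters for testing).  Sub-hexagon grids
(side 50 µm) are anchored per tile at the tile hexagon's bounding box, and
a sub-hexagon is excluded when it holds fewer than two cells of any type.
Cells inside excluded sub-hexagons are removed from the spatial statistic
(they sit outside the effective window), but the tile's *abundance* counts
— in particular the deserted rule — use all cells assigned to the tile:
the exclusion exists to protect the L estimate from near-empty areas, not
to change how many immune cells the tile contains.

## Tile classifier

The fused-lasso logistic objective is minimized by a monotone accelerated
proximal-gradient scheme (FISTA with a monotonicity safeguard).  The
proximal operator of λ₁·TV + λ₂·L1 in one dimension is exact: total
variation proximity by a direct non-iterative taut-string algorithm,
followed by soft thresholding (the composition is exact in 1-D).  The
unpenalized intercept is re-optimized each iteration by a 1-D Newton
solve, which avoids the slow intercept convergence a plain gradient step
would have when features are on µm scales.  Iterations stop when the
objective decrease stays below `tol` (default 1e-8) for 10 consecutive
iterations or at `max_iter` (default 5000).  Correctness is defined by the
objective, not the algorithm: the unpenalized fit agrees with an IRLS GLM
to 1e-4, and the λ→∞ limits (constant coefficients / intercept-only) are
attained exactly.

Class coding is inflamed = 1, excluded = 0; the decision threshold is
p = 0.5.  Cross-validation uses stratified 5-fold accuracy with ties
broken toward stronger regularization (larger λ₁+λ₂, then larger λ₁).
Tiles with more than 5 immune cells but fewer than 2 tumor cells (or an
empty effective window) are *unclassifiable* and excluded from TIP
numerators and denominators; without a tumor pattern the cross-L curve is
undefined.

## Sample-level TIPs

Proportions are computed over classifiable tiles, with inflamed, excluded
and deserted forming one simplex (the deserted tiles stay in the
denominator).  "Shifted by 10%" is interpreted as 10% of the tile edge
length (37.5 µm by default) in the directions 0°, 90°, 180°, 270°;
placements yielding zero classifiable tiles are dropped from the average
rather than imputed.  Group comparisons of TIPs use the two-sided Wilcoxon
rank-sum test, exact when group sizes permit and no ties are present.

## Genomic association layer

Stability selection subsamples ⌈S/2⌉ observations without replacement per
run (200 runs by default), standardizes covariates within the subsample,
and fits an L1-penalized linear regression of the continuous TIP
proportion on the covariates with the penalty chosen per run by internal
5-fold cross-validation.  A covariate is selected when its coefficient is
non-zero; the selection probability is the count over runs.  A gaussian
model on the proportion is used (rather than a quasi-binomial), matching
how the proportions enter the association analyses.

The biomarker-validation layer forces the base covariates (age, stage ≥
IV, CD8 density, CD4 density) into every model; TIP covariates are first
pruned greedily at |ρ| > 0.6 keeping the univariately better (lower
deviance) TIP, then subjected to AIC forward–backward selection, and the
final model is compared with the base model by a likelihood-ratio
chi-square test with df = number of retained TIP terms.  The TMB endpoint
can be used continuously or dichotomized at 20 mutations/Mb.

## Deconvolution and signatures

Normalization scales each sample column to the mean column total
(library-size normalization; counts-per-million would differ only by a
global constant) and then divides each gene row by the square root of its
mean — under a Poisson mean–variance relation this stabilizes the variance
so no highly expressed gene dominates the quadratic fit.

The mixture fit min ‖X − I·λᵀ − C·(1−λ)ᵀ‖²_F with I and C on the gene
simplex is a convex QP.  It is solved by accelerated projected gradient
with the exact O(G log G) sorting projection onto the simplex; the
Lipschitz constant is 2·λ_max of the 2×2 Gram matrix of (λ, 1−λ), so the
step size is exact, and iterations stop when the projected-gradient (KKT)
residual falls below 1e-8.  When var(λ) < 1e-6 the profiles are not
identifiable (any split along the fitted line is optimal); the fit is
still returned but flagged.

The signature regression a_s = β_g·r_{g,s} has no intercept, matching the
model definition; an intercept variant exists behind a flag but is off by
default.  β_g is tested with a t statistic on S−1 degrees of freedom, and
Bonferroni correction uses family size G = all tested genes at α = 0.05.
Zero-variance residual rows are skipped.  The TIP predictor is an
ε-support-vector *regression* with RBF kernel: the response is a
continuous proportion, which a classifier could only handle after
thresholding.  Defaults are cost 4 and gamma 2⁻¹⁰; features are
standardized inside the fitted pipeline, and an optional grid search tunes
(cost, gamma) around the defaults.

## Synthetic data: what it emulates, what it does not

Tile generators realize the three phenotypes with the simplest mechanisms
matching their definitions: a Thomas (Poisson-cluster) process with
*shared* parents for inflamed tiles (tumor and immune offspring
co-cluster), parents confined to complementary half-hexagons for excluded
tiles (disjoint supports), and an immune count drawn uniformly from 0–5
for deserted tiles.  Defaults are 60 expected tumor and 60 expected immune
cells per tile (split evenly between CD8 and CD4), 5 cluster parents, and
a 20 µm cluster standard deviation — densities and cluster scales a tumor
microenvironment section plausibly exhibits while keeping a 100-tile
sample generable in seconds.  Sample generation assigns phenotypes to the
tiles of a rectangular region by exact largest-remainder rounding of the
requested proportions.

The expression generator draws the prototype profiles from a Dirichlet
over genes, λ uniform on [0.05, 0.6], ties the TIP to λ with small jitter,
plants the signature as a residual proportional to the TIP, and adds
Gaussian noise (clipped at zero).  The mutation generator is Bernoulli
with additive planted effects on a continuous response in
noise-standard-deviation units.

These generators satisfy the structural assumptions of each stage by
construction.  Passing the recovery experiments therefore shows that the
estimators and solvers are correct and well calibrated *under the model
assumptions*; it does not show that real tissue follows Thomas-process
geometry, that real expression is an exact two-component mixture, or what
classification accuracy pathologist-labeled tiles would yield.

## Validation experiment sizes

The reproduction script (`scripts/acceptance.py`) and the corresponding
tests use: a 13-step immune-count sweep for the deserted boundary; 50
random patterns of up to 50 points for the oracle comparison; 200 CSR
simulations with 100 + 100 points in a 375 µm hexagon for the calibration;
S = 118 balanced synthetic curves for the cross-validation benchmark; a
10×10-tile sample with planted (0.7, 0.3, 0) proportions for end-to-end
recovery, plus 20 random grid anchors on a 4×4-tile sample for the
shift-averaging variance comparison; a noiseless G = 200, S = 30 mixture
for deconvolution; 30 planted genes among 2000 (effect 1.5, noise 0.3,
S = 40) for signature recovery with a 100/50 train/test split for the SVR;
and 20 replications × 200 runs for stability selection (60 patients, 19
binary covariates at mutation frequency 0.3, one covariate shifting the
response by exactly one response standard deviation).  All sub-seeds
derive deterministically from the single `--seed` argument.

## Known limitations

* No pathologist-labeled training tiles ship with the package; classifiers
  here are trained on synthetic tiles, and
  accuracies on synthetic separable data mirror, but do not reproduce,
  accuracy on expert labels.
* The isotropic correction assumes the process extends stationarily beyond
  the window; heavily clipped boundary tiles with few immune cells tend to
  read as deserted, visibly so in small synthetic samples with a high
  boundary-to-interior ratio.
* The two-component deconvolution cannot separate immune subpopulations,
  and constant immune fractions leave the profiles unidentifiable.
* Stability-selection probabilities depend on the per-run penalty rule;
  with CV-chosen penalties, null covariates retain non-trivial selection
  frequencies, so probabilities should be ranked, not read as error rates.
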