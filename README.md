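# tipmap

Tumor infiltration phenotypes (TIPs) from multiplex-IHC cell coordinates.

Whether T cells actually infiltrate a tumor — rather than being blocked at
its margin or absent altogether — is prognostic information that neither
bulk immune-cell abundances nor plain cell densities capture.  `tipmap`
quantifies the three canonical local infiltration patterns from per-cell
coordinates (tumor, CD8+, CD4+ cells inside a pathologist-annotated tumor
region):

* **inflamed** — immune and tumor cells co-localize,
* **excluded** — immune and tumor cells occupy disjoint areas,
* **deserted** — immune cells are (nearly) absent.

It then links the resulting sample-level phenotype proportions to genomics:
mutation and pathway associations by lasso stability selection, and gene
expression signatures via a constrained two-component deconvolution, which
in turn let TIPs be predicted from expression alone.

## Method

**Tile-level spatial statistics.**  The tumor region is tessellated into
flat-top hexagonal tiles (side 375 µm); sub-hexagons of side 50 µm holding
fewer than two cells are excluded from a tile's analysis window so that
tissue tears and holes do not bias the statistics.  Within each tile the
cross-type Ripley functions are estimated for the pair (i = tumor,
j ∈ {CD8, CD4}):

    K_ij(r) = 1/λ_j · E[ t(u, r, X⁽ʲ⁾) | u ∈ X⁽ⁱ⁾ ],     L_ij(r) = √(K_ij(r)/π)

where t(u, r, X⁽ʲ⁾) counts type-j cells within distance r of u and λ_j is
the type-j intensity.  Each pair is weighted by the isotropic edge
correction (reciprocal fraction of the circle through v centred at u lying
inside the window).  Under independence L(r) = r, so the feature vector
x_r = L(r) − r (50 equidistant radii, 1–338 µm) is positive under
co-localization and negative under segregation.

**Tile classification.**  Tiles with ≤ 5 immune cells are *deserted*.
Otherwise a fused-lasso logistic regression distinguishes inflamed (y = 1)
from excluded (y = 0):

    β̂ = argmin −1/S Σ_s { y_s(β₀+βᵀx_s) − log(1+e^{β₀+βᵀx_s}) }
               + λ₁ Σ_r |β_{r+1} − β_r| + λ₂ Σ_r |β_r|

with penalties chosen by stratified 5-fold cross-validation.  The fusion
penalty exploits the strong correlation of consecutive L-curve points.

**Sample-level TIPs.**  Tile labels are aggregated into proportions of
inflamed / excluded / deserted tiles; the tile grid is additionally shifted
by 10% of the tile edge in the four axis directions and the five proportion
vectors averaged, making the TIP robust to grid placement.

**Genomic association.**  Pathway mutation scores
m_{i,p} = #mutated genes of patient i in pathway p / #genes in pathway p
(pathways kept at ≥ 40% panel overlap, genes at ≥ 20% mutation frequency)
and single genes are related to TIPs by lasso stability selection (200
subsampled fits; the selection frequency measures association strength).
A biomarker-validation layer extends a forced-in base model (age, stage,
CD8/CD4 densities) with correlation-pruned TIPs (|ρ| > 0.6) by AIC
stepwise selection and a likelihood-ratio test.

**Deconvolution and signatures.**  Normalized expression (samples scaled to
a common total, genes divided by √mean) is approximated as a convex mixture
X ≈ I·λᵀ + C·(1−λ)ᵀ of an immune and a cancer prototype profile (both on
the gene simplex, λ = per-sample immune fraction from the images), solved
as a constrained least-squares problem.  Genes whose residuals
r_{g,s} = x_{g,s} − x̂_{g,s} predict a TIP (no-intercept regression
a_s = β_g·r_{g,s}, Bonferroni-corrected) form the TIP's signature, and an
RBF support-vector regression (cost 4, gamma 2⁻¹⁰) on the signature genes
predicts TIPs from expression alone.

## Worked example

No real cohort ships with the package; the `tipmap.simulate` module
generates every input with known ground truth.  `examples/02_sample_tips.py`
builds a synthetic sample whose tiles are 60% inflamed / 25% excluded /
15% deserted, trains the tile classifier on separately simulated labeled
tiles, and prints:

```
sample: 3509 cells, region 11.1 mm^2, planted proportions {'inflamed': 0.6, 'excluded': 0.25, 'deserted': 0.15}
shift-averaged TIP (tumor, CD8):
  inflamed  0.544
  excluded  0.157
  deserted  0.299
per-placement classifiable tile counts: [41, 41, 44, 40, 44]
```

The recovered inflamed fraction tracks the planted 0.6; part of the
excluded share reads as deserted because tiles clipped at the region border
hold few CD8 cells — a real edge effect that shrinks with sample size.
The other examples demonstrate tile-level classification
(`01_tile_phenotyping.py`), mutation/pathway stability selection
(`03_mutation_associations.py`) and the deconvolution → signature → SVR
prediction chain (`04_deconvolution_signatures.py`).

A `tipmap` command-line interface wraps the same functions for shell use
(`tipmap --help`): `simulate`, `tessellate`, `lcurve`, `train`,
`aggregate`, `assoc`, `deconvolve`, `signature`, `predict`.

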