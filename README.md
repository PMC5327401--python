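# irisquant

Quantitative iris-pigmentation phenotyping from digital eye photographs, and
the statistical-genetics battery that such phenotypes feed: SNP association,
SNP×SNP epistasis, and genotype-based prediction of quantitative eye colour.

Human eye colour is continuous, driven by the type and amount of two iris
pigments — dark, compact **eumelanin** and sparse yellow-red **pheomelanin** —
with blue/grey arising from stromal light scattering where pigment is absent.
Classical gene-mapping studies collapse this continuum into a few manual
categories (blue / intermediate / brown), losing power. `irisquant`
implements an automated alternative: segment the iris from a photograph,
classify every iris pixel into *non-pigmented*, *pheomelanin*, or
*eumelanin*, and use the three areal proportions — which sum to one — as
quantitative phenotypes for genetic analysis. It is aimed at researchers in
pigmentation genetics and forensic DNA phenotyping who need continuous eye
colour phenotypes and the associated inference pipeline.

## What the package computes

**Segmentation.** Canny edges of the luminance image, then a circular Hough
transform constrained to near-central circles finds the limbus (iris/sclera
boundary); a second pass inside it finds the pupil, with a concentric
fallback at 0.30·limbus radius when pupil contrast is too weak. The
phenotype is computed on the annulus mask between the two circles.

**Pixel classification.** Iris pixels are mapped to HSV and assigned by a
one-vs-one soft-margin SVM with an inhomogeneous quadratic kernel
K(x, y) = (γ·x·y + c)², trained on labelled pixel regions (a model trained
on synthetic class colours ships with the package). The phenotype per eye is

    p_non + p_pheo + p_eu = 1,

the areal proportions of the three classes. Five legacy quantifiers are
computed on the same pixels for comparison: mean hue/saturation, a
luminosity-based melanin index with CIE chroma colour score, mean CIELAB
components, the two-cluster PIE ratio score, and the T-index
1 − (mean B + mean G)/510.

**Category separation.** How well any quantifier subspace separates manual
colour categories is measured by the Hellinger distance between the
category distributions, HD = √(1 − Σᵢ √(pᵢqᵢ)) on a shared histogram grid
(0 = identical, 1 = disjoint), plus the full Pearson correlation structure
among quantifiers.

**Genetics.** Genotypes are minor-allele dosages (0/1/2). The battery
includes exact Hardy–Weinberg tests, LD r², Rosenberg's informativeness for
assignment (In), per-SNP association by partial correlation (reported as
partial R² in % after age, sex and population), epistasis via nested-model
F-tests on the product term of Y ~ b₀ + b₁X₁ + b₂X₂ + b₃X₁X₂ + b₄age +
b₅sex + b₆pop with Bonferroni control, and prediction evaluated by 100
randomised train/holdout splits (2/3 training) reporting mean holdout R²
with 5%/95% quantiles.

**Synthetic ground truth.** Because no eye photographs or genotypes are
distributed, `irisquant.synthetic` renders eye images with known circles and
exact pigment proportions (spatially patchy pigment via thresholded smoothed
noise) and simulates population-structured cohorts (Balding–Nichols Fst,
additive + interaction + covariate effects, noise scaled to a target genetic
variance fraction). Every analysis stage is validated against these
generators.

## Worked example

```bash
python examples/quantify_eye.py
```

renders an eye with true proportions (0.20, 0.30, 0.50) and prints:

```
limbus: r=56.0 px at (80.0, 80.0);  true r=56.0
pupil:  r=19.0 px;  true r=19.2

proportions (non-pigmented, pheomelanin, eumelanin):
  recovered: 0.206  0.297  0.496
  truth:     0.200  0.300  0.500
  closure:   sum = 1.000000000000

legacy quantifiers on the same iris pixels:
  mean hue 0.072  mean saturation 0.513
  melanin index (1 - luminance) 0.602  colour score (chroma) 26.1
  L* 42.3  a* 5.9  b* 15.8
  PIE score 0.694  T-index 0.657
```

The detected limbus and pupil match the rendered geometry, the recovered
proportions are within 0.006 of truth and close exactly to one, and the
melanin-oriented scores (melanin index, PIE, T-index) sit in the upper half
of their ranges, as expected for a half-eumelanin iris.

Other examples: `examples/category_separation.py` (Hellinger separation of
blue/intermediate/brown in different quantifier subspaces) and
`examples/genetics_pipeline.py` (QC → association → epistasis scan →
cross-validated prediction on a simulated cohort).

A thin CLI wraps the same library calls for batch work:

```bash
irisquant --seed 1 simulate --out-dir fixtures/
irisquant quantify fixtures/ --out-csv phenotypes.csv --failures-csv failures.csv
irisquant genetics phenotypes.csv genotypes.csv covariates.csv --out-dir reports/
```

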