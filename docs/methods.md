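# Methods

This note records the models and procedures `irisquant` implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions that matter for reproducing its
output.

## Imaging and colour spaces

Images are 8-bit RGB, at least 64×64, with 0-based (row, col) pixel
coordinates and real-valued circle centres. Three pixel representations are
used:

* **HSV** (classification features): the standard hexcone transform; hue is
  a fraction of the full circle in [0, 1) and is defined as 0 for achromatic
  pixels. Because hue wraps at red, a circular encoding
  (cos 2πH, sin 2πH, S, V) is available for classification via
  `circular_hue=True`; the default is raw (H, S, V), which is adequate when
  the pheomelanin hues sit well away from the wrap point.
* **CIELAB**: sRGB primaries with D65 white. The conversion is implemented
  directly from the published equations, with the reference white taken as
  the sRGB matrix's image of (1, 1, 1) so that achromatic inputs map to
  a\* = b\* = 0 exactly rather than to ~10⁻³ residuals. No camera colour
  profile or illumination correction is attempted: fundus-camera imagery is
  taken under controlled flash, and absolute colorimetry is not required for
  proportions.
* **Relative luminance**: Rec.601 weights (0.299, 0.587, 0.114)/255.

## Iris segmentation

Two-step Canny + circular Hough procedure on the luminance image.

* Canny smoothing σ = 2 px; hysteresis thresholds at the 0.70/0.90 quantiles
  of gradient magnitude. Quantile thresholds adapt to overall image contrast
  and leave a constant image with an empty edge map rather than an error.
* Hough accumulation over integer radii; candidate circles are kept only if
  their centre lies within 0.05·min(H, W) of the image centre (eye images
  are framed with the pupil central; off-centre imagery is out of scope).
  Scores are the fraction of circle perimeter supported by edges; ties break
  toward the larger radius, which prefers the limbus over internal texture
  rings.
* Radius bands as fractions of min(H, W): limbus in [0.20, 0.48]; pupil in
  [0.05·min dim, 0.60·limbus radius], searched with the centre constrained
  to the detected limbus centre. If no pupil circle is found (dark irides
  often have little pupil contrast) a concentric fallback pupil of
  0.30·limbus radius is used — the phenotype must be computed on iris
  pixels only, and a slightly misplaced pupil boundary costs far less than
  including pupil pixels. Both detection and fixed-ratio exclusion are
  therefore available.
* The mask is the annulus pupil.radius < d ≤ limbus.radius and must cover at
  least 5% of the image; otherwise segmentation fails carrying the sample id,
  and a manually curated circle pair can be applied via
  `override_segmentation` (curated results are flagged).

Segmentation is fully deterministic: identical image and configuration give
a bit-identical mask.

## Pixel classification and quantifiers

The three-class pixel classifier is a one-vs-one soft-margin SVM with kernel
K(x, y) = (γ·x·y + c)², defaults γ = 1, c = 1, penalty C = 1, on per-dimension
min–max-scaled features. Defaults matter little when the class colour
distributions are separated in at least one HSV axis, which is the intended
training regime (the recovered proportions move by < 0.02 when the kernel is
swapped for RBF on such data). Training requires ≥ 20 pixels per class.
Models serialise to versioned JSON storing the scaled training set plus
hyperparameters; loading refits the SVM, which is deterministic for fixed
inputs, so a save/load round-trip reproduces identical labels. The shipped
default model (`data/default_classifier_synthetic.json`) is trained on
synthetic class-colour pixels, since no hand-labelled iris regions are
distributable; users with real imagery should train on their own labelled
regions (`irisquant train`).

The phenotype is the vector of class proportions among iris pixels; it sums
to one by construction and is invariant to pixel ordering.

Legacy quantifiers are computed on the same masked pixels. Their published
descriptions under-determine the formulas, so the concrete forms below are
interpretations of the cited prior methods, fixed so that every score's
orientation agrees with the correlation signs reported for such quantifiers
against melanin content (each rises with darker/more pigmented irides where
it should):

* mean hue (circular mean by default; arithmetic available) and mean
  saturation;
* melanin index `lum_l = 1 − mean relative luminance` and colour score
  `colour_c = mean √(a*² + b*²)` (CIE chroma);
* mean L\*, a\*, b\*;
* PIE score: 2-means clustering in CIELAB (fixed seed, 10 restarts for
  determinism); the cluster with lower mean L\* counts as "brown" and
  PIE = n_brown/n_total. A degenerate single-colour iris scores 1 if its
  mean L\* is below mid-scale, else 0. Whether the original ratio counted
  blue or brown pixels is ambiguous in the literature; this orientation
  makes PIE rise with eumelanin.
* T-index: 1 − (mean B + mean G)/(2·255), likewise oriented to rise with
  melanin.

## Category separation and correlations

Hellinger distance between two point samples is estimated on a shared
histogram grid spanning the pooled min–max per dimension (64 bins in 1-D,
32×32 in 2-D), HD = √(1 − Σ √(pᵢqᵢ)). The shared grid preserves the limit
cases exactly: identical samples give 0, disjoint-support samples give 1.
The estimator is deliberately simple and deterministic; kernel-density HD
estimators are out of scope. Note a finite-sample floor: two samples from
the same distribution give HD ≈ √(B/4n) from bin sampling noise alone
(≈ 0.13 at B = 64, n = 1,000), so "near zero" is only meaningful at sample
sizes large relative to the bin count.

Pearson correlations between quantifiers use pairwise-complete deletion and
two-sided p-values from the t distribution with n − 2 df; constant variables
are reported missing with a warning.

## Genetics

Genotypes are minor-allele dosages in {0, 1, 2, missing}; missing values are
handled by pairwise-complete deletion per test (no imputation). Population
enters all models as indicator columns with the alphabetically first level
as reference.

* **HWE**: the exact conditional test — the sum of probabilities, given the
  observed allele counts, of all heterozygote configurations no more
  probable than the observed one; monomorphic markers return 1. Verified
  against integer-arithmetic enumeration for every configuration with
  total ≤ 50.
* **LD**: composite r², the squared Pearson correlation of dosages (phase
  unknown).
* **Ancestry informativeness**: Rosenberg's In over the two alleles,
  In = Σ_alleles [−p̄ log p̄ + Σ_pops (p_pop/K) log p_pop], nats, with
  0·log 0 = 0.
* **Association**: genotype and phenotype are residualised on [intercept,
  age, sex, population dummies]; the partial correlation r of the residuals
  gives R² = 100 r², with p from t = r√(df/(1 − r²)) at df = n − 2 − k
  (k covariate columns; no convention for df is universal, this one matches
  the equivalent full-regression t-test, which is asserted to 1e-10). The
  reported beta is the genotype coefficient of the full linear model. Both
  covariate sets (age+sex and age+sex+population) are supported; the default
  includes population.
* **Combined model**: one multiple regression on all SNPs plus covariates;
  perfectly collinear SNPs are dropped with a warning (keeping the first);
  adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1).
* **Epistasis**: nested OLS models with and without X₃ = X₁X₂ compared by
  F = (RSS₀ − RSS₁)/(RSS₁/(n − p₁)) on 1 df. Degenerate product terms
  (collinear with main effects, e.g. a SNP with a single heterozygote) are
  flagged untestable rather than tested. The scan covers all pairs ×
  phenotypes, excluding pairs with LD r² > 0.8 (a high-LD pair's product
  term carries no independent signal; the literature excludes such pairs
  without stating a threshold, and 0.8 is the conventional plink-style cut).
  Bonferroni family size defaults to the number of tests performed and is
  configurable, since the appropriate family depends on how many phenotypes
  a study treats as primary.
* **Prediction**: OLS on [SNP dosages, requested product terms, age, sex,
  population dummies]. Out-of-sample performance is the mean holdout
  R² = 100(1 − SS_res/SS_tot) over 100 seeded random 2/3–1/3 train/holdout
  splits, with 5%/95% quantiles; holdout R² is the coefficient of
  determination on the validation set, not a squared correlation, so it can
  be negative for badly overfit models. Identical seeds give bit-identical
  results.

## Synthetic generators

`render_synthetic_eye` composes sclera, a dark pupil disc, and an iris
annulus whose pixels carry the three class labels in exactly the requested
proportions (largest-remainder apportionment over the iris pixel count).
Labels are spatially contiguous: a Gaussian random field smoothed at
`texture_scale` (default 4 px) is rank-thresholded, so pigment forms patches
rather than i.i.d. speckle. Colours are Gaussian per class around fixed
means (blue-grey stroma, amber pheomelanin, dark-brown eumelanin, separated
by several spread units in at least one HSV axis), plus channel noise
(default SD 3), clipped to [0, 255]. Everything is a pure function of
(spec, seed).

What the renderer does **not** emulate: eyelid/eyelash occlusion, specular
glints, limbal ring gradients, crypts and furrows, off-centre gaze, camera
colour-calibration drift. Passing recovery tests on these images therefore
demonstrates correctness of the segmentation/classification machinery under
the stated geometry and colour-separability assumptions, not robustness to
real-world image pathology — real deployments should expect a manual
curation rate comparable to published automated-segmentation failure rates
and use the override hook.

`simulate_cohort` draws individuals from K populations (default 3, equal
weights), per-population allele frequencies from the Balding–Nichols beta
model around ancestral frequencies (default Fst = 0.02, typical of
intra-European differentiation; this induces the pooled-sample
Wahlund-effect HWE deviations seen in multi-population panels), genotypes
binomial(2, freq) within population (hence in HWE within population by
construction), age uniform on 65–85 years (an elderly study population),
sex Bernoulli(½). The phenotype is the linear predictor (additive betas,
optional product terms, age/sex effects) plus Gaussian noise whose SD solves
var_e = var_g(1 − t)/t − var_cov for the target genetic variance fraction t
(validation error if covariate variance exceeds that budget); the realised
fraction matches the target within Monte-Carlo error (~±1.5 percentage
points at n = 3,000). SNPs are generated independently — LD structure is not
simulated except via explicit duplicate columns for collinearity tests.

The standard test cohort (`default_cohort_spec`) uses n = 3,000, 12 SNPs
with one dominant effect and a tail of smaller ones (echoing the skewed
effect-size architecture of eye-colour loci), two planted interactions, and
t = 0.5. These sizes keep the full validation battery, including 2,000-fold
null calibration of the interaction test, within desktop runtimes while
leaving Monte-Carlo error well inside the ±3-percentage-point recovery
bands.

In recovery checks, the *planned* per-SNP partial R² is computed after
covariates — beta²·var(g̃)/(Σ beta²·var(g̃) + σ_e²) with g̃ the
population-residualised dosage — because with Fst > 0 part of each dosage's
variance lies between populations and is removed by the partial correlation
by design.

## Known limitations

* Proportions are camera- and training-dependent: a classifier trained on
  one imaging setup should not be applied to another without relabelling.
* The quadratic-kernel default is a convention; on poorly separated pixel
  classes the choice of kernel and of γ, c, C will matter and should be
  cross-validated on the labelled regions.
* The Hellinger estimator's histogram floor (above) biases small distances
  upward at modest n.
* OLS-based genetics assumes unrelated individuals; kinship/mixed models,
  imputation, haplotype phasing and genome-wide scale are out of scope.
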