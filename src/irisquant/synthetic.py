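"""Ground-truthed synthetic eye images and genotype–phenotype cohorts.

Every downstream module is validated against these generators, since the raw
study data (photographs and genotypes) are not distributable.

Eye images are composed of a bright sclera, a dark pupil disc, and an iris
annulus whose pixels belong to the three pigment classes in exactly the
requested areal proportions. Class membership is spatially patchy: a Gaussian
random field smoothed at ``texture_scale`` is rank-thresholded so pigment
forms contiguous patches rather than i.i.d. speckle, which is what the
segmentation and classification stages face in real irides.

Cohorts follow the standard quantitative-trait model: individuals are sampled
from K populations, per-population allele frequencies are drawn from the
Balding–Nichols beta model around an ancestral frequency (so pooled samples
show the Wahlund-effect HWE deviations characteristic of multi-population
panels), genotypes are binomial(2, freq) within population, and phenotypes
are a linear predictor (additive SNP effects, optional pairwise product
terms, age and sex effects) plus Gaussian noise scaled so the genetic share
of phenotypic variance hits a stated target.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import EyeImage
from .quantification import CLASSES, LabeledPixelSet
from .segmentation import Circle
from .genetics import CovariateTable, GenotypeMatrix

__all__ = [
    "ClassColour",
    "SyntheticEyeSpec",
    "EyeGroundTruth",
    "PhenotypeSpec",
    "CohortSpec",
    "CohortData",
    "DEFAULT_CLASS_COLOURS",
    "render_synthetic_eye",
    "synthetic_training_pixels",
    "simulate_cohort",
    "make_fixture_suite",
]

LABEL_CODES = {"sclera": 0, "pupil": 1, "non_pigmented": 2, "pheomelanin": 3, "eumelanin": 4}


@dataclass(frozen=True)
class ClassColour:
    """Mean RGB and per-channel spread (SD) of one pigment class."""

    mean: tuple[float, float, float]
    spread: float = 8.0


# Blue-grey stroma, amber pheomelanin, dark-brown eumelanin. The means are
# separated by several spread units in at least one HSV axis so a quadratic
# SVM recovers the classes nearly perfectly.
DEFAULT_CLASS_COLOURS: dict[str, ClassColour] = {
    "non_pigmented": ClassColour((150.0, 180.0, 210.0)),
    "pheomelanin": ClassColour((185.0, 140.0, 60.0)),
    "eumelanin": ClassColour((60.0, 40.0, 30.0)),
}


@dataclass
class SyntheticEyeSpec:
    height: int = 160
    width: int = 160
    center: tuple[float, float] | None = None     # default: image centre
    limbus_radius: float | None = None            # default: 0.35 * min(H, W)
    pupil_radius: float | None = None             # default: 0.12 * min(H, W)
    sclera_colour: tuple[float, float, float] = (235.0, 230.0, 225.0)
    pupil_colour: tuple[float, float, float] = (15.0, 15.0, 15.0)
    class_colours: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COLOURS))
    proportions: tuple[float, float, float] = (1.0, 0.0, 0.0)  # (non, pheo, eu)
    texture_scale: float = 4.0
    noise_sd: float = 3.0
    seed: int = 0
    sample_id: str = "synthetic"

    def resolved(self) -> tuple[tuple[float, float], float, float]:
        m = min(self.height, self.width)
        center = self.center or ((self.height - 1) / 2.0, (self.width - 1) / 2.0)
        limbus = self.limbus_radius if self.limbus_radius is not None else 0.35 * m
        pupil = self.pupil_radius if self.pupil_radius is not None else 0.12 * m
        if not (0 < pupil < limbus < m / 2):
            raise ValueError("require 0 < pupil radius < limbus radius < min(H, W)/2")
        if abs(sum(self.proportions) - 1.0) > 1e-9 or min(self.proportions) < 0:
            raise ValueError("proportions must be non-negative and sum to one")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        return center, float(limbus), float(pupil)


@dataclass
class EyeGroundTruth:
    labels: np.ndarray                    # H x W int8, codes per LABEL_CODES
    limbus: Circle
    pupil: Circle
    proportions: tuple[float, float, float]

    def realised_proportions(self) -> tuple[float, float, float]:
        iris = self.labels >= LABEL_CODES["non_pigmented"]
        n = int(iris.sum())
        return tuple(
            float(np.sum(self.labels == LABEL_CODES[cls])) / n for cls in CLASSES
        )


def _allocate_counts(n: int, proportions) -> np.ndarray:
    """Largest-remainder apportionment of n pixels to the three classes."""
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def render_synthetic_eye(spec: SyntheticEyeSpec) -> tuple[EyeImage, EyeGroundTruth]:
    """Render one eye image with its per-pixel ground-truth labels.

    Deterministic in (spec, seed). Iris class labels realise the requested
    proportions exactly up to pixel-count rounding; colours are drawn from
    the per-class Gaussian distributions, channel noise added, clipped to
    [0, 255].
    """
    center, limbus_r, pupil_r = spec.resolved()
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    rr, cc = np.ogrid[:h, :w]
    d = np.hypot(rr - center[0], cc - center[1])
    pupil_mask = d <= pupil_r
    iris_mask = (d > pupil_r) & (d <= limbus_r)
    n_iris = int(iris_mask.sum())
    if n_iris == 0:
        raise ValueError("iris annulus contains no pixels")

    labels = np.zeros((h, w), dtype=np.int8)  # sclera
    labels[pupil_mask] = LABEL_CODES["pupil"]

    # patchy class texture: rank-threshold a smoothed Gaussian field
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), spec.texture_scale)
    vals = texture[iris_mask]
    order = np.argsort(vals, kind="stable")
    counts = _allocate_counts(n_iris, spec.proportions)
    class_idx = np.empty(n_iris, dtype=np.int8)
    start = 0
    for ci, cnt in enumerate(counts):
        class_idx[order[start:start + cnt]] = ci
        start += cnt
    iris_labels = np.array(
        [LABEL_CODES[cls] for cls in CLASSES], dtype=np.int8
    )[class_idx]
    labels[iris_mask] = iris_labels

    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.sclera_colour
    img[pupil_mask] = spec.pupil_colour
    for ci, cls in enumerate(CLASSES):
        sel = labels == LABEL_CODES[cls]
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        cc_spec = spec.class_colours[cls]
        img[sel] = np.asarray(cc_spec.mean) + cc_spec.spread * rng.standard_normal((n_sel, 3))
    if spec.noise_sd > 0:
        img += spec.noise_sd * rng.standard_normal(img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    image = EyeImage(pixels=pixels, sample_id=spec.sample_id, source="synthetic")
    truth = EyeGroundTruth(
        labels=labels,
        limbus=Circle(center[0], center[1], limbus_r),
        pupil=Circle(center[0], center[1], pupil_r),
        proportions=tuple(spec.proportions),
    )
    return image, truth


def synthetic_training_pixels(
    n_per_class: int = 300,
    class_colours: dict | None = None,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> LabeledPixelSet:
    """Labelled HSV training pixels drawn from the per-class colour model.

    Mirrors the manual labelling of obviously pigmented / non-pigmented iris
    regions: RGB draws from each class distribution (plus channel noise) are
    converted to HSV and labelled with their generating class.
    """
    from .imaging import rgb_to_hsv

    colours = class_colours or DEFAULT_CLASS_COLOURS
    rng = np.random.default_rng(seed)
    feats, labs = [], []
    for cls in CLASSES:
        cspec = colours[cls]
        rgb = np.asarray(cspec.mean) + cspec.spread * rng.standard_normal((n_per_class, 3))
        rgb += noise_sd * rng.standard_normal(rgb.shape)
        rgb = np.clip(np.round(rgb), 0, 255)
        feats.append(rgb_to_hsv(rgb))
        labs.extend([cls] * n_per_class)
    return LabeledPixelSet(
        features=np.vstack(feats),
        labels=np.asarray(labs, dtype=object),
        provenance=("synthetic",),
    )


# ------------------------------------------------------------------ cohorts

@dataclass
class PhenotypeSpec:
    """One quantitative phenotype's generating model.

    ``target_r2`` is the genetic share (main + interaction terms) of total
    phenotypic variance; the residual SD is solved from the realised genetic
    and covariate variances to hit it.
    """

    name: str
    betas: dict                                  # snp_id -> additive effect
    interactions: tuple = ()                     # ((snp_a, snp_b, beta3), ...)
    beta_age: float = 0.0
    beta_sex: float = 0.0
    target_r2: float = 0.5
    residual_sd: float | None = None             # only used when target_r2 == 0


@dataclass
class CohortSpec:
    n_individuals: int = 3000
    populations: tuple[str, ...] = ("pop1", "pop2", "pop3")
    population_weights: tuple[float, ...] | None = None
    snp_ids: tuple[str, ...] = tuple(f"snp{i + 1}" for i in range(12))
    ancestral_freqs: tuple[float, ...] | None = None   # default 0.2..0.45
    fst: float | tuple[float, ...] = 0.02
    phenotypes: tuple[PhenotypeSpec, ...] = ()
    age_range: tuple[float, float] = (65.0, 85.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 50:
            raise ValueError("cohort size must be at least 50")
        if self.ancestral_freqs is None:
            k = len(self.snp_ids)
            self.ancestral_freqs = tuple(
                0.2 + 0.25 * i / max(1, k - 1) for i in range(k)
            )
        for f in self.ancestral_freqs:
            if not (0 < f < 1):
                raise ValueError("ancestral frequencies must lie in (0, 1)")
        for ph in self.phenotypes:
            if not (0 <= ph.target_r2 < 1):
                raise ValueError("target variance-explained must lie in [0, 1)")


@dataclass
class CohortData:
    genotypes: GenotypeMatrix
    covariates: CovariateTable
    phenotypes: pd.DataFrame
    truth: dict


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Simulate a population-structured genotype–phenotype cohort.

    Within each population genotypes are binomial(2, freq) — i.e. in HWE by
    construction; pooled-sample HWE deviations arise only from the
    Balding–Nichols frequency differentiation (Fst).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    k_pop = len(spec.populations)
    weights = (
        np.asarray(spec.population_weights, dtype=float)
        if spec.population_weights is not None
        else np.ones(k_pop) / k_pop
    )
    weights = weights / weights.sum()
    pop_idx = rng.choice(k_pop, size=n, p=weights)
    population = np.asarray(spec.populations, dtype=object)[pop_idx]

    n_snp = len(spec.snp_ids)
    fst = np.broadcast_to(np.asarray(spec.fst, dtype=float), (n_snp,)).copy()
    pop_freqs = np.empty((k_pop, n_snp))
    for j in range(n_snp):
        p = spec.ancestral_freqs[j]
        f = fst[j]
        if f <= 0:
            pop_freqs[:, j] = p
        else:
            a = p * (1 - f) / f
            b = (1 - p) * (1 - f) / f
            pop_freqs[:, j] = np.clip(rng.beta(a, b, size=k_pop), 1e-4, 1 - 1e-4)
    geno = rng.binomial(2, pop_freqs[pop_idx, :]).astype(float)
    G = GenotypeMatrix(values=geno, snp_ids=spec.snp_ids)

    age = rng.uniform(*spec.age_range, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    cov = CovariateTable(age=age, sex=sex, population=population)

    pheno = {}
    truth: dict = {"pop_freqs": pop_freqs.tolist(), "fst": fst.tolist(), "phenotypes": {}}
    for ph in spec.phenotypes:
        genetic = np.zeros(n)
        for snp, beta in ph.betas.items():
            genetic += beta * G.column(snp)
        for a, b, b3 in ph.interactions:
            genetic += b3 * G.column(a) * G.column(b)
        cov_part = ph.beta_age * age + ph.beta_sex * sex
        var_g = float(np.var(genetic))
        var_cov = float(np.var(cov_part))
        if ph.target_r2 == 0:
            sd = ph.residual_sd if ph.residual_sd is not None else 1.0
        else:
            if var_g == 0:
                raise ValueError(
                    f"phenotype {ph.name!r}: non-zero variance target with no genetic effects"
                )
            var_e = var_g * (1 - ph.target_r2) / ph.target_r2 - var_cov
            if var_e < 0:
                raise ValueError(
                    f"phenotype {ph.name!r}: covariate variance exceeds the noise "
                    f"budget implied by target_r2={ph.target_r2}"
                )
            sd = float(np.sqrt(var_e))
        noise = sd * rng.standard_normal(n)
        y = genetic + cov_part + noise
        pheno[ph.name] = y
        total = float(np.var(y))
        truth["phenotypes"][ph.name] = {
            "target_r2": ph.target_r2,
            "residual_sd": sd,
            "realised_genetic_fraction": var_g / total if total > 0 else 0.0,
            "realised_covariate_fraction": var_cov / total if total > 0 else 0.0,
            "betas": dict(ph.betas),
            "interactions": [list(t) for t in ph.interactions],
        }
    return CohortData(
        genotypes=G,
        covariates=cov,
        phenotypes=pd.DataFrame(pheno),
        truth=truth,
    )


# ----------------------------------------------------------------- fixtures

def default_cohort_spec(
    n: int = 3000, target_r2: float = 0.5, seed: int = 0,
    with_interactions: bool = True, covariate_effects: bool = True,
) -> CohortSpec:
    """The standard 12-SNP test cohort.

    One dominant-effect SNP plus a tail of smaller effects (echoing the
    skewed architecture of eye-colour loci), two planted product-term
    interactions, and modest age/sex effects.
    """
    snps = tuple(f"snp{i + 1}" for i in range(12))
    betas = {
        "snp1": 1.00, "snp2": 0.45, "snp3": 0.35, "snp4": 0.25,
        "snp5": 0.20, "snp6": 0.15, "snp7": 0.10, "snp8": 0.08,
    }
    interactions = (("snp1", "snp3", 0.30), ("snp2", "snp5", 0.25)) if with_interactions else ()
    pheno = PhenotypeSpec(
        name="p_non",
        betas=betas,
        interactions=interactions,
        beta_age=0.01 if covariate_effects else 0.0,
        beta_sex=0.10 if covariate_effects else 0.0,
        target_r2=target_r2,
    )
    return CohortSpec(
        n_individuals=n, snp_ids=snps, phenotypes=(pheno,), seed=seed
    )


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> pd.DataFrame:
    """Write the standard fixture set and return its manifest.

    Contents: 60 eye images (20 blue-like, 20 intermediate, 20 brown-like
    proportion specs) with indexed ground-truth label grids, one simulated
    cohort (n=3000, 12 SNPs, 2 planted interactions) as CSV tables plus a
    JSON truth record, and a manifest CSV with per-file checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .imaging import write_image
    from PIL import Image

    categories = {
        "blue": (0.85, 0.10, 0.05),
        "intermediate": (0.40, 0.35, 0.25),
        "brown": (0.10, 0.20, 0.70),
    }
    rows = []
    rng = np.random.default_rng(seed)
    for cat, props in categories.items():
        for i in range(20):
            eye_seed = int(rng.integers(0, 2**31 - 1))
            radius_frac = float(rng.uniform(0.28, 0.42))
            spec = SyntheticEyeSpec(
                proportions=props,
                limbus_radius=radius_frac * 160,
                seed=eye_seed,
                sample_id=f"{cat}_{i:02d}",
            )
            image, truth = render_synthetic_eye(spec)
            img_path = out / f"{spec.sample_id}.png"
            lab_path = out / f"{spec.sample_id}_labels.png"
            write_image(image, img_path)
            Image.fromarray(truth.labels.astype(np.uint8), mode="L").save(lab_path)
            for path in (img_path, lab_path):
                rows.append(_manifest_row(path, category=cat, sample_id=spec.sample_id,
                                          p_non=props[0], p_pheo=props[1], p_eu=props[2]))

    cohort = simulate_cohort(default_cohort_spec(seed=seed + 1))
    geno_df = pd.DataFrame(cohort.genotypes.values, columns=cohort.genotypes.snp_ids)
    geno_df.insert(0, "sample_id", [f"ind{i:04d}" for i in range(len(geno_df))])
    cov_df = pd.DataFrame(
        {
            "sample_id": geno_df["sample_id"],
            "age": cohort.covariates.age,
            "sex": cohort.covariates.sex,
            "population": cohort.covariates.population,
        }
    )
    pheno_df = cohort.phenotypes.copy()
    pheno_df.insert(0, "sample_id", geno_df["sample_id"])
    paths = {
        "genotypes.csv": geno_df,
        "covariates.csv": cov_df,
        "phenotypes.csv": pheno_df,
    }
    for name, df in paths.items():
        p = out / name
        df.to_csv(p, index=False)
        rows.append(_manifest_row(p))
    truth_path = out / "cohort_truth.json"
    truth_path.write_text(json.dumps(cohort.truth))
    rows.append(_manifest_row(truth_path))

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _manifest_row(path: Path, **extra) -> dict:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    row = {"file": path.name, "sha256": digest}
    row.update(extra)
    return row
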