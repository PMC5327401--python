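"""Pixel classification into pigment classes and the colour quantifiers.

The primary phenotype is the areal proportion of three pixel classes inside
the segmented iris:

* ``non_pigmented`` — stromal blue/grey (Tyndall scattering), low saturation,
  high value;
* ``pheomelanin`` — yellow-to-red sparse pigment;
* ``eumelanin`` — dark compact pigment, low value.

Pixels are mapped to HSV and assigned by a soft-margin support vector machine
with an inhomogeneous quadratic kernel ``K(x, y) = (gamma * x.y + c)^2``,
trained one-vs-one on manually labelled regions (or on synthetic labelled
pixels). The three proportions sum to one by construction.

Five legacy quantifiers from the prior literature are computed on the same
masked pixels for comparison: mean hue/saturation, a luminosity-based melanin
index plus CIE chroma colour score, mean L*a*b*, the PIE two-cluster ratio
score, and the T-index built from normalised blue and green channels. Their
published descriptions under-determine the formulas; the concrete forms here
are interpretations fixed so that each rises with darker/more pigmented
irides wherever the field's reported correlation signs require it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .imaging import EyeImage, relative_luminance, rgb_to_hsv, rgb_to_lab
from .segmentation import (
    DEFAULT_CONFIG,
    IrisSegmentation,
    SegmentationConfig,
    apply_mask,
    segment_iris,
)

CLASSES = ("non_pigmented", "pheomelanin", "eumelanin")
MODEL_FORMAT_VERSION = "1"

__all__ = [
    "CLASSES",
    "LabeledPixelSet",
    "PigmentClassifier",
    "PigmentProportions",
    "ColourQuantification",
    "train_pigment_classifier",
    "classify_iris_pixels",
    "pigment_proportions",
    "mean_hue_saturation",
    "luminosity_colour_score",
    "lab_summary",
    "pie_score",
    "t_index",
    "quantify_eye",
]


def _as_pixels(pixels) -> np.ndarray:
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise ValueError("expected a non-empty N x 3 collection of RGB pixels")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    return arr


@dataclass
class LabeledPixelSet:
    """HSV training pixels with pigment-class labels.

    ``features`` are HSV triplets (hue fraction, saturation, value);
    ``labels`` take values in :data:`CLASSES`. Every class must be present at
    least ``min_per_class`` times for training.
    """

    features: np.ndarray
    labels: np.ndarray
    provenance: tuple[str, ...] = ()
    min_per_class: int = 20

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2 or self.features.shape[1] != 3:
            raise ValueError("features must be N x 3 HSV triplets")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")

    def validate_counts(self) -> None:
        for cls in CLASSES:
            n = int(np.sum(self.labels == cls))
            if n < self.min_per_class:
                raise ValueError(
                    f"class {cls!r} has {n} labelled pixels; need >= {self.min_per_class}"
                )


@dataclass
class PigmentClassifier:
    """Trained three-class pixel classifier with its feature scaling.

    The SVM is refit deterministically from the stored (scaled) training set
    on deserialisation, so a save/load round-trip reproduces identical labels.
    """

    svc: SVC
    feature_min: np.ndarray
    feature_range: np.ndarray
    train_features: np.ndarray  # already min-max scaled
    train_labels: np.ndarray
    gamma: float = 1.0
    coef0: float = 1.0
    reg: float = 1.0
    kernel: str = "poly"
    circular_hue: bool = False
    format_version: str = MODEL_FORMAT_VERSION

    def _encode(self, hsv: np.ndarray) -> np.ndarray:
        if self.circular_hue:
            h = hsv[:, 0]
            return np.column_stack(
                [np.cos(2 * np.pi * h), np.sin(2 * np.pi * h), hsv[:, 1], hsv[:, 2]]
            )
        return hsv

    def scale(self, hsv: np.ndarray) -> np.ndarray:
        enc = self._encode(np.atleast_2d(hsv))
        return (enc - self.feature_min) / self.feature_range

    def predict_hsv(self, hsv: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.scale(hsv))

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": self.format_version,
            "classes": list(CLASSES),
            "kernel": self.kernel,
            "gamma": self.gamma,
            "coef0": self.coef0,
            "reg": self.reg,
            "circular_hue": self.circular_hue,
            "feature_min": self.feature_min.tolist(),
            "feature_range": self.feature_range.tolist(),
            "train_features": np.round(self.train_features, 6).tolist(),
            "train_labels": self.train_labels.tolist(),
            # fitted decision data, stored for inspection
            "support_vectors": np.round(self.svc.support_vectors_, 6).tolist(),
            "dual_coef": np.round(self.svc.dual_coef_, 6).tolist(),
            "intercept": self.svc.intercept_.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PigmentClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported classifier format {payload.get('format_version')!r}"
            )
        X = np.asarray(payload["train_features"], dtype=float)
        y = np.asarray(payload["train_labels"], dtype=object)
        svc = _make_svc(payload["kernel"], payload["gamma"], payload["coef0"], payload["reg"])
        svc.fit(X, y)
        return cls(
            svc=svc,
            feature_min=np.asarray(payload["feature_min"], dtype=float),
            feature_range=np.asarray(payload["feature_range"], dtype=float),
            train_features=X,
            train_labels=y,
            gamma=payload["gamma"],
            coef0=payload["coef0"],
            reg=payload["reg"],
            kernel=payload["kernel"],
            circular_hue=payload["circular_hue"],
        )


def _make_svc(kernel: str, gamma: float, coef0: float, reg: float) -> SVC:
    if kernel == "poly":
        return SVC(kernel="poly", degree=2, gamma=gamma, coef0=coef0, C=reg,
                   decision_function_shape="ovo")
    if kernel == "rbf":
        return SVC(kernel="rbf", gamma=gamma, C=reg, decision_function_shape="ovo")
    raise ValueError(f"unsupported kernel {kernel!r}")


@dataclass(frozen=True)
class PigmentProportions:
    p_non: float
    p_pheo: float
    p_eu: float

    def __post_init__(self):
        for p in (self.p_non, self.p_pheo, self.p_eu):
            if not (0.0 <= p <= 1.0):
                raise ValueError("proportions must lie in [0, 1]")
        if abs(self.p_non + self.p_pheo + self.p_eu - 1.0) > 1e-9:
            raise ValueError("proportions must sum to one")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_non, self.p_pheo, self.p_eu)


@dataclass
class ColourQuantification:
    """One eye's complete quantitative colour record."""

    sample_id: str
    p_non: float
    p_pheo: float
    p_eu: float
    mean_h: float
    mean_s: float
    lum_l: float
    colour_c: float
    l_star: float
    a_star: float
    b_star: float
    pie: float
    t_index: float
    category: str | None = None

    FIELDS = (
        "sample_id", "p_non", "p_pheo", "p_eu", "mean_h", "mean_s",
        "lum_l", "colour_c", "l_star", "a_star", "b_star", "pie",
        "t_index", "category",
    )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}


def train_pigment_classifier(
    training: LabeledPixelSet,
    gamma: float = 1.0,
    c: float = 1.0,
    reg: float = 1.0,
    kernel: str = "poly",
    circular_hue: bool = False,
) -> PigmentClassifier:
    """Fit the one-vs-one quadratic-kernel SVM on min-max-scaled HSV features.

    Raises a validation error if any class has fewer than
    ``training.min_per_class`` pixels. If the classes are not linearly
    distinguishable at all (identical feature sets across classes) a warning
    is emitted but the model is still returned.
    """
    training.validate_counts()
    stub = PigmentClassifier(
        svc=None, feature_min=np.zeros(1), feature_range=np.ones(1),
        train_features=np.zeros((1, 1)), train_labels=np.zeros(1),
        gamma=gamma, coef0=c, reg=reg, kernel=kernel, circular_hue=circular_hue,
    )
    enc = stub._encode(training.features)
    fmin = enc.min(axis=0)
    frange = enc.max(axis=0) - fmin
    frange[frange == 0] = 1.0
    X = (enc - fmin) / frange
    y = training.labels

    if len({tuple(row) for row in np.round(X, 12)}) < len(CLASSES):
        import warnings

        warnings.warn("training classes are not separable (degenerate features)")

    svc = _make_svc(kernel, gamma, c, reg)
    svc.fit(X, y)
    return PigmentClassifier(
        svc=svc, feature_min=fmin, feature_range=frange,
        train_features=X, train_labels=y,
        gamma=gamma, coef0=c, reg=reg, kernel=kernel, circular_hue=circular_hue,
    )


def classify_iris_pixels(model: PigmentClassifier, pixels) -> np.ndarray:
    """Assign every RGB pixel to one of the three pigment classes."""
    arr = _as_pixels(pixels)
    hsv = rgb_to_hsv(arr)
    return model.predict_hsv(np.atleast_2d(hsv))


def pigment_proportions(labels) -> PigmentProportions:
    """Class counts divided by the total pixel count; sums to one."""
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    n = labels.size
    counts = [int(np.sum(labels == cls)) for cls in CLASSES]
    if sum(counts) != n:
        raise ValueError("labels contain values outside the three pigment classes")
    return PigmentProportions(counts[0] / n, counts[1] / n, counts[2] / n)


def mean_hue_saturation(pixels, hue_mode: str = "circular") -> tuple[float, float]:
    """Mean hue and saturation of the iris pixels.

    ``hue_mode='circular'`` averages hue as unit vectors (hue wraps at red);
    ``'arithmetic'`` is the plain mean. Saturation is always arithmetic.
    """
    hsv = rgb_to_hsv(_as_pixels(pixels))
    hsv = np.atleast_2d(hsv)
    mean_s = float(hsv[:, 1].mean())
    h = hsv[:, 0]
    if hue_mode == "arithmetic":
        mean_h = float(h.mean())
    elif hue_mode == "circular":
        ang = 2 * np.pi * h
        mean_h = float(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi)) % 1.0
        if mean_s == 0.0:
            mean_h = 0.0
    else:
        raise ValueError("hue_mode must be 'arithmetic' or 'circular'")
    return mean_h, mean_s


def luminosity_colour_score(pixels) -> tuple[float, float]:
    """Melanin index and colour score.

    ``lum_l = 1 - mean relative luminance`` (larger = darker = more melanin)
    and ``colour_c`` = mean CIE chroma ``sqrt(a*^2 + b*^2)`` over pixels.
    """
    arr = _as_pixels(pixels)
    lum_l = 1.0 - float(np.mean(relative_luminance(arr)))
    lab = np.atleast_2d(rgb_to_lab(arr))
    colour_c = float(np.mean(np.hypot(lab[:, 1], lab[:, 2])))
    return lum_l, colour_c


def lab_summary(pixels) -> tuple[float, float, float]:
    """Per-component means of the pixel CIELAB values."""
    lab = np.atleast_2d(rgb_to_lab(_as_pixels(pixels)))
    return tuple(float(v) for v in lab.mean(axis=0))


def pie_score(pixels, seed: int = 0, n_restarts: int = 10) -> float:
    """Two-cluster ratio score: fraction of iris pixels in the darker cluster.

    Pixels are 2-means clustered in CIELAB; the cluster with lower mean L* is
    taken as "brown" and PIE = n_brown / n_total, so the score rises with
    eumelanin. Degenerate single-cluster irides score 1 when their mean L*
    is below mid-scale (dark) and 0 otherwise.
    """
    lab = np.atleast_2d(rgb_to_lab(_as_pixels(pixels)))
    uniq = np.unique(np.round(lab, 9), axis=0)
    if len(uniq) < 2:
        return 1.0 if lab[:, 0].mean() < 50.0 else 0.0
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(lab)
    mean_l = [lab[assign == k, 0].mean() if np.any(assign == k) else np.inf for k in (0, 1)]
    brown = int(np.argmin(mean_l))
    return float(np.mean(assign == brown))


def t_index(pixels) -> float:
    """Melanin index from the averaged, normalised blue and green channels:
    ``T = 1 - (mean B + mean G) / (2 * 255)``; rises with melanin."""
    arr = _as_pixels(pixels)
    return float(1.0 - (arr[:, 2].mean() + arr[:, 1].mean()) / (2 * 255.0))


def quantify_eye(
    image: EyeImage,
    model: PigmentClassifier,
    config: SegmentationConfig = DEFAULT_CONFIG,
    segmentation: IrisSegmentation | None = None,
    hue_mode: str = "circular",
    category: str | None = None,
) -> ColourQuantification:
    """Full pipeline for one eye: segment, mask, classify, quantify.

    A precomputed (e.g. manually curated) ``segmentation`` may be supplied to
    bypass the automatic one. Segmentation failures propagate with the
    sample id attached.
    """
    seg = segmentation if segmentation is not None else segment_iris(image, config)
    pixels = apply_mask(image, seg)
    labels = classify_iris_pixels(model, pixels)
    props = pigment_proportions(labels)
    mean_h, mean_s = mean_hue_saturation(pixels, hue_mode)
    lum_l, colour_c = luminosity_colour_score(pixels)
    l_star, a_star, b_star = lab_summary(pixels)
    return ColourQuantification(
        sample_id=image.sample_id,
        p_non=props.p_non, p_pheo=props.p_pheo, p_eu=props.p_eu,
        mean_h=mean_h, mean_s=mean_s,
        lum_l=lum_l, colour_c=colour_c,
        l_star=l_star, a_star=a_star, b_star=b_star,
        pie=pie_score(pixels), t_index=t_index(pixels),
        category=category,
    )


def default_classifier() -> PigmentClassifier:
    """The classifier shipped with the package.

    Trained on synthetic labelled pixels (no hand-labelled iris regions are
    distributed with the package); see ``data/default_classifier_synthetic.json``.
    """
    path = Path(__file__).parent / "data" / "default_classifier_synthetic.json"
    return PigmentClassifier.load(path)
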