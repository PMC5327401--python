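"""Iris localisation: Canny edges, circular Hough transform, annulus mask.

A two-step procedure finds first the limbus (the outer iris/sclera boundary)
as the best centre-constrained circle in an outer radius band, then the pupil
as the best circle inside the limbus sharing its centre within a tolerance.
If pupil contrast is too weak for detection, a concentric fallback pupil of
radius ``fallback_frac * limbus.radius`` is used, since colour proportions
must be computed on the iris annulus, never on the pupil.

All radii in :class:`SegmentationConfig` are fractions of ``min(H, W)`` so
one configuration serves any image scale. Pixel coordinates are 0-based
(row, col); circle centres are real-valued in that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import feature as skfeature
from skimage import transform as sktransform
from scipy import ndimage

from .imaging import EyeImage, relative_luminance

__all__ = [
    "EdgeMap",
    "Circle",
    "IrisSegmentation",
    "SegmentationConfig",
    "SegmentationFailure",
    "detect_edges",
    "find_circles",
    "segment_iris",
    "apply_mask",
    "override_segmentation",
]


class SegmentationFailure(RuntimeError):
    """Raised when no acceptable limbus circle is found; carries the sample id."""

    def __init__(self, sample_id: str, reason: str):
        self.sample_id = sample_id
        self.reason = reason
        super().__init__(f"segmentation failed for {sample_id!r}: {reason}")


@dataclass(frozen=True)
class EdgeMap:
    edges: np.ndarray            # H x W bool
    gradient_magnitude: np.ndarray  # H x W float, >= 0


@dataclass(frozen=True)
class Circle:
    center_row: float
    center_col: float
    radius: float
    score: float = 0.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("circle radius must be positive")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables for the two-step Canny/Hough segmentation."""

    sigma: float = 2.0
    low_quantile: float = 0.70
    high_quantile: float = 0.90
    limbus_r_band: tuple[float, float] = (0.20, 0.48)  # fractions of min(H, W)
    pupil_r_band: tuple[float, float] = (0.05, 0.60)   # (frac of min dim, frac of limbus r)
    center_tolerance: float = 0.05                      # fraction of min(H, W)
    pupil_center_tolerance: float = 0.05
    fallback_frac: float = 0.30
    min_mask_fraction: float = 0.05


DEFAULT_CONFIG = SegmentationConfig()


@dataclass(frozen=True)
class IrisSegmentation:
    limbus: Circle
    pupil: Circle
    mask: np.ndarray
    curated: bool = False

    def __post_init__(self):
        if self.pupil.radius >= self.limbus.radius:
            raise ValueError("pupil radius must be smaller than limbus radius")


def detect_edges(
    image: EyeImage,
    sigma: float = DEFAULT_CONFIG.sigma,
    low_q: float = DEFAULT_CONFIG.low_quantile,
    high_q: float = DEFAULT_CONFIG.high_quantile,
) -> EdgeMap:
    """Canny edges of the relative-luminance image.

    Hysteresis thresholds are set at the ``low_q``/``high_q`` quantiles of
    gradient magnitude. A constant image yields an empty edge map.
    """
    if not (0 < low_q < high_q < 1):
        raise ValueError("quantiles must satisfy 0 < low_q < high_q < 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    grey = relative_luminance(image.pixels)
    smoothed = ndimage.gaussian_filter(grey, sigma)
    gr, gc = np.gradient(smoothed)
    grad = np.hypot(gr, gc)
    if grad.max() == 0:
        return EdgeMap(edges=np.zeros(grey.shape, bool), gradient_magnitude=grad)
    edges = skfeature.canny(
        grey, sigma=sigma, low_threshold=low_q, high_threshold=high_q, use_quantiles=True
    )
    edges &= grad > 0
    return EdgeMap(edges=edges, gradient_magnitude=grad)


def find_circles(
    edge_map: EdgeMap,
    r_min: int,
    r_max: int,
    center_tolerance: float,
    center: tuple[float, float] | None = None,
    max_candidates: int = 8,
) -> list[Circle]:
    """Circular Hough accumulation over integer radii in ``[r_min, r_max]``.

    Candidates whose centre lies farther than ``center_tolerance`` pixels
    from ``center`` (default: the image centre) are discarded; survivors are
    sorted by descending accumulator score, ties broken toward the larger
    radius (prefers the limbus over internal texture rings).
    """
    h, w = edge_map.edges.shape
    if not (0 < r_min < r_max < min(h, w) / 2):
        raise ValueError("require 0 < r_min < r_max < min(H, W)/2")
    if not edge_map.edges.any():
        return []
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)

    radii = np.arange(int(r_min), int(r_max) + 1)
    accum = sktransform.hough_circle(edge_map.edges, radii)
    # normalised accumulator: fraction of the circle perimeter supported by edges
    _, cols, rows, rads = sktransform.hough_circle_peaks(
        accum, radii, total_num_peaks=max_candidates * 4, normalize=False
    )
    candidates: list[Circle] = []
    for c, r, rad in zip(cols, rows, rads):
        d = np.hypot(r - center[0], c - center[1])
        if d > center_tolerance:
            continue
        ridx = int(rad) - int(r_min)
        score = float(accum[ridx, r, c])
        candidates.append(Circle(center_row=float(r), center_col=float(c),
                                 radius=float(rad), score=score))
    candidates.sort(key=lambda circ: (circ.score, circ.radius), reverse=True)
    return candidates[:max_candidates]


def _build_mask(shape: tuple[int, int], limbus: Circle, pupil: Circle) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d = np.hypot(rr - limbus.center_row, cc - limbus.center_col)
    dp = np.hypot(rr - pupil.center_row, cc - pupil.center_col)
    return (d <= limbus.radius) & (dp > pupil.radius)


def segment_iris(
    image: EyeImage, config: SegmentationConfig = DEFAULT_CONFIG
) -> IrisSegmentation:
    """Locate limbus and pupil and build the iris annulus mask."""
    h, w = image.shape
    m = min(h, w)
    edge_map = detect_edges(image, config.sigma, config.low_quantile, config.high_quantile)

    lim_lo = max(2, int(round(config.limbus_r_band[0] * m)))
    lim_hi = int(round(config.limbus_r_band[1] * m))
    lim_hi = min(lim_hi, (m - 1) // 2)
    limbus_cands = find_circles(
        edge_map, lim_lo, lim_hi, center_tolerance=config.center_tolerance * m
    )
    if not limbus_cands:
        raise SegmentationFailure(image.sample_id, "no centre-constrained limbus circle")
    limbus = limbus_cands[0]

    pup_lo = max(2, int(round(config.pupil_r_band[0] * m)))
    pup_hi = int(round(config.pupil_r_band[1] * limbus.radius))
    pupil: Circle | None = None
    if pup_lo < pup_hi:
        pupil_cands = find_circles(
            edge_map,
            pup_lo,
            pup_hi,
            center_tolerance=config.pupil_center_tolerance * m,
            center=(limbus.center_row, limbus.center_col),
        )
        if pupil_cands:
            pupil = pupil_cands[0]
    if pupil is None:
        pupil = Circle(
            center_row=limbus.center_row,
            center_col=limbus.center_col,
            radius=config.fallback_frac * limbus.radius,
            score=0.0,
        )
    mask = _build_mask((h, w), limbus, pupil)
    if mask.mean() < config.min_mask_fraction:
        raise SegmentationFailure(
            image.sample_id,
            f"iris mask covers {mask.mean():.1%} of the image (< {config.min_mask_fraction:.0%})",
        )
    return IrisSegmentation(limbus=limbus, pupil=pupil, mask=mask, curated=False)


def apply_mask(image: EyeImage, seg: IrisSegmentation) -> np.ndarray:
    """Return the masked iris pixels (N x 3 uint8) in row-major order."""
    if seg.mask.shape != image.shape:
        raise ValueError("segmentation mask does not match image dimensions")
    if not seg.mask.any():
        raise ValueError("empty iris mask")
    return image.pixels[seg.mask]


def override_segmentation(
    seg_or_failure: IrisSegmentation | SegmentationFailure,
    manual: tuple[Circle, Circle],
    shape: tuple[int, int] | None = None,
) -> IrisSegmentation:
    """Replace an automatic result (or failure) with manually curated circles.

    The mask is rebuilt from the manual circles; ``shape`` is required when
    overriding a failure (no mask to take dimensions from).
    """
    limbus, pupil = manual
    if pupil.radius >= limbus.radius:
        raise ValueError("manual pupil radius must be smaller than limbus radius")
    if shape is None:
        if isinstance(seg_or_failure, IrisSegmentation):
            shape = seg_or_failure.mask.shape
        else:
            raise ValueError("shape is required when overriding a segmentation failure")
    mask = _build_mask(shape, limbus, pupil)
    return IrisSegmentation(limbus=limbus, pupil=pupil, mask=mask, curated=True)


def overlay_circles(image: EyeImage, seg: IrisSegmentation) -> np.ndarray:
    """Debug overlay: detected circles drawn in green/red on a copy of the image."""
    out = image.pixels.copy()
    for circ, colour in ((seg.limbus, (0, 255, 0)), (seg.pupil, (255, 0, 0))):
        theta = np.linspace(0, 2 * np.pi, int(8 * circ.radius), endpoint=False)
        rr = np.round(circ.center_row + circ.radius * np.sin(theta)).astype(int)
        cc = np.round(circ.center_col + circ.radius * np.cos(theta)).astype(int)
        ok = (rr >= 0) & (rr < out.shape[0]) & (cc >= 0) & (cc < out.shape[1])
        out[rr[ok], cc[ok]] = colour
    return out
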