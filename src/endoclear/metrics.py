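"""Quantitative evaluation of highlight removal.

Three measures:

* **Percentage of highlights remaining** H_r = 100 * N_h / N_t, where
  N_h counts pixels still satisfying the highlight criteria and N_t is
  the total pixel count. When scoring a cleaned image the thresholds
  must be frozen from the *original* image, otherwise the adaptive
  channel means would shift the criterion between the before and after
  measurements.
* **Coefficient of variation** CoV = sigma / mu of the intensity inside
  a bounding-box neighborhood of each highlight region, averaged over
  regions. Well-blended reconstructions leave the neighborhood smooth,
  so lower is better. Regions are taken from the original image's mask
  for both sides of a comparison so that the two scores integrate over
  identical pixels.
* **Mask SSIM** between the binary highlight mask and the extracted
  highlight component: the mask is the target support of H, so a clean
  extraction scores high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .io import WORKING_SCALE, rgb_to_hsv, validate_rgb
from .masking import HighlightMask, SoftThresholds

__all__ = [
    "RegionBox",
    "MetricReport",
    "highlight_percentage",
    "extract_region_boxes",
    "cov_score",
    "mask_ssim",
]

#: Default padding (pixels) added around each highlight region's tight
#: bounding box when measuring neighborhood CoV.
DEFAULT_COV_MARGIN = 10

# 8-connectivity: diagonal neighbors join a region
_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class RegionBox:
    """Half-open pixel box [top, bottom) x [left, right), 0-based."""

    top: int
    left: int
    bottom: int
    right: int
    region_id: int

    def __post_init__(self) -> None:
        if self.bottom <= self.top or self.right <= self.left:
            raise ValueError(f"degenerate box {self}")


@dataclass
class MetricReport:
    """Per-image metric bundle (H_r in percent, CoV dimensionless)."""

    h_r: float
    cov: float
    ssim: float | None = None
    per_region_cov: list[tuple[int, float]] = field(default_factory=list)


def highlight_percentage(image: np.ndarray, thresholds: SoftThresholds) -> float:
    """H_r: percent of pixels satisfying the highlight criteria.

    ``thresholds`` are supplied by the caller; freeze them from the
    original image when scoring its cleaned counterpart.
    """
    image = validate_rgb(image)
    hsv = rgb_to_hsv(image)
    sat, val = hsv[:, :, 1], hsv[:, :, 2]
    n_h = int(((sat < thresholds.s_tau) & (val > thresholds.v_tau)).sum())
    n_t = sat.size
    return 100.0 * n_h / n_t


def extract_region_boxes(mask: HighlightMask, margin: int = DEFAULT_COV_MARGIN) -> list[RegionBox]:
    """Bounding boxes of 8-connected mask components, padded by ``margin``.

    Boxes are clipped to the image bounds; an empty mask yields an
    empty list.
    """
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    labels, n_regions = ndimage.label(mask.values, structure=_EIGHT_CONNECTED)
    h, w = mask.shape
    boxes: list[RegionBox] = []
    for region_id, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        rows, cols = sl
        boxes.append(
            RegionBox(
                top=max(rows.start - margin, 0),
                left=max(cols.start - margin, 0),
                bottom=min(rows.stop + margin, h),
                right=min(cols.stop + margin, w),
                region_id=region_id,
            )
        )
    return boxes


def cov_score(
    image: np.ndarray,
    mask: HighlightMask,
    margin: int = DEFAULT_COV_MARGIN,
) -> tuple[float, list[tuple[int, float]]]:
    """Mean neighborhood coefficient of variation sigma/mu.

    For every highlight region's padded bounding box, the population
    standard deviation over mean of the HSV value channel (intensity,
    on [0, 1]) is computed over *all* pixels in the box; the image
    score is the unweighted mean across regions.

    Returns ``(mean_cov, [(region_id, cov), ...])``. Regions whose mean
    intensity is zero are skipped with a warning; an empty mask raises.
    """
    image = validate_rgb(image)
    if mask.shape != image.shape[:2]:
        raise ValueError("image and mask shapes differ")
    boxes = extract_region_boxes(mask, margin=margin)
    if not boxes:
        raise ValueError("no highlight regions in mask; CoV undefined")
    intensity = rgb_to_hsv(image)[:, :, 2]
    per_region: list[tuple[int, float]] = []
    for box in boxes:
        patch = intensity[box.top : box.bottom, box.left : box.right]
        mean = float(patch.mean())
        if mean == 0.0:
            warnings.warn(f"region {box.region_id} has zero mean intensity; skipped")
            continue
        per_region.append((box.region_id, float(patch.std()) / mean))
    if not per_region:
        raise ValueError("all regions degenerate (zero mean intensity)")
    mean_cov = float(np.mean([c for _, c in per_region]))
    return mean_cov, per_region


def mask_ssim(mask: HighlightMask, highlight: np.ndarray) -> float:
    """SSIM between the binary mask and the extracted highlight component.

    The highlight image is reduced to luma (channel mean) and rescaled
    to [0, 1]; the mask is cast to {0.0, 1.0}. Standard SSIM with an
    11x11 Gaussian window (sigma = 1.5) and data range 1.0.
    """
    highlight = validate_rgb(highlight)
    if mask.shape != highlight.shape[:2]:
        raise ValueError("mask and highlight shapes differ")
    luma = highlight.mean(axis=2) / WORKING_SCALE
    reference = mask.values.astype(np.float64)
    return float(
        structural_similarity(
            reference,
            luma,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
            data_range=1.0,
        )
    )
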