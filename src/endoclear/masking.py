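"""Highlight mask construction from HSV chromatic criteria.

Specular highlights on wet tissue carry the illuminant's color: they are
bright and desaturated. A pixel is flagged when its saturation falls
below a soft threshold S_tau and its value exceeds a soft threshold
V_tau, where

    S_tau = min(S_mean, S_hard)      V_tau = max(V_mean, V_hard)

The channel means adapt the thresholds to the scene illumination; the
hard floors keep a highlight-free image from flagging its own brightest
ordinary pixels. The binary mask is then dilated with a square
structuring element so it also absorbs the thin dark ring that hugs
highlight regions in endoscopic imagery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "SoftThresholds",
    "HighlightMask",
    "compute_thresholds",
    "build_mask",
    "dilate_mask",
    "DEFAULT_S_HARD",
    "DEFAULT_V_HARD",
    "DEFAULT_SE_SIZE",
]

# The hard floors are user-tunable; these defaults flag only bright,
# desaturated pixels and never well-saturated tissue.
DEFAULT_S_HARD = 0.30
DEFAULT_V_HARD = 0.70
DEFAULT_SE_SIZE = 7


@dataclass(frozen=True)
class SoftThresholds:
    """Adaptive saturation/value thresholds, all on the [0, 1] HSV scale."""

    s_tau: float
    v_tau: float
    s_hard: float
    v_hard: float
    s_mean: float
    v_mean: float

    def __post_init__(self) -> None:
        for name in ("s_tau", "v_tau", "s_hard", "v_hard", "s_mean", "v_mean"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")


@dataclass(frozen=True)
class HighlightMask:
    """Binary highlight support mask.

    Attributes
    ----------
    values : (h, w) uint8 array of {0, 1}
    dilated : whether morphological dilation has been applied
    se_size : structuring-element side length used (0 if undilated)
    """

    values: np.ndarray
    dilated: bool = False
    se_size: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        object.__setattr__(self, "values", vals.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        """Number of flagged pixels."""
        return int(self.values.sum())


def compute_thresholds(
    hsv: np.ndarray,
    s_hard: float = DEFAULT_S_HARD,
    v_hard: float = DEFAULT_V_HARD,
) -> SoftThresholds:
    """Compute the soft thresholds from an HSV image's channel means."""
    hsv = np.asarray(hsv, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[2] != 3 or hsv.shape[0] == 0 or hsv.shape[1] == 0:
        raise ValueError(f"expected nonempty (h, w, 3) HSV array, got {hsv.shape}")
    if not 0.0 <= s_hard <= 1.0 or not 0.0 <= v_hard <= 1.0:
        raise ValueError("hard thresholds must lie in [0, 1]")
    s_mean = float(hsv[:, :, 1].mean())
    v_mean = float(hsv[:, :, 2].mean())
    return SoftThresholds(
        s_tau=min(s_mean, s_hard),
        v_tau=max(v_mean, v_hard),
        s_hard=s_hard,
        v_hard=v_hard,
        s_mean=s_mean,
        v_mean=v_mean,
    )


def build_mask(hsv: np.ndarray, thresholds: SoftThresholds) -> HighlightMask:
    """Flag pixels with S < s_tau and V > v_tau (both strict)."""
    hsv = np.asarray(hsv, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) HSV array, got {hsv.shape}")
    sat, val = hsv[:, :, 1], hsv[:, :, 2]
    flagged = (sat < thresholds.s_tau) & (val > thresholds.v_tau)
    return HighlightMask(values=flagged.astype(np.uint8), dilated=False, se_size=0)


def dilate_mask(mask: HighlightMask, se_size: int = DEFAULT_SE_SIZE) -> HighlightMask:
    """Binary dilation with an all-ones ``se_size`` x ``se_size`` square.

    Pixels outside the image are treated as background, so the mask
    never wraps. ``se_size`` must be odd so the element is centered.
    """
    if se_size < 1 or se_size % 2 == 0:
        raise ValueError(f"se_size must be a positive odd integer, got {se_size}")
    if se_size == 1:
        return replace(mask, dilated=True, se_size=1)
    structure = np.ones((se_size, se_size), dtype=bool)
    grown = ndimage.binary_dilation(mask.values.astype(bool), structure=structure)
    return HighlightMask(values=grown.astype(np.uint8), dilated=True, se_size=se_size)
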