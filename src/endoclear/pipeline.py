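"""End-to-end convenience wrappers: mask -> decompose -> score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import DecompositionResult, SvtParams, decompose
from .io import rgb_to_hsv, validate_rgb
from .masking import (
    DEFAULT_S_HARD,
    DEFAULT_SE_SIZE,
    DEFAULT_V_HARD,
    HighlightMask,
    SoftThresholds,
    build_mask,
    compute_thresholds,
    dilate_mask,
)
from .metrics import DEFAULT_COV_MARGIN, MetricReport, cov_score, highlight_percentage

__all__ = ["RemovalOutput", "remove_highlights", "evaluate_pair"]


@dataclass
class RemovalOutput:
    """Everything produced by one highlight-removal run."""

    result: DecompositionResult
    mask: HighlightMask  # dilated mask used by the decomposition
    raw_mask: HighlightMask  # chromatic mask before dilation
    thresholds: SoftThresholds


def remove_highlights(
    image: np.ndarray,
    s_hard: float = DEFAULT_S_HARD,
    v_hard: float = DEFAULT_V_HARD,
    se_size: int = DEFAULT_SE_SIZE,
    params: SvtParams | None = None,
) -> RemovalOutput:
    """Full pipeline on one image: thresholds, mask, dilation, decomposition."""
    image = validate_rgb(image)
    hsv = rgb_to_hsv(image)
    thresholds = compute_thresholds(hsv, s_hard=s_hard, v_hard=v_hard)
    raw_mask = build_mask(hsv, thresholds)
    mask = dilate_mask(raw_mask, se_size=se_size)
    result = decompose(image, mask, params=params)
    return RemovalOutput(result=result, mask=mask, raw_mask=raw_mask, thresholds=thresholds)


def evaluate_pair(
    before: np.ndarray,
    after: np.ndarray,
    s_hard: float = DEFAULT_S_HARD,
    v_hard: float = DEFAULT_V_HARD,
    se_size: int = DEFAULT_SE_SIZE,
    cov_margin: int = DEFAULT_COV_MARGIN,
) -> tuple[MetricReport, MetricReport]:
    """Score an original/cleaned image pair with shared references.

    Thresholds and highlight regions are both computed on ``before``
    only, so H_r uses one fixed criterion and CoV integrates over
    identical pixels on both sides. Returns (before_report,
    after_report); SSIM is not filled in here since it needs the
    extracted highlight component rather than the cleaned image.
    """
    before = validate_rgb(before)
    after = validate_rgb(after)
    if before.shape != after.shape:
        raise ValueError(f"dimension mismatch: {before.shape} vs {after.shape}")
    hsv = rgb_to_hsv(before)
    thresholds = compute_thresholds(hsv, s_hard=s_hard, v_hard=v_hard)
    regions = dilate_mask(build_mask(hsv, thresholds), se_size=se_size)
    reports = []
    for img in (before, after):
        h_r = highlight_percentage(img, thresholds)
        if regions.count() > 0:
            cov, per_region = cov_score(img, regions, margin=cov_margin)
        else:
            cov, per_region = float("nan"), []
        reports.append(MetricReport(h_r=h_r, cov=cov, per_region_cov=per_region))
    return reports[0], reports[1]
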