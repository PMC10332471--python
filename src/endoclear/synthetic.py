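"""Synthetic endoscopy-like scenes with planted specular highlights.

Real endoscopic frames are dominated by a smooth, reddish, nearly
low-rank diffuse tissue component, punctured by scattered specular
blobs that are bright and desaturated, each wrapped in a thin dark
boundary ring. The generator reproduces exactly those three features —
and retains the clean background and the ground-truth highlight mask —
so the masking, decomposition and metric modules can be exercised and
scored without any external data.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import io as eio
from .masking import DEFAULT_S_HARD, DEFAULT_V_HARD, HighlightMask

__all__ = ["SceneConfig", "SyntheticScene", "generate_background", "plant_highlights",
           "generate_scene", "save_scene"]

# Per-channel gains applied to the shared smooth field. The shared
# structure gives the background a uniform reddish hue (saturation
# (R-B)/R ~ 0.67, far above the masking floor), matching the fairly
# homogeneous chroma of tissue while keeping each channel's rank equal
# to the configured background rank.
_CHANNEL_GAINS = (195.0, 110.0, 65.0)

_PLACEMENT_RETRIES = 500


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    The highlight bounds are chosen so planted cores satisfy the
    chromatic highlight criteria by construction:
    ``highlight_saturation_max`` must stay below the default saturation
    floor and ``highlight_value_min`` above the default value floor.
    """

    width: int = 256
    height: int = 256
    background_rank: int = 3
    n_spots: int = 8
    spot_radius_range: tuple[int, int] = (3, 9)
    ring_width: int = 2
    ring_darkening: float = 0.4
    highlight_saturation_max: float = 0.15
    highlight_value_min: float = 0.92
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("scene must be at least 8x8")
        if self.background_rank < 1:
            raise ValueError("background_rank must be >= 1")
        lo, hi = self.spot_radius_range
        if lo < 2 or hi < lo:
            raise ValueError("spot radii must satisfy 2 <= min <= max")
        if not 0.0 < self.ring_darkening < 1.0:
            raise ValueError("ring_darkening must lie in (0, 1)")
        if self.highlight_saturation_max >= DEFAULT_S_HARD:
            raise ValueError(
                "highlight_saturation_max must stay below the default "
                f"saturation floor {DEFAULT_S_HARD}"
            )
        if self.highlight_value_min <= DEFAULT_V_HARD:
            raise ValueError(
                "highlight_value_min must exceed the default value floor "
                f"{DEFAULT_V_HARD}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class SyntheticScene:
    """Composite image, its clean background, and the planted-core mask."""

    composite: np.ndarray
    background: np.ndarray
    truth_mask: HighlightMask
    config: SceneConfig


def _smooth_profile(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random smooth positive 1-D profile with values in [0.5, 1]."""
    raw = gaussian_filter1d(rng.standard_normal(n), sigma=max(n / 8.0, 1.0), mode="wrap")
    span = raw.max() - raw.min()
    if span < 1e-12:  # pathologically flat draw
        return np.full(n, 0.75)
    return 0.5 + 0.5 * (raw - raw.min()) / span


def generate_background(config: SceneConfig) -> np.ndarray:
    """Smooth low-rank reddish background on the [0, 255] scale.

    A shared spatial field is built as the mean of ``background_rank``
    outer products of smooth row/column profiles, normalized to peak 1,
    then scaled by fixed per-channel gains (R > G > B) and perturbed
    with Gaussian pixel noise of ``noise_sigma`` intensity levels.
    """
    rng = np.random.default_rng([config.seed, 0])
    h, w = config.height, config.width
    field = np.zeros((h, w))
    for _ in range(config.background_rank):
        field += np.outer(_smooth_profile(rng, h), _smooth_profile(rng, w))
    field /= field.max()
    image = np.empty((h, w, 3))
    for c, gain in enumerate(_CHANNEL_GAINS):
        image[:, :, c] = gain * field
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=image.shape)
        image = np.clip(image, 0.0, eio.WORKING_SCALE)
    return image


def _ellipse_masks(
    h: int, w: int, cy: float, cx: float, ry: float, rx: float, ring: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean core and surrounding-ring masks for an axis-aligned ellipse."""
    yy, xx = np.ogrid[:h, :w]
    core = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    outer = ((yy - cy) / (ry + ring)) ** 2 + ((xx - cx) / (rx + ring)) ** 2 <= 1.0
    return core, outer & ~core


def plant_highlights(background: np.ndarray, config: SceneConfig) -> SyntheticScene:
    """Plant non-overlapping highlight blobs and their dark rings.

    Core pixels are specified in HSV — saturation at most
    ``highlight_saturation_max``, value at least ``highlight_value_min``
    — and converted to RGB, so they meet the highlight criteria by
    construction rather than by tuning. The annulus of ``ring_width``
    pixels around each core is darkened by ``ring_darkening``. The
    returned truth mask marks cores only.
    """
    background = eio.validate_rgb(background)
    rng = np.random.default_rng([config.seed, 1])
    h, w = background.shape[:2]
    composite = background.copy()
    truth = np.zeros((h, w), dtype=np.uint8)

    r_lo, r_hi = config.spot_radius_range
    ring = config.ring_width
    placed: list[tuple[float, float, float]] = []  # (cy, cx, clearance radius)
    margin = r_hi + ring + 2

    for _ in range(config.n_spots):
        for attempt in range(_PLACEMENT_RETRIES):
            ry = rng.uniform(r_lo, r_hi)
            rx = rng.uniform(r_lo, r_hi)
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            clearance = max(rx, ry) + ring + 1
            if all(
                np.hypot(cy - py, cx - px) > clearance + pc for py, px, pc in placed
            ):
                placed.append((cy, cx, clearance))
                break
        else:
            raise ValueError(
                f"could not place {config.n_spots} non-overlapping spots in a "
                f"{w}x{h} frame; reduce n_spots or the spot radii"
            )

        core, ring_px = _ellipse_masks(h, w, cy, cx, ry, rx, ring)
        composite[ring_px] *= 1.0 - config.ring_darkening
        n_core = int(core.sum())
        hsv = np.empty((n_core, 1, 3))
        hsv[:, 0, 0] = rng.uniform(0.0, 1.0)  # hue is irrelevant at low saturation
        hsv[:, 0, 1] = rng.uniform(0.0, config.highlight_saturation_max, size=n_core)
        hsv[:, 0, 2] = rng.uniform(config.highlight_value_min, 1.0, size=n_core)
        composite[core] = eio.hsv_to_rgb(hsv)[:, 0, :]
        truth[core] = 1

    return SyntheticScene(
        composite=composite,
        background=background,
        truth_mask=HighlightMask(values=truth, dilated=False, se_size=0),
        config=config,
    )


def generate_scene(config: SceneConfig | None = None, **overrides) -> SyntheticScene:
    """Background + planted highlights; fully determined by the seed."""
    if config is None:
        config = SceneConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a SceneConfig or keyword overrides, not both")
    return plant_highlights(generate_background(config), config)


def save_scene(scene: SyntheticScene, out_dir: str | os.PathLike, stem: str) -> list[str]:
    """Write composite/background/mask PNGs plus a JSON config sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    paths.append(eio.write_image(scene.composite, os.path.join(out_dir, f"{stem}_composite.png")))
    paths.append(eio.write_image(scene.background, os.path.join(out_dir, f"{stem}_background.png")))
    mask_rgb = np.repeat(scene.truth_mask.values[:, :, None] * 255.0, 3, axis=2)
    paths.append(eio.write_image(mask_rgb, os.path.join(out_dir, f"{stem}_mask.png")))
    sidecar = os.path.join(out_dir, f"{stem}_config.json")
    with open(sidecar, "w") as fh:
        json.dump(asdict(scene.config), fh, indent=2, sort_keys=True)
    paths.append(sidecar)
    return paths
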