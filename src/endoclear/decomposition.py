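"""Iterative pseudo-low-rank + highlight decomposition.

The image X is split as X = L + H, where L is a *pseudo*-low-rank,
highlight-free component and H is the highlight component supported on
the chromatic mask M. Each iteration applies singular value
thresholding (SVT, the proximal operator of the nuclear norm) to the
highlight-subtracted image and then re-extracts the highlight from the
sparse residue through the mask:

    L <- D_mu(X - H)
    H <- (X - L) (*) M
    mu <- lam * mu

with (*) the elementwise product. Because the shrinkage applied to the
singular values is 1/mu and mu grows geometrically, the decomposition
becomes progressively gentler: early iterations aggressively strip the
bright sparse highlight into H, late iterations return the remaining
detail to L. The loop stops when ||X - L - H||_F^2 <= zeta.

All operators act per color channel on the shared mask; the schedule
and convergence residual are common to the three channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import validate_rgb
from .masking import HighlightMask

__all__ = ["SvtParams", "DecompositionResult", "soft_threshold", "svt", "decompose"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SvtParams:
    """Schedule parameters for the iterative decomposition.

    mu0
        Initial SVT parameter; the first iteration shrinks singular
        values by 1/mu0. The default 0.0006 (shrinkage ~1667) removes
        the tail of the singular spectrum of an 8-bit-scale image while
        keeping its dominant structure.
    lam
        Per-iteration multiplier for mu (> 1), so shrinkage decays
        geometrically by 1/lam.
    zeta_rel
        Convergence tolerance relative to the image energy: the loop
        stops when ||X - L - H||_F^2 <= zeta_rel * ||X||_F^2.
    max_iter
        Safety cap on iterations.
    """

    mu0: float = 0.0006
    lam: float = 1.2
    zeta_rel: float = 1e-4
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if self.lam <= 1:
            raise ValueError("lam must exceed 1 for the shrinkage to decay")
        if self.zeta_rel <= 0:
            raise ValueError("zeta_rel must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class DecompositionResult:
    """Converged (or capped) decomposition X ~= L + H.

    ``low_rank`` (L) is the highlight-free output; ``highlight`` (H) is
    exactly zero off the mask. ``residual_trace`` holds
    ||X - L - H||_F^2 after each iteration.
    """

    low_rank: np.ndarray
    highlight: np.ndarray
    residual_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    final_mu: float = 0.0
    zeta: float = 0.0


def soft_threshold(x: np.ndarray | float, tau: float) -> np.ndarray | float:
    """Elementwise shrinkage sgn(x) * max(|x| - tau, 0)."""
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    arr = np.asarray(x, dtype=np.float64)
    out = np.sign(arr) * np.maximum(np.abs(arr) - tau, 0.0)
    return float(out) if np.isscalar(x) else out


def svt(matrix: np.ndarray, mu: float) -> np.ndarray:
    """Singular value thresholding D_mu(X) = U S_{1/mu}(Sigma) V^T.

    Computes the full SVD, shrinks every singular value by 1/mu
    (flooring at zero) and reconstructs. The proximal operator of
    (1/mu) * nuclear norm.
    """
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValueError("svt expects a 2-D matrix")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("svt input contains non-finite entries")
    u, sigma, vt = np.linalg.svd(matrix, full_matrices=False)
    shrunk = np.maximum(sigma - 1.0 / mu, 0.0)
    return (u * shrunk) @ vt


def decompose(
    image: np.ndarray,
    mask: HighlightMask,
    params: SvtParams | None = None,
) -> DecompositionResult:
    """Run the iterative decomposition of ``image`` under ``mask``.

    Parameters
    ----------
    image : (h, w, 3) float array on the [0, 255] working scale.
    mask : dilated highlight mask of matching spatial shape. An
        undilated mask triggers a warning (dark boundary rings around
        highlights would leak into L) but the run proceeds.
    params : schedule parameters; defaults are mu0=0.0006, lam=1.2,
        zeta_rel=1e-4, max_iter=100.

    Returns
    -------
    DecompositionResult
        With ``converged`` False if ``max_iter`` was reached first;
        the last iterate is still returned for diagnostics.

    Notes
    -----
    L and H are not clipped to [0, 255] here — intermediate values may
    leave the display range, and clipping inside the loop would break
    the X = L + S identity. Clip at write-out instead.
    """
    image = validate_rgb(image)
    if params is None:
        params = SvtParams()
    if mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {image.shape[:2]}"
        )
    if not mask.dilated:
        warnings.warn(
            "decompose called with an undilated mask; dark boundary rings "
            "around highlights will not be absorbed into H",
            stacklevel=2,
        )

    m = mask.values.astype(np.float64)[:, :, None]
    x_energy = float(np.sum(image**2))
    zeta = params.zeta_rel * x_energy

    low_rank = np.zeros_like(image)
    highlight = np.zeros_like(image)
    mu = params.mu0
    trace: list[float] = []
    converged = False
    iterations = 0

    for iterations in range(1, params.max_iter + 1):
        for c in range(3):
            low_rank[:, :, c] = svt(image[:, :, c] - highlight[:, :, c], mu)
        highlight = (image - low_rank) * m
        residual = float(np.sum((image - low_rank - highlight) ** 2))
        trace.append(residual)
        logger.debug(
            "iter %d: mu=%.6g shrinkage=%.4g residual=%.6g (zeta=%.6g)",
            iterations, mu, 1.0 / mu, residual, zeta,
        )
        final_mu = mu
        mu *= params.lam
        if residual <= zeta:
            converged = True
            break

    return DecompositionResult(
        low_rank=low_rank,
        highlight=highlight,
        residual_trace=trace,
        iterations=iterations,
        converged=converged,
        final_mu=final_mu,
        zeta=zeta,
    )
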