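# Methods

## Model

An endoscopic frame is modeled as `X = L + H (+ R)`: a *pseudo-low-rank*
tissue component `L`, a specular highlight component `H` supported on a
binary mask `M`, and a residue `R` driven below a tolerance at
convergence. "Pseudo" is the operative word: `L` is not a true low-rank
factor — it retains sparse, clinically relevant detail — it is merely
*highlight-free*. The decomposition alternates singular value
thresholding (SVT) of the highlight-subtracted image with masked
re-extraction of the highlight:

```
L <- D_mu(X - H);   H <- (X - L) ⊗ M;   mu <- lam * mu
```

per color channel, with the mask shared across channels and computed
once, before the loop. The SVT operator `D_mu(A) = U S_{1/mu}(Σ) Vᵀ`
soft-thresholds each singular value by `1/mu` (it is the proximal
operator of `(1/mu)·||·||_*`, hence non-expansive — a property the test
suite checks directly). Since `lam > 1`, the shrinkage decays
geometrically: the first iterations remove a large singular tail,
pushing all sparse bright structure into `H`; later iterations shrink
almost nothing, so detail that the mask did not flag flows back into
`L`. Convergence is declared when `||X - L - H||_F² <= zeta`. Off the
mask the residue equals `X - L`, and since `L -> X - H_prev` as the
shrinkage vanishes while `H_prev` lives on the mask, the loop always
converges for `lam > 1` (in practice in 20–30 iterations at the default
tolerance).

### Assumptions

- The diffuse tissue component is approximately low-rank per channel;
  highlights are sparse and chromatically distinct (low saturation,
  high value).
- Highlight positions and the useful sparse detail are spatially
  disjoint, so masked multiplication cleanly splits the sparse residue.
- The mask from the first frame of the loop remains valid throughout
  (it is not recomputed between iterations).

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| `s_hard` | 0.30 | HSV saturation | hard floor in `S_tau = min(S_mean, s_hard)`; keeps a highlight-free image from flagging its own brightest pixels |
| `v_hard` | 0.70 | HSV value | hard floor in `V_tau = max(V_mean, v_hard)` |
| `se_size` | 7 | px | side of the square dilation element; must exceed twice the dark-ring width to absorb boundary artifacts |
| `mu0` | 0.0006 | — | initial SVT parameter; shrinkage `1/mu0 ≈ 1667` removes the singular tail of an 8-bit-scale image while keeping dominant structure |
| `lam` | 1.2 | — | geometric growth of `mu` per iteration |
| `zeta_rel` | 1e-4 | — | convergence tolerance relative to `‖X‖_F²` |
| `max_iter` | 100 | — | safety cap; non-convergence returns the last iterate with `converged=False` |
| `cov_margin` | 10 | px | padding of region bounding boxes for the CoV metric |

The working intensity scale is [0, 255] real-valued. This matters:
`mu0 = 0.0006` only behaves as intended (removing a *tail* of singular
values rather than everything) when singular values have 8-bit
magnitude. HSV channels are normalized to [0, 1] regardless, so the
mask thresholds are scale-free. `zeta` is defined *relatively* because
no absolute threshold can serve images of different sizes and
brightness; 1e-4 of the image energy corresponds to well under one
8-bit level RMS.

## Numerical choices

- Each color channel is decomposed independently with the shared mask;
  the convergence residual sums over all three channels. An unfolded
  `w x 3h` variant would couple chroma through a single SVD but is not
  the default.
- Strict inequalities in the mask criteria (`S < S_tau`, `V > V_tau`);
  threshold-equality pixels are not flagged.
- Dilation treats out-of-frame pixels as background; masks never wrap.
- `L` and `H` are never clipped inside the loop — clipping would break
  the `X = L + S` identity; quantization to [0, 255] happens only at
  PNG write-out.
- Full (non-truncated) LAPACK SVD: at endoscopy resolutions a 256–1024
  square SVD is milliseconds, and exactness keeps the SVT operator's
  contract testable to 1e-8.
- The loop is deterministic end to end; repeated runs are
  byte-identical (checked at PNG level).

## Metrics

- `H_r = 100 · N_h / N_t` counts pixels still meeting the highlight
  criteria. When scoring a cleaned image the thresholds are frozen from
  the *original* — recomputing the adaptive means on the cleaned image
  would shift the criterion mid-comparison.
- CoV = population sigma / mean of the HSV value channel over each
  highlight region's padded bounding box, averaged (unweighted) over
  regions. Regions come from the original image's dilated mask for both
  sides of a comparison, so both scores integrate over identical
  pixels. Intensity is used because highlight damage is an intensity
  artifact; population (not sample) sigma is the stated convention.
- Mask SSIM: the binary mask, cast to {0, 1}, against the highlight
  component's luma (channel mean / 255), 11×11 Gaussian window with
  sigma 1.5, data range 1. The highlight component is not binarized
  before comparison.

## Synthetic scenes

The generator emulates exactly the features the method exploits:

- a smooth background built as `background_rank` (default 3) outer
  products of random smooth profiles — one shared spatial field scaled
  by fixed per-channel gains (195, 110, 65), giving the reddish gamut
  `R > G > B` with constant tissue saturation ≈ 0.67, far above the
  0.30 masking floor, plus Gaussian pixel noise (sigma 2 levels);
- 8 non-overlapping elliptical highlight cores (radii 3–9 px) specified
  *in HSV* (S ≤ 0.15, V ≥ 0.92) and converted to RGB, so they satisfy
  the mask criteria by construction rather than by tuning;
- a 2 px annulus around each core darkened by 40%, reproducing the dark
  boundary ring.

Default scenes are 256×256: large enough for meaningful spectra and
region statistics, small enough that a full pipeline run takes about a
second and a 20-scene batch stays within half a minute.

What the generator does **not** model: bubbles, motion blur, debris,
vignetting, chromatic aberration, specular streaks with saturated
sensor clipping, or tissue with strong high-rank texture. Passing tests
therefore demonstrate the algorithm's contracts (conservation, support
containment, highlight elimination, blending, identity on clean input)
under its stated assumptions — not clinical performance on real
endoscopy, which must be assessed on real data.

## Design notes

- The shared background field (rather than fully independent channel
  fields) is a deliberate safety property: independent smooth channels
  can coincidentally produce bright desaturated background patches that
  meet the highlight criteria, making "clean background" scenes
  ill-defined as a test condition.
- Because the composite equals the background everywhere off the mask,
  no method with a global spectral step can match the ground truth
  there bit-for-bit; the preservation contract is therefore bounded:
  off-mask mean absolute deviation of `L` from the clean background
  stays below one 8-bit intensity level (the convergence tolerance
  implies roughly this bound).
- An undilated mask in `decompose` warns but proceeds: the result is
  valid, it merely leaves boundary rings in `L`.
- Grayscale input is rejected rather than channel-replicated — the mask
  logic is chromatic and saturation of a replicated gray image is
  identically zero, which would flag every bright pixel.

## Limitations

- A highlight overlapping structure that contributes heavily to the
  low-rank component is filled with globally plausible, not locally
  plausible, content; blending degrades when the image splits into
  regions with very different statistics.
- The mask is purely chromatic: desaturated bright non-highlight
  objects (instruments, bubbles' crowns) will be flagged and
  reconstructed.
- Hard floors (0.30 / 0.70) are sensible for typical endoscopic gamuts
  but are configuration, not ground truth; unusual illumination may
  need adjustment.
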