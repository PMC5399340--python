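# Methods

This note documents the model, the numerical choices, the synthetic
test-bed and the limits of what the tests demonstrate.

## Tracking model

The tracked object is an axis-aligned rectangular region (default
101×41 px) in a single-channel image sequence normalised to [0, 1].
Motion is assumed predominantly lateral (the tendon axis is the image
x axis); the depth (y) component is estimated but never drives any
decision. All coordinates are 0-based pixel indices, x rightward,
y downward, regions anchored at the top-left corner.

### Lucas–Kanade stage

For each adjacent frame pair the brightness-constancy equation
`Ix·Vx + Iy·Vy = −It` is solved by least squares over a `of_window`
(default 17×17) footprint at each node of a `flow_grid_step`-spaced grid
(default 2 px) inset into the region by `window // 2`, giving 43×13 = 559
flow points for the defaults. Numerics:

- Both frames are pre-blurred with an isotropic Gaussian
  (`presmooth_sigma`, default 1.0 px) before differentiation.
- Spatial gradients are central differences of the *first* frame; the
  temporal gradient is the two-frame forward difference. This single-step
  scheme is deliberately not symmetrised or iterated: it is accurate to
  ≲0.03 px for |s| ≤ 1 px on smooth images and *saturates below* the true
  value for multi-pixel motion. That saturation is a feature the adaptive
  frame-interval design depends on, and it is asserted by a test
  (≥5 px speckle shifts are always underestimated).
- The grid solve uses window sums of the gradient products via a uniform
  filter; this is algebraically the stacked least-squares system, and a
  test pins the vectorised path to the explicit per-point reference
  implementation.
- A flow point is invalid when the smaller eigenvalue of its 2×2 normal
  matrix is ≤ `eig_ratio` (default 1e−6) times the larger, or the matrix
  vanishes (flat texture). Invalid points carry NaN velocities and are
  dropped from all aggregation.

### Direction voting and the Va→N rule

Valid points vote `left` (Vx<0) / `right` (Vx>0) / `ignored` (Vx=0); the
majority class is retained. An exact tie falls back to the previous frame
pair's direction, else the pair reports no direction and zero displacement.
`Va` is the mean |Vx| of the top `top_fraction` (default 5 %) of retained
points; the `Va→N` table maps it to the percentage `N` of top
(|Vx|-ranked) points whose signed mean is the region displacement. Top-k
counts use `ceil` and are at least 1. The shipped default table
{0.5→60, 1.0→35, 1.5→20, 2.0→10, 3.0→5} is a monotone placeholder anchored
at the established operating point (1.5 px → 20 %); it is clamped outside
its knot range and should be recalibrated per imaging setup with
`calibrate_va_n`, which picks, per calibration pair, the smallest N whose
top-N% mean matches the reference displacement within tolerance, bins the
(Va, N) samples over Va, and enforces a non-increasing N with a
pool-adjacent-violators fit.

Whether `Va` averages signed or absolute displacements is an open choice;
here it averages |Vx| over the retained (single-sign) class, so the
distinction only affects the sign, which is restored in the output.

### Flow periods and block matching

Signed per-pair lateral displacements accumulate into `Da`; the period
closes at the first frame where `|Da| ≥ λ` (default 10 px) or at sequence
end (the final partial period is still matched). Back-and-forth motion
that cancels in the signed sum does not trigger the threshold. Within a
period the flow region follows the rounded cumulative flow displacement.

MKBM then matches the template (extracted at the previous anchor) against
the period's end frame: the block is split 2×2 into sub-blocks sharing
`subblock_overlap` (default 10) pixels per dimension — left/top sub-blocks
take the extra pixel when the split is odd — and each sub-block is located
by exhaustive integer SAD search over `predicted ± search_range`
(default ±20 x, ±10 y) centred on the flow-predicted displacement.
Matching is integer-only by default; sub-pixel template resampling is the
very drift mechanism interval matching avoids, so the optional parabolic
refinement stays off. SAD ties break to the smallest displacement
magnitude, then leftmost, then topmost candidate.

Fusion keeps the sub-block with the **largest |horizontal displacement|**
(ties: lower SAD, then lower index) and copies its signed (dx, dy). The
maximum-displacement rule exists to reject passively dragged neighbouring
tissue, which moves less than the tendon; reading the maximum over
*magnitudes* implements that rationale for both motion directions, and a
signed-max mode plus the original NCC-weighted-average fusion are exposed
as alternatives (`fusion_mode`).

### Interpolation and template update

Interior frames are interpolated along the flow trend (README equation).
The printed form of that equation contains the matched displacement at
interior frames, a quantity block matching never produces there (and which
double-counts at the period end); it is read here as the anchor value
`d_MKBM(t)`, which makes both endpoints consistent. Endpoints are assigned
exactly (not recomputed through floating-point arithmetic), so anchor
identities hold bit-exactly. If the net flow over a period is exactly zero
the interpolation falls back to linear in frame index and the period is
flagged. The y component always interpolates linearly — only lateral
motion carries trend information. After each period the region moves by
the rounded fused displacement and the template is re-extracted from the
end frame (integer placement only, no resampling).

### Comparators

`of_only` chains the per-pair region displacement; `mkbm_only` applies
MKBM to every adjacent pair with per-frame template update; and
`adaptive_mkbm` uses the same anchors as OFTB-MKBM with linear
interpolation between them. With λ → 0 the full tracker degenerates to
per-frame MKBM; a test asserts exact trajectory equality on a moving
sequence.

## Evaluation metrics

`E_a` is the mean absolute difference of instantaneous (frame-to-frame)
lateral displacements; a `mode="cumulative"` switch compares the
cumulative curves instead, since displacement-vs-frame plots show
cumulative values and published per-case tables may be computed either
way. `E_r` compares signed totals (last minus first frame) and is flagged
undefined when the reference total is zero. Millimetre values are pixel
values times the lateral pixel spacing; the tests check the two scales
relevant to tendon imaging (0.0265 and 0.075 mm/px).

## Synthetic speckle test-bed

Frames are rendered from point scatterers with continuous coordinates:
shift by the ground-truth cumulative displacement (sub-pixel motion is
exact by construction), bilinear splat, anisotropic Gaussian blur
(axial σ 1.0 px < lateral σ 2.0 px, matching B-mode point-spread
anisotropy at the 0.075 mm/px scale), a single global intensity
normalisation, then additive Gaussian noise clipped to [0, 1]. Scatterer
density defaults to 0.05/px²; speckle-like intensity variation emerges
from the random interference of the blurred scatterer field.

Out-of-plane motion cannot exist in a 2-D renderer, so its signature —
texture decorrelation — is emulated: each frame, an independently drawn
fraction ρ of a *persistent* base scatterer field is transiently replaced.
This models reversible elevational jitter (tissue wobbling through the
beam and back), bounding the decorrelation between any two frames at
roughly (1−ρ)², which is the partial-decorrelation regime interval
matching is designed to tolerate. An irreversible elevational sweep
(compounding churn, frame-pair correlation (1−ρ)ⁿ) destroys the texture
across a 30-frame flow period at ρ = 0.05 and with it any endpoint
matcher; that regime is deliberately not what the test-bed emulates, and
trackers evaluated here inherit that caveat for strongly out-of-plane
acquisitions.

What passing tests therefore show: correct algorithmics (exact search,
exact interpolation identities, cadence), correct sub-pixel behaviour,
and the expected method ordering under speckle, sensor noise and bounded
decorrelation. What they do not show: performance under probe pressure
changes, tissue deformation within the region, shadowing, or sustained
out-of-plane sweeps — none of which the renderer produces.

### Study-condition defaults

- Phantom analog: 206 frames, 5 mm total lateral travel at 0.075 mm/px
  (66.67 px, ≈0.325 px/frame), σ = 0.02, ρ = 0.05 — a motorized
  constant-velocity scan of a tissue-mimicking phantom.
- Tendon analog: sinusoidal or triangle lateral motion (default
  amplitude 30 px, period 60 frames) at the finger scale 0.0265 mm/px,
  σ = 0.02, ρ = 0.02 — flexion/extension cycles with direction
  reversals.
- Frame size 400×200 px: room for the 101×41 region plus search margins
  over the full motion range.

The four-method phantom comparison first calibrates the Va→N table on
~300 synthetic adjacent frame pairs from separately seeded sequences —
the same procedure a user performs on real data with reference
displacements — then scores five replicates. Typical outcome: OFTB-MKBM
E_r ≈ 1–2 %, plain optical flow ≈ 15–20 %, per-frame MKBM ≈ 95 %
(integer matching stalls at 0.33 px/frame), adaptive MKBM equal to
OFTB-MKBM on constant-velocity motion (the flow trend is linear there)
but late at direction reversals, where OFTB-MKBM hits the turning point
within 2 frames.

## Design choices where the design was open

- **Single CLI entry point** `tendontrack` with `track / simulate /
  evaluate / calibrate-van` subcommands rather than four separate
  executables.
- **Video input** goes through imageio when an ffmpeg backend is present;
  TIFF stacks and PNG frame directories are the first-class formats, and
  screen-capture inputs must be pre-cropped to the image area by the user
  (the crop rectangle is acquisition-specific).
- **Intensity normalisation** to [0, 1] floats: every stage except
  absolute SAD values is scale-covariant, and SAD is only ever compared
  within one search, so normalisation is safe; it is recorded in the run
  report via the config echo.
- **Degenerate inputs**: all-invalid or all-ignored flow fields report
  direction `none` with zero displacement; a region drifting against the
  frame border truncates the track at the last valid frame with a warning
  rather than raising.
- **Determinism**: no hidden randomness anywhere in the pipeline;
  identical inputs and config produce bit-identical trajectories, and the
  simulator is bit-reproducible per seed.

## Problem sizes used in tests

Test sequences are rendered at 200–300 px width and 10–120 frames; the
phantom comparison uses the full 206-frame spec with five replicates and
three calibration sequences. The integer-shift check covers all 861
shifts in ±(20, 10) px with a 48×24 template, and oracle agreement uses
50 random noisy instances against a naive double-loop search.

## Known limitations

- Tracking quality on real clinical video depends on a per-setup Va→N
  calibration; the shipped table is a placeholder anchored at one point.
- Integer-only matching quantises anchor displacements to ±0.5 px per
  period; errors accumulate as a random walk over periods.
- Vertical (depth-dominant) motion, multi-target tracking, affine or
  deformable matching, and pyramidal flow are out of scope.
- The cadaver benchmark (mean E_a ≤ 0.05 mm over five sequences) requires
  the original marker-annotated cadaver recordings, which are not
  distributed here; its test documents the expected layout under
  `data/cadaver/` and fails until that data is supplied.
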