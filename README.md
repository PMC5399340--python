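# tendontrack

Automatic tracking of tendon motion in 2-D ultrasound image sequences using
**optical-flow-trend-based multi-kernel block matching (OFTB-MKBM)**.

Tendon excursion is a key quantity in hand and elbow biomechanics and in
tendinopathy assessment (trigger finger, tennis elbow), and B-mode
ultrasound is the standard way to observe it. Tracking a tendon region
through an ultrasound video is hard for two complementary reasons: speckle
noise decorrelates the texture frame to frame, and the two classical
trackers each fail in one regime. Differential optical flow is accurate for
small (sub-pixel) inter-frame motion but *underestimates* large motion;
template (block) matching is reliable for large displacements but, at
sub-pixel per-frame motion, per-frame template updates accumulate drift and
integer matching stalls.

## The method

OFTB-MKBM combines the two estimators through an adaptively chosen frame
interval:

1. **Optical flow per adjacent pair.** Lucas–Kanade flow
   `Ix·Vx + Iy·Vy = −It` is solved by least squares over a 17×17 window at a
   grid of flow points (43×13 points at 2-px spacing inside the default
   101×41 tracking region). Points are voted by horizontal direction
   (`left` if `Vx<0`, `right` if `Vx>0`, else ignored); the majority class
   is kept. The index `Va` — the mean of the top 5 % |Vx| — selects,
   through a calibrated `Va→N` table, the percentage `N` of top flow points
   whose mean gives the region displacement (e.g. `Va = 1.5 px → N = 20 %`).
2. **Adaptive interval.** Signed horizontal displacements accumulate into
   `Da`; when `|Da| ≥ λ` (default λ = 10 px) the run of frames closes as a
   *flow period*.
3. **Multi-kernel block matching at the period endpoints.** The reference
   block is split into four sub-blocks overlapping by 10 px; each is located
   by exhaustive integer search minimising the mean sum of absolute
   differences `SAD = (1/MN) Σ|T − R|` around the flow-predicted position.
   The sub-block with the largest |horizontal displacement| wins
   (`D_t = Max(D_t,1 … D_t,4)`) — passively dragged neighbouring tissue
   moves less than the tendon, so the fastest kernel rides the tendon.
4. **Flow-trend interpolation.** Frames inside the period get
   `d(t+i) = d_MKBM(t) + (d_OF(t+i) − d_OF(t)) ·
   (d_MKBM(t+n) − d_MKBM(t)) / (d_OF(t+n) − d_OF(t))`,
   so the endpoints equal the matched anchors exactly and the in-between
   shape follows the flow. The template is then re-extracted at the new
   anchor and the cycle repeats.

The package also provides the three baselines used for comparison (plain
chained optical flow, per-frame MKBM, and "adaptive MKBM" = same anchors
with linear interpolation), the two evaluation metrics
(`E_a = Σ|d_GT,t − d_PA,t|/N` on instantaneous lateral displacement;
`E_r = |(D_GT − D_PA)/D_GT|·100 %` on totals), a `Va→N` calibration routine,
and a synthetic speckle simulator that renders sequences with exact
sub-pixel ground-truth motion, sensor noise and out-of-plane-style texture
decorrelation.

## Worked example

Track a synthetic phantom scan — 206 frames, 5 mm total lateral travel at
0.075 mm/px (≈ 0.33 px/frame), speckle noise σ = 0.02 and decorrelation
ρ = 0.05:

```python
import numpy as np
from tendontrack import (
    Region, TrackerConfig, phantom_analog_spec, render_sequence,
    track, average_absolute_error, relative_error,
)

spec = phantom_analog_spec(seed=0)          # 206 frames, 5 mm at 0.075 mm/px
seq, motion = render_sequence(spec)
traj = track(seq, Region(150, 80, 101, 41), TrackerConfig())

gt = motion.to_trajectory()
e_a = average_absolute_error(gt, traj)
e_r = relative_error(gt, traj)
print(f"frames tracked      : {traj.n_frames}")
print(f"flow periods        : {len(traj.periods)}")
print(f"anchor frames       : {np.flatnonzero(traj.is_anchor).tolist()}")
print(f"total displacement  : {traj.total_displacement_x:.2f} px "
      f"({traj.total_displacement_x * seq.pixel_spacing[0]:.2f} mm, truth 5.00 mm)")
print(f"E_a = {e_a:.3f} px   E_r = {e_r:.1f} %")
```

Output:

```
frames tracked      : 206
flow periods        : 12
anchor frames       : [0, 19, 37, 54, 73, 90, 108, 125, 143, 159, 178, 196, 205]
total displacement  : 68.00 px (5.10 mm, truth 5.00 mm)
E_a = 0.066 px   E_r = 2.0 %
```

The tracker closed 12 flow periods (anchors every ~17–19 frames: the flow
slightly overestimates 0.33 px/frame under noise with the uncalibrated
default `Va→N` table, so `|Da|` reaches λ = 10 a little early — recalibrate
with `calibrate_va_n` / `tendontrack calibrate-van` for your texture). The
total lateral displacement lands within 2 % of the 5 mm ground truth, with a
mean per-frame error of 0.066 px (≈ 5 µm at this scale).

The same workflow from the shell:

```bash
tendontrack simulate --spec phantom.yaml --out-dir sim/
tendontrack track --input sim/sequence.tif --roi 150,80,101,41 \
    --pixel-spacing 0.075 --out traj.csv --report run.json
tendontrack evaluate --pred traj.csv --gt sim/ground_truth.csv --pixel-spacing 0.075
tendontrack track ... --method of|mkbm|adaptive     # baselines
```

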