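# Methods

## The assay and its statistic

One experimental session exposes each larva to the standard protocol —
5 s stationary stripes, 10 s drifting right, 5 s stationary, 10 s drifting
left — twice, giving four stripe-motion *trials* per larva. Scoring is
per trial and uses a single distance threshold, 20% of the lane length
(27 mm for the 135 mm lane):

- **valid**: the larva's position at motion onset leaves at least 27 mm of
  lane ahead in the motion direction (otherwise it has no room to respond
  and the trial is discarded);
- **responsive** (valid trials only): the larva's maximal signed excursion
  from its onset position, in the motion direction and within the 10 s
  window, reaches at least 27 mm.

A larva with at least three valid trials out of four is *included* and its
response rate is `100 × responses / valid trials`; with four valid trials
the attainable rates are exactly {0, 25, 50, 75, 100}%, with three
{0, 33.3, 66.7, 100}%. Groups are summarised by the median rate over
included larvae and compared by pairwise two-sided t tests with Bonferroni
correction.

Two wordings of the inclusion rule circulate ("at least three" vs "more
than three" valid trials); this package uses ≥ 3 as the default because it
is the operational choice consistent with reported rates such as 66.7%
(= 2/3), and offers the strict all-4 variant behind
`RunConfig.inclusion_mode = "all_4"`.

The displacement metric is the **maximal excursion**, not final-minus-
initial position: the projection images a human scorer reads show the full
excursion, and a larva that follows the stripes and then swims back has
still responded. Net displacement is available via `metric="net"`.
Both rule boundaries are inclusive ("at least 27 mm"), applied with a
1 × 10⁻⁹ mm tolerance so binary floating point cannot turn an exact 27 mm
into a miss (0.2 × 135 is not exactly representable).

## Stimulus model

Stripe parameters live in display units: one display pixel is 0.2 mm on
screen and 50 frames make one second, so an 8 mm stripe is 40 px and
6.5 mm/s is 0.65 px/frame. The pattern is a square wave of period
2 × stripe width along the motion axis. *Contrast* is implemented as the
opacity of colour 2 composited over colour 1 — at 0 the field collapses to
uniform colour 1, at 1 the two nominal colours alternate — which makes the
parameter testable (per-channel colour difference is linear and monotone in
contrast). Fractional per-frame offsets are accumulated in floating point
and rounded at render time, with no anti-aliasing: rendering is then
bit-exact, whole-period offsets reproduce the identical raster, and integer
speeds are circular shifts.

## Synthetic recordings

The simulator emulates what the IR camera sees, not the optics of a real
rig: an orthographic view at a fixed 2 px/mm, a uniform bright background
(value 200/255), faint lane-boundary rows (170), and one dark disk (50) per
lane with coverage-weighted (anti-aliased) edges. Larval behaviour is
decided per trial: with probability `response_prob` the larva *responds*,
swimming at a constant `swim_speed_mm_s` (default 8 mm/s, i.e. ~80 mm per
trial, far beyond threshold) in the stripe direction with a small
positional noise (default 20% of the exploratory step — directed swimming
is much steadier than free exploration, and a noise as large as the
exploratory one can statistically cancel the drift, which no responding
larva does). Otherwise — and during stationary phases — it keeps up
spontaneous swimming, modelled as a Gaussian random walk (step SD
`baseline_jitter_mm` = 1.5 mm/frame at 20 fps) reflected inside a
±15 mm band around its phase-onset position. The band serves two purposes
that mirror real larvae: the animal keeps moving (so the
background-subtraction tracker can see it) while its spontaneous excursions
stay safely below the 27 mm response threshold. Positions are clamped to
the lane.

What the simulator deliberately omits: burst–glide kinematics, body shape
and orientation, cross-lane (2-D) motion, lens distortion, illumination
gradients, and water-surface artefacts. Tests passing on simulator output
therefore validate the *pipeline logic and its numerics* — detection,
calibration, classification, aggregation — not robustness to every optical
property of a real recording; real-rig deployments should calibrate lane
ROIs from their own frames (`LaneMap.from_csv`).

All randomness derives from one integer seed; identical parameters give
bit-identical ground truth, stacks and downstream CSVs.

## Tracking

Each trial window (default 200 frames = 10 s at the 20 fps implied by a
200-frame window per 10 s phase) is processed as: signed subtraction of the
window's first frame (float32), radius-6 circular median filter, polarity
flip so the larva is the brightest object. The median is computed on an
8-bit quantisation of the signed difference (scale ½, offset 128) with a
histogram-based rank filter; since the median commutes with monotone maps
this is exact up to the 2-gray-level quantisation, roughly an order of
magnitude below the ~150-level blob amplitude, and about 8× faster than a
float median.

Detection is per lane and frame: negative values (the frame-0 "ghost") are
clipped, a frame whose lane amplitude (max − median) is below 30 gray
levels is a gap, otherwise Otsu's threshold is applied within the lane, the
largest connected component with area ≥ 9 px is kept, and the position is
its intensity-weighted centroid mapped to mm through the lane's affine
calibration. Interior gaps are linearly interpolated; leading/trailing gaps
stay missing. A trial with more than 50% gaps is unscorable and counts as
non-valid.

Because the background reference is the first window frame, a larva sitting
on its onset position is invisible to the subtraction — exactly as in the
original bench workflow, where validity is judged on the saved first slice.
The pipeline therefore detects **onset positions directly on the raw first
frame** (dark blob on bright field, same lane-wise detector on the inverted
image) and uses them for the validity rule and as the excursion reference.

Measured on simulator stacks, detected-frame RMSE is ≈ 0.2 camera px on
clean video and well under 2 px at Gaussian noise SD 10 (8-bit).

## Statistics

The default pairwise t test pools a common residual SD across *all* groups
(df = N − k), matching the classical pairwise-t procedure of standard
statistical environments (verified in the tests against a frozen reference
computation from one of them); Welch's test and a paired test are
alternatives. Bonferroni multiplies each raw p by the number of pairs and
caps at 1. Under a simulated null (three groups of 15 from one normal) the
family-wise rate of adjusted p ≤ 0.05 stays at the nominal 5%. Excluded
larvae have no rate and are rejected (NaN check) rather than silently
dropped.

## Problem sizes and numerical choices

- Test and acceptance simulations use the full 15-lane arena for
  end-to-end checks (parameter recovery at response probability 0, 0.5, 1;
  tracking accuracy) and a 5-lane arena for unit-level fixtures — ample to
  exercise every code path while keeping runs to a couple of minutes.
- Camera scale 2 px/mm, blob radius 5 px (2.5 mm): the blob must exceed
  the radius-6 median kernel's half-area to survive denoising, as real
  larvae do relative to the original optics.
- Ties and degenerate inputs: constant frames yield gaps (no Otsu on a
  one-level histogram); zero-variance group pairs yield NaN statistics,
  reported as such; empty groups of included larvae yield n = 0 with an
  undefined median.
- `camera_fps` defaults to 20 and is configurable; classification consumes
  time in seconds, so other cameras only change the window's frame count.

## Known limitations

- One animal per lane is assumed; debris is handled only via the
  largest-component rule.
- The time-coloured projection is a generic continuous-colormap rendering
  for QC, not a byte-exact replica of any specific LUT plugin.
- Real recordings need a user-supplied lane ROI calibration; automatic
  lane finding is not implemented.
- The tracker's gap policy (interpolate interior, drop > 50%-gap trials)
  is a pragmatic rule, not tuned against annotated real video.
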