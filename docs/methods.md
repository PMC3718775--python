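# Methods

This note documents the models behind `okncurve`: what is assumed, what
the tunable parameters mean, what the synthetic-data generator does and
does not emulate, and where the genuinely open design choices were
settled. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Geometry of the bend

The world is a flat ground plane. The bend is a pair of concentric
circles: the vehicle drives on the circle of radius R (default 49.2 m)
about the curve centre; the inside road edge is the circle of radius
r < R (default 47.2 m). The eye sits `eye_height` (default 1.2 m) above
the ground and looks horizontally. Angles in the vehicle frame are
degrees: horizontal h positive toward the inside of the (right-hand)
curve, vertical v positive up. Defaults were chosen so that steady
cornering at the emulated cohort speed (42.7 km/h) yields a yaw rate of
V/R ≈ 13.8 °/s and a tangent-point eccentricity of
90° − arcsin(r/R) ≈ 16.4°, inside the 15–20° band typical of
steady-state cornering. The real study road climbs uphill; the flat
plane keeps every quantity closed-form and affects only vertical
angles.

Three exact identities anchor the analysis and are asserted in tests:

1. **Tangent point.** The forward tangent from the eye to the inner
   circle has horizontal eccentricity 90° − arcsin(r/D) (D = distance
   to the centre), is stationary under concentric motion, and the optic
   flow at its *contact point* is purely vertical (downward).
2. **Future path.** A fixed point on the driven circle an arc θ ahead
   sits at h = θ/2 from heading (inscribed-angle theorem) and its
   bearing recedes at exactly −ω/2, independent of θ.
3. **Straight road.** With ω = 0 a centreline point has zero horizontal
   flow (pure expansion).

Optic flow is computed analytically (documented in
`geometry.optic_flow_at_point`): with relative position W, range ρ, eye
velocity V⃗ and heading rate −ω, dh/dt = −ω − (W_y V_x − W_x V_y)/ρ²
and dv/dt = −e (W·V⃗)/(ρ(ρ² + e²)). A central-difference cross-check is
part of the test suite.

## 2. Synthetic gaze generator

The generator emulates 60 Hz on-road gaze and telemetry recordings of
steady cornering, with known ground truth. Conditions follow the study
being emulated: per-subject yaw ~ Normal(13.8, 1.4) °/s on the fixed-R
bend (speed = ω·R), 60 s of cornering per subject, 17 subjects.

Strategies:

* `fp_track` — gaze locks onto a fixed world point on the future driven
  path and follows its exact angular track (slow phase); after an
  exponential dwell (mean `dwell_mean`, default 0.5 s) an instantaneous
  quick phase resets to a new target a fixed arc ahead. On the circle
  this makes every slow phase's horizontal slope exactly −ω/2.
* `gaze_poll` — as `fp_track`, plus occasional out-and-back episodes to
  a second, more distal path target (probability 0.2 per reset, 0.3 s
  dwell): the "polling" pattern of active gaze-sampling strategies.
* `tp_fixate` — gaze locked on the tangent-point track (optokinetic
  reflex fully suppressed): constant gaze under concentric motion.

All strategies then add i.i.d. Gaussian noise per axis (`noise_sd`,
default 0.5°, inside the 1–3° accuracy budget of on-road trackers but
small enough for informative recovery tests) and replace samples with
tracker glitches at Poisson rate `outlier_rate` (default 0.5/s),
drawing both axes Uniform(±30°) — glitches are unbounded relative to
signal scale, and replacing (rather than adding to) the true sample
matches how tracking losses behave.

Choices the generator makes where the emulated conditions leave a gap:

* **Lookahead.** `lookahead_arc` defaults to 35° of arc (≈ 30 m at
  R = 49.2). This places targets at h ≈ 17.5°, just beyond the tangent
  point — the far-zone pattern the generator exists to emulate — and
  sustains 0.5-s dwells: at 13.8 °/s the vehicle consumes ~7° of arc
  per dwell. Short lookaheads (≤ 20°) are geometrically inconsistent
  with the strategy being modelled: targets sit in the near zone well
  inside the TP, the vehicle overruns them mid-dwell, and the vertical
  track becomes strongly nonlinear.
* **Dwell truncation.** Dwells are clipped below at 4 samples (a
  2-parameter line needs ≥ 3 points; real slow phases are rarely under
  ~70 ms) and above at the time needed to cover 70 % of the lookahead
  distance, so tracked points stay well ahead of the eye and slow
  phases stay close to linear. At the defaults the upper clip binds
  rarely (the cap is ≈ 3.5 dwell means).
* **Quick phases are instantaneous** between-sample jumps: at 60 Hz a
  real saccade spans ≤ 1–2 samples, and this keeps ground-truth
  labelling unambiguous. Consequently the synthetic data contain no
  saccadic *samples*; "QP" classification matters for real data and for
  fitted segments that happen to span a jump.
* Ground-truth slopes are the least-squares slopes of the noise-free
  angular track per episode — exact for the horizontal track, the best
  linear summary for the (slightly curved) vertical track.

What the generator does **not** emulate: saccade kinematics
(main-sequence profiles), autocorrelated tracker noise, blinks/dropout
patterns, binocular disparity, road elevation, and lane-position
variation (the vehicle is exactly concentric, so the TP is exactly
stationary). Passing recovery tests on this world therefore shows the
estimator handles the *stated* noise model at realistic magnitudes — it
does not certify performance under structured real-world artefacts.

## 3. Segmentation model and score

The gaze signal is modelled as piecewise-linear in time per axis with
known Gaussian noise σ, Poisson-distributed episode changes, and
Poisson-distributed outliers. The penalized log-likelihood of a
candidate (segments, outlier set) is, explicitly:

```
  Σ_{non-outlier samples} [ log N(res_h; 0, σ) + log N(res_v; 0, σ) ]
+ Σ_{gaps g} [ log p_c(g) if a boundary falls in g else log(1 − p_c(g)) ]
+ Σ_{samples} [ log q + 2·log(1/(2A)) if outlier else log(1 − q) ]
− Σ_{segments} 2·log(n_seg)
```

with p_c(g) = gap duration / `expected_segment_length` (capped at ½),
q = `outlier_rate` · median sampling interval, A = `outlier_range`,
and n_seg the segment's non-outlier count. Residuals come from each
segment's per-axis OLS lines; outliers are excluded from fits and
residuals. Time enters in seconds from actual timestamps, so dropped
frames do not bias slopes.

The last term — a BIC cost of 2 parameters per axis per segment, the
Laplace approximation to marginalizing each segment's slope and
intercept — is essential: with known σ and only the Bernoulli
changepoint prior (≈ 3.4 nats per boundary at the defaults), the
maximum-likelihood partition is inconsistent, buying four free
parameters plus an optimized location per split and oversegmenting pure
noise (measured: a 120-sample noisy line is "optimally" cut into 9
pieces, 14 nats above the single segment). With the parameter cost the
same series recovers one segment and noise-free piecewise-linear
inputs are still recovered exactly.

**Solver.** The score decomposes over segments, gaps and samples, so
for a fixed outlier assignment the exact optimum over partitions is
found by optimal-partitioning dynamic programming; PELT pruning (with a
margin covering the changepoint penalty plus the parameter-cost slack,
which keeps pruning lossless) makes it near-linear in practice.
Outliers are handled by block-coordinate ascent: partition → per-segment
iterative reassignment (a sample is flagged when the broad-uniform
outlier term beats its Gaussian inlier term; each segment keeps at
least `min_segment_samples` = 3 inliers; at most `beam_width` new
proposals per refit round) → re-partition, keeping the best-scoring
iterate over ≤ 5 rounds. A greedy merge-repair pass additionally
proposes removing each internal boundary with local re-assignment,
which frees gross outliers trapped in minimum-length segments. For
short series (n ≤ 25) the solver instead searches outlier subsets
(|O| ≤ 2) × exact partitions exhaustively, and a brute-force
enumeration oracle in the test suite verifies the optimum is attained
on a 100-instance battery.

Reported scores always equal the score function re-evaluated on the
output. Ties (exactly equal scores) are broken toward fewer segments,
then fewer outliers; with continuous noise they occur only on
degenerate constructed inputs. Runs of invalid samples longer than
`max_gap` = 0.5 s split the series into independently segmented chunks;
shorter invalid runs are bridged.

**Known limitation.** The MAP partition under this model still differs
from the sample-level truth near the information limit: at the default
conditions the per-sample median |horizontal slope error| on synthetic
pursuit data is ≈ 0.3 °/s, of which ≈ 0.2 is irreducible OLS noise on
~0.5-s segments (measured with oracle boundaries) and the rest is MAP
boundary jitter and occasional chance splits/merges. Mode-based cohort
statistics are robust to this; per-segment slopes of very short
episodes are not.

**Classification.** Segments with slope magnitude ≥
`qp_speed_threshold` (default 40 °/s; ties to QP) are quick phases.
The threshold sits an order of magnitude above pursuit at ω/2 ≈ 7 °/s
and well below a one-sample 2° jump (120 °/s at 60 Hz). Only SP
segments feed the orientation histogram and velocity densities.

## 4. Curve phases

Trials are projected onto a reference trajectory (perpendicular
projection onto its segments, assignments non-decreasing in time so
backward GPS jitter cannot reverse route distance). Phases come from
the |yaw| profile, first smoothed by a 1-s centred rolling median
(exact on linear ramps, so clean trapezoids are unaffected): the
plateau is the median of |yaw| over samples above 50 % of its 95th
percentile; *cornering* is the maximal contiguous interval within
± 20 % of the plateau; *entry* runs from the first sample above 10 % of
the plateau to cornering start, *exit* symmetrically. All three
fractions are arguments. This thresholded rule is an algorithmic
stand-in for a manual judgement based on median yaw; downstream
phase-conditioned results are conditional on it. Note that on a ramp
the ± 20 % band is entered at 80 % of the plateau level — the cornering
interval deliberately includes that last stretch of the ramp, since the
rule is defined by the band, not by the generator's knot points.

## 5. Statistics

* **Displacement from the TP** uses the *fitted* (denoised) gaze
  position from the segmentation, not raw samples.
* **AOI catch**: percentage of samples within radius 2–10° of the TP;
  monotone in radius by construction. Entry-vs-cornering differences
  are tested with the exact two-sided binomial sign test (zeros
  dropped, doubled smaller tail capped at 1).
* **Densities**: product-Gaussian KDE. Velocity densities use the d = 2
  Silverman rule h_j = σ̂_j · n^(−1/6) per axis; position densities use
  a fixed 1.0° bandwidth (degrees — the natural unit of the axes).
  Grids extend 4 bandwidths beyond the data at 0.25 (°, °/s)
  resolution, refined below bandwidth/3 when the bandwidth is small so
  trapezoidal integrals stay within 1 ± 0.01.
* **Modes**: best grid node, then bounded derivative-free (Powell)
  maximization of the continuous KDE within that node's bin; the
  refined density never falls below the grid maximum; flat maxima are
  flagged and resolved toward the smallest coordinates. Per-subject
  modes pool all of a subject's cornering-phase SP samples (one mode
  per subject, not per trial).
* **Hotelling T²** region for the mean of the N per-subject modes:
  {μ : N(x̄−μ)ᵀS⁻¹(x̄−μ) ≤ 2(N−1)/(N−2)·F_{2,N−2}(level)} at 95/99/99.9 %;
  nested by construction, coverage checked by Monte Carlo in the
  acceptance suite.
* **Half-yaw-rate consistency**: d_i = ω̄_i/2 − |modal horizontal SP
  velocity|, using magnitudes so left- and right-hand bends pool; mean
  with a t-based 95 % CI; Shapiro–Wilk normality (delegated to scipy)
  reported alongside. Per-subject Pearson correlations between
  instantaneous yaw and instantaneous |SP velocity| are defined only
  when yaw varies within a trial; the telemetry generator's optional
  speed-wobble argument exists for exactly that use, and the default
  (constant-yaw) cohort reports them as NaN.

## 6. Problem sizes

The shipped analyses use 17 subjects × 60 s × 60 Hz for the cohort
recoveries, 6 subjects × 30 s for the two-strategy comparison, a
100-instance n ≤ 12 battery for solver-vs-enumeration equivalence, and
2000 Monte-Carlo replicates for Hotelling coverage — sizes at which
every quantity of interest is stable to well within its stated
tolerance while a full run stays in the minutes range on one CPU.
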