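# Methods

This note documents the models, numerical choices, and design
decisions behind `splinelnp`, and what the synthetic-data tests do and
do not establish about real recordings.

## Encoding model

Spike counts *n_t* in 20 ms bins are modeled as Poisson with mean
`exp(b0 + Σ_i x_i(t)·w_i)`, where each behavioral variable enters
through a cardinal-spline basis (tension s, default 0.6; results are
insensitive over 0.5–0.7).  Bin counts follow the dataset conventions:
open field — arena cm × 15/100 position bins per axis, 10 azimuth
bins, 5 cm/s speed bins, 8 bins for pitch/roll/azimuthal velocity;
virtual track — 20 position bins, 5 cm/s speed bins, 5 bins per eye
variable.  Knots span the percentile-windowed range of the observed
values (2.5–97.5 open field, 1–99 head-fixed); model input is
restricted to time bins where **every** modeled variable lies inside
its window, computed per variable on the full session.  Circular
variables (azimuth; virtual-track position, which wraps) index control
points modulo the bin count and are not windowed.  Non-circular
variables receive one phantom control point beyond each end of the
range so the spline's j−1 and j+2 indices always exist; the phantom
weights are fitted parameters like any other.

Two-dimensional open-field position uses the tensor product of two
1-D spline bases (16 active weights per sample).  The 1-D expansion's
partition of unity carries over, and the 2-D block behaves exactly
like the scalar blocks in the likelihood.

### Fitting

The penalized objective (negative mean log-likelihood plus
β·‖w‖²/T with β = 1; b0 unpenalized so the mean rate is not shrunk)
is smooth and convex.  It is minimized by trust-region Newton-CG with
the analytic gradient and Hessian-vector product; linear predictors
are clipped at ±30 to keep `exp` finite in early iterations.  The
full-data fit runs to gradient norm 1e−7 (1e−8 for standalone fits);
per-fold refits warm-start from the full-data solution and stop at
1e−6, which moves held-out log-likelihoods by < 0.01 nats — far below
fold-to-fold variation.  Convergence is flagged on every fit.

### Cross-validation and selection

The retained time axis is cut into contiguous 10-s sections, allocated
round-robin to 10 disjoint folds (temporal balance without fold
overlap).  Per fold, the model is trained on the other nine and scored
on the held-out fold by the log-likelihood increase (LLI) over the
training-set mean-rate model; a spike-normalized LLI (per held-out
spike) is recorded alongside.  Forward selection starts from the best
single-variable model by mean LLI, then repeatedly adds the
best-scoring remaining variable while a one-sided Wilcoxon signed-rank
test on the ten fold-paired raw LLIs rejects at α = 0.05, and finally
requires the selected model to beat the mean-rate baseline by the same
test; otherwise the cell encodes nothing.  Ties between equal-scoring
candidates break lexicographically by symbol (documented, and in
practice unreachable with continuous data).

A note on null behavior: fitting an irrelevant spline block to
mean-rate data yields a slightly *negative* held-out LLI (the held-out
cost of superfluous parameters, ≈ −0.5 nats/fold at 5·10⁴ bins).
This is why the final baseline test calibrates well: on simulated
untuned cells the pipeline reports "no significant tuning" in ≈ 100%
of runs at the sizes tested.

## Tuning-curve machinery

Model-derived curves evaluate `exp(Y_i(m)·w_i)·γ/dt` on M = 200 bins,
with γ the product of b0 and every other encoded variable's mean
exponentiated contribution over the retained bins; for a
single-variable model γ = exp(b0).  Raw curves are total spikes over
occupancy seconds in 20 bins, smoothed by robust locally weighted
linear regression spanning 7 bins (two robustifying iterations);
zero-occupancy bins stay NaN.  Display ranges intersect the behavioral
percentiles with preset bounds (±50° pitch/roll, ±100°/s azimuthal
velocity, ±3 horizontal / ±2 vertical eye units and units/s).
Stability refits the selected model on each session half and
correlates the two curves over the intersection of their behavioral
ranges, up-sampling the shorter by linear interpolation.

Shape classification range-normalizes the curve to [0, 1]
(pitch/roll curves additionally Gaussian-smoothed with a 20-bin
window, σ = window/5), fits polynomials of degree 1–5 on a
standardized abscissa, and accepts the first degree whose fraction of
error explained against the flat baseline reaches 0.9; flat curves are
reported undefined, and classification requires behavioral coverage of
at least 50% (head variables) or 80% (eye variables) of the display
range.  Velocity subtypes come from least-squares lines on either side
of zero velocity: degree-1 curves are linear-asymmetric; otherwise
opposite-signed slopes with magnitude ratio ≥ 0.5 (configurable; no
published numeric criterion exists) are symmetric (positive or
negative by the sign of the above-zero slope) and the rest are
asymmetric, preferring the steeper side.  Preferred positions take the
global extremum among detected interior peaks/valleys, falling back to
endpoints only for monotone curves.

Variable contributions are the mean spike-normalized LLI of the
selected model minus that of the model refit without the variable on
the same folds, reported raw (matching the units in which such
contributions are usually plotted); a variant normalized by the
selected model's performance is available.  Contributions are defined
only for cells encoding the variable plus at least one other.

## Sensor processing

**IMU.**  The head-fixed calibration segment's mean gravity vector
gives the mounting roll/pitch (θ_r = arctan(a_y/a_z),
θ_p = arctan(−a_x/√(a_y²+a_z²))) and the sensor-to-head rotation
R = (R_roll·R_pitch)ᵀ; per sample, the rotated gravity vector is
projected onto the pitch (x–z) and roll (y–z) planes and the signed
angle to the head-frame vertical taken.  The arccos is unsigned; the
sign is restored from the in-plane coordinate (pitch positive =
nose-up, roll positive = rightward).  These sign conventions are a
package decision — gravity sensing alone cannot fix them — so
directional preferences derived from them are convention-relative.
Degenerate projections (‖proj‖ < 1e−8) mask the sample; calibrations
with |a| < 0.5 g are rejected.  Angles at or beyond 90° are outside
the gravity-only model and are rejected by the simulator.

**LEDs.**  Body position is the LED midpoint; speed the per-frame
displacement over dt; azimuth the atan2 of the LED difference vector,
counterclockwise from +x in [0, 360).  Angular velocities are wrapped
finite differences (shortest signed arc for circular variables), so
|Ḣ_a|·dt ≤ 180° always.  Spike times bin into half-open [t, t+dt)
windows; IMU channels are linearly interpolated onto the 50 Hz LED
clock after matching shared sync pulses (linear extrapolation beyond
the outermost pulses).

**Eyes.**  The pupil is the largest connected region darker than a
hand-picked threshold inside a search region, valid only with strictly
between 50 and 1000 pixels; a circle is fit to the region
(algebraic least squares) and its center taken.  The corneal
reflection is detected the same way with the inequality reversed, and
its deviations from the session mean are subtracted from pupil
position (camera-jitter cancellation).  Invalid frames are linearly
interpolated (the interpolation method is a package decision);
sessions with > 25% invalid frames are rejected (threshold ours).
Slow drift is removed by subtracting a 1000-point Gaussian smoothing
(σ = window/6 — only the window length is conventional); then the top
and bottom 1% of values per coordinate are masked, positions are
projected onto the manually defined horizontal (tear duct → outer
canthus) and orthogonal vertical axes, and divided by the eye width
(×100 → % of eye width).  Extremal masking is applied after the
high-pass, matching the processing order described for this type of
data.  Position is smoothed with a 10 ms Gaussian; velocity is the
smoothed finite difference, further smoothed with a 140 ms Gaussian,
which together suppress saccadic transients.

## Synthetic data

The generator's defaults are the study conditions, calibrated once to
the published across-mouse percentile tables and not retuned:

* **Pitch / roll** — stationary Ornstein–Uhlenbeck processes
  (mean 11.5°, SD 19°; mean −0.8°, SD 24°; τ = 2 s), reproducing the
  published 2.5/25/50/75/97.5 percentiles within their ±3 sem
  envelopes.
* **Azimuth** — circular random walk whose per-step angular velocity
  is a Gaussian scale mixture (90% SD 45°/s, 10% SD 550°/s), giving
  the published heavy-tailed velocity percentiles (±390°/s at 2.5/97.5
  vs ±37°/s quartiles).
* **Position** — speed = |OU| (mean 10 cm/s) along a slowly wandering
  movement direction, reflected at the arena walls; 20-min sessions
  cover ≥ 70% of position bins, matching the session-inclusion rule.
* **Eyes** — per axis: offset + slow OU drift + a piecewise-constant
  fixation component whose levels come from a skewed
  Gaussian/half-normal mixture, jumping at shared Poisson saccade
  times (0.6 Hz), plus a slow-phase drift (−0.11 %/s horizontally)
  that resets at each saccade.  This reproduces the skewed,
  heavy-tailed published eye position and velocity percentiles,
  including the slightly negative median horizontal eye velocity.
  Because a single session's median wanders more than the published
  across-mouse sem, percentile checks average over several simulated
  sessions, as the published values average over mice.
* **Accelerometer** — gravity-only (no translational acceleration),
  the exact inverse of the pitch/roll recovery, with optional sensor
  noise and drift and a head-fixed calibration segment.
* **Spikes** — Poisson counts with log-mean = bias + Σ tuning_i,
  log-rates above 20 rejected as overflow.

One seeded generator drives everything; identical (spec, seed) pairs
are byte-identical.  What the generator does **not** emulate: joint
dependence between variables (only marginals are matched — the
published tables constrain nothing else), vestibulo-ocular coupling
between head and eye movements, video compression artifacts, spike
sorting errors, or inter-animal variability structure.  Passing tests
therefore demonstrate that the pipeline recovers what it models —
correct attribution under independent regressors and calibrated nulls
— not that any particular real dataset satisfies those assumptions.

## Population and validation statistics

The binomial preference test pairs a continuity-corrected normal
statistic z = sign(k − n/2)·max(|k − n/2| − 0.5, 0)/(√n/2) with an
exact two-sided p (twice the smaller binomial tail, capped at 1) —
the single convention that reproduces the published worked examples;
z is exactly 0 when the correction crosses the mean.  Entropy and
mutual information use natural logarithms over occupied bins, with an
equal-count uniform reference for entropy and permutation nulls for
MI (bin edges held fixed under the null).  The tuning-space clustering
test centers and unit-range-scales curve rows, projects onto two
principal components, and compares the mean k-nearest same-label
neighbor distance (k = 1..10, capped at one less than the labeled
count) to a label-permutation null (1000 permutations by default — no
published count exists), Bonferroni-corrected at 0.05/10; an
all-labeled population makes the null degenerate and the test is
reported inapplicable.

False-detection rates permute a variable's values over time
(destroying autocorrelation, as distinct from shift-based nulls, which
are kept as a separate operation) and re-run the full selection.
Ablated-spiketrain regeneration deletes a fitted variable's design
block and weights, redraws Poisson spikes, and re-runs selection;
dropping everything leaves the bias-only model.  Shuffle significance
correlates behavior with spiking and compares against 500 circular
shifts of the spiketrain (wrap-around preserves both marginals and the
train's autocorrelation; shifts exceed 20 s) at the 2.5/97.5
percentiles, within-cell or pooled across cells (pooled nulls are
built within session); the symmetric-velocity variant tests the two
sides of zero velocity separately at the 5/95 percentiles for V and
inverse-V sign patterns.

## Problem sizes and evaluation

The acceptance studies use 50 cells × 20-min sessions for selection
recovery (five archetypes: place; pitch; place×pitch; place×speed;
place×symmetric-velocity), 40 untuned cells × 10-min sessions for LN
null calibration, 200 cells × 5-min sessions for shuffle calibration,
and 20 virtual-track cells × 15-min sessions for the eye-ablation
control — the smallest sizes at which the binomial bands on the
reported rates are informative.  Open-field studies use a 50 × 50 cm
arena (8 × 8 position bins at the 15/100 rule).

## Known limitations

Percentile windows are computed per variable on the full session
(whether they should condition on other variables' masks is not
determined by the published description); the NL_s slope-ratio
threshold 0.5 and the 25% invalid-frame session-rejection threshold
are package choices; the shape search smooths only pitch/roll curves
(smoothing is described only for those); no interaction terms, spike
history, or non-Poisson likelihoods; no Kalman filtering of the IMU or
handling of translational acceleration; no ellipse-based 3-D gaze
reconstruction or saccade event detection.
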