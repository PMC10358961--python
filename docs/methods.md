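# Methods

`stridevar` studies how well wearable inertial sensors recover the
temporal structure of treadmill running — stride frequency (SF), duty
factor (DF), and two stride-to-stride variability indices, the
detrended-fluctuation scaling exponent (DFA-α) and Higuchi's fractal
dimension (HG-D) — relative to a reference gait-event stream, across
three estimation strategies:

1. **reference**: exact per-foot foot-strike/toe-off events (the
   simulator's ground truth, standing in for an optoelectronic
   system);
2. **foot-IMU**: events detected from the acceleration-norm peaks of
   instep-worn sensors;
3. **thorax-IMU + learning**: a single chest sensor feeding either a
   short-window (2 s) convolutional regressor for SF/DF or a
   long-window (120 s) dense regressor for DFA-α.

Because no public recordings accompany this design, the package's
first-class component is a synthetic-data generator whose outputs make
every downstream stage testable, plus the analysis stages themselves
and a statistical harness for comparing strategies.

## Stride-interval model

A runner × condition cell is parameterised by a mean stride frequency
(Hz), a stride-interval coefficient of variation (CV), a Hurst
exponent H ∈ (0, 1], a mean duty factor with per-stride spread, a
sensor-noise amplitude, and a seed. Stride intervals are

    T_i = T̄ · (1 + cv · z_i),

where z is unit-variance fractional Gaussian noise with the prescribed
H, synthesized by circulant embedding (Davies–Harte), which realises
the exact finite-sample fGn covariance rather than an approximation.
H = 1 requests 1/f-spectrum noise via spectral synthesis, since H = 1
is the fGn boundary. Draws violating positivity are redrawn (≤10
attempts); parameter combinations that would make >1 % of intervals
non-positive (cv ≳ 0.43 under the Gaussian model) are rejected
outright. Per-stride contact times are duty-factor draws times the
interval. DFA-α of the resulting interval (or stride-frequency)
series recovers H to within 0.05 in the mean over 100 seeds, the
package's central calibration property.

The two feet are phase-locked: the right foot's strikes sit near the
midpoint of the left stride with a small jittered phase, sharing the
left series' interval structure. Independent per-foot draws would
drift out of phase over a 10-minute trial, which no alternating gait
does.

Condition-level means emulate treadmill running at 80–120 % of
preferred running speed and slopes of ±2/±5/±8 % at 90 % speed: SF
rises ≈1.36→1.44 Hz and DF falls ≈0.45→0.37 across the speed ladder,
and the slope ladder perturbs the generating Hurst exponent (−8 % →
0.55 up to +8 % → 0.75, level 0.70). The inclination→Hurst map is a
simulator convention that reproduces the direction of the
uphill/downhill variability contrast; it is not a physiological
claim. Between-runner heterogeneity: ±4 % relative SF, ±0.02 DF,
±0.02 Hurst, CV drawn uniformly in 1–2 % (typical of steady treadmill
running).

## Signal synthesis

Waveforms are analytic raised-cosine bumps, not biomechanical
simulations; only the event geometry that detectors rely on is
contractual.

* **Foot sensor** (208 Hz): the vertical channel carries a dominant
  impact bump at each foot strike (8 g, 35 ms half-width), a smaller
  bump at each toe off (3.5 g, 30 ms), low swing-phase oscillation,
  and white sensor noise (default 0.1 g). The acceleration norm
  therefore has, per cycle, two separated local maxima in
  strike→toe-off order.
* **Thorax sensor**: each step contributes a vertical burst spanning
  that stride's contact time with peak amplitude ∝ 1/DF (shorter
  contact, sharper impact), so the vertical channel oscillates at
  step frequency with DF-modulated amplitude. The mediolateral
  channel alternates sign with the stance foot; the anteroposterior
  channel carries an odd-symmetric braking/propulsion couple; the
  angular-velocity channels carry step-locked roll/pitch/yaw
  oscillation plus band-limited noise. All six channels are
  step-locked because real trunk kinematics are; an early variant
  with noise-only gyro channels left two-thirds of the long-window
  feature matrix uninformative.

Everything is deterministic in the runner seed, with independent
named substreams per signal.

## Gait-event detection (foot path)

Foot strikes are acceleration-norm peaks above a scale-free threshold
(median + 3 MAD) separated by ≥0.6 stride periods, the period being
bootstrapped by splitting the coarse peak train into impact and
toe-off height classes and taking the median interval of the tall
class (a raw periodogram argmax locks onto harmonics of the bump
train). The toe off of each stride is the largest norm maximum in the
15–80 % interior of the stride. Traces without impact/toe-off height
separation (ratio < 1.5) or with erratic intervals (CV > 0.30) raise a
detection error instead of returning plausible-looking nonsense;
edge-buried peaks are dropped. On default-noise synthetic data the
detector recovers strikes to ±1 sample and stride intervals to <5 ms
RMSE, and per-stride SF/DF to well within 0.5 % / 0.02.

A vertical-acceleration-peak variant is available behind
`detect_strides_vertical` for comparison only; the norm variant is the
package default.

## Fractal metrics

DFA: the series is integrated (cumulative sum of deviations from the
mean), split into non-overlapping windows of each size n, detrended
with an order-1 polynomial per window, and the pooled residual RMS
F(n) is regressed on n in natural-log space; α is the slope. The
default "long-range" scale set is 12 log-spaced integer windows from
16 to N/9 (≈93 for N = 840), emphasising long-range correlation; all
settings are configurable. Constant series raise a degenerate-input
error; series shorter than 64 points (or too short for two distinct
scales) are length errors.

Higuchi: normalized curve lengths L_m(k) over down-sampling factors
k = 2..k_max (default 10) and offsets m, with D = −slope of
log L(k) vs log k. On white noise D → 2; on a smooth ramp D → 1. The
finite-length conventions mean 1/f noise reads D ≈ 1.84 and
H = 0.75 fGn reads D ≈ 1.94 at N = 840 — the values the estimator
actually produces are reported, never forced to round figures.

`variability_from_stride_frequency` applies both estimators to one
stride-frequency sequence (reciprocal intervals by default; intervals
via a switch — the exponents agree asymptotically at small CV) and
supports truncation to leading analysis windows (2/4/6/8/10 min) for
duration-sensitivity runs.

## Windows and labels

A rolling 2-s window stepped by 1 s partitions each trial
half-open, [t, t+2); per-stride values are assigned by stride
midpoint, and windows lacking a full stride for a foot are flagged
missing and excluded from training. The short-window sample is the
6 × 416 matrix of the thorax channels (accelerations in g —
equivalently raw m/s² divided by 9.81 — and angular velocities
divided by the 500-unit gyro normalizer, kept verbatim from the
recording convention though the unit is odd), labelled with the
4-vector (SF left, SF right, DF left, DF right) of reference window
means, z-standardized by training-split statistics that are frozen
into the model.

The long-window sample is a 6 × 23 feature matrix over a 120-s
window stepped by 20 s (25 windows per 10-minute trial), labelled
with the trial's reference DFA-α (left/right average) — one label per
condition shared by its windows. Features per channel, fixed
registry order: skewness; excess kurtosis; Higuchi-D (k_max 10);
DFA-α (sample-domain scales); standard deviation; mean; spectral
centroid; normalized spectral entropy; peak frequency; autocorrelation
at ten gait-cycle lags; and the relative energies of the four detail
bands of a 4-level db4 wavelet decomposition.

The **cycle-lagged autocorrelation** deserves its own paragraph
because it carries nearly all of the variability information. Sample
lags of 1–10 at 208 Hz span ≤48 ms and measure only waveform
smoothness; empirically they carry no information about the
stride-interval Hurst exponent (neither ridge regression nor gradient
boosting beat a predict-the-mean baseline from them). The package
instead evaluates the autocorrelation at multiples of the dominant
cycle period (spectral peak in 0.5–5 Hz), at geometric lags
1, 2, 3, 4, 6, 9, 13, 19, 28, 42 cycles. Step-timing deviations
accumulate with lag as k^(2H), so coherence at k cycles decays the
faster the larger H, and the geometric grid traces that decoherence
power law across more than a decade — a linear readout of one
channel's ten values already predicts the trial's DFA-α with RMSE
≈0.06 against a 0.10 baseline. Constant channels yield zero
shape/spectral features and flagged (NaN) fractal features, which the
window-level extractor refuses to pass on silently.

## Estimators

Both models run on a compact in-package neural-network core (im2col
1-D convolution, dense, batch-norm, dropout layers; Adam with
optional decoupled weight decay; mini-batch MSE; early stopping with
best-state restoration; bit-reproducible under a seed).

* **Short model**: conv(6→12, k=15) → ReLU → maxpool 4 →
  conv(12→24, k=9) → ReLU → maxpool 4 → dense 64 → dense 4, ≈42 k
  parameters. Defaults: Adam 1e-3, batch 128, 30 epochs, patience 15,
  early stopping on one held-out training runner. Predictions are
  de-standardized and clipped to SF ∈ (0.5, 3) Hz, DF ∈ (0, 1), with a
  clip counter on the estimator.
* **Long model**: dense 128 → batch-norm → ReLU → dropout 0.2 →
  dense 64 → batch-norm → ReLU → dropout 0.2 → dense 32 → ReLU →
  dense 1 on the flattened, per-feature-standardized 138-vector.
  Defaults: Adam 1e-3, weight decay 1e-4, batch 64, up to 400 epochs,
  patience 60. The condition-level estimate is the mean of the 25
  window predictions, matching per-condition evaluation; the
  per-window RMSE is also reported.

Splits are always by runner — train/test halves, plus one training
runner held out for early stopping — asserted by construction.
`dfa_from_short_path` composes the short model over a condition's
rolling grid, takes the per-second predicted SF (left/right mean) as a
sequence, and applies the fractal metrics: the short-path variability
strategy that the long model is benchmarked against. Window averaging
and one-per-second resampling smooth genuine stride-to-stride
structure, so this path overestimates α in weakly correlated
(downhill-analog) conditions — the motivating failure mode for the
long model.

## Statistical harness

Accuracy is RMSE against the reference on paired values (windows for
SF/DF, conditions for the fractal indices). Group comparisons are
normality-gated: Shapiro–Wilk per group at 0.05, majority rule (ties
go parametric). Parametric branch: Welch's heteroscedastic one-way F,
ω² (via the F-to-ω² approximation) with bootstrap CI (2000
resamples), Games–Howell post-hoc on the studentized range with Holm
correction. Nonparametric: Kruskal–Wallis χ², rank ε² with bootstrap
CI, Dunn post-hoc with tie correction and Holm. Post-hoc tests run
when the omnibus test is significant (configurable). The two-factor
analysis (condition × strategy) runs a classical two-way ANOVA
(type-II, statsmodels) on the parametric branch; the nonparametric
branch uses an aligned-rank-transform two-factor analysis — there is
no canonical "nonparametric two-way ANOVA", so the ART variant is the
declared stand-in and the parametric table is always reported
alongside. Both one-way branches are calibrated: under the null their
type-I error is 5 % ± 1.5 % over 1000 simulations. The one-way
analysis across conditions uses all runners' reference values; the
two-way analysis uses the test split only.

## Evaluation harness and problem sizes

`run_cohort_evaluation` generates a cohort (default 12 runners × 5
conditions — two downhill analogs, level, two uphill — 10 min each at
208 Hz), realizes trials lazily to bound memory, runs all strategies,
trains both models on the 6-runner training half, and reports
headline metrics plus the tidy comparison table. Short-window
training samples are taken every 2 s (window subsampling 2) so a full
train-and-evaluate run fits in roughly ten minutes on one CPU core;
the examples use still smaller cohorts. Observed at these sizes (seed
0): detection SF relative error ~1e-5 and DF error ~1e-4; short-model
test SF RMSE ≈0.014 Hz and DF RMSE ≈0.005 vs a 0.018 mean baseline;
long-model condition-level DFA-α RMSE ≈0.072 vs a 0.109 baseline, and
≈0.080 on downhill analogs vs ≈0.111 for the short path.

## What the simulator does and does not show

The generator reproduces the *event geometry and correlation
structure* real pipelines rely on: impact-peak trains, alternating
feet, step-frequency oscillation, prescribed long-range stride
correlations, realistic SF/DF ranges. It does not model
musculoskeletal dynamics, ground-reaction forces, soft-tissue
artifact, sensor drift/saturation, or surface/footwear effects, and
its waveform shapes are analytic conveniences. Passing tests
therefore demonstrate that the analysis stages are correct and that
the strategies can recover known structure under controlled noise —
not that identical accuracies would be obtained on human recordings.
The duty-factor series is white within a trial (only stride timing
carries the long-range structure), and thorax channel amplitudes are
stationary; real trunk signals likely carry variability information
through additional routes, so the long model's synthetic accuracy is,
if anything, conservative.

## Numerical choices and degenerate inputs

Natural-log fits throughout; least-squares slopes via polyfit;
batched window detrending via one lstsq per scale. Constant series →
degenerate-input errors (DFA, Higuchi, short-path composition on
constant predictions); too-short series → length errors; non-running
traces → detection errors carrying diagnostics; DF outside (0, 1) →
dropped and counted, never propagated. Interval redraws cap at 10
attempts. Seeds: every stochastic component takes a seed or a named
substream of one; two runs with identical specs are bit-identical.

## Known limitations

* The long-window model's accuracy rests heavily on the cycle-lagged
  autocorrelation features; on signals whose dominant spectral line is
  ambiguous (e.g., non-locomotor input) those features degrade
  gracefully but uninformatively.
* The Higuchi↔noise-colour correspondences are finite-length
  conventions; only the white-noise value (D ≈ 2) is
  length-independent.
* Welch-branch ω² uses the F-approximation rather than a sums-of-
  squares decomposition (heteroscedastic SS are not well defined);
  CIs are bootstrap percentiles.
* The aligned-rank-transform two-way analysis is a stand-in; no claim
  is made that it matches any specific prior software's
  "nonparametric ANOVA".
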