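# Methods

## Signal model and processing chain

The monitor consumes beat-to-beat R-R intervals (RRIs, ms) with
cumulative timestamps, one record per beat. The chain is strictly
streaming: every stage can be driven one beat at a time, and the
per-beat path produces results identical to batch computation over the
same window (asserted by test).

### Outlier screening

Accepted intervals are held in a first-in first-out buffer covering the
most recent ~180 s of beat time. For each incoming interval the buffer
(excluding the candidate) provides a robust location/scale estimate:
`σ = 1.4826 × MAD`, and the normal range is the open interval
`median ± 4σ`. Intervals at or below the lower bound are removed —
they are almost always spurious detections (e.g., T-waves counted as
beats, ectopic complexes). Intervals at or above the upper bound are
interpreted as `N = round(RRI/median)` merged beats and replaced by `N`
equal intervals of `RRI/N` flagged `corrected`; the replacement
conserves the summed interval exactly, so cumulative beat time is never
distorted by correction. Design choices the screen needed beyond this
rule:

* **Warm-up** — screening starts once the buffer covers ≥ 30 s
  (configurable); earlier beats pass through unscreened. A 2-beat
  buffer would otherwise produce meaningless MADs.
* **Even-count median** — mean of the two central order statistics.
* **Boundary convention** — equality with a bound is classified as the
  adjacent outlier class (measure-zero for real data; conservative).
* **Constant buffer (MAD = 0)** — the ±4σ band collapses to a point.
  Intervals within ±20% of the median are then accepted; anything
  further is classified by sign. This keeps a pathological but valid
  constant rhythm from rejecting every subsequent beat.
* **Corrected intervals re-enter the buffer** and contribute to later
  medians; removed intervals never do. Removed beats stay in the
  *output* with their original timestamps (flag `removed`) so reports
  can count them, and the HRV path simply omits them.

The failure rate of a stream is `outliers / total beats × 100%`.

### HRV indices

Eight indices per 180-s window, in fixed order
(meanNN, SDNN, RMSSD, NN50, TP, LF, HF, LF/HF):

* Time domain on the buffered intervals: meanNN (ms), SDNN (ms,
  population divisor by default, configurable), RMSSD (ms), NN50
  (count of successive differences strictly greater than 50 ms).
* Frequency domain: the (beat time, interval) tachogram is
  cubic-spline interpolated and sampled at 4 Hz strictly inside the
  knot range (no extrapolation). The mean-removed series is fitted
  with an AR(40) model by the Burg method (forward–backward prediction
  error; the standard choice for short HRV windows — a windowed-
  autocorrelation Yule–Walker fit is available as a configuration
  fallback). The one-sided AR spectrum is evaluated on 1024 grid
  points over [0, 2 Hz] and normalized so its integral over the grid
  equals the series variance. Band powers are trapezoid integrals with
  interpolated band edges: LF over 0.04–0.15 Hz, HF over 0.15–0.4 Hz,
  TP over 0–0.4 Hz.

Degenerate windows are handled without exceptions: a constant window
has zero spectral power and LF/HF is reported as a configurable
sentinel (10⁶) when HF = 0. Total power is ambiguous in the HRV
literature (PSD band integral vs. time-domain variance); the default is
the PSD integral over the monitored 0–0.4 Hz band with a
`tp_mode="variance"` switch.

### MSPC monitoring

The eight indices mix units (ms, ms², counts, a ratio), so vectors are
z-scored with the training mean and standard deviation before the
monitoring statistics are evaluated — without autoscaling the ms²
powers would dominate every principal component. The PCA model is the
eigendecomposition of the training correlation matrix; the six leading
eigenvectors form `V_R` and the square roots of their eigenvalues the
score scales `Σ_R`. Loadings carry a deterministic sign convention
(largest-magnitude element positive) so serialized models are
byte-reproducible. The two statistics are

* `Q = zᵀ(I − V_R V_Rᵀ)z` — squared distance from the PC subspace;
  rises when the *correlation structure* among indices breaks;
* `T² = Σ_r (v_rᵀz / σ_r)²` — Mahalanobis distance inside the
  subspace; rises when the sample shifts far along modeled directions.

Control limits are empirical upper-percentile estimates (linear
interpolation between order statistics) of each statistic over
normal-condition samples at α = 99%. A one-sided upper limit is the
standard MSPC reading for nonnegative statistics. Model files are JSON
and round-trip bit-exactly (floats serialized at full precision).

The two-level deployment scheme — a population-level PCA model plus
per-recording control-limit tuning — is supported by keeping
`fit_model` and `tune_control_limits` separate; a pretrained model is
just an importable JSON file.

### Alarm state machine

Two states, interictal and preictal. A counter τ accumulates the beat
durations (seconds) while the *leaving* condition of the current state
holds — exceedance while interictal, recovery while preictal — and
resets to zero the moment it fails; at τ ≥ 10 s the state toggles and τ
resets. Equality with a control limit is not an exceedance. The default
driving mode is a single statistic (`q` or `t2`, run in parallel when
both are wanted, matching how the two statistics are scored separately);
an `either` mode (alarm when Q **or** T² exceeds) is available. Under
`either`, recovery defaults to the logical negation of exceedance (both
statistics back at or under their limits), which makes the machine a
clean symmetric debouncer; the literal disjunctive reading — one quiet
statistic suffices to start the recovery clock even while the other
persists above its limit — is available as `recovery="literal"`.

### Evaluation conventions

All intervals are half-open `[start, end)`. A seizure counts as
predicted iff any alarm episode overlaps `[onset − 900 s, onset)` — an
alarm that opens earlier but reaches into the horizon counts, and
multiple alarms before one seizure count once. The false-positive rate
attributes an episode to the interictal interval containing its
*onset*, divided by total interictal hours. Interictal intervals must
sit ≥ 30 min from every onset (configurable margin for short synthetic
recordings). The sign test is the exact binomial tail; the group
comparison of FP rates is Welch's t-test (two identical zero-variance
groups give p = 1 by convention). Bland–Altman limits of agreement are
bias ± 1.96 × SD (sample SD, n−1) of the reference-minus-device
differences. Failure-rate summaries round per-subject rates to one
decimal and summarize them with the population-SD divisor, matching the
precision conventions of small-cohort reporting.

## Synthetic data: what it emulates, and what it does not

The generator emits beats from an instantaneous RR function —
`mean_rr + lf_amp·sin(2π·0.10·t + φ₁) + hf_amp·sin(2π·0.25·t + φ₂) +
noise` — with each interval read at the current cumulative time, a
lightweight stand-in for integral pulse frequency modulation. Defaults
describe a resting adult: 1000 ms mean interval, 30 ms oscillation
amplitude in each band, 20 ms white jitter. This reproduces the two
features the monitor relies on: energy placed in the canonical LF/HF
bands, and a stable correlation structure among the eight indices.

Artifacts are injected to exercise the screen: a *miss* merges two
consecutive intervals (high outlier), an *ectopic-like* event splits an
interval into a 30–45%/70–55% pair (both halves land below the lower
bound and are removed). A *preictal anomaly* multiplies the generator
parameters inside a window (defaults: mean ×0.85, LF ×2.5, HF ×0.35,
noise ×1.8) and mixes the LF/HF amplitudes with strength 0.6 — breaking
the trained correlation structure so Q rises. The default effect size
is an artifact constant chosen during implementation so the end-to-end
recovery check passes with margin; it is a property of the test
harness, not an empirical claim about preictal physiology.

What the generator does **not** model: circadian and sleep-stage
modulation, respiratory frequency drift, true ectopic morphology,
baseline wander of the detector, nonstationary band amplitudes, or any
pathophysiology of real preictal autonomic change. Passing the
end-to-end tests therefore demonstrates that the pipeline detects the
*kind* of change the method postulates (location/correlation shifts of
the HRV vector) at the stated calibration; it says nothing about
clinical sensitivity or false-positive rates on patients.

## Calibration and problem sizes

Calibration vectors are drawn **one per independently seeded stream**
(fresh phases and noise each time, ~195-s streams): sliding windows
within one stream overlap by 179/180 beats and share the oscillator
phases, so they form a strongly dependent sample that would distort an
empirical percentile and its exceedance estimate. Default sizes: 1000
training vectors, 6000 tuning vectors, 10,000 held-out vectors — enough
that the held-out exceedance of a 99% limit is estimated to ±0.2
percentage points (1σ). The end-to-end cohort check uses 7 subjects ×
1-h streams with two 300-s anomaly windows each (onsets at the window
ends) and ~0.5% + 0.5% artifact rates, monitored per beat. The
interictal-consistency check of that cohort is made on the held-out
independent windows: a 1-h stream contains only a handful of dependent
exceedance clusters, so a stream-internal exceedance fraction is a
Poisson-level estimate with no diagnostic value at this scale (the
stream-internal fraction is still reported by the acceptance script).

## Known limitations

* The AR-spectrum residual variance follows the classic Burg recursion
  as implemented by statsmodels; alternative normalizations differ by
  ~1% at order 40 on short windows (the spectral *shape* is identical).
* NN50 is computed over successive accepted intervals; across a removed
  beat the "successive" pair spans the gap.
* The screen tests each interval against the buffer excluding the
  candidate; a burst of consecutive genuine outliers can still drag the
  median once corrections are appended.
* The predictor treats τ-accumulation and toggling per beat, so state
  changes are quantized at beat boundaries (~1 s).
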