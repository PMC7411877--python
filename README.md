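# hrvmspc

Heart-rate-variability (HRV) anomaly detection for epileptic seizure
warning, built as a reusable, tested Python pipeline.

Epileptic seizures perturb the central autonomic network before and
during the electrographic onset, which leaves a signature in the
beat-to-beat variability of the heart rhythm. A wearable ECG telemeter
can stream R-R intervals (RRIs) continuously, so a monitor that flags
anomalous HRV in real time can warn a patient minutes before a seizure.
This package implements the full analysis chain for such a monitor:

1. **RRI screening** (`hrvmspc.rri_stream`) — a 180-s FIFO buffer of
   accepted intervals; each incoming interval is tested against the
   robust range `median ± 4σ` with `σ = 1.4826·MAD`. Short spurious
   intervals are removed; an over-long interval is interpreted as
   `N = round(RRI/median)` missed beats and replaced by `N` equal
   intervals, conserving elapsed time exactly.
2. **HRV features** (`hrvmspc.hrv_features`) — eight indices per
   3-minute window: meanNN, SDNN, RMSSD, NN50 (time domain) and TP, LF
   (0.04–0.15 Hz), HF (0.15–0.4 Hz), LF/HF (frequency domain, via
   cubic-spline resampling of the tachogram at 4 Hz and an AR(40) Burg
   power spectrum).
3. **MSPC monitoring** (`hrvmspc.mspc`) — multivariate statistical
   process control on the autoscaled index vector `x` with a PCA model
   of interictal (normal) data. With `V_R` the 8×6 loading matrix and
   `Σ_R` the diagonal matrix of score standard deviations:

       Q  = xᵀ (I − V_R V_Rᵀ) x        squared prediction error
       T² = xᵀ V_R Σ_R⁻² V_Rᵀ x        Hotelling statistic

   Control limits are the empirical 99th percentiles of each statistic
   over normal samples.
4. **Alarm state machine** (`hrvmspc.predictor`) — a two-state
   (interictal/preictal) debouncer: the state toggles only after a
   statistic stays beyond (or back within) its control limit for 10 s
   of accumulated beat time.
5. **Evaluation** (`hrvmspc.evaluation`) — sensitivity within a 15-min
   pre-onset horizon, false positives per interictal hour, exact
   one-sided sign test, Welch t-test on false-positive rates,
   Bland–Altman agreement, and measurement failure-rate summaries.
6. **Synthetic data** (`hrvmspc.synthetic`) — an RRI generator with
   LF (~0.10 Hz) and HF (~0.25 Hz) oscillations, missed-beat/ectopic
   artifact injection, and preictal anomaly windows that shift the
   generator parameters and mix the LF/HF channels so the index
   correlation structure breaks the way the monitor assumes.

## Worked example

Generate a small synthetic cohort, calibrate a monitoring model on
clean interictal streams, and run the alarm pipeline on one subject:

```sh
$ hrvmspc simulate cohort --subjects 2 --duration 1800 --seed 3
wrote 2 subjects to cohort (0.25 interictal hours)

$ python -c "from hrvmspc import pipeline; \
             pipeline.calibrate_model(seed=3, n_train=300, n_tune=1000).save('model.json')"

$ hrvmspc clean cohort/subject_A_rri.csv cleaned.csv --report report.json
1909 beats, 88 outliers (4.6%)

$ hrvmspc predict --rri cohort/subject_A_rri.csv --model model.json --mode q
preictal      781.3 ..     1320.9 s  [q]
preictal     1373.9 ..     1799.5 s  [q]
2 episode(s) over 1663 monitored beats
```

Subject A carries two injected preictal anomaly windows starting at
750 s and 1350 s (seizure onsets at 1050 s and 1650 s). The Q statistic
raises an alarm ~30 s into each window — both seizures are "predicted"
inside the 15-min horizon — and the cleaning step flags the injected
measurement artifacts (4.6% of beats) for removal or missed-beat
correction before any HRV index is computed.

The same machinery reproduces the published worked examples: predicting
12 of 14 seizures gives an exact one-sided sign-test p of
`106/16384 ≈ 0.0065`; the per-seizure alarm-interval tables yield
sensitivities of 85.7% (Q) and 14.3% (T²) at the 15-min horizon; and
the per-subject outlier counts summarize to a failure rate of
3.46 ± 1.91% (mean ± population SD).

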