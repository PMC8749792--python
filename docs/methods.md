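# Methods

## The measurement model

An Android measurement is 30 amplitude samples, one per 500 ms over 15 s;
each sample is the recorder API's maximum absolute amplitude since the last
poll, a unitless integer modelled here on the 16-bit scale [0, 32767]. Two
empirical recorder artifacts are modelled: the first polled sample is 0 and
the second is depressed (both fall within the first second of recording,
before the audio pipeline has settled). The deployed app averaged all 30
samples arithmetically in the amplitude domain and stored that single value;
the corrected pathway discards the first two samples, converts each retained
sample to dB(C) through the device's calibration curve, and takes the
energetic average.

Two further known defects of the deployed measurement are documented but not
modelled: the narrowband AMR codec band-limits the signal outside roughly
200–3400 Hz, and the app gave no visual indication that a measurement was
running, so users could cover the microphone or put the phone down
mid-measurement. Neither is a reproducible computation; they are caveats on
any converted value, not terms in the model.

## Calibration model

Device response is log-linear, `L = a·log10(x) + b` with `L` in dB(C) and
`x` the amplitude. The slope `a` (dB/decade) is near 20 — what one expects
if amplitude is roughly proportional to sound pressure, since
`L_p = 20·log10(p/p0)` — and the intercept `b` absorbs the device's gain
offset. Fitting is ordinary least squares of `L` on `log10(x)`: the
reference level is the controlled variable and the amplitude the noisy
reading, and minimizing in the dB direction keeps the model well-specified
under multiplicative (log-normal in amplitude) microphone gain error. `R²`
is the ordinary coefficient of determination, `1 − SS_res/SS_tot`. OLS is
delegated to `scipy.stats.linregress`; tests cross-check the result against
the closed-form normal-equation solution computed independently.

A standard session has seven points, 50–80 dB(C) in 5 dB steps, taken at
1000 Hz with C-weighting — at 1000 Hz the A- and C-weighting offsets are
both zero, so dB_SPL, dB(A) and dB(C) coincide and the weighting is carried
as a metadata tag only. Because device curves share nearly the same slope, a
single (level, amplitude) point plus a reference slope calibrates an
additional device by offset alone (`b = L − a_ref·log10(x)`); such profiles
carry no `R²`.

Conversions are defined for any amplitude `x > 0` but the integer recorder
scale makes values below 1 digital unit meaningless, so pipeline stages that
model stored data (`corrected_average`, `transform_entries`) treat retained
samples or stored amplitudes `< 1` as invalid rather than converting them.
Conversions outside the 50–80 dB(C) fitted range are allowed — field data
routinely falls outside it — but flagged `extrapolated` in outputs. Display
rounding is half-up to 0.1 dB (the resolution of a class-2 sound level
meter) and happens only at presentation; internal values keep full
precision.

The packaged registry maps the device IDs observed in user-agent strings to
canonical model names, with alias groups for model families that appear
under several IDs (e.g. the Moto G family: `Moto G`, `XT1028`, `XT1032`).
Matching is case-sensitive exact string — device IDs are verbatim platform
constants. Unknown IDs resolve to `("unknown", no calibration)` as a normal
outcome. The ID `SM-A300FU` (2015 "Galaxy A3" hardware) is deliberately kept
uncalibrated: the calibrated Galaxy A3 profile was measured on the 2016
SM-A310F, and name-level grouping would silently apply one device's curve to
different hardware.

## The legacy averaging bias

Write `m = a/10`. Converting the arithmetic amplitude mean gives
`a·log10(mean(x)) + b = 10·log10(M_1(x)^m) + b`, while the corrected Leq of
per-sample levels equals `10·log10(mean(x^m)) + b = 10·log10(M_m(x)^m) + b`,
where `M_r` is the power mean of order `r`. For `a > 10` (all real devices),
`M_m ≥ M_1` with equality iff the series is constant — so the stored value
never exceeds the correct one, and the gap grows with within-series spread.
The gap is independent of the intercept `b`, which cancels between inversion
and re-application; it depends on the slope, which is why the steeper
Pixel 2 shows the largest worst-case error.

The worst-case audit reconstructs the low/high amplitudes by inverting each
device's fitted curve at 50 and 80 dB(C) rather than using the original lab
readings, which are not available in machine-readable form. For a device
whose lab points sit exactly on its curve this is lossless; in general the
reconstruction shifts audit values by up to a few tenths of a dB against
lab-measured references. Reconstruction uses continuous amplitudes by
default; an `integer_amplitudes` flag quantizes to the recorder scale and
changes results by well under 0.1 dB.

## Synthetic data

The generators emulate the study conditions so every stage is testable
without private data:

- **Series**: retained samples are `round(10^((L + ε − b)/a))` with
  `ε ~ N(0, σ²)` in dB, clipped to [0, 32767]; default `σ = 0.5` dB, the
  accuracy class of the reference meter and calibrator. Noise additive in dB
  (log-normal in amplitude) matches multiplicative microphone gain error.
  With the startup artifact on, sample 1 is 0 and sample 2 a uniform
  fraction in [0, 1) of sample 3 — "depressed but variable", the observed
  pattern.
- **Sessions**: one point per reference level (default the seven-point
  50–80 dB(C) ladder); the recorded amplitude is the corrected (Leq) average
  of a full series inverted through the curve, kept continuous because an
  average over 28 samples resolves below one digital unit. This makes the
  noiseless round trip exact (refit recovers `a`, `b` to machine precision),
  which quantized single samples would not.
- **Databases**: per-model user and measurement counts are reproduced
  exactly (round-robin user assignment so every prescribed user appears);
  Android stored amplitudes are produced by the *legacy* arithmetic
  averaging of simulated series, so the synthetic table carries the
  documented downward bias end to end. True per-entry levels are Gaussian in
  dB(C) (default mean 65, sd 12) clipped to [30, 100], consistent with the
  ranges seen in converted field data; per-user loudness is a Gaussian base
  in [0, 1] (default mean 0.4, sd 0.15) with per-entry fluctuation of
  sd 0.08. iOS and no-user-agent entries carry no amplitude; uncalibrated
  Android models synthesize through a generic curve (a = 21, b = 8, labelled
  synthetic) so that their raw amplitudes exist even though the transform
  correctly refuses to convert them.

All generators are pure functions of (parameters, seed). What passing tests
on synthetic data do **not** show: real microphones' frequency response and
codec band-limiting, room acoustics, user interference, or how far real
per-device amplitude scales deviate from log-linearity outside 50–80 dB(C).

## Numerical choices and degenerate inputs

- Energetic averaging uses the power form `10·log10(mean(10^(L/10)))`. For
  the worst-case composition this evaluates to 65.35 dB(C), consistent (at
  0.1 dB) with reference audit values; pressure-RMS averaging (20·log10
  form) would give 65.0 and is not used.
- Fits require ≥ 2 points with distinct amplitudes; otherwise a
  degenerate-design error. `R²` is recomputed from residuals (not the
  squared correlation) so the two-point exact line reports `R² = 1`.
- Empty level lists, non-positive pressures/amplitudes, mixed weighting
  tags, and user/measurement count inconsistencies raise immediately with
  specific exceptions; unknown devices and unconvertible entries are
  *statuses*, not errors — entry count is conserved through the transform.
- Series of nonstandard length are accepted with a warning (experiment
  builds and the deployed app differ in effective sample count); the legacy
  average is defined over all samples of whatever length arrives, the
  corrected average over all retained ones.
- The second-sample artifact flag uses a concrete rule — below half the
  median of samples 3–30 — chosen because the empirical description
  ("often too low") needs a testable threshold; detection only flags and
  never repairs.
- Per-model summaries report both the arithmetic mean of per-entry dB values
  and their energetic mean: which of the two a legacy report's "average"
  column means is ambiguous, so both are emitted and the arithmetic one is
  labelled `db_c_avg`.

## Problem sizes

The test suite exercises the full platform-composition scale (76,542
synthetic entries) once, via the vectorized generator, and uses databases of
10²–10³ entries elsewhere; hypothesis property tests run at their default
example counts with derandomized seeds. These sizes make every documented
property measurable while keeping the suite interactive.
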