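# soundcal

Calibration and auditing of crowdsensed smartphone sound-level data.

Mobile-health (mHealth) platforms that run ecological momentary assessments
sometimes record the environmental sound level while a user fills in a
questionnaire — on Android, by polling the recorder API's maximum absolute
amplitude every 500 ms for 15 s (30 samples) and storing a single averaged
value. Those stored values are **uncalibrated**: the amplitude scale differs
by device model, so readings from different phones cannot be compared, let
alone interpreted as decibels. `soundcal` is for researchers who have such a
legacy table of raw amplitudes and want to make it interpretable.

The package implements:

- **Device calibration curves.** Each device model's response is log-linear:
  `L = a·log10(x) + b`, where `x` is the recorder amplitude, `L` the sound
  level in dB(C), `a` the slope in dB per decade of amplitude (≈ 20–24 for
  real devices, close to the 20·log10 of the sound-pressure-level definition
  `L_p = 20·log10(p/p0)`, `p0 = 20 µPa`), and `b` a device-specific offset.
  Curves are fitted by ordinary least squares of level on log10(amplitude)
  from a seven-point session (50–80 dB(C) in 5 dB steps at 1000 Hz, where A-
  and C-weighting offsets are both zero). Five lab-calibrated profiles
  (Galaxy S7, Galaxy A3, Moto G, Moto G 5S Plus, Pixel 2) ship in a packaged
  device-ID registry, and a one-point offset calibration extends coverage to
  new devices using a reference slope.
- **Correct energetic averaging.** Levels are logarithmic; the equivalent
  continuous level of a series is `Leq = 10·log10(mean(10^(L_i/10)))`, never
  the arithmetic mean of dB values — and never the dB of an arithmetic mean
  of amplitudes, which is what the legacy app stored.
- **Legacy-error auditing.** A worst-case series of 29 quiet (50 dB(C)) and
  1 loud (80 dB(C)) samples shows the stored values understate true loudness
  by ≈ 9.5–10.7 dB depending on the device slope — roughly a factor of two
  in perceived loudness. The audit also detects the recorder startup
  artifact (first sample 0, second sample depressed).
- **Bulk transformation** of a stored entries table into dB(C) with explicit
  per-entry statuses, per-model summaries, platform composition reports and
  per-user plausibility screening.
- **Seeded synthetic data**: generators that emulate the calibration
  experiment and a full crowdsensed database (including the legacy averaging
  bias), so the whole pipeline is testable without any private data.

## Worked example

```python
import soundcal as sc

table = sc.error_table(sc.default_registry())
print(table[["device_id", "model_name", "legacy_db_display",
             "correct_db_display", "difference_display"]].to_string(index=False))
```

prints

```
       device_id     model_name  legacy_db_display  correct_db_display  difference_display
        SM-G930F      Galaxy S7               55.9                65.4                 9.5
        SM-A310F      Galaxy A3               55.8                65.4                 9.6
          XT1032         Moto G               55.6                65.4                 9.8
Moto G (5S) Plus Moto G 5S Plus               55.5                65.4                 9.8
         Pixel 2        Pixel 2               54.7                65.4                10.7
```

`legacy_db` is what the deployed app would store for the worst-case series
(29 samples at 50 dB(C), one at 80 dB(C)), converted to dB(C) through each
device's curve; `correct_db` is the energetic (Leq) average of the same
series; the difference is how far stored values understate true loudness —
about 9.5 dB here, i.e. roughly half the perceived loudness.

The `examples/` directory contains one short narrative script per
capability: fitting a calibration curve from a simulated session, the audit
above, converting a stored entries table (with statuses and per-model
summaries), and generating a full synthetic database. The same operations
are available from the shell via the `soundcal` CLI (`soundcal audit`,
`convert`, `summarize`, `screen`, `simulate`).

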