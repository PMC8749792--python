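"""Convert stored crowdsensed amplitudes into dB(C), with explicit statuses.

Every entry gets exactly one status: converted (Android, calibrated device,
amplitude >= 1), non_android, no_calibration, or invalid_amplitude — nothing
is silently dropped.
"""

import soundcal as sc

entries = [
    sc.SoundEntry("e1", "u1", device_id="SM-G930F", stored_amplitude=451.1),
    sc.SoundEntry("e2", "u1", device_id="SM-G930F", stored_amplitude=28.0),
    sc.SoundEntry("e3", "u2", device_id="XT1028", stored_amplitude=1000.0),
    sc.SoundEntry("e4", "u3", device_id="SM-G900F", stored_amplitude=500.0),
    sc.SoundEntry("e5", "u4", device_id="SM-G930F", stored_amplitude=0.0),
    sc.SoundEntry("e6", "u5", platform="ios", tinnitus_loudness=0.4),
]

out = sc.transform_entries(entries, sc.default_registry())
cols = ["entry_id", "device_id", "model_name", "status", "db_c", "extrapolated"]
print(out[cols].to_string(index=False))
print(
    "\ndb_c is the calibrated level a*log10(amplitude)+b for the resolved\n"
    "device model; 'extrapolated' marks levels outside the 50-80 dB(C) range\n"
    "the calibration experiment covered.  XT1028 resolves to the Moto G\n"
    "profile through its alias group; the Galaxy S5 has no calibration, and\n"
    "iOS stores relative dB values that amplitude curves cannot convert."
)

summary = sc.summarize_levels(out)
print("\nper-model summary of converted entries:")
print(summary.to_string(index=False))
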