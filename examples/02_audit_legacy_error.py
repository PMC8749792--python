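"""Quantify the legacy averaging bias with the worst-case audit.

The deployed app averaged its 30 amplitude samples arithmetically before
storing them.  Because levels are logarithmic, a series of 29 quiet samples
(50 dB(C)) and one loud one (80 dB(C)) then stores a value ~9.5 dB below the
true equivalent continuous level — about half the perceived loudness.
"""

import soundcal as sc

table = sc.error_table(sc.default_registry())
print("worst case: 29 samples at 50 dB(C), 1 sample at 80 dB(C)\n")
print(
    table[
        ["device_id", "model_name", "legacy_db_display", "correct_db_display",
         "difference_display"]
    ].to_string(index=False)
)
print(
    "\nlegacy_db: what the deployed app would store (converted to dB(C));\n"
    "correct_db: the energetic (Leq) average of the same series;\n"
    "difference: how much stored values understate true loudness.\n"
    "A 10 dB difference is perceived as roughly double loudness."
)
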