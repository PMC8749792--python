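"""Generate a synthetic crowdsensed database and run the full pipeline.

The generator emulates the structure of a real mHealth sound-measurement
table: prescribed per-platform and per-model composition, per-user loudness
traces, and Android amplitudes produced by the *legacy* arithmetic averaging
of simulated 30-sample series — so the synthetic data carries the deployed
app's documented downward bias.
"""

import soundcal as sc

spec = sc.DatabaseSpec(
    models=(
        sc.ModelCount("Galaxy S7", n_users=4, n_measurements=300),
        sc.ModelCount("Moto G", n_users=3, n_measurements=200),
        sc.ModelCount("Galaxy S5", n_users=5, n_measurements=150),  # uncalibrated
    ),
    n_ios=400,
    n_no_user_agent=5,
    seed=20260927,
)
db = sc.generate_synthetic_database(spec)
print(f"generated {len(db)} entries\n")

comp = sc.dataset_composition(db)
print("platform composition:")
print(comp.platforms.to_string(index=False))
print("\nper-model usage (descending by measurements):")
print(comp.models.to_string(index=False))

out = sc.transform_entries(db)
print("\nconversion statuses:")
print(out["status"].value_counts().to_string())

screen = sc.plausibility_screen(db, min_entries=60)
print(f"\nusers with >60 plausible sound entries: "
      f"{int(screen['eligible'].sum())} of {len(screen)}")
print(
    "\nEligibility requires more than the threshold number of sound entries\n"
    "AND fluctuating (non-constant, non-zero) amplitude and loudness traces."
)
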