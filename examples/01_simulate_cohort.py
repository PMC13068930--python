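"""Simulate a synthetic aging cohort with planted exposome effects.

Generates 1000 participants aged 44-82 with regional grey-matter volumes
declining along an individual effective brain age, an exposome table whose
variables shift the aging deviation d, and exported ground truth.  Prints
the cohort's shape and the planted effect battery.
"""

from expobag import CohortConfig, default_effects, default_missingness, generate_cohort

effects = default_effects(n_null=20)
config = CohortConfig(
    n_participants=1000, seed=7, missingness_blocks=default_missingness(effects)
)
bundle = generate_cohort(config, effects)

print(f"participants: {bundle.participants.shape[0]}")
print(f"grey-matter levels: { {k: v.shape for k, v in bundle.gm.items()} }")
print(f"exposome: {bundle.exposome.shape[1]} variables, "
      f"{int(bundle.exposome.isna().sum().sum())} missing cells")
d = bundle.ground_truth.deviations
print(f"aging deviation d: mean {d.mean():+.2f} y, sd {d.std():.2f} y")
print("planted effects (strength in years of deviation per SD of exposure):")
for e in bundle.ground_truth.effects:
    if e.kind != "null":
        extra = f" (partner {e.partner})" if e.partner else ""
        print(f"  {e.name:<20} {e.kind:<10} strength {e.strength:+.1f}{extra}")
# A positive strength means higher exposure -> older-appearing brain.
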