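"""Train and select a brain-age model on the healthy reference sample.

Compares ridge candidates at two grey-matter granularities; hyperparameters
are tuned on inner folds of the 80% training split and the reported r / MAE
come from the untouched 20% hold-out.  The model with the smallest hold-out
MAE is selected.
"""

from expobag import (
    CohortConfig, CVSpec, ModelCandidate, default_effects, generate_cohort,
    select_best_model, select_healthy, train_candidate,
)

bundle = generate_cohort(
    CohortConfig(n_participants=1200, seed=3), default_effects(n_null=10)
)
healthy = select_healthy(bundle.participants)
print(f"healthy reference sample: {len(healthy)} of {len(bundle.participants)}")

ages = bundle.participants.loc[healthy, "age"]
cv = CVSpec(outer_folds=5, outer_repeats=1, inner_folds=5, holdout_fraction=0.2, seed=0)
evaluations = []
for granularity in (100, 50):
    candidate = ModelCandidate("ridge", granularity)
    model, ev = train_candidate(
        bundle.gm[granularity].loc[healthy], ages, candidate, cv, nested_breakdown=False
    )
    evaluations.append((candidate, ev))
    print(f"  ridge @ {granularity:>3} regions: hold-out MAE {ev.mae:.2f} y, r {ev.r:.3f}")

best = select_best_model(evaluations)
print(f"selected: {best.name} (minimum hold-out MAE)")
# Hold-out MAE is in years of predicted-vs-chronological age error; r is the
# Pearson correlation between predicted and chronological age.
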