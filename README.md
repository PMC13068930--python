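# expobag

Brain-age-gap normative modelling and exposome-based prediction of
grey-matter health, as a tested, reusable tabular pipeline.

## The problem

How much of the variability in structural brain health across an aging
population can be explained by the totality of exposures — biomedical,
lifestyle, socio-affective, early-life and environmental — acting on each
individual?  `expobag` implements the two-stage analysis used to answer
this question at population scale:

1. **Brain age and BAG.**  A regression model is trained to predict
   chronological age from parcellated grey-matter volumes in a strictly
   healthy reference sample (the *normative* model).  Because predictions
   regress toward the training mean, the raw gap correlates artefactually
   with age; the standard correction fits, on the training set only, the
   OLS line of predicted age ŷ on age *a* and adjusts each prediction as

       ŷ_adj = (ŷ − β₀) / β₁,     BAG = ŷ_adj − a.

   On the fitting set this makes mean(BAG) = 0 and corr(BAG, a) = 0
   exactly.  Positive BAG marks an older-appearing brain.
2. **Exposome → BAG.**  In the disjoint population set, BAG is predicted
   from a curated exposome table under repeated nested cross-validation.
   Confound residualization (age, age², sex, height, volumetric scaling)
   and standardization are fitted on training folds only.  Significance is
   assessed by permuting the target and re-running the CV (p = (1+b)/(1+B),
   so the floor at B = 500 is ≈ 0.002), with Benjamini–Hochberg FDR across
   metrics.  Per-variable contributions are quantified by Shapley values
   satisfying the local-accuracy identity (base + Σφ = prediction), with a
   univariate linear contrast alongside to expose *moderators*: variables
   with top-quartile multivariate contribution yet null marginal
   correlation with BAG.

Real cohorts of this kind are under restricted access, so the package ships
a **synthetic cohort generator** with planted, exported ground truth —
linear, nonlinear, duration-type, moderator and null exposome effects on an
individual aging deviation — making every stage testable end to end.

## Worked example

```bash
python examples/07_full_pipeline.py      # ~1 minute, one CPU
```

prints (abridged; seed 1, n = 1500):

```
brain-age model selection (hold-out):
  ridge_100          MAE 2.389 y   r 0.961
  selected: ridge_100
age-bias correction: slope 0.9415, intercept 3.73 y
BAG [train]: mean -0.000 sd 2.40 p5 -3.65 p95 3.81 (n=360)
BAG [population]: mean -0.221 sd 8.25 p5 -13.44 p95 12.43 (n=1050)
exposome prediction (random_forest), B=49 permutations:
  pearson_r 0.5878 +- 0.0617  p 0.02  q 0.02
  r2        0.2915 +- 0.0429  p 0.02  q 0.02
attribution fold stability (Spearman): 0.625
ground-truth recovery: 10/10 planted effects in top ranks; null median rank 27.5
  moderator hip_circumference: attribution rank 12, marginal r with BAG -0.046
  pearson_r significant after FDR: True
```

Reading this: the healthy-train BAG mean is zero by construction and the
population BAG spread (±13 y at the 5th/95th percentiles) reflects the
planted aging deviations; the exposome model predicts BAG well above its
permutation null (q < 0.05 after FDR across the five metrics), all ten
planted effect variables surface at the top of the Shapley ranking, and the
planted moderator ranks 12th of 62 while being marginally uncorrelated with
BAG — the moderator phenomenon a univariate contrast alone would miss.

Each capability also has its own narrative script under `examples/`, and a
thin CLI wraps the pipeline: `expobag simulate`, `expobag run`,
`expobag report`.

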