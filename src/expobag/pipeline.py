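"""End-to-end orchestration: simulate -> brain age -> BAG -> curate -> predict
-> explain -> report.

The pipeline enforces the leakage discipline of the two-stage design: the
brain-age model (and its bias correction) is developed on the healthy
reference sample only, the exposome prediction runs on the disjoint
population set, and overlap between the two raises
:class:`PipelineIntegrityError`.  Every stage writes plain-text tables and a
machine-readable summary; a run manifest records the configuration echo,
derived seeds, output hashes, stage timings and package version so any
stage can be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from expobag._version import __version__ as _version
from expobag.attribution import (
    explain_run,
    fold_stability,
    rank_contributions,
    univariate_association,
)
from expobag.bag import apply_correction, compute_bag, fit_bias_correction
from expobag.brainage import (
    CVSpec,
    ModelCandidate,
    predict_age,
    select_best_model,
    select_healthy,
    train_candidate,
)
from expobag.cohort import (
    CohortConfig,
    default_effects,
    default_missingness,
    generate_cohort,
    variable_specs,
    write_cohort,
)
from expobag.curation import build_subsets, curate
from expobag.errors import PipelineIntegrityError
from expobag.prediction import (
    PermutationConfig,
    PredictionCVSpec,
    confound_matrix,
    make_null_runner,
    permutation_test,
    run_prediction,
    summarize_metrics,
)

# reference-scale availability filter: 2000 of 34365 population participants
REFERENCE_N_MIN = 2000
REFERENCE_POPULATION = 34365


@dataclass
class PipelineConfig:
    """Desk-scale defaults for a complete synthetic run."""

    seed: int = 0
    n_participants: int = 3000
    n_null_variables: int = 50
    cohort_overrides: dict = field(default_factory=dict)
    brainage_candidates: tuple = (("ridge", 100), ("ridge", 50), ("ridge", 25))
    brainage_outer_folds: int = 5
    brainage_outer_repeats: int = 1
    brainage_inner_folds: int = 5
    holdout_fraction: float = 0.2
    n_min: int | None = None  # None -> 2000 scaled by population-size ratio
    prediction_algorithm: str = "random_forest"
    prediction_outer_folds: int = 5
    prediction_outer_repeats: int = 5
    prediction_inner_folds: int = 5
    n_permutations: int = 99
    retune_permutations: bool = False
    sex_as_predictor: bool = False
    subset: str = "main"
    explain_samples_per_fold: int = 100
    explain_background: int = 25
    explain_permutations: int = 4
    top_k: int = 30

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["brainage_candidates"] = [list(c) for c in self.brainage_candidates]
        return out


def _stage_seed(seed: int, offset: int) -> int:
    return int((seed * 1000 + offset) % (2**31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline; returns the summary dict (also written).

    Outputs under ``outdir``: the simulated cohort (``cohort/``), brain-age
    model-selection table, bias-correction parameters, the population BAG
    table, the curated exposome with its curation report, prediction
    metrics/predictions, the attribution ranking and per-sample values, the
    univariate contrast, a ground-truth recovery scorecard, ``summary.json``
    / ``summary.txt`` and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings, t_all = {}, time.time()

    # --- simulate -----------------------------------------------------------
    t0 = time.time()
    effects = default_effects(n_null=config.n_null_variables)
    cohort_kwargs = dict(
        n_participants=config.n_participants,
        seed=_stage_seed(config.seed, 0),
        missingness_blocks=default_missingness(effects),
    )
    cohort_kwargs.update(config.cohort_overrides)
    cohort_cfg = CohortConfig(**cohort_kwargs)
    bundle = generate_cohort(cohort_cfg, effects)
    write_cohort(bundle, outdir / "cohort")
    timings["simulate"] = time.time() - t0

    # --- healthy / population split ----------------------------------------
    healthy_ids = select_healthy(bundle.participants)
    population_ids = bundle.participants.index.difference(healthy_ids)
    if len(healthy_ids.intersection(population_ids)) > 0:
        raise PipelineIntegrityError("healthy and population sets overlap")

    # --- brain age ----------------------------------------------------------
    t0 = time.time()
    ages = bundle.participants.loc[healthy_ids, "age"]
    cv = CVSpec(
        outer_folds=config.brainage_outer_folds,
        outer_repeats=config.brainage_outer_repeats,
        inner_folds=config.brainage_inner_folds,
        holdout_fraction=config.holdout_fraction,
        seed=_stage_seed(config.seed, 1),
    )
    fitted, selection_rows = {}, []
    for algorithm, granularity in config.brainage_candidates:
        cand = ModelCandidate(algorithm, int(granularity))
        model, ev = train_candidate(
            bundle.gm[int(granularity)].loc[healthy_ids], ages, cand, cv,
            nested_breakdown=False,
        )
        fitted[cand.name] = (cand, model, ev)
        selection_rows.append(
            {"candidate": cand.name, "algorithm": algorithm,
             "granularity": int(granularity), "holdout_mae": ev.mae, "holdout_r": ev.r}
        )
    best = select_best_model([(c, e) for c, _m, e in fitted.values()])
    best_model = fitted[best.name][1]
    selection = pd.DataFrame(selection_rows).sort_values("holdout_mae", kind="stable")
    selection.to_csv(outdir / "brainage_selection.tsv", sep="\t", index=False)
    timings["brainage"] = time.time() - t0

    # --- bias correction + BAG ---------------------------------------------
    t0 = time.time()
    gm_best = bundle.gm[best.granularity]
    train_ids = best_model.train_ids
    pred_train = predict_age(best_model, gm_best.loc[train_ids])
    params = fit_bias_correction(
        pred_train, bundle.participants.loc[train_ids, "age"].to_numpy(), source="healthy_train"
    )
    params.to_json(outdir / "bias_correction.json")
    bag_train = compute_bag(
        apply_correction(pred_train, params),
        bundle.participants.loc[train_ids, "age"].to_numpy(),
        ids=train_ids,
        raw_predicted=pred_train,
    )
    pred_pop = predict_age(best_model, gm_best.loc[population_ids])
    bag_pop = compute_bag(
        apply_correction(pred_pop, params),
        bundle.participants.loc[population_ids, "age"].to_numpy(),
        ids=population_ids,
        raw_predicted=pred_pop,
    )
    bag_pop.to_csv(outdir / "bag_population.tsv", sep="\t")
    timings["bag"] = time.time() - t0

    # --- exposome curation ---------------------------------------------------
    t0 = time.time()
    n_min = config.n_min
    if n_min is None:
        n_min = max(1, round(REFERENCE_N_MIN * len(population_ids) / REFERENCE_POPULATION))
    specs = variable_specs(effects)
    curated, creport, _ = curate(
        bundle.exposome.loc[population_ids], specs,
        bundle.participants.loc[population_ids], n_min,
    )
    creport.to_json(outdir / "curation_report.json")
    curated.to_csv(outdir / "curated_exposome.tsv", sep="\t")

    socio = [
        c for c in curated.columns
        if any(e.name == c and e.domain == "socio-affective/mental" for e in effects)
    ]
    variable_sets = {
        "main": list(curated.columns),
        "replication": [c for c in curated.columns if c != "bone_density"],
        "variables_restricted": [c for c in curated.columns if c not in socio],
    }
    subsets = build_subsets(curated, variable_sets)
    timings["curate"] = time.time() - t0

    # --- prediction -----------------------------------------------------------
    t0 = time.time()
    subset_ids = subsets[config.subset]
    subset_vars = variable_sets[config.subset]
    X = curated.loc[subset_ids, subset_vars]
    confounds = confound_matrix(bundle.participants.loc[subset_ids])
    if config.sex_as_predictor:
        X = X.copy()
        X["sex"] = bundle.participants.loc[subset_ids, "sex"].astype(float)
        confounds = confounds.drop(columns="sex")
    y = bag_pop.loc[subset_ids, "bag"]
    pcv = PredictionCVSpec(
        outer_folds=config.prediction_outer_folds,
        outer_repeats=config.prediction_outer_repeats,
        inner_folds=config.prediction_inner_folds,
        algorithm=config.prediction_algorithm,
        seed=_stage_seed(config.seed, 2),
    )
    run = run_prediction(X, y, confounds, pcv)
    perm_cfg = PermutationConfig(
        n_permutations=config.n_permutations,
        folds=config.prediction_outer_folds,
        seed=_stage_seed(config.seed, 3),
        retune=config.retune_permutations,
    )
    runner = make_null_runner(X, confounds, pcv, perm_cfg, fixed_params=run.consensus_params())
    p_values, _nulls = permutation_test(runner, y, run.metric_means, perm_cfg)
    metrics = summarize_metrics(run, p_values)
    metrics.to_csv(outdir / "prediction_metrics.tsv", sep="\t")
    run.fold_metrics.to_csv(outdir / "prediction_fold_metrics.tsv", sep="\t", index=False)
    run.predictions.to_csv(outdir / "predictions.tsv", sep="\t")
    timings["predict"] = time.time() - t0

    # --- explanation ----------------------------------------------------------
    t0 = time.time()
    attributions = explain_run(
        run, X, confounds,
        samples_per_fold=config.explain_samples_per_fold,
        background_size=config.explain_background,
        n_permutations=config.explain_permutations,
        tolerance=1e-6,
        seed=_stage_seed(config.seed, 4),
    )
    ranking = rank_contributions(attributions)
    stability = fold_stability(attributions)
    ranking.to_csv(outdir / "attribution_ranking.tsv", sep="\t", index=False)
    pd.DataFrame(
        attributions.values, columns=attributions.feature_names, index=attributions.sample_ids
    ).to_csv(outdir / "attribution_values.tsv", sep="\t")
    univariate = univariate_association(X, y, confounds)
    univariate.to_csv(outdir / "univariate_association.tsv", sep="\t")
    timings["explain"] = time.time() - t0

    # --- ground-truth recovery scorecard -------------------------------------
    truth = bundle.ground_truth
    rank_of = dict(zip(ranking["variable"], ranking["rank"]))
    effect_ranks = {v: int(rank_of[v]) for v in truth.effect_names if v in rank_of}
    null_ranks = [int(rank_of[v]) for v in truth.null_names if v in rank_of]
    moderators = {}
    for v in truth.moderator_names:
        if v in rank_of and v in univariate.index:
            moderators[v] = {
                "rank": int(rank_of[v]),
                "marginal_r": float(univariate.loc[v, "pearson_r"]),
            }
    k = config.top_k
    scorecard = {
        "effect_ranks": effect_ranks,
        "effects_in_top_k": sum(1 for r in effect_ranks.values() if r <= k),
        "n_effects": len(truth.effect_names),
        "null_median_rank": float(np.median(null_ranks)) if null_ranks else None,
        "moderators": moderators,
        "significant_pearson_r": bool(metrics.loc["pearson_r", "q"] < 0.05)
        if "q" in metrics.columns
        else None,
    }

    summary = {
        "version": _version,
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_healthy": int(len(healthy_ids)),
        "n_population": int(len(population_ids)),
        "brainage": {
            "selection": selection.to_dict(orient="records"),
            "best_candidate": best.name,
        },
        "bias_correction": {"slope": params.slope, "intercept": params.intercept},
        "bag_train_summary": bag_train.attrs["summary"],
        "bag_population_summary": bag_pop.attrs["summary"],
        "curation": {
            "n_min": n_min,
            "n_retained_variables": int(curated.shape[1]),
            "dropped": creport.dropped,
        },
        "subset_sizes": {name: int(len(ids)) for name, ids in subsets.items()},
        "analysis_subset": config.subset,
        "prediction": {
            "algorithm": config.prediction_algorithm,
            "metrics": json.loads(metrics.to_json(orient="index")),
            "pooled_r_per_repeat": run.pooled_r_per_repeat,
            "n_permutations": config.n_permutations,
        },
        "attribution": {
            "top_k": ranking.head(k).to_dict(orient="records"),
            "fold_stability": stability,
        },
        "ground_truth_recovery": scorecard,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    timings["total"] = time.time() - t_all

    manifest = {
        "version": _version,
        "config": config.to_dict(),
        "stage_seeds": {name: _stage_seed(config.seed, i) for i, name in enumerate(
            ["simulate", "brainage", "predict", "permutations", "explain"]
        )},
        "output_hashes": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.json"))
            if p.name != "manifest.json"
        },
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    report(outdir)
    return summary


def report(outdir) -> str:
    """Render a human-readable summary from pipeline outputs.

    Missing stage outputs are noted, not fatal.  Returns the text and writes
    ``summary.txt``.
    """
    outdir = Path(outdir)
    lines = ["expobag pipeline report", "=" * 24]
    summary_path = outdir / "summary.json"
    if not summary_path.exists():
        lines.append("summary.json missing: pipeline did not complete")
        text = "\n".join(lines) + "\n"
        (outdir / "summary.txt").write_text(text)
        return text
    s = json.loads(summary_path.read_text())
    lines += [
        f"seed {s['seed']}  participants {s['n_participants']} "
        f"(healthy {s['n_healthy']}, population {s['n_population']})",
        "",
        "brain-age model selection (hold-out):",
    ]
    for row in s["brainage"]["selection"]:
        lines.append(
            f"  {row['candidate']:<18} MAE {row['holdout_mae']:.3f} y   r {row['holdout_r']:.3f}"
        )
    lines.append(f"  selected: {s['brainage']['best_candidate']}")
    bc = s["bias_correction"]
    lines.append(f"age-bias correction: slope {bc['slope']:.4f}, intercept {bc['intercept']:.2f} y")
    for key, label in [("bag_train_summary", "train"), ("bag_population_summary", "population")]:
        b = s.get(key)
        if b:
            lines.append(
                f"BAG [{label}]: mean {b['mean']:.3f} sd {b['sd']:.2f} "
                f"p5 {b['p5']:.2f} p95 {b['p95']:.2f} (n={b['n']})"
            )
    lines.append("")
    lines.append(f"subset sizes: {s['subset_sizes']}  (analysed: {s['analysis_subset']})")
    lines.append(f"exposome prediction ({s['prediction']['algorithm']}), "
                 f"B={s['prediction']['n_permutations']} permutations:")
    for metric, vals in sorted(s["prediction"]["metrics"].items()):
        p = vals.get("p")
        q = vals.get("q")
        extra = f"  p {p:.4g}  q {q:.4g}" if p is not None and q is not None else ""
        lines.append(f"  {metric:<9} {vals['mean']:.4f} +- {vals['sd']:.4f}{extra}")
    attr = s.get("attribution")
    if attr:
        lines.append(f"attribution fold stability (Spearman): {attr['fold_stability']:.3f}")
        lines.append("top contributing variables:")
        for row in attr["top_k"][:10]:
            lines.append(f"  {row['rank']:>3}. {row['variable']:<24} {row['mean_abs_attr']:.4f}")
    gt = s.get("ground_truth_recovery")
    if gt:
        lines.append("")
        lines.append(
            f"ground-truth recovery: {gt['effects_in_top_k']}/{gt['n_effects']} planted effects "
            f"in top ranks; null median rank {gt['null_median_rank']}"
        )
        for name, info in gt.get("moderators", {}).items():
            lines.append(
                f"  moderator {name}: attribution rank {info['rank']}, "
                f"marginal r with BAG {info['marginal_r']:+.3f}"
            )
        if gt.get("significant_pearson_r") is not None:
            lines.append(f"  pearson_r significant after FDR: {gt['significant_pearson_r']}")
    text = "\n".join(lines) + "\n"
    (outdir / "summary.txt").write_text(text)
    return text
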