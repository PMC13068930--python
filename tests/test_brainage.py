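"""Brain-age model training, selection and healthy-sample filtering."""

import numpy as np
import pandas as pd
import pytest

from expobag import (
    CohortConfig,
    CVSpec,
    Distribution,
    EffectSpec,
    ModelCandidate,
    generate_cohort,
    predict_age,
    select_best_model,
    select_healthy,
    train_candidate,
)
from expobag.brainage import ModelEvaluation
from expobag.errors import DegenerateModelError, SchemaError


def _flags_frame(n):
    return pd.DataFrame(
        {
            "long_standing_illness": 0,
            "diabetes": 0,
            "stroke": 0,
            "icd10_diagnosis": 0,
            "self_rated_health": 4,
        },
        index=pd.Index([f"P{i}" for i in range(n)], name="participant_id"),
    )


class TestSelectHealthy:
    def test_all_healthy_returns_everyone(self):
        table = _flags_frame(5)
        assert list(select_healthy(table)) == list(table.index)

    def test_single_criterion_excludes(self):
        table = _flags_frame(5)
        table.loc["P2", "diabetes"] = 1
        table.loc["P4", "self_rated_health"] = 2
        assert list(select_healthy(table)) == ["P0", "P1", "P3"]

    def test_missing_flag_column_raises(self):
        table = _flags_frame(3).drop(columns="stroke")
        with pytest.raises(SchemaError):
            select_healthy(table)

    def test_flagged_fraction_matches_config(self, small_cohort):
        bundle, config, _ = small_cohort
        healthy = select_healthy(bundle.participants)
        expected = config.n_participants - round(
            config.frac_nonhealthy * config.n_participants
        )
        assert len(healthy) == expected


@pytest.fixture(scope="module")
def noiseless_cohort():
    effects = [EffectSpec("v0", "null", Distribution("normal", (0, 1)))]
    config = CohortConfig(
        n_participants=400, n_regions=20, granularity_levels=(20,),
        noise_sd_gm=0.0, deviation_noise_sd=0.0, scaling_sd=0.0,
        frac_nonhealthy=0.0, aberrant_rate=0.0, seed=5,
    )
    return generate_cohort(config, effects)


def test_ridge_recovers_age_from_noise_free_features(noiseless_cohort):
    bundle = noiseless_cohort
    ages = bundle.participants["age"]
    model, ev = train_candidate(
        bundle.gm[20], ages, ModelCandidate("ridge", 20), CVSpec(5, 1, 5, 0.2, 0),
        nested_breakdown=False,
    )
    assert ev.mae < 0.5
    assert ev.r > 0.99
    # memorization limit: training rows are reproduced up to regularization bias
    pred = predict_age(model, bundle.gm[20])
    assert np.abs(pred - ages.to_numpy()).max() < 1.0


def test_permuted_target_gives_null_correlation():
    rng = np.random.default_rng(0)
    idx = pd.Index([f"P{i}" for i in range(1000)], name="participant_id")
    features = pd.DataFrame(rng.normal(size=(1000, 15)), index=idx)
    ages = pd.Series(rng.permutation(np.linspace(44, 82, 1000)), index=idx)
    _, ev = train_candidate(
        features, ages, ModelCandidate("ridge", 15), CVSpec(5, 1, 5, 0.2, 0),
        nested_breakdown=False,
    )
    assert abs(ev.r) < 0.1


def test_holdout_rows_never_used_for_tuning(noiseless_cohort):
    bundle = noiseless_cohort
    ages = bundle.participants["age"]
    model, _ = train_candidate(
        bundle.gm[20], ages, ModelCandidate("ridge", 20), CVSpec(5, 1, 5, 0.2, 0),
        nested_breakdown=False,
    )
    assert len(model.train_ids.intersection(model.holdout_ids)) == 0
    assert len(model.train_ids) + len(model.holdout_ids) == len(ages)


def test_nested_breakdown_reports_fold_metrics(noiseless_cohort):
    bundle = noiseless_cohort
    ages = bundle.participants["age"]
    _, ev = train_candidate(
        bundle.gm[20], ages, ModelCandidate("ridge", 20), CVSpec(3, 2, 3, 0.2, 0),
        nested_breakdown=True,
    )
    assert len(ev.fold_metrics) == 6  # 3 folds x 2 repeats
    assert (ev.fold_metrics["mae"] >= 0).all()
    assert ev.fold_metrics["r_pooled_repeat"].nunique() == 2


class TestSelectBestModel:
    @staticmethod
    def _ev(mae, r=0.5):
        return ModelEvaluation(r=r, mae=mae, fold_metrics=pd.DataFrame(), n_holdout=10, best_params={})

    def test_single_candidate_selected(self):
        cand = ModelCandidate("ridge", 10)
        assert select_best_model([(cand, self._ev(4.0))]) is cand

    def test_argmin_mae(self):
        a, b = ModelCandidate("ridge", 10), ModelCandidate("svr", 10)
        assert select_best_model([(a, self._ev(4.2)), (b, self._ev(3.9))]) is b

    def test_tie_breaks_by_r_then_name(self):
        a, b = ModelCandidate("ridge", 10), ModelCandidate("svr", 10)
        assert select_best_model([(a, self._ev(4.0, 0.5)), (b, self._ev(4.0, 0.6))]) is b
        c, d = ModelCandidate("linear", 10), ModelCandidate("ridge", 10)
        assert select_best_model([(d, self._ev(4.0, 0.5)), (c, self._ev(4.0, 0.5))]) is c

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            select_best_model([])

    def test_planted_granularity_selected_across_seeds(self):
        """When one granularity carries all age signal, selection finds it."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            idx = pd.Index([f"P{i}" for i in range(n)], name="participant_id")
            ages = pd.Series(rng.uniform(44, 82, n), index=idx)
            signal = pd.DataFrame(
                np.outer(ages, rng.normal(1, 0.2, 10)) + rng.normal(0, 2, (n, 10)),
                index=idx,
            )
            noise = pd.DataFrame(rng.normal(size=(n, 5)), index=idx)
            evs = []
            for gran, feats in [(10, signal), (5, noise)]:
                _, ev = train_candidate(
                    feats, ages, ModelCandidate("ridge", gran),
                    CVSpec(3, 1, 3, 0.2, seed), nested_breakdown=False,
                )
                evs.append((ModelCandidate("ridge", gran), ev))
            if select_best_model(evs).granularity == 10:
                hits += 1
        assert hits >= 9


class TestPredictAge:
    def test_schema_mismatch_raises(self, noiseless_cohort):
        bundle = noiseless_cohort
        ages = bundle.participants["age"]
        model, _ = train_candidate(
            bundle.gm[20], ages, ModelCandidate("linear", 20), CVSpec(3, 1, 3, 0.2, 0),
            nested_breakdown=False,
        )
        with pytest.raises(SchemaError):
            predict_age(model, bundle.gm[20].iloc[:, :10])

    def test_constant_features_give_constant_predictions(self, noiseless_cohort):
        bundle = noiseless_cohort
        ages = bundle.participants["age"]
        model, _ = train_candidate(
            bundle.gm[20], ages, ModelCandidate("ridge", 20), CVSpec(3, 1, 3, 0.2, 0),
            nested_breakdown=False,
        )
        const = bundle.gm[20].iloc[:5].copy()
        const.loc[:, :] = bundle.gm[20].mean().to_numpy()
        pred = predict_age(model, const)
        assert np.ptp(pred) < 1e-8

    def test_degenerate_target_raises(self):
        idx = pd.Index([f"P{i}" for i in range(50)], name="participant_id")
        features = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)), index=idx)
        ages = pd.Series(60.0, index=idx)
        with pytest.raises(DegenerateModelError):
            train_candidate(features, ages, ModelCandidate("ridge", 3), CVSpec(3, 1, 3, 0.2, 0))
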