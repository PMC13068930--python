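"""Curation rules: uniqueness, validity, uninformative codes, durations,
availability filtering, subsets and the redundancy heatmap."""

import numpy as np
import pandas as pd
import pytest

from expobag import (
    CurationReport,
    VariableSpec,
    build_subsets,
    curate,
    derive_durations,
    drop_uninformative,
    enforce_uniqueness,
    filter_min_availability,
    redundancy_heatmap,
    validate_values,
    variable_specs,
)
from expobag.errors import SchemaError


def _table(values, columns, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i}" for i in range(len(values))]
    return pd.DataFrame(values, columns=columns, index=pd.Index(ids, name="participant_id"))


class TestEnforceUniqueness:
    def test_no_duplicates_is_identity(self):
        t = _table([[1.0], [2.0]], ["a"])
        out = enforce_uniqueness(t)
        pd.testing.assert_frame_equal(out, t)

    def test_exact_duplicate_removed_and_counted(self):
        t = _table([[1.0], [1.0], [2.0]], ["a"], ids=["P0", "P0", "P1"])
        report = CurationReport()
        out = enforce_uniqueness(t, report)
        assert len(out) == 2
        assert report.duplicates_removed == 1
        assert report.duplicate_conflicts == []

    def test_conflicting_duplicate_keeps_first_and_logs(self):
        t = _table([[1.0], [9.0]], ["a"], ids=["P0", "P0"])
        report = CurationReport()
        out = enforce_uniqueness(t, report)
        assert out.loc["P0", "a"] == 1.0
        assert report.duplicate_conflicts == [
            {"participant_id": "P0", "variable": "a", "kept": 1.0, "discarded": 9.0}
        ]


class TestValidateValues:
    specs = [
        VariableSpec("cont", valid_range=(0.0, 10.0)),
        VariableSpec("cat", dtype="categorical", valid_categories=(1.0, 2.0, 3.0),
                     uninformative_codes=(-1.0,)),
    ]

    def test_in_range_untouched_invalid_category_nulled(self):
        t = _table([[5.0, 1.0], [5.0, 7.0]], ["cont", "cat"])
        report = CurationReport()
        out = validate_values(t, self.specs, report)
        assert out.loc["P0", "cat"] == 1.0
        assert np.isnan(out.loc["P1", "cat"])
        assert report.aberrant_nulled == {"cont": 0, "cat": 1}

    def test_uninformative_codes_left_for_next_step(self):
        t = _table([[5.0, -1.0]], ["cont", "cat"])
        out = validate_values(t, self.specs)
        assert out.loc["P0", "cat"] == -1.0

    def test_planted_aberrant_cells_counted_exactly(self):
        rng = np.random.default_rng(0)
        t = _table(rng.uniform(1, 9, size=(30, 2)), ["cont", "cat"])
        t["cat"] = rng.choice([1.0, 2.0, 3.0], size=30)
        bad_rows = [1, 4, 7, 11, 15]
        t.iloc[bad_rows, 0] = 99.0
        t.iloc[[2, 9], 1] = 8.0
        report = CurationReport()
        validate_values(t, self.specs, report)
        assert report.aberrant_nulled == {"cont": 5, "cat": 2}

    def test_missing_spec_raises(self):
        t = _table([[1.0]], ["unknown"])
        with pytest.raises(SchemaError):
            validate_values(t, self.specs)


class TestDropUninformative:
    def test_coded_cells_nulled_others_untouched(self):
        specs = [
            VariableSpec("a", dtype="ordinal", valid_categories=(0.0, 1.0, 2.0),
                         uninformative_codes=(-1.0, -3.0)),
            VariableSpec("b", valid_range=(0.0, 5.0)),
        ]
        t = _table([[-1.0, 1.0], [2.0, -1.0], [-3.0, 3.0]], ["a", "b"])
        report = CurationReport()
        out = drop_uninformative(t, specs, report)
        assert np.isnan(out.loc["P0", "a"]) and np.isnan(out.loc["P2", "a"])
        # b has no uninformative codes: its -1 is left (to be caught as aberrant)
        assert out.loc["P1", "b"] == -1.0
        assert report.uninformative_nulled == {"a": 2, "b": 0}


class TestDeriveDurations:
    participants = pd.DataFrame(
        {"age": [60.0, 60.0, 60.0]},
        index=pd.Index(["P0", "P1", "P2"], name="participant_id"),
    )
    specs = [VariableSpec("onset", valid_range=(0.0, 120.0), is_onset_age=True)]

    def test_duration_is_assessment_minus_onset(self):
        t = _table([[50.0], [np.nan], [65.0]], ["onset"])
        report = CurationReport()
        out = derive_durations(t, self.participants, self.specs, report)
        assert out.loc["P0", "onset_duration"] == 10.0
        assert np.isnan(out.loc["P1", "onset_duration"])  # missing onset
        assert np.isnan(out.loc["P2", "onset_duration"])  # onset after assessment
        assert report.duration_inconsistencies == {"onset_duration": 1}
        assert report.durations_derived == {"onset_duration": 1}

    def test_missing_assessment_age_raises(self):
        t = _table([[50.0]], ["onset"])
        with pytest.raises(SchemaError):
            derive_durations(t, pd.DataFrame(index=self.participants.index), self.specs)


class TestFilterMinAvailability:
    def test_boundary_inclusive_at_n_min(self):
        n = 2001
        rng = np.random.default_rng(1)
        t = _table(rng.normal(size=(n, 3)), ["a1999", "a2000", "a2001"])
        t.iloc[:2, 0] = np.nan   # 1999 observed
        t.iloc[:1, 1] = np.nan   # 2000 observed
        participants = pd.DataFrame(
            {"sex": rng.binomial(1, 0.5, n)}, index=t.index
        )
        out, report = filter_min_availability(t, participants, n_min=2000)
        assert list(out.columns) == ["a2000", "a2001"]
        assert "a1999" in report.dropped

    def test_single_sex_variable_dropped(self):
        t = _table(np.ones((10, 2)), ["both", "fem_only"])
        participants = pd.DataFrame({"sex": [0] * 5 + [1] * 5}, index=t.index)
        t.loc[participants["sex"] == 1, "fem_only"] = np.nan
        out, report = filter_min_availability(t, participants, n_min=3)
        assert list(out.columns) == ["both"]
        assert report.dropped["fem_only"] == "observed in a single sex only"


class TestBuildSubsets:
    def test_empty_variable_list_gives_all_participants(self):
        t = _table([[1.0, np.nan], [2.0, 3.0]], ["a", "b"])
        subsets = build_subsets(t, {"all": []})
        assert list(subsets["all"]) == list(t.index)

    def test_nested_sets_give_reverse_nested_participants(self):
        rng = np.random.default_rng(2)
        t = _table(rng.normal(size=(50, 3)), ["a", "b", "c"])
        t.iloc[rng.choice(50, 10, replace=False), 1] = np.nan
        t.iloc[rng.choice(50, 10, replace=False), 2] = np.nan
        subsets = build_subsets(t, {"A": ["a"], "B": ["a", "b"], "C": ["a", "b", "c"]})
        assert set(subsets["C"]) <= set(subsets["B"]) <= set(subsets["A"])

    def test_unknown_variable_raises(self):
        t = _table([[1.0]], ["a"])
        with pytest.raises(SchemaError):
            build_subsets(t, {"bad": ["ghost"]})

    def test_subset_sizes_match_simulated_block_arithmetic(self, small_cohort):
        bundle, config, effects = small_cohort
        (names, _), = config.missingness_blocks
        table = bundle.exposome
        subsets = build_subsets(
            table, {"main": list(table.columns),
                    "no_block": [c for c in table.columns if c not in names]}
        )
        expected_main = int(table.notna().all(axis=1).sum())
        assert len(subsets["main"]) == expected_main
        assert len(subsets["no_block"]) >= expected_main


class TestRedundancyHeatmap:
    def test_duplicated_column_perfectly_correlated(self):
        rng = np.random.default_rng(3)
        t = _table(rng.normal(size=(100, 1)), ["a"])
        t["b"] = t["a"]
        corr = redundancy_heatmap(t)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        t = _table(rng.normal(size=(5000, 6)), list("abcdef"))
        corr = redundancy_heatmap(t)
        off = corr.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_symmetric_with_unit_diagonal_and_nan_for_constant(self):
        t = _table([[1.0, 2.0, 5.0], [1.0, 3.0, 6.0], [1.0, 4.0, 8.0]], ["const", "a", "b"])
        corr = redundancy_heatmap(t)
        assert corr.equals(corr.T)
        assert np.isnan(corr.loc["const", "a"])
        assert corr.loc["a", "a"] == 1.0


class TestFullChain:
    def test_idempotent_and_non_imputing(self, small_cohort):
        bundle, _, effects = small_cohort
        specs = variable_specs(effects)
        n_min = 50
        once, report1, specs_out = curate(
            bundle.exposome, specs, bundle.participants, n_min
        )
        twice, report2, _ = curate(once, specs_out, bundle.participants, n_min)
        pd.testing.assert_frame_equal(once, twice)
        # no imputation: observed cells never increase for original columns
        shared = [c for c in once.columns if c in bundle.exposome.columns]
        assert (
            once[shared].notna().sum() <= bundle.exposome[shared].notna().sum()
        ).all()

    def test_report_counts_reconcile_with_cell_diffs(self, small_cohort):
        bundle, _, effects = small_cohort
        specs = variable_specs(effects)
        report = CurationReport()
        t0 = enforce_uniqueness(bundle.exposome, report)
        t1 = drop_uninformative(t0, specs, report)
        assert sum(report.uninformative_nulled.values()) == int(
            (t0.notna() & t1.isna()).sum().sum()
        )
        t2 = validate_values(t1, specs, report)
        assert sum(report.aberrant_nulled.values()) == int(
            (t1.notna() & t2.isna()).sum().sum()
        )
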