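"""Exposome variable curation and analysis-subset construction.

The curation chain applies, in order: participant uniqueness, uninformative
response-code exclusion ("do not know" / "prefer not to answer" style codes),
aberrant-value exclusion (out-of-range numbers, invalid category codes),
duration derivation for medical-onset variables, and a minimum-availability
filter (variables observed in too few participants, or in one sex only, are
dropped).  No step ever imputes a value: the count of non-missing cells is
non-increasing through the chain, except for the newly derived duration
columns.  Every removal is tallied in a :class:`CurationReport`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from expobag.errors import SchemaError

DOMAINS = (
    "biomedical",
    "lifestyle",
    "socio-affective/mental",
    "early-life",
    "environmental",
    "socio-economic",
)


@dataclass(frozen=True)
class VariableSpec:
    """Validation metadata for one exposome variable."""

    name: str
    dtype: str = "continuous"  # continuous | ordinal | categorical | binary
    domain: str = "biomedical"
    valid_range: tuple | None = None
    valid_categories: tuple | None = None
    uninformative_codes: tuple = ()
    is_onset_age: bool = False

    def __post_init__(self):
        if self.dtype == "continuous" and self.valid_range is None:
            raise SchemaError(f"{self.name!r}: continuous variable needs a valid_range")
        if self.dtype in ("ordinal", "categorical", "binary") and self.valid_categories is None:
            raise SchemaError(f"{self.name!r}: {self.dtype} variable needs valid_categories")


@dataclass
class CurationReport:
    """Audit trail: per-variable counts for every curation rule applied."""

    duplicates_removed: int = 0
    duplicate_conflicts: list = field(default_factory=list)
    aberrant_nulled: dict = field(default_factory=dict)
    uninformative_nulled: dict = field(default_factory=dict)
    durations_derived: dict = field(default_factory=dict)
    duration_inconsistencies: dict = field(default_factory=dict)
    availability: dict = field(default_factory=dict)
    dropped: dict = field(default_factory=dict)  # variable -> reason
    retained: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _spec_map(specs) -> dict:
    return {s.name: s for s in specs}


def enforce_uniqueness(table: pd.DataFrame, report: CurationReport | None = None) -> pd.DataFrame:
    """Keep the first record per participant; log conflicting duplicates.

    Duplicate participant rows are removed keeping the first occurrence.  A
    duplicate whose values differ from the kept row in any cell is recorded
    as a conflict (the first value still wins).
    """
    if table.index.name is None:
        raise SchemaError("exposome table must be indexed by participant id")
    report = report if report is not None else CurationReport()
    dup_mask = table.index.duplicated(keep="first")
    if dup_mask.any():
        first = table[~table.index.duplicated(keep="first")]
        for pid in table.index[dup_mask].unique():
            kept = first.loc[pid]
            for _, row in table.loc[[pid]].iloc[1:].iterrows():
                neq = ~((row == kept) | (row.isna() & kept.isna()))
                for var in row.index[neq]:
                    report.duplicate_conflicts.append(
                        {"participant_id": str(pid), "variable": var,
                         "kept": _scalar(kept[var]), "discarded": _scalar(row[var])}
                    )
        report.duplicates_removed += int(dup_mask.sum())
        table = first
    return table


def _scalar(v):
    return None if pd.isna(v) else float(v)


def validate_values(
    table: pd.DataFrame, specs, report: CurationReport | None = None
) -> pd.DataFrame:
    """Null out-of-range numbers and invalid category codes.

    Cells holding a value listed in the variable's ``uninformative_codes``
    are left for :func:`drop_uninformative` so the two tallies stay disjoint.
    """
    report = report if report is not None else CurationReport()
    smap = _spec_map(specs)
    missing = [c for c in table.columns if c not in smap]
    if missing:
        raise SchemaError(f"no VariableSpec for columns: {missing}")
    table = table.copy()
    for col in table.columns:
        spec = smap[col]
        x = table[col]
        if spec.valid_range is not None:
            lo, hi = spec.valid_range
            bad = x.notna() & ((x < lo) | (x > hi))
        else:
            bad = x.notna() & ~x.isin(spec.valid_categories)
        if spec.uninformative_codes:
            bad &= ~x.isin(spec.uninformative_codes)
        n_bad = int(bad.sum())
        if n_bad:
            table.loc[bad, col] = np.nan
        report.aberrant_nulled[col] = report.aberrant_nulled.get(col, 0) + n_bad
    return table


def drop_uninformative(
    table: pd.DataFrame, specs, report: CurationReport | None = None
) -> pd.DataFrame:
    """Null cells holding configured uninformative response codes."""
    report = report if report is not None else CurationReport()
    smap = _spec_map(specs)
    table = table.copy()
    for col in table.columns:
        spec = smap.get(col)
        if spec is None or not spec.uninformative_codes:
            report.uninformative_nulled.setdefault(col, 0)
            continue
        bad = table[col].isin(spec.uninformative_codes)
        n_bad = int(bad.sum())
        if n_bad:
            table.loc[bad, col] = np.nan
        report.uninformative_nulled[col] = report.uninformative_nulled.get(col, 0) + n_bad
    return table


def derive_durations(
    table: pd.DataFrame,
    participants: pd.DataFrame,
    specs,
    report: CurationReport | None = None,
) -> pd.DataFrame:
    """Derive exposure durations from onset ages.

    For every spec flagged ``is_onset_age``, a ``<name>_duration`` column is
    added as assessment age minus onset age.  An onset after the assessment
    age is inconsistent: the duration is left missing and the case logged.
    The raw onset column is kept (it carries life-period information of its
    own, distinct from chronicity).
    """
    report = report if report is not None else CurationReport()
    if "age" not in participants.columns:
        raise SchemaError("participants table must provide assessment 'age'")
    table = table.copy()
    assessment = participants["age"].reindex(table.index)
    if assessment.isna().any():
        raise SchemaError("assessment age missing for some exposome participants")
    for spec in specs:
        if not spec.is_onset_age or spec.name not in table.columns:
            continue
        onset = table[spec.name]
        duration = assessment - onset
        inconsistent = duration.notna() & (duration < 0)
        duration[inconsistent] = np.nan
        new_col = f"{spec.name}_duration"
        table[new_col] = duration
        report.durations_derived[new_col] = int(duration.notna().sum())
        report.duration_inconsistencies[new_col] = int(inconsistent.sum())
    return table


def filter_min_availability(
    table: pd.DataFrame,
    participants: pd.DataFrame,
    n_min: int,
    require_both_sexes: bool = True,
    report: CurationReport | None = None,
):
    """Drop variables observed in fewer than ``n_min`` participants, or
    (optionally) observed in only one sex.  The bound is inclusive: a
    variable observed in exactly ``n_min`` participants of both sexes is
    retained."""
    if n_min < 1:
        raise SchemaError("n_min must be >= 1")
    report = report if report is not None else CurationReport()
    sex = participants["sex"].reindex(table.index) if require_both_sexes else None
    keep = []
    for col in table.columns:
        observed = table[col].notna()
        n_obs = int(observed.sum())
        report.availability[col] = n_obs
        if n_obs < n_min:
            report.dropped[col] = f"available in {n_obs} < {n_min} participants"
            continue
        if require_both_sexes and sex[observed].nunique() < 2:
            report.dropped[col] = "observed in a single sex only"
            continue
        keep.append(col)
    report.retained = keep
    return table[keep], report


def build_subsets(table: pd.DataFrame, variable_sets: dict) -> dict:
    """Complete-case participant sets for named variable lists.

    For each name, returns the index of participants with no missing value on
    any listed variable.  An empty variable list yields all participants;
    nested variable sets yield reverse-nested participant sets.
    """
    out = {}
    for name, cols in variable_sets.items():
        unknown = [c for c in cols if c not in table.columns]
        if unknown:
            raise SchemaError(f"subset {name!r}: unknown variables {unknown}")
        if not cols:
            out[name] = table.index
        else:
            out[name] = table.index[table[list(cols)].notna().all(axis=1)]
    return out


def redundancy_heatmap(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations on pairwise-complete observations.

    Symmetric with unit diagonal; zero-variance variables produce NaN rows
    and columns (diagonal kept at 1 where defined).
    """
    if table.shape[1] < 2:
        raise SchemaError("need at least 2 variables for a redundancy heatmap")
    corr = table.corr(min_periods=2)
    return corr


def curate(
    table: pd.DataFrame,
    specs,
    participants: pd.DataFrame,
    n_min: int,
    require_both_sexes: bool = True,
):
    """Run the full curation chain; returns (curated table, report).

    The chain is idempotent: re-running it on its own output (with duration
    specs added for the derived columns) changes nothing.
    """
    report = CurationReport()
    table = enforce_uniqueness(table, report)
    table = drop_uninformative(table, specs, report)
    table = validate_values(table, specs, report)
    table = derive_durations(table, participants, specs, report)
    # derived duration columns get permissive range specs for the filter step
    all_specs = list(specs) + [
        VariableSpec(c, dtype="continuous", valid_range=(0.0, 130.0), domain=_spec_map(specs)[c[: -len("_duration")]].domain)
        for c in table.columns
        if c.endswith("_duration") and c not in _spec_map(specs)
    ]
    table, report = filter_min_availability(
        table, participants, n_min, require_both_sexes, report
    )
    return table, report, all_specs
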