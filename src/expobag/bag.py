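"""Age-bias correction and the Brain Age Gap (BAG).

Brain-age predictions regress toward the training mean, producing a spurious
negative correlation between the raw gap and age.  The standard correction
fits, on the training set only, an ordinary least-squares line of predicted
age on chronological age and then adjusts every prediction by subtracting
the intercept and dividing by the slope.  On the fitting set this makes the
mean BAG exactly zero and BAG exactly uncorrelated with age (both are
algebraic consequences of OLS residual orthogonality, since
``BAG = (residual) / slope``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from expobag.errors import DegenerateModelError

SLOPE_TOL = 1e-6


@dataclass(frozen=True)
class BiasCorrectionParams:
    """Slope/intercept of predicted age regressed on chronological age."""

    slope: float
    intercept: float
    source: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"slope": self.slope, "intercept": self.intercept, "source": self.source}, fh)

    @classmethod
    def from_json(cls, path) -> "BiasCorrectionParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_bias_correction(
    predicted, chronological, source: str = ""
) -> BiasCorrectionParams:
    """OLS of predicted age on chronological age (training data only).

    Raises :class:`DegenerateModelError` if the slope magnitude falls below
    ``1e-6`` — a prediction that carries no age signal cannot be corrected.
    """
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.shape != chronological.shape or predicted.ndim != 1:
        raise ValueError("predicted and chronological must be equal-length vectors")
    if len(predicted) < 3:
        raise ValueError("need at least 3 observations to fit the correction")
    if np.std(chronological) == 0:
        raise DegenerateModelError("chronological age has zero variance")
    fit = stats.linregress(chronological, predicted)
    if abs(fit.slope) < SLOPE_TOL:
        raise DegenerateModelError(
            f"bias-correction slope {fit.slope:.2e} below tolerance {SLOPE_TOL:g}; "
            "prediction carries no age signal"
        )
    return BiasCorrectionParams(slope=float(fit.slope), intercept=float(fit.intercept), source=source)


def apply_correction(predicted, params: BiasCorrectionParams) -> np.ndarray:
    """adjusted = (predicted - intercept) / slope."""
    if abs(params.slope) < SLOPE_TOL:
        raise DegenerateModelError("bias-correction slope below tolerance")
    return (np.asarray(predicted, dtype=float) - params.intercept) / params.slope


def compute_bag(
    adjusted,
    chronological,
    ids=None,
    raw_predicted=None,
) -> pd.DataFrame:
    """Row-wise BAG table: adjusted predicted age minus chronological age.

    Positive BAG marks an older-appearing brain, negative a younger one.
    Summary statistics (mean, sd, 5th/95th percentiles) are attached under
    ``table.attrs["summary"]``.
    """
    adjusted = np.asarray(adjusted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if adjusted.shape != chronological.shape:
        raise ValueError("adjusted and chronological must have equal length")
    bag = adjusted - chronological
    if not np.all(np.isfinite(bag)):
        raise ValueError("BAG contains non-finite values")
    index = pd.Index(ids, name="participant_id") if ids is not None else pd.RangeIndex(len(bag))
    table = pd.DataFrame(
        {
            "age": chronological,
            "predicted_age": np.asarray(raw_predicted, dtype=float)
            if raw_predicted is not None
            else np.full(len(bag), np.nan),
            "adjusted_age": adjusted,
            "bag": bag,
        },
        index=index,
    )
    table.attrs["summary"] = {
        "mean": float(bag.mean()),
        "sd": float(bag.std(ddof=1)) if len(bag) > 1 else 0.0,
        "p5": float(np.percentile(bag, 5)),
        "p95": float(np.percentile(bag, 95)),
        "n": int(len(bag)),
    }
    return table
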