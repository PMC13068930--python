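import numpy as np
import pandas as pd
import pytest

from expobag import (
    CohortConfig,
    Distribution,
    EffectSpec,
    default_effects,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared by read-only tests (n=500, 30 variables)."""
    effects = default_effects(n_null=20)
    config = CohortConfig(
        n_participants=500,
        n_regions=40,
        granularity_levels=(40, 20),
        seed=42,
        missingness_blocks=((("bone_density",), 0.1),),
    )
    return generate_cohort(config, effects), config, effects


@pytest.fixture()
def clean_cohort():
    """Deterministic cohort: no planted effects, no noise anywhere."""
    effects = [
        EffectSpec(f"v{k}", "null", Distribution("normal", (0.0, 1.0)))
        for k in range(5)
    ]
    config = CohortConfig(
        n_participants=200,
        n_regions=10,
        granularity_levels=(10, 5),
        noise_sd_gm=0.0,
        deviation_noise_sd=0.0,
        scaling_sd=0.0,
        sex_offset_sd=0.0,
        height_coef_mean=0.0,
        height_coef_sd=0.0,
        aberrant_rate=0.0,
        frac_nonhealthy=0.0,
        seed=7,
    )
    return generate_cohort(config, effects), config, effects


def make_regression_frame(n, p, seed, index_prefix="P"):
    """Plain aligned (X, confounds) frames for prediction-stage tests."""
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"{index_prefix}{i:05d}" for i in range(n)], name="participant_id")
    X = pd.DataFrame(
        rng.normal(size=(n, p)), index=idx, columns=[f"x{j}" for j in range(p)]
    )
    confounds = pd.DataFrame(
        {
            "age": rng.uniform(44, 82, n),
            "sex": rng.binomial(1, 0.5, n).astype(float),
            "height": rng.normal(168, 8, n),
        },
        index=idx,
    )
    confounds["age_squared"] = confounds["age"] ** 2
    return X, confounds
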