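"""Synthetic aging-cohort generator with planted, exported ground truth.

The generator emulates the statistical structure the two-stage analysis
assumes: participants aged 44-82 whose regional grey-matter volumes decline
with an individual *effective brain age* (chronological age plus an aging
deviation ``d``), an exposome table whose variables shift ``d`` through
configurable linear, nonlinear, duration, moderator/interaction or null
effects, health-eligibility flags that preferentially mark large-|d|
participants as non-healthy, and block-structured missingness that yields
main/replication/variables-restricted style analysis subsets.

Every cohort is fully determined by a single integer seed, which is expanded
into independent per-component substreams (demographics, region parameters,
grey-matter noise, exposome draws, deviation noise, flags, missingness,
data-glitch injection) so each table is reproducible on its own.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from expobag.curation import VariableSpec
from expobag.errors import ConfigurationError

EFFECT_KINDS = ("null", "linear", "nonlinear", "duration", "moderator", "interaction")
DIST_FAMILIES = ("normal", "lognormal", "ordinal", "binary", "exposure_duration")

# substream labels, in spawn order, for the documented seed expansion
_SUBSTREAMS = (
    "demographics",
    "regions",
    "gm_noise",
    "exposome",
    "deviation_noise",
    "flags",
    "missingness",
    "glitches",
)


@dataclass(frozen=True)
class Distribution:
    """Sampling law for one exposome variable.

    families
    --------
    normal(mu, sigma)         continuous Gaussian
    lognormal(mu, sigma)      parameters of the underlying normal
    ordinal(n_levels[, probs]) integer levels 0..n_levels-1
    binary(p)                 Bernoulli 0/1
    exposure_duration(low, high)  uniform exposure duration in years; used by
                              duration-type effects.  The emitted column is
                              the onset age (assessment age minus duration),
                              so the analysis variable (duration) must be
                              derived downstream.  Durations are drawn
                              independently of age, keeping the aging
                              deviation age-orthogonal by construction.
    """

    family: str
    params: tuple = ()

    def __post_init__(self):
        if self.family not in DIST_FAMILIES:
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        object.__setattr__(self, "params", tuple(self.params))
        p = self.params
        try:
            if self.family in ("normal", "lognormal"):
                mu, sigma = p
                if sigma <= 0:
                    raise ValueError
            elif self.family == "ordinal":
                n_levels = int(p[0])
                if n_levels < 2:
                    raise ValueError
                if len(p) > 1:
                    probs = np.asarray(p[1], dtype=float)
                    if len(probs) != n_levels or probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
                        raise ValueError
            elif self.family == "binary":
                (prob,) = p
                if not 0.0 < prob < 1.0:
                    raise ValueError
            elif self.family == "exposure_duration":
                low, high = p
                if not 0 <= low < high:
                    raise ValueError
        except (ValueError, TypeError, IndexError):
            raise ConfigurationError(
                f"invalid parameters {self.params!r} for {self.family!r} distribution"
            ) from None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            mu, sigma = self.params
            return rng.normal(mu, sigma, size=n)
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size=n)
        if self.family == "ordinal":
            n_levels = int(self.params[0])
            probs = None
            if len(self.params) > 1:
                probs = np.asarray(self.params[1], dtype=float)
            return rng.choice(n_levels, size=n, p=probs).astype(float)
        if self.family == "binary":
            return rng.binomial(1, self.params[0], size=n).astype(float)
        # exposure_duration
        low, high = self.params
        return rng.uniform(low, high, size=n)


@dataclass(frozen=True)
class EffectSpec:
    """One exposome variable and its planted effect on the aging deviation.

    ``strength`` is the contribution to ``d`` in years per standard deviation
    of the (derived) exposure.  Moderator/interaction effects contribute
    ``strength * z(partner) * z(self)``; with both factors standardized the
    product has zero mean and zero covariance with either factor, so the
    moderator's population marginal correlation with ``d`` is zero by
    construction.
    """

    name: str
    kind: str
    distribution: Distribution
    strength: float = 0.0
    partner: str | None = None
    domain: str = "biomedical"
    uninformative_codes: tuple = ()
    uninformative_rate: float = 0.0

    def __post_init__(self):
        if self.kind not in EFFECT_KINDS:
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "null" and self.strength != 0.0:
            raise ConfigurationError(f"null effect {self.name!r} must have strength 0")
        if self.kind in ("moderator", "interaction") and not self.partner:
            raise ConfigurationError(f"{self.kind} effect {self.name!r} requires a partner")
        if self.kind not in ("moderator", "interaction") and self.partner:
            raise ConfigurationError(f"{self.kind} effect {self.name!r} must not name a partner")
        if self.kind == "duration" and self.distribution.family != "exposure_duration":
            raise ConfigurationError(
                f"duration effect {self.name!r} needs an exposure_duration distribution"
            )
        if self.uninformative_rate and not self.uninformative_codes:
            raise ConfigurationError(f"{self.name!r}: uninformative rate without codes")

    @property
    def analysis_column(self) -> str:
        """Name of the column carrying the effect after curation.

        Duration-type effects are emitted as onset ages; the derived duration
        column (``<name>_duration``) is the one that carries the planted
        signal.
        """
        return f"{self.name}_duration" if self.kind == "duration" else self.name


@dataclass(frozen=True)
class CohortConfig:
    """Desk-scale cohort defaults: 3000 participants, 100 fine regions."""

    n_participants: int = 3000
    age_range: tuple = (44.0, 82.0)
    n_regions: int = 100
    granularity_levels: tuple = (100, 50, 25)
    noise_sd_gm: float = 5.0
    aging_slope_sd: float = 0.2
    region_slope_mean: float = 0.5
    sex_offset_sd: float = 2.0
    height_coef_mean: float = 0.05
    height_coef_sd: float = 0.02
    scaling_sd: float = 0.03
    deviation_noise_sd: float = 2.0
    # most participants fail at least one strict health criterion, so the
    # healthy reference norm is the minority and the population set (where
    # the exposome analysis runs) is the majority, as in the reference cohort
    frac_nonhealthy: float = 0.7
    nonhealthy_tilt: float = 4.0
    aberrant_rate: float = 0.001
    aberrant_value: float = 9999.0
    missingness_blocks: tuple = ()  # ((variable names...), fraction) pairs
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigurationError("need at least 2 participants")
        low, high = self.age_range
        if not low < high:
            raise ConfigurationError("age_range low must be < high")
        for level in self.granularity_levels:
            if not 1 <= level <= self.n_regions:
                raise ConfigurationError(
                    f"granularity level {level} incompatible with {self.n_regions} regions"
                )
        if not 0.0 <= self.frac_nonhealthy < 1.0:
            raise ConfigurationError("frac_nonhealthy must be in [0, 1)")
        for block in self.missingness_blocks:
            names, frac = block
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"missingness fraction {frac} out of [0, 1]")
            if not names:
                raise ConfigurationError("empty variable set in missingness block")


@dataclass
class GroundTruth:
    """Planted truth exported with every simulated cohort."""

    deviations: pd.Series  # participant id -> aging deviation d (years)
    effects: list
    region_slopes: np.ndarray
    config: CohortConfig

    @property
    def effect_names(self) -> list:
        return [e.analysis_column for e in self.effects if e.kind != "null"]

    @property
    def null_names(self) -> list:
        return [e.name for e in self.effects if e.kind == "null"]

    @property
    def moderator_names(self) -> list:
        return [e.analysis_column for e in self.effects if e.kind == "moderator"]

    def to_dict(self) -> dict:
        return {
            "config": _config_to_dict(self.config),
            "effects": [_effect_to_dict(e) for e in self.effects],
            "deviations": {
                "participant_id": [str(i) for i in self.deviations.index],
                "d": [float(v) for v in self.deviations.to_numpy()],
            },
            "region_slopes": [float(s) for s in self.region_slopes],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GroundTruth":
        config = _config_from_dict(payload["config"])
        effects = [_effect_from_dict(e) for e in payload["effects"]]
        dev = pd.Series(
            payload["deviations"]["d"],
            index=pd.Index(payload["deviations"]["participant_id"], name="participant_id"),
            name="d",
        )
        return cls(
            deviations=dev,
            effects=effects,
            region_slopes=np.asarray(payload["region_slopes"], dtype=float),
            config=config,
        )


@dataclass
class CohortBundle:
    participants: pd.DataFrame
    gm: dict  # granularity level -> DataFrame (participants x regions)
    exposome: pd.DataFrame
    ground_truth: GroundTruth


def default_effects(n_null: int = 50, seed_names: bool = True) -> list:
    """The default planted-effect battery: 10 effect variables, ``n_null`` nulls.

    Strengths are in years of aging deviation per SD of exposure and span the
    effect kinds the analysis must recover, including one pure moderator
    (``hip_circumference``) whose marginal correlation with ``d`` is zero by
    construction.  Distributions loosely mimic the corresponding population
    measures (e.g. systolic blood pressure ~ N(140, 18) mmHg, hip
    circumference ~ N(102, 9) cm).
    """
    effects = [
        EffectSpec("systolic_bp", "linear", Distribution("normal", (140.0, 18.0)), 2.0),
        EffectSpec(
            "alcohol_intake", "linear", Distribution("lognormal", (1.0, 0.6)), 1.5,
            domain="lifestyle",
        ),
        EffectSpec(
            "smoking_onset", "duration", Distribution("exposure_duration", (5.0, 40.0)), 2.5,
            domain="lifestyle",
        ),
        EffectSpec(
            "hypertension_onset", "duration", Distribution("exposure_duration", (1.0, 14.0)), 2.5,
        ),
        EffectSpec(
            "coffee_intake", "nonlinear", Distribution("ordinal", (7,)), 1.5,
            domain="lifestyle",
        ),
        EffectSpec("hba1c", "linear", Distribution("normal", (36.0, 6.0)), 1.2),
        EffectSpec(
            "cereal_intake", "linear", Distribution("ordinal", (8,)), -1.2,
            domain="lifestyle",
        ),
        EffectSpec("bone_density", "linear", Distribution("normal", (0.55, 0.1)), -1.5),
        EffectSpec(
            "education_years", "linear", Distribution("ordinal", (6,)), -1.0,
            domain="socio-economic",
        ),
        EffectSpec(
            "hip_circumference", "moderator", Distribution("normal", (102.0, 9.0)), 4.0,
            partner="systolic_bp",
        ),
    ]
    domains = ("biomedical", "lifestyle", "socio-affective/mental", "early-life", "environmental")
    families = (
        Distribution("normal", (0.0, 1.0)),
        Distribution("lognormal", (0.0, 0.5)),
        Distribution("ordinal", (5,)),
        Distribution("binary", (0.3,)),
    )
    for k in range(n_null):
        dist = families[k % len(families)]
        kwargs = {}
        # a few ordinal nulls emit "do not know"/"prefer not to answer" codes
        if dist.family == "ordinal" and k % 8 == 2:
            kwargs = {"uninformative_codes": (-1.0, -3.0), "uninformative_rate": 0.015}
        effects.append(
            EffectSpec(
                f"null_{k:02d}", "null", dist, 0.0,
                domain=domains[k % len(domains)], **kwargs,
            )
        )
    return effects


def default_missingness(effects: list) -> tuple:
    """Blocks that mimic main/replication/variables-restricted subsets.

    Bone density is missing for 15% of participants (replication subset drops
    the variable instead of the participants); socio-affective variables are
    missing for 35% (the variables-restricted subset drops them).
    """
    socio = [e.name for e in effects if e.domain == "socio-affective/mental"][:5]
    blocks = []
    if any(e.name == "bone_density" for e in effects):
        blocks.append((("bone_density",), 0.15))
    if socio:
        blocks.append((tuple(socio), 0.35))
    return tuple(blocks)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_cohort(config: CohortConfig, effects: list) -> CohortBundle:
    """Simulate one cohort; fully deterministic given ``config.seed``."""
    names = [e.name for e in effects]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate variable names: {dupes}")
    name_set = set(names)
    for e in effects:
        if e.partner is not None and e.partner not in name_set:
            raise ConfigurationError(f"{e.name!r}: partner {e.partner!r} not in variable set")
    for block_names, _frac in config.missingness_blocks:
        unknown = set(block_names) - name_set
        if unknown:
            raise ConfigurationError(f"missingness block names not in variable set: {sorted(unknown)}")

    streams = dict(zip(_SUBSTREAMS, np.random.SeedSequence(config.seed).spawn(len(_SUBSTREAMS))))
    rng_demo = np.random.default_rng(streams["demographics"])
    rng_reg = np.random.default_rng(streams["regions"])
    rng_gm = np.random.default_rng(streams["gm_noise"])
    rng_expo = np.random.default_rng(streams["exposome"])
    rng_dev = np.random.default_rng(streams["deviation_noise"])
    rng_flags = np.random.default_rng(streams["flags"])
    rng_miss = np.random.default_rng(streams["missingness"])
    rng_glitch = np.random.default_rng(streams["glitches"])

    n = config.n_participants
    ids = pd.Index([f"P{i:06d}" for i in range(n)], name="participant_id")
    low, high = config.age_range
    age = rng_demo.uniform(low, high, size=n)
    sex = rng_demo.binomial(1, 0.5, size=n)  # 0 = female, 1 = male
    height = rng_demo.normal(163.0, 6.5, size=n) + 13.0 * sex
    scaling = rng_demo.normal(1.0, config.scaling_sd, size=n)

    # raw exposome draws (before glitch injection / missingness); duration
    # variables are sampled as durations and emitted as onset ages
    raw = {e.name: e.distribution.sample(n, rng_expo) for e in effects}
    for e in effects:
        if e.kind == "duration":
            raw[e.name] = np.maximum(age - raw[e.name], 0.5)  # onset age

    # planted aging deviation d
    contributions = {}
    for e in effects:
        if e.kind == "null":
            continue
        if e.kind == "linear":
            contributions[e.name] = e.strength * _zscore(raw[e.name])
        elif e.kind == "nonlinear":
            # standardized quadratic: U-shaped, ~zero linear association
            z = _zscore(raw[e.name])
            contributions[e.name] = e.strength * _zscore(z**2)
        elif e.kind == "duration":
            contributions[e.name] = e.strength * _zscore(age - raw[e.name])
        else:  # moderator / interaction
            contributions[e.name] = e.strength * _zscore(raw[e.name]) * _zscore(raw[e.partner])
    d = sum(contributions.values(), np.zeros(n)) + rng_dev.normal(
        0.0, config.deviation_noise_sd, size=n
    )
    effective_age = age + d

    # regional grey matter: intercept - slope * effective age + confound terms
    p = config.n_regions
    base = rng_reg.uniform(400.0, 600.0, size=p)
    slopes = np.clip(
        rng_reg.normal(config.region_slope_mean, config.aging_slope_sd, size=p), 0.05, None
    )
    sex_off = rng_reg.normal(0.0, config.sex_offset_sd, size=p)
    h_coef = rng_reg.normal(config.height_coef_mean, config.height_coef_sd, size=p)
    vol = (
        base[None, :]
        - np.outer(effective_age, slopes)
        + np.outer(sex, sex_off)
        + np.outer(height - 167.0, h_coef)
    ) * scaling[:, None] + rng_gm.normal(0.0, config.noise_sd_gm, size=(n, p))
    fine_cols = [f"gm_{j:04d}" for j in range(p)]
    gm_fine = pd.DataFrame(vol, index=ids, columns=fine_cols)

    gm = {}
    for level in sorted(set(config.granularity_levels), reverse=True):
        if level == p:
            gm[level] = gm_fine
            continue
        groups = np.array_split(np.arange(p), level)
        cols = {f"roi{level}_{g:04d}": vol[:, idx].mean(axis=1) for g, idx in enumerate(groups)}
        gm[level] = pd.DataFrame(cols, index=ids)

    # health-eligibility flags: exactly round(frac * n) flagged non-healthy,
    # preferentially in the top |d| quantile (rank-tilted sampling)
    flags = pd.DataFrame(
        0,
        index=ids,
        columns=["long_standing_illness", "diabetes", "stroke", "icd10_diagnosis"],
        dtype=int,
    )
    srh = rng_flags.choice([3, 4], size=n, p=[0.45, 0.55])  # good / excellent
    k = int(round(config.frac_nonhealthy * n))
    if k > 0:
        ranks = np.argsort(np.argsort(np.abs(d))) + 1  # 1 = smallest |d|
        w = (ranks / n) ** config.nonhealthy_tilt
        flagged = rng_flags.choice(n, size=k, replace=False, p=w / w.sum())
        primary = rng_flags.choice(5, size=k, p=[0.35, 0.2, 0.1, 0.2, 0.15])
        for row, which in zip(flagged, primary):
            if which < 4:
                flags.iloc[row, which] = 1
                srh[row] = rng_flags.choice([1, 2, 3, 4])
            else:
                srh[row] = rng_flags.choice([1, 2])
    flags["self_rated_health"] = srh  # 1 poor .. 4 excellent
    healthy = (
        (flags[["long_standing_illness", "diabetes", "stroke", "icd10_diagnosis"]].sum(axis=1) == 0)
        & (flags["self_rated_health"] >= 3)
    )

    participants = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "height": height,
            "volumetric_scaling": scaling,
        },
        index=ids,
    ).join(flags)
    participants["healthy"] = healthy.astype(int)

    exposome = pd.DataFrame(raw, index=ids, columns=names).astype(float)

    # data glitches: aberrant cells and uninformative response codes,
    # injected after d was computed (they model measurement/coding noise)
    if config.aberrant_rate > 0:
        for e in effects:
            if e.distribution.family == "exposure_duration":
                continue
            mask = rng_glitch.random(n) < config.aberrant_rate
            exposome.loc[mask, e.name] = config.aberrant_value
    for e in effects:
        if e.uninformative_rate > 0:
            mask = rng_glitch.random(n) < e.uninformative_rate
            codes = rng_glitch.choice(np.asarray(e.uninformative_codes, dtype=float), size=int(mask.sum()))
            exposome.loc[mask, e.name] = codes

    # blockwise missingness: same participants missing every variable in a block
    for block_names, frac in config.missingness_blocks:
        m = int(round(frac * n))
        if m == 0:
            continue
        rows = rng_miss.choice(n, size=m, replace=False)
        exposome.iloc[rows, [exposome.columns.get_loc(c) for c in block_names]] = np.nan

    truth = GroundTruth(
        deviations=pd.Series(d, index=ids, name="d"),
        effects=list(effects),
        region_slopes=slopes,
        config=config,
    )
    return CohortBundle(participants=participants, gm=gm, exposome=exposome, ground_truth=truth)


def variable_specs(effects: list) -> list:
    """Curation-ready variable specs matching the generated exposome table."""
    specs = []
    for e in effects:
        fam, p = e.distribution.family, e.distribution.params
        kwargs = dict(
            domain=e.domain,
            uninformative_codes=tuple(e.uninformative_codes),
        )
        if fam == "normal":
            mu, s = p
            spec = VariableSpec(e.name, dtype="continuous", valid_range=(mu - 8 * s, mu + 8 * s), **kwargs)
        elif fam == "lognormal":
            mu, s = p
            spec = VariableSpec(e.name, dtype="continuous", valid_range=(0.0, float(np.exp(mu + 8 * s))), **kwargs)
        elif fam == "ordinal":
            spec = VariableSpec(e.name, dtype="ordinal", valid_categories=tuple(float(v) for v in range(int(p[0]))), **kwargs)
        elif fam == "binary":
            spec = VariableSpec(e.name, dtype="binary", valid_categories=(0.0, 1.0), **kwargs)
        else:  # exposure_duration -> emitted as onset age
            spec = VariableSpec(e.name, dtype="continuous", valid_range=(0.0, 120.0), is_onset_age=True, **kwargs)
        specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# serialization

def _config_to_dict(config: CohortConfig) -> dict:
    out = dataclasses.asdict(config)
    out["age_range"] = list(config.age_range)
    out["granularity_levels"] = list(config.granularity_levels)
    out["missingness_blocks"] = [[list(ns), f] for ns, f in config.missingness_blocks]
    return out


def _config_from_dict(payload: dict) -> CohortConfig:
    payload = dict(payload)
    payload["age_range"] = tuple(payload["age_range"])
    payload["granularity_levels"] = tuple(payload["granularity_levels"])
    payload["missingness_blocks"] = tuple(
        (tuple(ns), f) for ns, f in payload["missingness_blocks"]
    )
    return CohortConfig(**payload)


def _effect_to_dict(e: EffectSpec) -> dict:
    return {
        "name": e.name,
        "kind": e.kind,
        "strength": e.strength,
        "partner": e.partner,
        "domain": e.domain,
        "distribution": {"family": e.distribution.family, "params": _jsonable(e.distribution.params)},
        "uninformative_codes": list(e.uninformative_codes),
        "uninformative_rate": e.uninformative_rate,
    }


def _jsonable(params):
    return [list(p) if isinstance(p, (tuple, list, np.ndarray)) else p for p in params]


def _effect_from_dict(payload: dict) -> EffectSpec:
    params = tuple(
        tuple(p) if isinstance(p, list) else p for p in payload["distribution"]["params"]
    )
    return EffectSpec(
        name=payload["name"],
        kind=payload["kind"],
        distribution=Distribution(payload["distribution"]["family"], params),
        strength=payload["strength"],
        partner=payload["partner"],
        domain=payload["domain"],
        uninformative_codes=tuple(payload["uninformative_codes"]),
        uninformative_rate=payload["uninformative_rate"],
    )


def write_cohort(bundle: CohortBundle, directory) -> list:
    """Write a cohort as CSV tables plus a JSON ground-truth/metadata file.

    Returns the list of written paths.  Files round-trip losslessly through
    :func:`read_cohort` (floats serialized at full repr precision; missing
    cells as empty fields).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str):
        path = directory / name
        df.to_csv(path)
        written.append(path)

    _write(bundle.participants, "participants.csv")
    for level, gm in sorted(bundle.gm.items()):
        _write(gm, f"gm_{level}.csv")
    _write(bundle.exposome, "exposome.csv")
    gt_path = directory / "ground_truth.json"
    gt_path.write_text(json.dumps(bundle.ground_truth.to_dict(), indent=1))
    written.append(gt_path)
    return written


def read_cohort(directory) -> CohortBundle:
    directory = Path(directory)
    truth = GroundTruth.from_dict(json.loads((directory / "ground_truth.json").read_text()))
    participants = pd.read_csv(directory / "participants.csv", index_col="participant_id")
    exposome = pd.read_csv(directory / "exposome.csv", index_col="participant_id")
    gm = {}
    for level in sorted(set(truth.config.granularity_levels)):
        gm[level] = pd.read_csv(directory / f"gm_{level}.csv", index_col="participant_id")
    return CohortBundle(participants=participants, gm=gm, exposome=exposome, ground_truth=truth)
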