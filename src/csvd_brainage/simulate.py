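"""Synthetic cohort generation with known ground truth.

The simulator emulates the post-imaging data layout of a two-cohort
brain-age study:

* a healthy *training* cohort (ages 18–92) whose voxel-level grey-matter
  volume (GMV) declines with age region by region, used to fit brain-age
  models;
* an older *application* cohort (ages >= 50) with covariates, CSVD markers
  (WMH volume, TIV, lacunes, microbleeds), cognitive scores, and — in
  subjects who satisfy the CSVD marker rule — an extra-aging offset planted
  in designated regions.

CSVD status is not stored as a label: a latent severity variable couples
the marker distributions, the marker rule is applied to the generated
markers, and subjects it flags receive GMV evaluated at an *effective age*
``age + delta`` in the affected regions.  Downstream classification with
the same rule therefore reconstructs the planted groups, exercising the
classifier rather than bypassing it.

Per-subject extra aging is ``delta_r * L_i`` with ``L_i`` a Gamma-distributed
severity multiplier with mean 1, so extra aging varies within the CSVD
group (this within-group variance is what identifies the mediator path b
downstream).  Cognitive scores are linear in covariates, in true per-region
extra aging (coefficients ``b``) and in CSVD status (direct effect ``c'``),
plus Gaussian noise.  Every generated cohort is accompanied by a
:class:`GroundTruth` record sufficient to compute the true indirect effect
``a*b`` and the true proportion mediated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasSpec
from .csvd import classify_csvd, wmh_ratio
from .features import FeatureSet

__all__ = [
    "MarkerModel",
    "OutcomeModel",
    "SimulationConfig",
    "GroundTruth",
    "generate_training_cohort",
    "generate_application_cohort",
]


@dataclass
class MarkerModel:
    """CSVD marker generative model, age- and severity-linked.

    WMH volume (ml) is lognormal: ``log wmh = loc + age_coef*(age-65)
    + sev_coef*s + scale*eps`` with ``s ~ N(0,1)`` the latent severity.
    Lacune and CMB counts are Poisson with log-rates linear in the same
    age term and severity.  TIV is Gaussian in litres.  Defaults put the
    WMH/TIV population median near 0.7e-3 and the CSVD-rule prevalence
    near one sixth in a >= 50 y cohort.
    """

    wmh_log_loc: float = -0.10  # log ml at age 65, severity 0
    wmh_log_scale: float = 0.55
    wmh_age_coef: float = 0.035  # per year
    wmh_sev_coef: float = 0.65
    lacune_log_rate: float = -1.9
    lacune_age_coef: float = 0.03
    lacune_sev_coef: float = 1.1
    cmb_log_rate: float = -2.1
    cmb_age_coef: float = 0.03
    cmb_sev_coef: float = 1.1
    tiv_mean_l: float = 1.31
    tiv_sd_l: float = 0.12


@dataclass
class OutcomeModel:
    """Generative model for one cognitive score.

    ``b_per_region`` maps region_id -> change in the score per year of true
    extra aging in that region (the planted mediator path b).
    ``direct_effect`` is the CSVD effect not routed through any mediator
    (path c').  Covariate coefficients define the confounded background.
    """

    intercept: float = 27.0
    b_per_region: dict[str, float] = field(default_factory=dict)
    direct_effect: float = 0.0
    age_coef: float = -0.06  # per year
    sex_coef: float = 0.2
    education_coef: float = 0.18  # per year of schooling
    efc_coef: float = 0.0
    tiv_coef: float = 0.0
    noise_sd: float = 2.0


def _default_outcomes() -> dict[str, OutcomeModel]:
    return {
        "mmse": OutcomeModel(intercept=27.0, noise_sd=2.0),
        "cvvlt": OutcomeModel(intercept=7.0, age_coef=-0.04, education_coef=0.08,
                              noise_sd=1.8),
        "vft": OutcomeModel(intercept=15.0, age_coef=-0.05, education_coef=0.15,
                            noise_sd=3.5),
        "cdt": OutcomeModel(intercept=8.0, age_coef=-0.03, education_coef=0.10,
                            noise_sd=2.0),
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic two-cohort study.

    Defaults mirror the cohort structure the analysis assumes: 1482
    training subjects aged 18–92 and 734 application subjects aged >= 50,
    risk-factor prevalences in the range reported for community-dwelling
    older cohorts, TIV near 1.31 l, and a WMH/TIV median near 0.7e-3.
    """

    n_train: int = 1482
    n_app: int = 734
    train_age_range: tuple[float, float] = (18.0, 92.0)
    app_age_range: tuple[float, float] = (50.0, 92.0)

    # regional GMV model (arbitrary volume units per voxel)
    baseline_mean: float = 550.0
    baseline_sd: float = 40.0  # spread of region baselines
    voxel_offset_sd: float = 10.0  # spread of voxel baselines within a region
    slope_range: tuple[float, float] = (0.8, 2.5)  # units lost per year
    quadratic_coef: float = 0.0  # optional units/year^2 (same for all regions)
    noise_sd: float = 25.0  # sigma_g

    # planted CSVD effect
    affected_regions: tuple[str, ...] = ()
    delta_years: float | dict[str, float] = 5.0
    severity_gamma_shape: float = 4.0  # multiplier L ~ Gamma(k, 1/k), mean 1

    # covariates
    hypertension_prev: float = 0.33
    diabetes_prev: float = 0.14
    dyslipidemia_prev: float = 0.06
    smoking_prev: float = 0.15
    risk_sev_coef: float = 0.45  # logit shift per unit latent severity
    education_mean: float = 7.0
    education_sd: float = 5.0
    efc_mean: float = 0.545
    efc_sd: float = 0.023

    marker: MarkerModel = field(default_factory=MarkerModel)
    outcomes: dict[str, OutcomeModel] = field(default_factory=_default_outcomes)
    percentile: float = 50.0  # WMH split used when planting CSVD status

    seed: int = 0
    # Optional separate seed for subject-level draws.  Region baselines and
    # slopes always derive from ``seed``, so two configs sharing ``seed``
    # but differing in ``cohort_seed`` describe fresh cohorts measured with
    # the same regional GMV model (replicate designs).
    cohort_seed: int | None = None

    # ------------------------------------------------------------ validate
    def validate(self, atlas: AtlasSpec | None = None) -> None:
        for nm in ("n_train", "n_app"):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be >= 1, got {getattr(self, nm)}")
        for nm in ("train_age_range", "app_age_range"):
            lo, hi = getattr(self, nm)
            if not lo < hi:
                raise ValueError(f"{nm} must be non-degenerate, got ({lo}, {hi})")
        for nm in ("noise_sd", "baseline_sd", "voxel_offset_sd",
                   "education_sd", "efc_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0, got {getattr(self, nm)}")
        if self.marker.tiv_sd_l <= 0 or self.marker.wmh_log_scale <= 0:
            raise ValueError("marker: tiv_sd_l and wmh_log_scale must be > 0")
        for nm, out in self.outcomes.items():
            if out.noise_sd <= 0:
                raise ValueError(f"outcomes[{nm!r}].noise_sd must be > 0")
        deltas = self.delta_map()
        for rid, d in deltas.items():
            if d < 0:
                raise ValueError(f"delta_years must be >= 0, got {d} for {rid!r}")
        if self.severity_gamma_shape <= 0:
            raise ValueError("severity_gamma_shape must be > 0")
        for nm in ("hypertension_prev", "diabetes_prev", "dyslipidemia_prev",
                   "smoking_prev"):
            p = getattr(self, nm)
            if not 0 <= p <= 1:
                raise ValueError(f"{nm} must be in [0, 1], got {p}")
        if atlas is not None:
            unknown = [r for r in self.affected_regions
                       if r not in set(atlas.region_ids)]
            if unknown:
                raise ValueError(
                    f"affected_regions not in atlas: {unknown}"
                )
            for rid, out in [(rid, nm) for nm, o in self.outcomes.items()
                             for rid in o.b_per_region]:
                if rid not in set(atlas.region_ids):
                    raise ValueError(
                        f"outcomes[{out!r}].b_per_region references unknown "
                        f"region {rid!r}"
                    )

    def delta_map(self) -> dict[str, float]:
        """Extra-aging years per affected region."""
        if isinstance(self.delta_years, dict):
            return dict(self.delta_years)
        return {r: float(self.delta_years) for r in self.affected_regions}


@dataclass
class GroundTruth:
    """Planted parameters of one generated application cohort.

    ``extra_aging`` has one row per subject and one column per affected
    region; the true mediator group difference for region r is
    ``delta[r]`` (the severity multiplier has mean 1), the true indirect
    effect for (outcome, region) is ``delta[r] * b``, and the true total
    effect adds the direct effect and all other planted region paths.
    """

    csvd_flag: pd.Series
    wmh_threshold: float
    delta: dict[str, float]
    severity_multiplier: pd.Series  # L_i (1.0 where not CSVD-flagged)
    extra_aging: pd.DataFrame
    b_per_outcome: dict[str, dict[str, float]]
    direct_effect: dict[str, float]

    def true_a(self, region: str) -> float:
        return self.delta.get(region, 0.0)

    def true_b(self, outcome: str, region: str) -> float:
        return self.b_per_outcome.get(outcome, {}).get(region, 0.0)

    def true_ab(self, outcome: str, region: str) -> float:
        return self.true_a(region) * self.true_b(outcome, region)

    def true_c(self, outcome: str) -> float:
        total = self.direct_effect.get(outcome, 0.0)
        for region in self.delta:
            total += self.true_ab(outcome, region)
        return total

    def true_proportion_mediated(self, outcome: str, region: str) -> float:
        """True 100*ab/c for one (outcome, region) pair (percent)."""
        c = self.true_c(outcome)
        if abs(c) < 1e-12:
            return math.nan
        return 100.0 * self.true_ab(outcome, region) / c

    def to_json(self, path: str | Path) -> None:
        payload = {
            "csvd_flag": {str(k): bool(v) for k, v in self.csvd_flag.items()},
            "wmh_threshold": self.wmh_threshold,
            "delta": self.delta,
            "severity_multiplier": {str(k): float(v)
                                    for k, v in self.severity_multiplier.items()},
            "extra_aging": self.extra_aging.to_dict(orient="index"),
            "b_per_outcome": self.b_per_outcome,
            "direct_effect": self.direct_effect,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# --------------------------------------------------------------- internals

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


def _region_params(config: SimulationConfig, atlas: AtlasSpec):
    """Per-region GMV model parameters, shared by both cohorts.

    Drawn from a dedicated stream of the config seed so that the training
    and application cohorts see identical region baselines and slopes.
    """
    rng = _rng(config.seed, 0xA71A5)
    lo, hi = config.slope_range
    params = {}
    for rid in atlas.region_ids:
        n_vox = atlas.voxels_per_region[rid]
        baseline = rng.normal(config.baseline_mean, config.baseline_sd)
        offsets = rng.normal(0.0, config.voxel_offset_sd, size=n_vox)
        slope = rng.uniform(lo, hi)
        params[rid] = (baseline + offsets, slope)
    return params


def _gmv_features(
    config: SimulationConfig,
    atlas: AtlasSpec,
    effective_age: dict[str, np.ndarray],
    rng: np.random.Generator,
    subject_ids: np.ndarray,
) -> FeatureSet:
    """Voxel GMV at per-region effective ages plus iid Gaussian noise."""
    params = _region_params(config, atlas)
    blocks = []
    cols: list[str] = []
    q = config.quadratic_coef
    for rid in atlas.region_ids:
        mu, beta = params[rid]
        age = effective_age[rid]
        signal = mu[None, :] - beta * age[:, None] - q * (age**2)[:, None]
        noise = rng.normal(0.0, config.noise_sd, size=signal.shape) \
            if config.noise_sd > 0 else 0.0
        blocks.append(signal + noise)
        cols.extend(atlas.voxel_columns(rid))
    mat = np.hstack(blocks)
    voxels = pd.DataFrame(mat, index=pd.Index(subject_ids, name="subject_id"),
                          columns=cols)
    return FeatureSet(voxels=voxels, atlas=atlas)


# -------------------------------------------------------------- generators

def generate_training_cohort(
    config: SimulationConfig, atlas: AtlasSpec
) -> tuple[pd.DataFrame, FeatureSet]:
    """Healthy training cohort: ages, sex and GMV features only.

    Ages are uniform over ``train_age_range``; voxel GMV is the affine
    (optionally quadratic) age signal plus iid Gaussian noise.
    Deterministic given ``config.seed``.
    """
    config.validate(atlas)
    cs = config.cohort_seed if config.cohort_seed is not None else config.seed
    rng = _rng(cs, 1)
    n = config.n_train
    lo, hi = config.train_age_range
    ages = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n)
    ids = np.array([f"T{i + 1:05d}" for i in range(n)])
    subjects = pd.DataFrame({"subject_id": ids, "age": ages, "sex": sex})
    eff = {rid: ages for rid in atlas.region_ids}
    features = _gmv_features(config, atlas, eff, rng, ids)
    return subjects, features


def generate_application_cohort(
    config: SimulationConfig, atlas: AtlasSpec
) -> tuple[pd.DataFrame, FeatureSet, GroundTruth]:
    """Application cohort with covariates, CSVD markers, GMV and cognition.

    Subjects flagged by the CSVD marker rule (applied to the generated
    markers) receive GMV computed at effective age ``age + delta_r * L_i``
    in the affected regions; cognitive scores load on the resulting true
    extra aging and on CSVD status directly.
    """
    config.validate(atlas)
    cs = config.cohort_seed if config.cohort_seed is not None else config.seed
    rng = _rng(cs, 2)
    n = config.n_app
    lo, hi = config.app_age_range
    m = config.marker

    ages = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n)
    severity = rng.normal(0.0, 1.0, size=n)
    education = np.clip(
        rng.normal(config.education_mean, config.education_sd, size=n)
        - 0.05 * (ages - 65.0),
        0.0, 22.0,
    )
    efc = rng.normal(config.efc_mean, config.efc_sd, size=n)
    tiv_l = np.clip(rng.normal(m.tiv_mean_l, m.tiv_sd_l, size=n), 0.9, None)

    def risk(prev: float) -> np.ndarray:
        logit = math.log(prev / (1 - prev)) if 0 < prev < 1 else (
            -np.inf if prev == 0 else np.inf)
        p = 1.0 / (1.0 + np.exp(-(logit + config.risk_sev_coef * severity
                                  + 0.02 * (ages - 65.0))))
        return (rng.uniform(size=n) < p).astype(int)

    hypertension = risk(config.hypertension_prev)
    diabetes = risk(config.diabetes_prev)
    dyslipidemia = risk(config.dyslipidemia_prev)
    smoking = risk(config.smoking_prev)

    age_c = ages - 65.0
    wmh_ml = np.exp(m.wmh_log_loc + m.wmh_age_coef * age_c
                    + m.wmh_sev_coef * severity
                    + m.wmh_log_scale * rng.normal(size=n))
    lacunes = rng.poisson(np.exp(m.lacune_log_rate + m.lacune_age_coef * age_c
                                 + m.lacune_sev_coef * severity))
    cmbs = rng.poisson(np.exp(m.cmb_log_rate + m.cmb_age_coef * age_c
                              + m.cmb_sev_coef * severity))

    ids = np.array([f"A{i + 1:05d}" for i in range(n)])
    markers = pd.DataFrame({
        "subject_id": ids,
        "wmh_volume_ml": wmh_ml,
        "tiv_l": tiv_l,
        "lacune_count": lacunes,
        "cmb_count": cmbs,
    })
    cls = classify_csvd(markers, percentile=config.percentile)
    flag = cls.flags.to_numpy()

    # per-subject extra aging
    k = config.severity_gamma_shape
    mult = np.ones(n)
    mult[flag] = rng.gamma(shape=k, scale=1.0 / k, size=int(flag.sum()))
    deltas = config.delta_map()
    extra = pd.DataFrame(
        {rid: deltas[rid] * mult * flag for rid in deltas},
        index=pd.Index(ids, name="subject_id"),
        dtype=float,
    )

    eff = {}
    for rid in atlas.region_ids:
        eff[rid] = ages + (extra[rid].to_numpy() if rid in extra.columns else 0.0)
    features = _gmv_features(config, atlas, eff, rng, ids)

    subjects = pd.DataFrame({
        "subject_id": ids,
        "age": ages,
        "sex": sex,
        "education_years": education,
        "efc": efc,
        "tiv_l": tiv_l,
        "hypertension": hypertension,
        "diabetes": diabetes,
        "dyslipidemia": dyslipidemia,
        "smoking": smoking,
        "wmh_volume_ml": wmh_ml,
        "wmh_ratio": wmh_ratio(wmh_ml, tiv_l, "ml", "l"),
        "lacune_count": lacunes,
        "cmb_count": cmbs,
    })

    for name, om in config.outcomes.items():
        y = (om.intercept
             + om.age_coef * ages
             + om.sex_coef * sex
             + om.education_coef * education
             + om.efc_coef * efc
             + om.tiv_coef * tiv_l
             + om.direct_effect * flag.astype(float)
             + om.noise_sd * rng.normal(size=n))
        for rid, b in om.b_per_region.items():
            contrib = extra[rid].to_numpy() if rid in extra.columns else 0.0
            y = y + b * contrib
        subjects[name] = y

    truth = GroundTruth(
        csvd_flag=pd.Series(flag, index=ids, name="csvd"),
        wmh_threshold=cls.threshold,
        delta=deltas,
        severity_multiplier=pd.Series(mult, index=ids, name="severity_multiplier"),
        extra_aging=extra,
        b_per_outcome={nm: dict(om.b_per_region)
                       for nm, om in config.outcomes.items()},
        direct_effect={nm: om.direct_effect
                       for nm, om in config.outcomes.items()},
    )
    return subjects, features, truth
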