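"""Synthetic cohorts with a known true exposure effect and an NLP
observation layer.

The original EHR analysis datasets are not deposited, so every stage of
the pipeline is exercised on generated cohorts instead: a binary "true"
exposure of moderate prevalence, generic confounders, an outcome drawn
from one of three families (survival, binary, longitudinal), and an
observed exposure produced by pushing the truth through a classifier
with known sensitivity/specificity.  Defaults for the observation layer
are set so the realized PPV/NPV land near 0.76/0.99 — the weakest tool
in the studies the pipeline emulates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

from .error_model import realized_confusion

__all__ = [
    "ConfounderSpec",
    "CohortSpec",
    "generate_cohort",
    "generate_survival_cohort",
    "generate_binary_outcome_cohort",
    "generate_longitudinal_cohort",
    "observe_exposure",
    "write_cohort",
    "read_cohort",
]

OUTCOME_FAMILIES = ("survival", "binary", "longitudinal")


@dataclass(frozen=True)
class ConfounderSpec:
    """One generic confounder: its marginal distribution and its effect
    on the outcome's linear predictor."""

    name: str
    dist: str  # "bernoulli" or "normal"
    params: tuple  # (p,) for bernoulli, (mu, sigma) for normal
    effect: float = 0.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "bernoulli":
            (p,) = self.params
            return rng.binomial(1, p, size=n).astype(float)
        if self.dist == "normal":
            mu, sigma = self.params
            return rng.normal(mu, sigma, size=n)
        raise ValueError(f"unknown confounder distribution {self.dist!r}")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``true_exposure_effect`` is a log hazard ratio (survival), a log odds
    ratio (binary) or a mean difference (longitudinal).  ``baseline`` is
    the baseline hazard per unit time, the outcome-model intercept, or
    the grand mean, respectively.  ``exposure_confounding`` optionally
    maps confounder names to coefficients of a logistic
    exposure-assignment model, so that confounding (and propensity
    weighting) can be exercised; by default exposure is independent of
    the confounders.
    """

    n_subjects: int
    outcome_family: str
    true_exposure_effect: float
    baseline: float
    exposure_prevalence: float = 0.10
    confounders: list[ConfounderSpec] = field(default_factory=list)
    censoring_rate: float = 0.0
    visits_per_subject: int = 1
    random_intercept_sd: float = 1.0
    residual_sd: float = 1.0
    sensitivity: float = 0.89
    specificity: float = 0.969
    exposure_confounding: dict[str, float] | None = None
    seed: int | None = None

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_subjects < 2:
            bad.append(f"n_subjects={self.n_subjects} (need >= 2)")
        if self.outcome_family not in OUTCOME_FAMILIES:
            bad.append(f"outcome_family={self.outcome_family!r}")
        for name in ("exposure_prevalence", "censoring_rate", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(f"{name}={v} (need proportion in [0, 1])")
        if self.outcome_family == "survival" and self.baseline <= 0:
            bad.append(f"baseline={self.baseline} (hazard must be > 0)")
        if self.outcome_family == "longitudinal":
            if self.visits_per_subject < 1:
                bad.append(f"visits_per_subject={self.visits_per_subject} (need >= 1)")
            if self.random_intercept_sd < 0 or self.residual_sd < 0:
                bad.append("random_intercept_sd/residual_sd must be >= 0")
        if self.exposure_confounding:
            known = {c.name for c in self.confounders}
            unknown = set(self.exposure_confounding) - known
            if unknown:
                bad.append(f"exposure_confounding references unknown confounders {sorted(unknown)}")
        if bad:
            raise ValueError("invalid cohort spec: " + "; ".join(bad))

    def confounder_names(self) -> list[str]:
        return [c.name for c in self.confounders]


def observe_exposure(
    true_exposure,
    sensitivity: float,
    specificity: float,
    seed: int | np.random.Generator,
) -> np.ndarray | pd.Series:
    """Push a true binary exposure through an imperfect classifier.

    Each true 1 is observed as 1 with probability ``sensitivity``; each
    true 0 is observed as 1 with probability ``1 - specificity``;
    independent across subjects.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    truth = np.asarray(true_exposure.to_numpy() if isinstance(true_exposure, pd.Series) else true_exposure)
    p_obs_pos = np.where(truth == 1, sensitivity, 1.0 - specificity)
    observed = (rng.random(truth.size) < p_obs_pos).astype(np.int64)
    if isinstance(true_exposure, pd.Series):
        return pd.Series(observed, index=true_exposure.index, name="observed_exposure")
    return observed


def _draw_base(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Ids, confounders, true and observed exposure — shared by all families."""
    n = spec.n_subjects
    df = pd.DataFrame({"subject_id": np.arange(n)})
    for conf in spec.confounders:
        df[conf.name] = conf.draw(n, rng)
    if spec.exposure_confounding:
        logit = special.logit(spec.exposure_prevalence) + sum(
            coef * df[name].to_numpy() for name, coef in spec.exposure_confounding.items()
        )
        p_exposed = special.expit(logit)
    else:
        p_exposed = np.full(n, spec.exposure_prevalence)
    df["true_exposure"] = rng.binomial(1, p_exposed)
    df["observed_exposure"] = observe_exposure(
        df["true_exposure"].to_numpy(), spec.sensitivity, spec.specificity, rng
    )
    return df


def _linear_predictor(spec: CohortSpec, df: pd.DataFrame) -> np.ndarray:
    lp = spec.true_exposure_effect * df["true_exposure"].to_numpy().astype(float)
    for conf in spec.confounders:
        lp += conf.effect * df[conf.name].to_numpy()
    return lp


def _solve_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Rate of an independent exponential censoring time such that the
    expected censored fraction equals ``target``.

    With event hazard h_i and censoring rate c, P(censored_i) = c/(c+h_i);
    solve mean_i c/(c+h_i) = target for c.
    """
    if target <= 0:
        return 0.0
    if target >= 1:
        raise ValueError("censoring_rate must be < 1")

    def f(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - target

    lo, hi = np.log(hazards.min()) - 30, np.log(hazards.max()) + 30
    return float(np.exp(optimize.brentq(f, lo, hi)))


def generate_survival_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Exponential event times with hazard ``baseline * exp(lp)`` and
    independent exponential censoring tuned to the requested censored
    fraction.  The constant baseline keeps the Cox oracle simple; Cox
    estimates are invariant to the baseline shape anyway.
    """
    spec.validate()
    if spec.outcome_family != "survival":
        raise ValueError(f"spec outcome_family is {spec.outcome_family!r}, not 'survival'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    df = _draw_base(spec, rng)
    hazards = spec.baseline * np.exp(_linear_predictor(spec, df))
    event_time = rng.exponential(1.0 / hazards)
    if spec.censoring_rate > 0:
        c_rate = _solve_censoring_rate(hazards, spec.censoring_rate)
        cens_time = rng.exponential(1.0 / c_rate, size=len(df))
        df["time"] = np.minimum(event_time, cens_time)
        df["event"] = (event_time <= cens_time).astype(int)
    else:
        df["time"] = event_time
        df["event"] = 1
    return df


def generate_binary_outcome_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Bernoulli outcome with logit ``baseline + lp``."""
    spec.validate()
    if spec.outcome_family != "binary":
        raise ValueError(f"spec outcome_family is {spec.outcome_family!r}, not 'binary'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    df = _draw_base(spec, rng)
    p = special.expit(spec.baseline + _linear_predictor(spec, df))
    df["outcome"] = rng.binomial(1, p)
    return df


def generate_longitudinal_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """One row per subject-visit:
    ``measure = baseline + b_i + effect*exposure + sum(gamma*confounder) + e_ij``
    with ``b_i ~ N(0, random_intercept_sd^2)`` and
    ``e_ij ~ N(0, residual_sd^2)``.
    """
    spec.validate()
    if spec.outcome_family != "longitudinal":
        raise ValueError(f"spec outcome_family is {spec.outcome_family!r}, not 'longitudinal'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    base = _draw_base(spec, rng)
    subject_mean = spec.baseline + _linear_predictor(spec, base)
    b = rng.normal(0.0, spec.random_intercept_sd, size=len(base))
    v = spec.visits_per_subject
    long = base.loc[base.index.repeat(v)].reset_index(drop=True)
    long["visit_index"] = np.tile(np.arange(v), len(base))
    noise = rng.normal(0.0, spec.residual_sd, size=len(long))
    long["measure"] = np.repeat(subject_mean + b, v) + noise
    return long


_GENERATORS = {
    "survival": generate_survival_cohort,
    "binary": generate_binary_outcome_cohort,
    "longitudinal": generate_longitudinal_cohort,
}


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Dispatch on ``spec.outcome_family``."""
    spec.validate()
    return _GENERATORS[spec.outcome_family](spec, seed)


def _realized_observation_stats(df: pd.DataFrame) -> dict:
    subj = df.drop_duplicates("subject_id")
    conf = realized_confusion(
        subj["true_exposure"].to_numpy(), subj["observed_exposure"].to_numpy()
    )
    return {
        "realized_ppv": conf.ppv,
        "realized_npv": conf.npv,
        "realized_sensitivity": conf.sensitivity,
        "realized_specificity": conf.specificity,
        "realized_prevalence": float(subj["true_exposure"].mean()),
        "realized_observed_prevalence": float(subj["observed_exposure"].mean()),
    }


def _to_plain(obj):
    """Numpy scalars -> python scalars so the YAML sidecar stays portable."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def write_cohort(df: pd.DataFrame, spec: CohortSpec, csv_path, yaml_path=None) -> None:
    """Write the cohort as CSV plus a YAML sidecar recording the
    generating spec, the seed, and the realized PPV/NPV/prevalence."""
    csv_path = str(csv_path)
    df.to_csv(csv_path, index=False)
    if yaml_path is None:
        yaml_path = csv_path[:-4] + ".yaml" if csv_path.endswith(".csv") else csv_path + ".yaml"
    record = dataclasses.asdict(spec)
    record["confounders"] = [dataclasses.asdict(c) for c in spec.confounders]
    for c in record["confounders"]:
        c["params"] = list(c["params"])
    record.update(_realized_observation_stats(df))
    record = _to_plain(record)
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=True)


def read_cohort(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
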