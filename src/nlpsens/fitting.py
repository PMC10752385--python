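"""Regression fits and per-fit assumption checks.

Three model families cover the emulated study designs: a Cox
proportional-hazards model (optionally with stabilized
inverse-probability-of-treatment weights and a robust variance), a
logistic regression, and a linear mixed model with random intercepts
fitted by REML.  Estimation is delegated to lifelines and statsmodels;
this module owns the uniform result container, the Wald p-value
convention, and the assumption battery used to exclude replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "AssumptionCheck",
    "AssumptionReport",
    "fit_model",
    "estimate_propensity_weights",
    "check_assumptions",
]

FAMILIES = ("cox", "logistic", "linear_mixed")
_WEIGHT_COL = "__ipt_weight__"


@dataclass
class ModelSpec:
    """What to fit: family, exposure/confounder columns, outcome columns.

    ``weighting="propensity"`` (cox only) applies stabilized IPT weights
    estimated from the exposure and confounders.  ``alpha`` is the
    two-sided significance level used throughout the summaries.
    """

    family: str
    exposure: str
    confounders: list[str] = field(default_factory=list)
    time_col: str = "time"
    event_col: str = "event"
    outcome_col: str = "outcome"
    measure_col: str = "measure"
    group: str = "subject_id"
    weighting: str = "none"
    stabilized_weights: bool = True
    alpha: float = 0.05

    def validate(self, cohort: pd.DataFrame) -> None:
        bad: list[str] = []
        if self.family not in FAMILIES:
            bad.append(f"family={self.family!r} (must be one of {FAMILIES})")
        if not (0.0 < self.alpha < 1.0):
            bad.append(f"alpha={self.alpha} (need 0 < alpha < 1)")
        if self.weighting not in ("none", "propensity"):
            bad.append(f"weighting={self.weighting!r}")
        if self.weighting == "propensity" and self.family != "cox":
            bad.append("propensity weighting is only supported for the cox family")
        missing = [c for c in self.columns_used() if c not in cohort.columns]
        if missing:
            bad.append(f"columns missing from cohort: {missing}")
        if bad:
            raise ValueError("invalid model spec: " + "; ".join(bad))

    def columns_used(self) -> list[str]:
        cols = [self.exposure, *self.confounders]
        if self.family == "cox":
            cols += [self.time_col, self.event_col]
        elif self.family == "logistic":
            cols += [self.outcome_col]
        else:
            cols += [self.measure_col, self.group]
        return cols


@dataclass
class FitResult:
    """One model fit, normalized across families.

    ``params`` is indexed by variable name with columns ``coefficient``
    (log scale for cox/logistic), ``native_estimate`` (exp(coefficient)
    for cox/logistic, identity for linear_mixed), ``se`` and ``p_value``
    (two-sided Wald).  Intercepts/grand means are not tabulated — only
    the exposure and confounders enter the sensitivity summaries.
    """

    family: str
    params: pd.DataFrame
    converged: bool
    n_obs: int
    extras: dict = field(default_factory=dict)
    # live handles for assumption checks; dropped on serialization
    _fitted: object = field(default=None, repr=False, compare=False)
    _train_df: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def coefficient(self, variable: str) -> float:
        return float(self.params.loc[variable, "coefficient"])

    def native_estimate(self, variable: str) -> float:
        return float(self.params.loc[variable, "native_estimate"])

    def p_value(self, variable: str) -> float:
        return float(self.params.loc[variable, "p_value"])

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "extras": {k: float(v) for k, v in self.extras.items()},
            "variables": list(self.params.index),
            "params": {
                col: [float(x) for x in self.params[col]]
                for col in ("coefficient", "native_estimate", "se", "p_value")
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        params = pd.DataFrame(
            {k: d["params"][k] for k in ("coefficient", "native_estimate", "se", "p_value")},
            index=pd.Index(d["variables"], name="variable"),
        )
        return cls(
            family=d["family"],
            params=params,
            converged=d["converged"],
            n_obs=d["n_obs"],
            extras=dict(d.get("extras", {})),
        )


def _failed_fit(family: str, variables: list[str], n_obs: int) -> FitResult:
    params = pd.DataFrame(
        np.nan,
        index=pd.Index(variables, name="variable"),
        columns=["coefficient", "native_estimate", "se", "p_value"],
    )
    return FitResult(family=family, params=params, converged=False, n_obs=n_obs)


def _params_frame(variables, coefs, ses, pvals, log_scale: bool) -> pd.DataFrame:
    coefs = np.asarray(coefs, dtype=float)
    native = np.exp(coefs) if log_scale else coefs
    return pd.DataFrame(
        {
            "coefficient": coefs,
            "native_estimate": native,
            "se": np.asarray(ses, dtype=float),
            "p_value": np.asarray(pvals, dtype=float),
        },
        index=pd.Index(list(variables), name="variable"),
    )


def estimate_propensity_weights(
    cohort: pd.DataFrame,
    exposure: str,
    confounders: list[str],
    stabilized: bool = True,
) -> np.ndarray:
    """Inverse-probability-of-treatment weights from a logistic
    propensity model of exposure on the confounders.

    Stabilized weights (default) multiply by the marginal exposure
    probability: exposed subjects get ``P(exposed) / p_i``, unexposed
    ``(1 - P(exposed)) / (1 - p_i)``; their mean is ~1 in each group,
    which bounds the variance.  Raw weights use 1 in the numerator.
    With no confounders the propensity model is intercept-only and every
    stabilized weight is exactly 1.
    """
    a = cohort[exposure].to_numpy().astype(float)
    marginal = a.mean()
    if not confounders:
        if stabilized:
            return np.ones(len(cohort))
        return np.where(a == 1, 1.0 / marginal, 1.0 / (1.0 - marginal))
    X = sm.add_constant(cohort[confounders].to_numpy().astype(float))
    import warnings

    try:
        with warnings.catch_warnings():
            # separation is screened explicitly below
            warnings.simplefilter("ignore")
            res = sm.GLM(a, X, family=sm.families.Binomial()).fit()
            p = np.asarray(res.fittedvalues)  # lazy; keep inside the guard
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely here
        raise ValueError(f"propensity model failed ({exc}); consider an unweighted fit")
    eps = 1e-10
    if not res.converged or np.max(np.abs(res.params[1:])) > 15 or np.any(
        (p < eps) | (p > 1 - eps)
    ):
        raise ValueError(
            "perfect or quasi-perfect separation in the propensity model; "
            "use an unweighted fit"
        )
    num = np.where(a == 1, marginal, 1.0 - marginal) if stabilized else 1.0
    w = num / np.where(a == 1, p, 1.0 - p)
    if np.any(w <= 0):  # pragma: no cover - guarded by eps clip above
        raise ValueError("non-positive propensity weight")
    return w


def _fit_cox(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    variables = [spec.exposure, *spec.confounders]
    cols = [spec.time_col, spec.event_col, *variables]
    df = cohort[cols].copy()
    weights_col = None
    robust = False
    if spec.weighting == "propensity":
        df[_WEIGHT_COL] = estimate_propensity_weights(
            cohort, spec.exposure, spec.confounders, stabilized=spec.stabilized_weights
        )
        weights_col = _WEIGHT_COL
        robust = True
    cph = CoxPHFitter()  # Efron tie handling is the lifelines default
    try:
        cph.fit(
            df,
            duration_col=spec.time_col,
            event_col=spec.event_col,
            weights_col=weights_col,
            robust=robust,
        )
    except Exception:
        return _failed_fit("cox", variables, len(df))
    summ = cph.summary.loc[variables]
    fr = FitResult(
        family="cox",
        params=_params_frame(variables, summ["coef"], summ["se(coef)"], summ["p"], log_scale=True),
        converged=True,
        n_obs=len(df),
        _fitted=cph,
        _train_df=df,
    )
    return fr


def _fit_logistic(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    variables = [spec.exposure, *spec.confounders]
    y = cohort[spec.outcome_col].to_numpy().astype(float)
    X = sm.add_constant(cohort[variables].to_numpy().astype(float))
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        converged = bool(res.converged)
    except Exception:
        return _failed_fit("logistic", variables, len(cohort))
    # column 0 is the intercept
    fr = FitResult(
        family="logistic",
        params=_params_frame(
            variables, res.params[1:], res.bse[1:], res.pvalues[1:], log_scale=True
        ),
        converged=converged,
        n_obs=len(cohort),
        extras={"intercept": float(res.params[0])},
        _fitted=res,
    )
    return fr


def _fit_linear_mixed(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    import warnings

    from statsmodels.regression.mixed_linear_model import MixedLMParams
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    variables = [spec.exposure, *spec.confounders]
    y = cohort[spec.measure_col].to_numpy().astype(float)
    X = sm.add_constant(cohort[variables].to_numpy().astype(float))
    groups = cohort[spec.group].to_numpy()
    try:
        with warnings.catch_warnings():
            # boundary-ish replicates warn loudly; the convergence flag and
            # the zero-variance LRT below carry the same information
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=True)
            converged = bool(res.converged)
            # restricted-likelihood ratio against sigma_b^2 = 0 (fixed
            # effects unchanged, so REML loglikelihoods are comparable)
            p0 = MixedLMParams.from_components(
                fe_params=res.fe_params, cov_re=np.array([[1e-10]])
            )
            re_zero_lrt = float(2.0 * (res.llf - model.loglike(p0, profile_fe=True)))
    except Exception:
        return _failed_fit("linear_mixed", variables, len(cohort))
    k = len(variables)
    fr = FitResult(
        family="linear_mixed",
        params=_params_frame(
            variables,
            res.params[1 : k + 1],
            res.bse[1 : k + 1],
            res.pvalues[1 : k + 1],
            log_scale=False,
        ),
        converged=converged,
        n_obs=len(cohort),
        extras={
            "intercept": float(res.params[0]),
            "random_intercept_var": float(np.asarray(res.cov_re)[0, 0]),
            "residual_var": float(res.scale),
            "re_zero_lrt": re_zero_lrt,
        },
        _fitted=res,
    )
    return fr


def fit_model(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    exposure_override=None,
) -> FitResult:
    """Fit ``spec`` to the cohort, optionally swapping in a replacement
    exposure vector (aligned row-by-row or by a pandas index).

    Non-convergence is reported through ``FitResult.converged``, not an
    exception.  Missing values in any used column are an input error:
    the analysis is complete-case only.
    """
    spec.validate(cohort)
    if exposure_override is not None:
        cohort = cohort.copy()
        vals = (
            exposure_override.to_numpy()
            if isinstance(exposure_override, pd.Series)
            else np.asarray(exposure_override)
        )
        if len(vals) != len(cohort):
            raise ValueError("exposure_override length does not match cohort")
        cohort[spec.exposure] = vals
    used = cohort[spec.columns_used()]
    if used.isna().any().any():
        na_cols = list(used.columns[used.isna().any()])
        raise ValueError(f"missing values in columns {na_cols}; complete cases required")
    if spec.family == "cox":
        return _fit_cox(cohort, spec)
    if spec.family == "logistic":
        return _fit_logistic(cohort, spec)
    return _fit_linear_mixed(cohort, spec)


@dataclass(frozen=True)
class AssumptionCheck:
    name: str
    statistic: float
    threshold: float
    passed: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": float(self.statistic),
            "threshold": float(self.threshold),
            "passed": bool(self.passed),
            "note": self.note,
        }


@dataclass
class AssumptionReport:
    checks: list[AssumptionCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_dict(self) -> dict:
        return {"passed": self.passed, "checks": [c.to_dict() for c in self.checks]}

    @classmethod
    def from_dict(cls, d: dict) -> "AssumptionReport":
        return cls(checks=[AssumptionCheck(**c) for c in d["checks"]])


def _ph_global_check(fit: FitResult, ph_alpha: float) -> AssumptionCheck:
    """Global proportional-hazards test: per-covariate scaled-Schoenfeld
    tests combined by Fisher's method; fails when the combined p < threshold."""
    try:
        result = proportional_hazard_test(fit._fitted, fit._train_df, time_transform="rank")
        pvals = np.asarray(result.p_value, dtype=float)
        pvals = np.clip(pvals, 1e-300, 1.0)
        fisher = -2.0 * np.sum(np.log(pvals))
        p_global = float(stats.chi2.sf(fisher, df=2 * len(pvals)))
        return AssumptionCheck(
            name="proportional_hazards",
            statistic=p_global,
            threshold=ph_alpha,
            passed=p_global > ph_alpha,
        )
    except Exception as exc:
        return AssumptionCheck(
            name="proportional_hazards",
            statistic=float("nan"),
            threshold=ph_alpha,
            passed=True,
            note=f"not verifiable ({exc})",
        )


def check_assumptions(
    fit: FitResult,
    cohort: pd.DataFrame,
    spec: ModelSpec,
    ph_alpha: float = 0.01,
    separation_threshold: float = 10.0,
    singularity_lrt: float = 3.84,
) -> AssumptionReport:
    """Family-specific diagnostic battery; deterministic given the fit.

    cox: convergence + global proportional-hazards test (scaled
    Schoenfeld residuals, Fisher-combined, fail when p <= ``ph_alpha``).
    logistic: convergence + separation screen (any |coefficient| above
    ``separation_threshold`` fails).  linear_mixed: convergence + a
    non-singular random-intercept variance, judged by the restricted
    likelihood ratio against sigma_b^2 = 0 (fails when the statistic is
    below ``singularity_lrt``, default the chi-square-1 95% point).
    """
    checks = [
        AssumptionCheck(
            name="convergence",
            statistic=float(fit.converged),
            threshold=1.0,
            passed=bool(fit.converged),
        )
    ]
    if fit.family == "cox":
        if fit.converged and fit._fitted is not None:
            checks.append(_ph_global_check(fit, ph_alpha))
        else:
            checks.append(
                AssumptionCheck(
                    name="proportional_hazards",
                    statistic=float("nan"),
                    threshold=ph_alpha,
                    passed=True,
                    note="not verifiable (no converged fit)",
                )
            )
    elif fit.family == "logistic":
        max_abs = float(np.nanmax(np.abs(fit.params["coefficient"]))) if fit.converged else float("nan")
        checks.append(
            AssumptionCheck(
                name="separation_screen",
                statistic=max_abs,
                threshold=separation_threshold,
                passed=bool(fit.converged and max_abs <= separation_threshold),
            )
        )
    else:  # linear_mixed
        lrt = fit.extras.get("re_zero_lrt", float("nan"))
        checks.append(
            AssumptionCheck(
                name="random_effects_nonsingular",
                statistic=lrt if np.isfinite(lrt) else float("nan"),
                threshold=singularity_lrt,
                passed=bool(np.isfinite(lrt) and lrt > singularity_lrt),
            )
        )
    return AssumptionReport(checks=checks)
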