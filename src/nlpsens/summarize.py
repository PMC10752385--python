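"""Stability metrics over a replicate set.

For each model variable the summaries report how far the replicate
estimates moved from the original fit (mean/median percent change and
its interquartile range, on the natively reported scale — hazard or
odds ratio for cox/logistic, the fixed effect for the mixed model), how
often the coefficient changed sign, and how often statistical
significance at level alpha was eliminated (for variables originally
significant) or acquired (for variables originally non-significant).
Confounder metrics can additionally be pooled across all
confounder x replicate pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .monte_carlo import ReplicateSet

__all__ = [
    "pct_change",
    "significance_transition",
    "VariableSummary",
    "PooledConfounderSummary",
    "summarize_variable",
    "summarize_all",
    "summarize_confounders",
    "summary_frame",
    "write_summaries",
]


def pct_change(original: float, simulated: float, scale: str = "native") -> float:
    """Percent change of a replicate estimate relative to the original.

    ``100 * (simulated - original) / original`` on the natively reported
    scale.  Division is by the *signed* original, so a mixed-model
    effect moving from -1.43 toward 0 reports a negative percent change.
    ``scale="log"`` applies the same formula to the logs (both inputs
    must then be positive ratios).
    """
    if scale == "log":
        original, simulated = np.log(original), np.log(simulated)
    if original == 0:
        raise ValueError("percent change undefined for original estimate 0")
    return 100.0 * (simulated - original) / original


def significance_transition(original_p: float, simulated_p: float, alpha: float = 0.05) -> str:
    """Classify one replicate's p-value against the original.

    ``"eliminated"`` iff original_p < alpha <= simulated_p;
    ``"acquired"`` iff simulated_p < alpha <= original_p; else
    ``"unchanged"``.
    """
    orig_sig = original_p < alpha
    sim_sig = simulated_p < alpha
    if orig_sig and not sim_sig:
        return "eliminated"
    if sim_sig and not orig_sig:
        return "acquired"
    return "unchanged"


@dataclass
class VariableSummary:
    """Stability metrics for one model variable.

    Exactly one of ``p_sig_eliminated`` / ``p_sig_acquired`` is defined
    (non-None), depending on whether the variable was originally
    significant.  All proportions are counts over ``n_included``.
    """

    variable: str
    original_estimate: float
    original_coefficient: float
    original_p: float
    mean_pct_change: float
    median_pct_change: float
    iqr_pct_change: tuple[float, float]
    p_sign_change: float
    p_sig_eliminated: float | None
    p_sig_acquired: float | None
    n_included: int

    def to_dict(self) -> dict:
        d = {
            "variable": self.variable,
            "original_estimate": self.original_estimate,
            "original_coefficient": self.original_coefficient,
            "original_p": self.original_p,
            "mean_pct_change": self.mean_pct_change,
            "median_pct_change": self.median_pct_change,
            "iqr_pct_change_q1": self.iqr_pct_change[0],
            "iqr_pct_change_q3": self.iqr_pct_change[1],
            "p_sign_change": self.p_sign_change,
            "p_sig_eliminated": self.p_sig_eliminated,
            "p_sig_acquired": self.p_sig_acquired,
            "n_included": self.n_included,
        }
        return d


def _pct_changes(rs: ReplicateSet, variable: str, scale: str) -> np.ndarray:
    original = rs.original_fit.native_estimate(variable)
    return np.array(
        [
            pct_change(original, r.fit.native_estimate(variable), scale=scale)
            for r in rs.included_replicates()
        ]
    )


def summarize_variable(
    rs: ReplicateSet, variable: str, alpha: float | None = None, scale: str = "native"
) -> VariableSummary:
    """Mean/median/IQR percent change, sign-change and significance-
    transition rates for one variable.

    Quantiles use linear interpolation (type 7, the numpy default), so
    the worked examples in the tests are exact.  Sign changes are judged
    on the coefficient (log) scale: for ratio-type estimates "direction"
    means crossing 1, which is the sign of the log.
    """
    if alpha is None:
        alpha = rs.alpha
    included = rs.included_replicates()
    if not included:
        raise ValueError("no included replicates to summarize")
    if variable not in rs.original_fit.params.index:
        raise KeyError(f"variable {variable!r} not in the fitted model")
    changes = _pct_changes(rs, variable, scale)
    q1, q3 = np.percentile(changes, [25, 75])
    orig_coef = rs.original_fit.coefficient(variable)
    orig_p = rs.original_fit.p_value(variable)
    sign_changes = np.array(
        [np.sign(r.fit.coefficient(variable)) != np.sign(orig_coef) for r in included]
    )
    transitions = [
        significance_transition(orig_p, r.fit.p_value(variable), alpha) for r in included
    ]
    n = len(included)
    orig_sig = orig_p < alpha
    return VariableSummary(
        variable=variable,
        original_estimate=rs.original_fit.native_estimate(variable),
        original_coefficient=orig_coef,
        original_p=orig_p,
        mean_pct_change=float(np.mean(changes)),
        median_pct_change=float(np.median(changes)),
        iqr_pct_change=(float(q1), float(q3)),
        p_sign_change=float(np.mean(sign_changes)),
        p_sig_eliminated=(transitions.count("eliminated") / n) if orig_sig else None,
        p_sig_acquired=(transitions.count("acquired") / n) if not orig_sig else None,
        n_included=n,
    )


def summarize_all(rs: ReplicateSet, alpha: float | None = None) -> list[VariableSummary]:
    return [summarize_variable(rs, v, alpha=alpha) for v in rs.variables]


@dataclass
class PooledConfounderSummary:
    """Confounder metrics pooled over all confounder x replicate pairs.

    ``sig_acquired_mean_pct`` / ``sig_eliminated_mean_pct`` average the
    per-confounder transition percentages within the relevant
    original-significance stratum (equal weight per confounder);
    ``sig_acquired_pooled_pct`` / ``sig_eliminated_pooled_pct`` pool all
    pairs in the stratum instead.  Both are reported because either
    reading of "mean % simulations" is defensible.
    """

    n_confounders: int
    n_included: int
    mean_pct_change: float
    median_pct_change: float
    iqr_pct_change: tuple[float, float]
    n_direction_changes: int
    sig_acquired_mean_pct: float | None
    sig_eliminated_mean_pct: float | None
    sig_acquired_pooled_pct: float | None
    sig_eliminated_pooled_pct: float | None

    def to_dict(self) -> dict:
        return {
            "n_confounders": self.n_confounders,
            "n_included": self.n_included,
            "mean_pct_change": self.mean_pct_change,
            "median_pct_change": self.median_pct_change,
            "iqr_pct_change_q1": self.iqr_pct_change[0],
            "iqr_pct_change_q3": self.iqr_pct_change[1],
            "n_direction_changes": self.n_direction_changes,
            "sig_acquired_mean_pct": self.sig_acquired_mean_pct,
            "sig_eliminated_mean_pct": self.sig_eliminated_mean_pct,
            "sig_acquired_pooled_pct": self.sig_acquired_pooled_pct,
            "sig_eliminated_pooled_pct": self.sig_eliminated_pooled_pct,
        }


def summarize_confounders(
    rs: ReplicateSet, confounders: list[str] | None = None, alpha: float | None = None
) -> PooledConfounderSummary:
    """Pool the stability metrics over all confounders."""
    if confounders is None:
        confounders = list(rs.confounders)
    if not confounders:
        raise ValueError("no confounders to pool")
    if alpha is None:
        alpha = rs.alpha
    per_var = [summarize_variable(rs, c, alpha=alpha) for c in confounders]
    all_changes = np.concatenate([_pct_changes(rs, c, "native") for c in confounders])
    q1, q3 = np.percentile(all_changes, [25, 75])
    included = rs.included_replicates()
    n_dir = sum(int(round(s.p_sign_change * s.n_included)) for s in per_var)

    elim = [s.p_sig_eliminated for s in per_var if s.p_sig_eliminated is not None]
    acq = [s.p_sig_acquired for s in per_var if s.p_sig_acquired is not None]

    def _mean_pct(rates: list[float]) -> float | None:
        return 100.0 * float(np.mean(rates)) if rates else None

    def _pooled_pct(rates: list[float]) -> float | None:
        # every confounder contributes n_included pairs, so pooling over
        # pairs equals the unweighted mean here; kept separate in case a
        # variable is ever missing from some replicates
        return _mean_pct(rates)

    return PooledConfounderSummary(
        n_confounders=len(confounders),
        n_included=len(included),
        mean_pct_change=float(np.mean(all_changes)),
        median_pct_change=float(np.median(all_changes)),
        iqr_pct_change=(float(q1), float(q3)),
        n_direction_changes=n_dir,
        sig_acquired_mean_pct=_mean_pct(acq),
        sig_eliminated_mean_pct=_mean_pct(elim),
        sig_acquired_pooled_pct=_pooled_pct(acq),
        sig_eliminated_pooled_pct=_pooled_pct(elim),
    )


def summary_frame(rs: ReplicateSet, alpha: float | None = None) -> pd.DataFrame:
    """One row per model variable (exposure first) with all metrics."""
    rows = [s.to_dict() for s in summarize_all(rs, alpha=alpha)]
    return pd.DataFrame(rows).set_index("variable")


def write_summaries(rs: ReplicateSet, out_dir, alpha: float | None = None) -> dict:
    """Write the per-variable CSV, the pooled-confounder CSV (when the
    model has confounders), and a machine-readable JSON with all
    per-replicate values.  Returns the paths written."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    frame = summary_frame(rs, alpha=alpha)
    paths["variables_csv"] = os.path.join(out_dir, "variable_summary.csv")
    frame.to_csv(paths["variables_csv"])
    if rs.confounders:
        pooled = summarize_confounders(rs, alpha=alpha)
        paths["confounders_csv"] = os.path.join(out_dir, "confounder_summary.csv")
        pd.DataFrame([pooled.to_dict()]).to_csv(paths["confounders_csv"], index=False)
    from .monte_carlo import replicate_estimate_matrix

    est, pvals = replicate_estimate_matrix(rs, included_only=False)
    record = {
        "n_requested": rs.n_requested,
        "n_included": rs.n_included,
        "n_excluded": rs.n_excluded,
        "alpha": rs.alpha if alpha is None else alpha,
        "estimates": {v: [float(x) for x in est.loc[v]] for v in est.index},
        "p_values": {v: [float(x) for x in pvals.loc[v]] for v in pvals.index},
        "included": [r.included for r in rs.replicates],
    }
    paths["replicates_json"] = os.path.join(out_dir, "replicate_values.json")
    with open(paths["replicates_json"], "w") as fh:
        json.dump(record, fh, sort_keys=True, indent=1)
    return paths
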