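"""The replicate loop: perturb the exposure column, refit, check, collect.

One sensitivity analysis fits the model once to the observed data, then
runs ``n_sims`` replicates.  Each replicate replaces only the exposure
column with a perturbed copy (flips drawn per the PPV/NPV error
profile), re-estimates propensity weights when the model is weighted,
refits, and runs the assumption battery.  Replicates failing the checks
are retained in the record, flagged, and omitted only at summarization
so the exclusion rate stays auditable.

Seeding: a single master seed spawns one independent substream per
replicate via ``numpy.random.SeedSequence``; every replicate records the
integer seed of its substream, so any single replicate can be re-run in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .error_model import ErrorProfile, FlipPlan, compute_flip_counts, perturb_calls
from .fitting import AssumptionReport, FitResult, ModelSpec, check_assumptions, fit_model

__all__ = ["Replicate", "ReplicateSet", "run_sensitivity_analysis", "replicate_estimate_matrix"]


@dataclass
class Replicate:
    index: int
    seed: int
    fit: FitResult
    assumptions: AssumptionReport
    flip_plan: FlipPlan

    @property
    def included(self) -> bool:
        return self.fit.converged and self.assumptions.passed

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "seed": self.seed,
            "fit": self.fit.to_dict(),
            "assumptions": self.assumptions.to_dict(),
            "flip_plan": dataclasses.asdict(self.flip_plan),
            "included": self.included,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Replicate":
        return cls(
            index=d["index"],
            seed=d["seed"],
            fit=FitResult.from_dict(d["fit"]),
            assumptions=AssumptionReport.from_dict(d["assumptions"]),
            flip_plan=FlipPlan(**d["flip_plan"]),
        )


@dataclass
class ReplicateSet:
    """Original fit plus the full replicate record of one analysis."""

    original_fit: FitResult
    replicates: list[Replicate]
    n_requested: int
    master_seed: int
    profile: ErrorProfile
    alpha: float = 0.05
    family: str = ""
    exposure: str = ""
    confounders: list[str] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return sum(r.included for r in self.replicates)

    @property
    def n_excluded(self) -> int:
        return self.n_requested - self.n_included

    def included_replicates(self) -> list[Replicate]:
        return [r for r in self.replicates if r.included]

    @property
    def variables(self) -> list[str]:
        return list(self.original_fit.params.index)

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "n_requested": self.n_requested,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "profile": {"ppv": self.profile.ppv, "npv": self.profile.npv},
            "alpha": self.alpha,
            "family": self.family,
            "exposure": self.exposure,
            "confounders": list(self.confounders),
            "original_fit": self.original_fit.to_dict(),
            "replicates": [r.to_dict() for r in self.replicates],
        }

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=indent)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json(indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "ReplicateSet":
        return cls(
            original_fit=FitResult.from_dict(d["original_fit"]),
            replicates=[Replicate.from_dict(r) for r in d["replicates"]],
            n_requested=d["n_requested"],
            master_seed=d["master_seed"],
            profile=ErrorProfile(**d["profile"]),
            alpha=d.get("alpha", 0.05),
            family=d.get("family", ""),
            exposure=d.get("exposure", ""),
            confounders=list(d.get("confounders", [])),
        )

    @classmethod
    def load(cls, path) -> "ReplicateSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def run_sensitivity_analysis(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    profile: ErrorProfile,
    n_sims: int = 500,
    master_seed: int = 0,
    rounding: str = "nearest",
) -> ReplicateSet:
    """Run the full perturb → refit → check loop.

    The default of 500 replicates matches common practice for this kind
    of Monte Carlo error propagation.  Replicates are executed
    sequentially; results depend only on each replicate's own substream,
    never on execution order.
    """
    spec.validate(cohort)
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    original_fit = fit_model(cohort, spec)
    if not original_fit.converged:
        raise RuntimeError(
            "original model fit did not converge; nothing to compare replicates against"
        )
    observed = cohort[spec.exposure].to_numpy()
    n_pos = int(observed.sum())
    n_neg = int(observed.size - n_pos)
    children = np.random.SeedSequence(master_seed).spawn(n_sims)
    replicates: list[Replicate] = []
    for i in range(n_sims):
        sub_seed = int(children[i].generate_state(1, dtype=np.uint32)[0])
        rng = np.random.default_rng(sub_seed)
        plan = compute_flip_counts(n_pos, n_neg, profile, rounding=rounding, rng=rng)
        perturbed = perturb_calls(observed, profile, rng, plan=plan)
        fit = fit_model(cohort, spec, exposure_override=perturbed)
        report = check_assumptions(fit, cohort, spec)
        replicates.append(
            Replicate(index=i, seed=sub_seed, fit=fit, assumptions=report, flip_plan=plan)
        )
    return ReplicateSet(
        original_fit=original_fit,
        replicates=replicates,
        n_requested=n_sims,
        master_seed=master_seed,
        profile=profile,
        alpha=spec.alpha,
        family=spec.family,
        exposure=spec.exposure,
        confounders=list(spec.confounders),
    )


def replicate_estimate_matrix(
    rs: ReplicateSet, included_only: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variable x replicate tables of native estimates and p-values.

    Returns ``(estimates, p_values)``; columns are replicate indices,
    rows are model variables.  With ``included_only`` the excluded
    replicates are dropped.
    """
    reps = rs.included_replicates() if included_only else rs.replicates
    cols = [r.index for r in reps]
    est = pd.DataFrame(
        {r.index: r.fit.params["native_estimate"] for r in reps},
        index=rs.original_fit.params.index,
        columns=cols,
    )
    pvals = pd.DataFrame(
        {r.index: r.fit.params["p_value"] for r in reps},
        index=rs.original_fit.params.index,
        columns=cols,
    )
    est.index.name = pvals.index.name = "variable"
    return est, pvals
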