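"""YAML configuration for the command-line pipeline.

Two documents are understood: a cohort spec (consumed by ``simulate``)
and a run config (consumed by ``run``).  Validation is by explicit field
checks that raise ``ValueError`` naming every offending field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .cohort import CohortSpec, ConfounderSpec
from .error_model import ErrorProfile
from .fitting import ModelSpec

__all__ = ["RunConfig", "load_cohort_spec", "load_run_config"]


def _load_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping at the top level")
    return doc


def _reject_unknown(doc: dict, allowed: set[str], where: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown fields {sorted(unknown)}")


def cohort_spec_from_dict(doc: dict) -> CohortSpec:
    allowed = {
        "n_subjects", "outcome_family", "true_exposure_effect", "baseline",
        "exposure_prevalence", "confounders", "censoring_rate", "visits_per_subject",
        "random_intercept_sd", "residual_sd", "sensitivity", "specificity",
        "exposure_confounding", "seed",
    }
    _reject_unknown(doc, allowed, "cohort spec")
    doc = dict(doc)
    confs = []
    for i, c in enumerate(doc.pop("confounders", []) or []):
        for key in ("name", "dist", "params"):
            if key not in c:
                raise ValueError(f"cohort spec: confounders[{i}] missing field {key!r}")
        confs.append(
            ConfounderSpec(
                name=c["name"],
                dist=c["dist"],
                params=tuple(c["params"]),
                effect=float(c.get("effect", 0.0)),
            )
        )
    try:
        spec = CohortSpec(confounders=confs, **doc)
    except TypeError as exc:
        raise ValueError(f"cohort spec: {exc}")
    spec.validate()
    return spec


def load_cohort_spec(path) -> CohortSpec:
    return cohort_spec_from_dict(_load_yaml(path))


@dataclass
class RunConfig:
    """Everything one sensitivity-analysis run needs."""

    cohort_path: str
    model: ModelSpec
    profile: ErrorProfile
    n_sims: int = 500
    master_seed: int = 0
    rounding: str = "nearest"
    make_figures: bool = True
    figure_variables: list[str] | None = field(default=None)


def run_config_from_dict(doc: dict, base_dir: str = ".") -> RunConfig:
    allowed = {
        "cohort", "model", "error_profile", "n_sims", "master_seed",
        "rounding", "make_figures", "figure_variables",
    }
    _reject_unknown(doc, allowed, "run config")
    bad = [k for k in ("cohort", "model", "error_profile") if k not in doc]
    if bad:
        raise ValueError(f"run config: missing required fields {bad}")
    cohort_path = doc["cohort"]
    if not os.path.isabs(cohort_path):
        cohort_path = os.path.join(base_dir, cohort_path)
    if not os.path.exists(cohort_path):
        raise ValueError(f"run config: cohort file not found: {cohort_path}")
    m = dict(doc["model"])
    allowed_model = {
        "family", "exposure", "confounders", "time_col", "event_col",
        "outcome_col", "measure_col", "group", "weighting",
        "stabilized_weights", "alpha",
    }
    _reject_unknown(m, allowed_model, "run config: model")
    for key in ("family", "exposure"):
        if key not in m:
            raise ValueError(f"run config: model missing field {key!r}")
    model = ModelSpec(**m)
    ep = dict(doc["error_profile"])
    _reject_unknown(ep, {"ppv", "npv"}, "run config: error_profile")
    profile = ErrorProfile(**ep)
    n_sims = int(doc.get("n_sims", 500))
    if n_sims < 1:
        raise ValueError(f"run config: n_sims={n_sims} (need >= 1)")
    return RunConfig(
        cohort_path=cohort_path,
        model=model,
        profile=profile,
        n_sims=n_sims,
        master_seed=int(doc.get("master_seed", 0)),
        rounding=doc.get("rounding", "nearest"),
        make_figures=bool(doc.get("make_figures", True)),
        figure_variables=doc.get("figure_variables"),
    )


def load_run_config(path) -> RunConfig:
    return run_config_from_dict(_load_yaml(path), base_dir=os.path.dirname(os.path.abspath(path)))
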