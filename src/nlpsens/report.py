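"""Boxplot reports of replicate estimates against the original fit.

Each figure shows one box per variable over the included replicates'
native estimates, with a dashed horizontal line at the original point
estimate.  Every figure ships with a sidecar CSV of the plotted values
so its claims are checkable without image comparison.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .monte_carlo import ReplicateSet, replicate_estimate_matrix

__all__ = ["make_boxplot"]


def make_boxplot(
    rs: ReplicateSet,
    variables: list[str] | None = None,
    out_base: str = "replicate_boxplot",
    title: str | None = None,
) -> dict:
    """Write ``<out_base>.png``, ``<out_base>.svg`` and the sidecar
    ``<out_base>.csv``; returns the paths and the plotted data."""
    if variables is None:
        variables = rs.variables
    unknown = [v for v in variables if v not in rs.variables]
    if unknown:
        raise KeyError(f"unknown variables: {unknown}")
    est, _ = replicate_estimate_matrix(rs, included_only=True)
    data = est.loc[variables]
    originals = [rs.original_fit.native_estimate(v) for v in variables]

    fig, ax = plt.subplots(figsize=(1.6 + 1.1 * len(variables), 4.5))
    ax.boxplot([data.loc[v].to_numpy() for v in variables], tick_labels=variables)
    for i, orig in enumerate(originals, start=1):
        ax.hlines(orig, i - 0.35, i + 0.35, colors="tab:red", linestyles="dashed")
    ax.set_ylabel(
        {"cox": "hazard ratio", "logistic": "odds ratio"}.get(rs.family, "estimate")
    )
    ax.set_title(title or f"Replicate estimates vs original ({rs.n_included} included)")
    fig.tight_layout()

    out_dir = os.path.dirname(out_base)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    paths = {"png": out_base + ".png", "svg": out_base + ".svg", "csv": out_base + ".csv"}
    fig.savefig(paths["png"], dpi=150)
    fig.savefig(paths["svg"])
    plt.close(fig)

    sidecar = data.copy()
    sidecar.insert(0, "original_estimate", originals)
    sidecar.to_csv(paths["csv"])
    paths["data"] = data
    return paths
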