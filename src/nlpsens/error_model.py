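"""Semi-synthetic perturbation of binary NLP-derived calls.

An NLP tool that extracts a binary variable from clinical text has a
positive predictive value (PPV = TP / positive calls) and a negative
predictive value (NPV = TN / negative calls).  Given only the observed
calls and an (PPV, NPV) error profile, a plausible "truth" vector is
obtained by flipping ``N_P * (1 - PPV)`` randomly chosen positive calls
to negative and ``N_N * (1 - NPV)`` randomly chosen negative calls to
positive.  Repeating this under many random seeds yields the replicate
exposure vectors driving the downstream sensitivity analysis.

All functions here operate on in-memory vectors; cohort I/O lives in
:mod:`nlpsens.cohort` and :mod:`nlpsens.cli`.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorProfile",
    "FlipPlan",
    "ConfusionSummary",
    "compute_flip_counts",
    "perturb_calls",
    "realized_confusion",
]


@dataclass(frozen=True)
class ErrorProfile:
    """PPV/NPV of a binary classifier, each in (0, 1].

    Profiles with ppv or npv equal to 0 are rejected: the perturbation
    scheme presumes mostly-correct calls (flipping *all* positives is a
    different experiment, not an error model).
    """

    ppv: float
    npv: float

    def __post_init__(self) -> None:
        for name in ("ppv", "npv"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")


@dataclass(frozen=True)
class FlipPlan:
    """How many positive calls to flip negative and vice versa."""

    k_pos_to_neg: int
    k_neg_to_pos: int

    def __post_init__(self) -> None:
        if self.k_pos_to_neg < 0 or self.k_neg_to_pos < 0:
            raise ValueError("flip counts must be non-negative")

    @property
    def total(self) -> int:
        return self.k_pos_to_neg + self.k_neg_to_pos


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts and the derived rates.

    Rates whose denominator is zero are reported as ``nan``, never 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @staticmethod
    def _rate(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    @property
    def ppv(self) -> float:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._rate(self.tn, self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._rate(self.tn, self.tn + self.fp)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.update(
            ppv=self.ppv,
            npv=self.npv,
            sensitivity=self.sensitivity,
            specificity=self.specificity,
        )
        return d


def _round_count(x: float, rounding: str, rng: np.random.Generator | None) -> int:
    # Snap float noise (e.g. 100 * (1 - 0.95) = 5.000000000000004) before
    # applying the tie rule.
    x = round(x, 9)
    if rounding == "nearest":
        # Nearest integer, ties away from zero (x is always >= 0 here).
        return int(math.floor(x + 0.5))
    if rounding == "stochastic":
        if rng is None:
            raise ValueError("stochastic rounding requires an rng")
        lo = math.floor(x)
        frac = x - lo
        return int(lo + (rng.random() < frac))
    raise ValueError(f"unknown rounding rule {rounding!r}")


def compute_flip_counts(
    n_pos: int,
    n_neg: int,
    profile: ErrorProfile,
    rounding: str = "nearest",
    rng: np.random.Generator | None = None,
) -> FlipPlan:
    """Number of calls to flip in each direction.

    ``k_pos_to_neg = round(n_pos * (1 - ppv))`` and
    ``k_neg_to_pos = round(n_neg * (1 - npv))``.

    Parameters
    ----------
    rounding
        ``"nearest"`` (default): nearest integer, ties away from zero —
        deterministic, error below one subject.  ``"stochastic"``: floor
        plus a Bernoulli draw on the fractional part, which preserves the
        expected flip count exactly (requires ``rng``).
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("call counts must be non-negative")
    k_p = _round_count(n_pos * (1.0 - profile.ppv), rounding, rng)
    k_n = _round_count(n_neg * (1.0 - profile.npv), rounding, rng)
    # Cannot exceed the bounds for a valid profile; guard anyway.
    if k_p > n_pos or k_n > n_neg:
        logger.warning(
            "flip counts (%d, %d) clamped to bounds (%d, %d)", k_p, k_n, n_pos, n_neg
        )
        k_p, k_n = min(k_p, n_pos), min(k_n, n_neg)
    return FlipPlan(k_pos_to_neg=k_p, k_neg_to_pos=k_n)


def _as_array(calls) -> tuple[np.ndarray, object]:
    """Validate a binary call vector; return (int array, original container)."""
    if isinstance(calls, pd.Series):
        if calls.index.has_duplicates:
            raise ValueError("subject ids must be unique")
        values = calls.to_numpy()
    else:
        values = np.asarray(calls)
    if values.size == 0:
        raise ValueError("empty call vector: degenerate cohort")
    arr = values.astype(np.int64, copy=True)
    if not np.isin(arr, (0, 1)).all() or not np.array_equal(arr, values):
        raise ValueError("calls must be exactly 0 or 1")
    return arr, calls


def perturb_calls(
    calls,
    profile: ErrorProfile,
    seed: int | np.random.Generator,
    rounding: str = "nearest",
    plan: FlipPlan | None = None,
) -> np.ndarray | pd.Series:
    """Flip observed calls per the error profile; deterministic given seed.

    Exactly ``k_pos_to_neg`` of the 1s and ``k_neg_to_pos`` of the 0s are
    flipped, each subset chosen uniformly without replacement.  Accepts a
    numpy array or a pandas Series indexed by subject id and returns the
    same container type.  A precomputed ``plan`` may be supplied (used by
    the replicate loop so the recorded plan and the applied flips always
    agree under stochastic rounding).
    """
    arr, original = _as_array(calls)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pos_idx = np.flatnonzero(arr == 1)
    neg_idx = np.flatnonzero(arr == 0)
    if plan is None:
        plan = compute_flip_counts(pos_idx.size, neg_idx.size, profile, rounding, rng)
    elif plan.k_pos_to_neg > pos_idx.size or plan.k_neg_to_pos > neg_idx.size:
        raise ValueError("flip plan exceeds available calls")
    out = arr.copy()
    if plan.k_pos_to_neg:
        out[rng.choice(pos_idx, size=plan.k_pos_to_neg, replace=False)] = 0
    if plan.k_neg_to_pos:
        out[rng.choice(neg_idx, size=plan.k_neg_to_pos, replace=False)] = 1
    if isinstance(original, pd.Series):
        return pd.Series(out, index=original.index, name=original.name)
    return out


def realized_confusion(truth, calls) -> ConfusionSummary:
    """Cross-tabulate a truth vector against observed calls.

    Both vectors must be aligned: pandas Series must share an index,
    arrays must have equal length.
    """
    t_arr, t_orig = _as_array(truth)
    c_arr, c_orig = _as_array(calls)
    if t_arr.shape != c_arr.shape:
        raise ValueError("truth and calls differ in length")
    if isinstance(t_orig, pd.Series) and isinstance(c_orig, pd.Series):
        if not t_orig.index.equals(c_orig.index):
            raise ValueError("truth and calls have mismatched subject ids")
    tp = int(np.sum((t_arr == 1) & (c_arr == 1)))
    fp = int(np.sum((t_arr == 0) & (c_arr == 1)))
    fn = int(np.sum((t_arr == 1) & (c_arr == 0)))
    tn = int(np.sum((t_arr == 0) & (c_arr == 0)))
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)
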