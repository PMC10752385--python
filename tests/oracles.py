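"""Independent oracles used by the tests.

These are deliberately naive computations (closed forms, brute-force
enumeration) kept separate from the package code paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def expected_or_under_flips(a, y, k_pos_to_neg: int, k_neg_to_pos: int) -> float:
    """Exact E[odds ratio] of the exposure/outcome 2x2 table after
    flipping ``k_pos_to_neg`` uniformly chosen exposed calls and
    ``k_neg_to_pos`` unexposed calls, by brute-force enumeration over
    the two hypergeometric flip-count distributions.

    With the exposure as sole covariate the logistic MLE of the OR is
    the sample cross-product ratio of the table, so this is the exact
    expectation of the per-replicate estimate.
    """
    a = np.asarray(a)
    y = np.asarray(y)
    n_p = int(np.sum(a == 1))
    n_n = int(np.sum(a == 0))
    a1 = int(np.sum((a == 1) & (y == 1)))  # exposed with outcome
    b1 = int(np.sum((a == 0) & (y == 1)))  # unexposed with outcome
    a0, b0 = n_p - a1, n_n - b1

    # i exposed-with-outcome calls flipped to unexposed; j the reverse
    hp = stats.hypergeom(n_p, a1, k_pos_to_neg)
    hn = stats.hypergeom(n_n, b1, k_neg_to_pos)
    total = 0.0
    for i in range(max(0, k_pos_to_neg - a0), min(a1, k_pos_to_neg) + 1):
        pi = hp.pmf(i)
        for j in range(max(0, k_neg_to_pos - b0), min(b1, k_neg_to_pos) + 1):
            pj = hn.pmf(j)
            e1 = a1 - i + j
            e0 = a0 - (k_pos_to_neg - i) + (k_neg_to_pos - j)
            u1 = b1 + i - j
            u0 = b0 + (k_pos_to_neg - i) - (k_neg_to_pos - j)
            if min(e1, e0, u1, u0) <= 0:
                # degenerate table: the MLE does not exist; with the
                # cohort sizes used in the tests these cells carry
                # negligible probability and are skipped
                continue
            total += pi * pj * (e1 * u0) / (e0 * u1)
    return total


def ppv_from_bayes(prevalence: float, sensitivity: float, specificity: float) -> float:
    tp = prevalence * sensitivity
    fp = (1 - prevalence) * (1 - specificity)
    return tp / (tp + fp)


def npv_from_bayes(prevalence: float, sensitivity: float, specificity: float) -> float:
    tn = (1 - prevalence) * specificity
    fn = prevalence * (1 - sensitivity)
    return tn / (tn + fn)


def or_from_2x2(n11: int, n10: int, n01: int, n00: int) -> float:
    """Cross-product ratio: (exposed-event * unexposed-nonevent) /
    (exposed-nonevent * unexposed-event)."""
    return (n11 * n00) / (n10 * n01)


def anova_icc(measure: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA (method-of-moments) intraclass correlation."""
    import pandas as pd

    df = pd.DataFrame({"y": measure, "g": groups})
    k = df.groupby("g").size()
    if k.nunique() != 1:
        raise ValueError("balanced design required")
    m = int(k.iloc[0])
    n = len(k)
    group_means = df.groupby("g")["y"].mean()
    grand = df["y"].mean()
    msb = m * np.sum((group_means - grand) ** 2) / (n - 1)
    msw = np.sum((df["y"] - df["g"].map(group_means)) ** 2) / (n * (m - 1))
    var_b = (msb - msw) / m
    return var_b / (var_b + msw)
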