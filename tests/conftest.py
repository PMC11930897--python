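"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (explicit pair loops, textbook
ANOVA sums) and independent of the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from clungrads.simulate import CalibrationTarget
from clungrads.stratify import SystemId


# Published confusion cells of the three systems on the two study sets.
# The Lung-RADS v2022 training column sums to 168 as printed.
STUDY_CELLS = {
    ("training", SystemId.LUNGRADS10): (9, 1, 129, 30),
    ("training", SystemId.LUNGRADS2022): (3, 0, 135, 30),
    ("training", SystemId.CLUNGRADS2022): (131, 14, 7, 17),
    ("validation", SystemId.LUNGRADS10): (27, 2, 256, 118),
    ("validation", SystemId.LUNGRADS2022): (5, 0, 278, 120),
    ("validation", SystemId.CLUNGRADS2022): (257, 53, 26, 67),
}


def target_for(set_name: str, system: SystemId) -> CalibrationTarget:
    tp, fp, fn, tn = STUDY_CELLS[(set_name, system)]
    return CalibrationTarget(system, tp, fp, fn, tn, tp + fp + fn + tn)


def brute_auc(scores, labels) -> float:
    """O(m*n) pairwise Mann-Whitney AUC with 0.5 credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def naive_delong(scores_a, scores_b, labels):
    """Textbook DeLong with explicit double loops over placement values.

    Returns (auc_a, auc_b, var_diff).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)

    def psi(x, yv):
        return 1.0 if x > yv else (0.5 if x == yv else 0.0)

    def components(s):
        pos = s[y]
        neg = s[~y]
        m, n = pos.size, neg.size
        v10 = np.array([np.mean([psi(p, q) for q in neg]) for p in pos])
        v01 = np.array([np.mean([psi(p, q) for p in pos]) for q in neg])
        return v10, v01

    v10a, v01a = components(sa)
    v10b, v01b = components(sb)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = v10a.size, v01a.size

    def cov(u, v):
        return np.sum((u - u.mean()) * (v - v.mean())) / (u.size - 1)

    s10aa, s10bb, s10ab = cov(v10a, v10a), cov(v10b, v10b), cov(v10a, v10b)
    s01aa, s01bb, s01ab = cov(v01a, v01a), cov(v01b, v01b), cov(v01a, v01b)
    var_a = s10aa / m + s01aa / n
    var_b = s10bb / m + s01bb / n
    cov_ab = s10ab / m + s01ab / n
    return float(auc_a), float(auc_b), float(var_a + var_b - 2 * cov_ab)


def anova_icc21(ratings) -> float:
    """ICC(2,1) from explicit two-way ANOVA sums (independent of the
    package implementation)."""
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = (
        np.sum((x - grand) ** 2)
        - k * np.sum((x.mean(axis=1) - grand) ** 2)
        - n * np.sum((x.mean(axis=0) - grand) ** 2)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240314)
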