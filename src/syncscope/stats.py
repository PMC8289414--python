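"""Statistical decision tree, ROUT outlier detection and a validation suite.

The decision tree for two-group comparisons:

1. Shapiro-Wilk on each group (alpha 0.05).
2. If both groups pass, an F-test compares variances (two-sided,
   alpha 0.05): equal variance -> Student's t, unequal -> Welch's t.
3. If either group fails normality -> Mann-Whitney U.

All tests are two-sided and routing depends only on the gate p-values,
so permuting the order of observations cannot change the test chosen.

ROUT (robust outlier removal at false-discovery rate Q) is applied to a
constant-only model: the robust location is the median, the robust
scale is the RSDR (68.27th percentile of absolute residuals with the
small-sample correction n / (n - 1)), and residual t-scores are tested
largest-first with a Benjamini-Hochberg style threshold at rate Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .errors import InputError

ALPHA = 0.05
ROUT_Q_DEFAULT = 0.001  # Q = 0.1%


@dataclass
class TestReport:
    """Outcome of a routed two-group comparison."""

    test_used: str  # "student_t" | "welch_t" | "mann_whitney"
    normality_p: tuple[float, float]
    variance_p: Optional[float]
    statistic: float
    p_value: float
    n: tuple[int, int]
    outliers_flagged: list[int] = field(default_factory=list)
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def f_test_equal_variance(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F-test p-value for equality of two sample variances."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx >= vy:
        f, dfn, dfd = vx / vy, len(x) - 1, len(y) - 1
    else:
        f, dfn, dfd = vy / vx, len(y) - 1, len(x) - 1
    return float(min(1.0, 2.0 * sps.f.sf(f, dfn, dfd)))


def choose_and_run(x, y, alpha: float = ALPHA) -> TestReport:
    """Route a two-group comparison through the normality/variance gates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise InputError("need at least 3 observations per group")
    px = float(sps.shapiro(x).pvalue)
    py = float(sps.shapiro(y).pvalue)
    if px >= alpha and py >= alpha:
        pv = f_test_equal_variance(x, y)
        if pv >= alpha:
            res = sps.ttest_ind(x, y, equal_var=True)
            used = "student_t"
        else:
            res = sps.ttest_ind(x, y, equal_var=False)
            used = "welch_t"
        return TestReport(
            test_used=used,
            normality_p=(px, py),
            variance_p=pv,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=(len(x), len(y)),
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestReport(
        test_used="mann_whitney",
        normality_p=(px, py),
        variance_p=None,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(x), len(y)),
    )


def robust_scale_rsdr(residuals: np.ndarray, n_params: int = 1) -> float:
    """Robust standard deviation of residuals: corrected 68.27th percentile."""
    n = len(residuals)
    p68 = np.percentile(np.abs(residuals), 68.27)
    return float(p68 * n / (n - n_params))


def rout_outliers(x, q: float = ROUT_Q_DEFAULT) -> np.ndarray:
    """Indices of observations flagged as outliers at FDR rate Q.

    A constant-only robust fit: residuals are taken from the median,
    scaled by the RSDR, converted to two-sided t-tail p-values with
    n - 1 degrees of freedom, and tested largest residual first: the
    i-th largest is flagged (together with all larger ones) when its
    p-value falls below ``Q * i / n``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise InputError("ROUT needs at least 5 observations")
    residuals = x - np.median(x)
    scale = robust_scale_rsdr(residuals)
    if scale == 0:
        return np.array([], dtype=int)
    t = np.abs(residuals) / scale
    p = 2.0 * sps.t.sf(t, df=n - 1)
    order = np.argsort(p, kind="stable")  # most extreme first
    flagged_upto = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] < q * i / n:
            flagged_upto = i
    return np.sort(order[:flagged_upto])


def remove_outliers(x, q: float = ROUT_Q_DEFAULT) -> tuple[np.ndarray, np.ndarray]:
    """(cleaned sample, flagged indices)."""
    x = np.asarray(x, dtype=float)
    flags = rout_outliers(x, q=q)
    keep = np.ones(len(x), dtype=bool)
    keep[flags] = False
    return x[keep], flags


def compare_with_outlier_removal(x, y, q: float = ROUT_Q_DEFAULT) -> TestReport:
    """Decision-tree comparison re-run after ROUT flagging in each group."""
    xc, fx = remove_outliers(x, q=q)
    yc, fy = remove_outliers(y, q=q)
    report = choose_and_run(xc, yc)
    report.outliers_flagged = sorted(fx.tolist()) + [len(np.asarray(x)) + i for i in fy]
    return report


def typeI_power_suite(
    effect: float,
    n: int,
    reps: int,
    seed: int,
    noise: str = "normal",
) -> tuple[float, float]:
    """Empirical type-I error and power of the decision tree.

    Simulates ``reps`` pairs of samples of size ``n`` — a null pair and
    a pair shifted by ``effect`` (in units of the noise sd) — routes
    each through :func:`choose_and_run` and reports the rejection rates
    at alpha 0.05.  ``noise`` may be "normal" or "exponential".
    """
    if reps < 100:
        raise InputError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    null_rej = alt_rej = 0
    for _ in range(reps):
        if noise == "normal":
            a, b = rng.normal(size=n), rng.normal(size=n)
        elif noise == "exponential":
            a, b = rng.exponential(size=n) - 1.0, rng.exponential(size=n) - 1.0
        else:
            raise InputError(f"unknown noise model {noise!r}")
        if choose_and_run(a, b).significant:
            null_rej += 1
        if choose_and_run(a, b + effect).significant:
            alt_rej += 1
    return null_rej / reps, alt_rej / reps
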