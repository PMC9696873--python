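"""Relative and absolute reliability statistics on a score matrix.

Relative reliability is the intraclass correlation under the two-way model
with the absolute-agreement definition: ICC(A,1) for single scores (Hv/Lv
rules) and ICC(A,k) for session averages (Avg rule), with F-based 95%
confidence intervals (McGraw & Wong, 1996) and the Koo & Li qualitative
classification (poor < 0.50 <= moderate <= 0.75 < good <= 0.90 < excellent).

Absolute reliability is the within-subject coefficient of variation:
each subject's SD across sessions divided by their mean, averaged over
subjects, in percent.

Systematic bias between sessions (e.g. a learning effect) is tested with a
one-within-factor repeated-measures ANOVA on session, F = MSC/MSE.
Distributional gates (Shapiro-Wilk normality per session, Levene
homogeneity across sessions) are advisory: they are reported and logged but
never abort the analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .aggregation import AggregationRule, ScoreMatrix
from .datamodel import UndefinedStatisticError, Variable

logger = logging.getLogger("retestkit")

DEFAULT_ALPHA = 0.05

#: Relative tolerance (on the squared data scale) below which a mean square
#: is treated as exactly zero.
_ZERO_RTOL = 1e-12


# ---------------------------------------------------------------------------
# ANOVA decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanSquares:
    """Two-way (subjects x sessions) mean squares of a complete matrix."""

    msr: float  # between-subject (rows)
    msc: float  # between-session (columns)
    mse: float  # residual
    n: int
    k: int
    grand_mean: float

    @property
    def df_r(self) -> int:
        return self.n - 1

    @property
    def df_c(self) -> int:
        return self.k - 1

    @property
    def df_e(self) -> int:
        return (self.n - 1) * (self.k - 1)


def mean_squares(Y: ScoreMatrix | np.ndarray) -> MeanSquares:
    """Decompose a complete n x k matrix into row, column and residual MS.

    MSR = k * sum_i (ybar_i - ybar)^2 / (n-1), MSC analogous over columns,
    MSE = residual SS / ((n-1)(k-1)); SSR + SSC + SSE reproduces the total
    SS to numerical tolerance.
    """
    vals = Y.values if isinstance(Y, ScoreMatrix) else np.asarray(Y, dtype=float)
    n, k = vals.shape
    if n < 2 or k < 2:
        raise UndefinedStatisticError("mean squares need at least a 2 x 2 matrix")
    gm = vals.mean()
    row_means = vals.mean(axis=1)
    col_means = vals.mean(axis=0)
    msr = k * np.sum((row_means - gm) ** 2) / (n - 1)
    msc = n * np.sum((col_means - gm) ** 2) / (k - 1)
    resid = vals - row_means[:, None] - col_means[None, :] + gm
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    if msr == 0 and msc == 0 and mse == 0:
        logger.warning("degenerate matrix: all cells identical")
    return MeanSquares(float(msr), float(msc), float(mse), n, k, float(gm))


def _is_zero(ms_value: float, scale: float) -> bool:
    return ms_value <= _ZERO_RTOL * max(1.0, scale)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

Classification = Literal["poor", "moderate", "good", "excellent"]


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    form: Literal["single", "mean"]
    alpha: float
    classification: Classification
    n: int
    k: int


def classify_icc(estimate: float) -> Classification:
    """Koo & Li bands; 0.50 and 0.75 close their upper class, 0.90 does not."""
    if estimate < 0.50:
        return "poor"
    if estimate <= 0.75:
        return "moderate"
    if estimate <= 0.90:
        return "good"
    return "excellent"


def _icc_single_ci(ms: MeanSquares, est: float, alpha: float) -> tuple[float, float]:
    """F-based CI for ICC(A,1) with Satterthwaite denominator df."""
    n, k = ms.n, ms.k
    msr, msc, mse = ms.msr, ms.msc, ms.mse
    if est >= 1.0:
        return 1.0, 1.0
    a = k * est / (n * (1.0 - est))
    b = 1.0 + k * est * (n - 1) / (n * (1.0 - est))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else float((n - 1) * (k - 1))
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    lower = (n * (msr - f_low * mse)
             / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr))
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    upper = (n * (f_up * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_up * msr))
    return float(lower), float(min(upper, 1.0))


def _check_not_degenerate(ms: MeanSquares) -> float:
    scale = max(abs(ms.grand_mean) ** 2, ms.msr, ms.msc, ms.mse)
    if _is_zero(ms.msr, scale) and _is_zero(ms.msc, scale) and _is_zero(ms.mse, scale):
        raise UndefinedStatisticError("ICC undefined: matrix has no variance at all")
    if ms.msr + ms.mse <= 0:
        raise UndefinedStatisticError("ICC undefined: msr + mse is zero")
    return scale


def icc_single(ms: MeanSquares, alpha: float = DEFAULT_ALPHA) -> ICCResult:
    """ICC(A,1): absolute agreement of single session scores.

    estimate = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    Estimates below zero are reported as computed, never clamped.
    """
    scale = _check_not_degenerate(ms)
    n, k = ms.n, ms.k
    est = (ms.msr - ms.mse) / (ms.msr + (k - 1) * ms.mse + (k / n) * (ms.msc - ms.mse))
    if _is_zero(ms.mse, scale) and _is_zero(ms.msc, scale):
        logger.info("perfect agreement: ICC = 1, CI collapses to [1, 1]")
        return ICCResult(1.0, 1.0, 1.0, "single", alpha, "excellent", n, k)
    lo, hi = _icc_single_ci(ms, est, alpha)
    return ICCResult(float(est), lo, hi, "single", alpha, classify_icc(est), n, k)


def _spearman_brown(icc1: float, k: int) -> float:
    return k * icc1 / (1.0 + (k - 1) * icc1)


def icc_mean(ms: MeanSquares, alpha: float = DEFAULT_ALPHA) -> ICCResult:
    """ICC(A,k): absolute agreement of k-session mean scores.

    estimate = (MSR - MSE) / (MSR + (MSC - MSE)/n); CI bounds are the
    single-score bounds stepped up with Spearman-Brown, L -> kL/(1+(k-1)L).
    """
    scale = _check_not_degenerate(ms)
    n, k = ms.n, ms.k
    est = (ms.msr - ms.mse) / (ms.msr + (ms.msc - ms.mse) / n)
    if _is_zero(ms.mse, scale) and _is_zero(ms.msc, scale):
        logger.info("perfect agreement: ICC = 1, CI collapses to [1, 1]")
        return ICCResult(1.0, 1.0, 1.0, "mean", alpha, "excellent", n, k)
    single_est = (ms.msr - ms.mse) / (
        ms.msr + (k - 1) * ms.mse + (k / n) * (ms.msc - ms.mse)
    )
    lo1, hi1 = _icc_single_ci(ms, single_est, alpha)
    lo, hi = _spearman_brown(lo1, k), _spearman_brown(hi1, k)
    return ICCResult(float(est), float(lo), float(hi), "mean", alpha,
                     classify_icc(est), n, k)


def icc_for_rule(ms: MeanSquares, rule: AggregationRule,
                 alpha: float = DEFAULT_ALPHA) -> ICCResult:
    """Mean-form ICC for session averages, single-form for best values."""
    if rule is AggregationRule.AVG:
        return icc_mean(ms, alpha)
    return icc_single(ms, alpha)


# ---------------------------------------------------------------------------
# Coefficient of variation
# ---------------------------------------------------------------------------

def cv_percent(Y: ScoreMatrix | np.ndarray,
               method: Literal["per_subject", "pooled"] = "per_subject") -> float:
    """Within-subject CV in percent.

    ``per_subject`` (default): each subject's sample SD across sessions over
    their own mean, averaged across subjects.  ``pooled``: the RMS-pooled
    within-subject SD over the grand mean, a common alternative in the
    reliability literature.
    """
    vals = Y.values if isinstance(Y, ScoreMatrix) else np.asarray(Y, dtype=float)
    means = vals.mean(axis=1)
    if (means <= 0).any():
        raise UndefinedStatisticError("CV undefined: a subject mean is <= 0")
    sds = vals.std(axis=1, ddof=1)
    if method == "per_subject":
        return float(np.mean(sds / means) * 100.0)
    if method == "pooled":
        return float(np.sqrt(np.mean(sds**2)) / vals.mean() * 100.0)
    raise ValueError(f"unknown CV method {method!r}")


# ---------------------------------------------------------------------------
# Systematic bias (repeated-measures ANOVA on session)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasTest:
    f_stat: float
    df1: int
    df2: int
    p_value: float
    significant: bool
    alpha: float
    degenerate: bool = False
    gg_epsilon: float | None = None


def rm_anova(Y: ScoreMatrix | np.ndarray, alpha: float = DEFAULT_ALPHA,
             gg_correction: bool = False) -> BiasTest:
    """Test for systematic session-to-session bias, F = MSC / MSE.

    With zero residual variance and a genuine column effect the F ratio is
    unbounded: reported as significant with p = 0 and flagged degenerate.
    For k = 2 the statistic equals the squared paired-t statistic.
    ``gg_correction`` applies the Greenhouse-Geisser sphericity adjustment
    to the p-value (off by default).
    """
    vals = Y.values if isinstance(Y, ScoreMatrix) else np.asarray(Y, dtype=float)
    ms = mean_squares(vals)
    scale = max(abs(ms.grand_mean) ** 2, ms.msr, ms.msc, ms.mse)
    df1, df2 = ms.df_c, ms.df_e
    if _is_zero(ms.msc, scale):
        return BiasTest(0.0, df1, df2, 1.0, False, alpha,
                        degenerate=_is_zero(ms.mse, scale))
    if _is_zero(ms.mse, scale):
        logger.warning("degenerate rmANOVA: zero residual variance with a "
                       "session effect; reporting p = 0")
        return BiasTest(math.inf, df1, df2, 0.0, True, alpha, degenerate=True)
    f = ms.msc / ms.mse
    eps = None
    if gg_correction and ms.k > 2:
        eps = _gg_epsilon(vals)
        p = float(stats.f.sf(f, df1 * eps, df2 * eps))
    else:
        p = float(stats.f.sf(f, df1, df2))
    return BiasTest(float(f), df1, df2, p, p < alpha, alpha, gg_epsilon=eps)


def _gg_epsilon(vals: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the session covariance matrix."""
    k = vals.shape[1]
    S = np.cov(vals, rowvar=False, ddof=1)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2)
                     + k**2 * mean_all**2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# Distributional gates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateResult:
    test: Literal["shapiro_wilk", "levene"]
    statistic: float
    p_value: float
    passed: bool
    alpha: float
    column: str | None = None


def distribution_gates(
    Y: ScoreMatrix,
    alpha: float = DEFAULT_ALPHA,
    levene_center: Literal["mean", "median"] = "mean",
) -> list[GateResult]:
    """Shapiro-Wilk per session column plus Levene across columns.

    Advisory only: failures are logged, never raised.  Normality gates are
    skipped (with a warning) for n < 3 where the test is undefined.
    """
    out: list[GateResult] = []
    vals = Y.values
    if vals.shape[0] >= 3:
        for j, sess in enumerate(Y.sessions):
            col = vals[:, j]
            if np.ptp(col) == 0:
                logger.warning("normality gate skipped for constant column %s", sess)
                continue
            w, p = stats.shapiro(col)
            out.append(GateResult("shapiro_wilk", float(w), float(p),
                                  p >= alpha, alpha, column=sess))
    else:
        logger.warning("normality gate skipped: fewer than 3 subjects")
    stat, p = stats.levene(*[vals[:, j] for j in range(vals.shape[1])],
                           center=levene_center)
    if not np.isfinite(stat):  # identical columns
        stat, p = 0.0, 1.0
    out.append(GateResult("levene", float(stat), float(p), p >= alpha, alpha))
    for g in out:
        if not g.passed:
            logger.warning("distribution gate failed: %s p=%.4g (column=%s)",
                           g.test, g.p_value, g.column)
    return out


# ---------------------------------------------------------------------------
# Composite per-comparison result
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReliabilityResult:
    """All reliability outputs for one variable x rule x session comparison."""

    variable: Variable
    rule: AggregationRule
    comparison: tuple[str, ...]
    label: str
    icc: ICCResult
    cv_pct: float
    bias: BiasTest
    session_means: tuple[float, ...]
    session_sds: tuple[float, ...]
    n_subjects: int


def analyze_reliability(
    Y: ScoreMatrix,
    label: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    cv_method: Literal["per_subject", "pooled"] = "per_subject",
) -> ReliabilityResult:
    """ICC (form matched to the rule), CV% and bias test for one matrix."""
    ms = mean_squares(Y)
    icc = icc_for_rule(ms, Y.rule, alpha)
    return ReliabilityResult(
        variable=Y.variable,
        rule=Y.rule,
        comparison=tuple(Y.sessions),
        label=label or "-".join(Y.sessions),
        icc=icc,
        cv_pct=cv_percent(Y, method=cv_method),
        bias=rm_anova(Y, alpha),
        session_means=tuple(Y.values.mean(axis=0).tolist()),
        session_sds=tuple(Y.values.std(axis=0, ddof=1).tolist()),
        n_subjects=Y.n,
    )
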