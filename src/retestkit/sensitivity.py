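"""The sensitivity chain: SEm -> SWC -> MD.

A test is useful for monitoring change only if its measurement noise floor
(the standard error of measurement, SEm = SD_pooled * sqrt(1 - ICC)) sits
below the smallest practically meaningful change (SWC = 0.2 * SD_pooled,
the "small" standardized effect).  The minimal difference
MD = SEm * 1.96 * sqrt(2) is the observed change required to exceed
measurement error with 95% confidence; SEm% and MD% express both relative
to the pooled mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .aggregation import AggregationRule, ScoreMatrix
from .datamodel import UndefinedStatisticError, Variable
from .reliability import ICCResult

#: MD / SEm = 1.96 * sqrt(2), the 95% two-measurement error multiplier.
MD_FACTOR = 1.96 * math.sqrt(2.0)

DEFAULT_SWC_MULTIPLIER = 0.2


@dataclass(frozen=True)
class PooledMoments:
    sd_pooled: float
    mean_pooled: float
    sessions_used: tuple[str, ...]


@dataclass(frozen=True)
class SensitivityResult:
    variable: Variable
    rule: AggregationRule
    comparison: tuple[str, ...]
    label: str
    sem: float
    sem_pct: float
    swc: float
    md: float
    md_pct: float
    sensitive: bool
    icc_estimate: float
    pooled: PooledMoments


def pooled_moments(
    Y: ScoreMatrix | np.ndarray,
    sessions: tuple[str, ...] | None = None,
    method: Literal["per_session", "centered_cells"] = "per_session",
) -> PooledMoments:
    """Pooled SD and mean over the matrix's sessions.

    ``per_session`` (default): sd_pooled is the root of the mean of the
    per-session sample variances -- the standard equal-n pooled SD --
    and mean_pooled the mean of the per-session means.  ``centered_cells``
    pools all cells after removing each session's mean (equivalent weights,
    slightly different small-sample normalisation).
    """
    if isinstance(Y, ScoreMatrix):
        vals, sessions = Y.values, tuple(Y.sessions)
    else:
        vals = np.asarray(Y, dtype=float)
        sessions = sessions or tuple(f"C{j + 1}" for j in range(vals.shape[1]))
    mean_pooled = float(vals.mean(axis=0).mean())
    if method == "per_session":
        sd = float(np.sqrt(np.mean(vals.var(axis=0, ddof=1))))
    elif method == "centered_cells":
        centered = vals - vals.mean(axis=0, keepdims=True)
        sd = float(np.sqrt(np.sum(centered**2) / (centered.size - vals.shape[1])))
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    return PooledMoments(sd, mean_pooled, sessions)


def compute_sem(pm: PooledMoments, icc: ICCResult | float) -> tuple[float, float]:
    """SEm = SD_pooled * sqrt(1 - ICC) and SEm% = SEm / mean_pooled * 100.

    Negative ICC estimates are admitted (SEm then exceeds SD_pooled).
    """
    est = icc.estimate if isinstance(icc, ICCResult) else float(icc)
    if est > 1:
        raise UndefinedStatisticError(f"ICC estimate {est} exceeds 1")
    sem = pm.sd_pooled * math.sqrt(1.0 - est)
    if pm.mean_pooled == 0:
        raise UndefinedStatisticError("SEm%% undefined: pooled mean is zero")
    return float(sem), float(sem / pm.mean_pooled * 100.0)


def compute_swc(pm: PooledMoments, multiplier: float = DEFAULT_SWC_MULTIPLIER) -> float:
    """SWC = SD_pooled * multiplier (0.2 = the 'small' standardized effect)."""
    if not multiplier > 0:
        raise ValueError(f"SWC multiplier must be > 0, got {multiplier}")
    return float(pm.sd_pooled * multiplier)


def compute_md(sem: float, mean_pooled: float | None = None) -> tuple[float, float | None]:
    """MD = SEm * 1.96 * sqrt(2); MD% when a pooled mean is given."""
    if sem < 0:
        raise ValueError(f"SEm must be >= 0, got {sem}")
    md = float(sem * MD_FACTOR)
    if mean_pooled is None:
        return md, None
    if mean_pooled == 0:
        raise UndefinedStatisticError("MD%% undefined: pooled mean is zero")
    return md, float(md / mean_pooled * 100.0)


def sensitivity_verdict(sem: float, swc: float) -> bool:
    """Sensitive iff SEm < SWC, strictly: ties are not sensitive."""
    if sem < 0 or swc < 0:
        raise ValueError("sem and swc must be nonnegative")
    return sem < swc


def analyze_sensitivity(
    Y: ScoreMatrix,
    icc: ICCResult,
    label: str | None = None,
    swc_multiplier: float = DEFAULT_SWC_MULTIPLIER,
    sd_pool_method: Literal["per_session", "centered_cells"] = "per_session",
) -> SensitivityResult:
    """Full sensitivity chain for one matrix and its matching ICC.

    The ICC form should match the aggregation rule of ``Y`` (mean-form for
    Avg scores, single-form for Hv/Lv), mirroring how each reliability row
    is paired with its sensitivity row.
    """
    pm = pooled_moments(Y, method=sd_pool_method)
    sem, sem_pct = compute_sem(pm, icc)
    swc = compute_swc(pm, swc_multiplier)
    md, md_pct = compute_md(sem, pm.mean_pooled)
    return SensitivityResult(
        variable=Y.variable,
        rule=Y.rule,
        comparison=tuple(Y.sessions),
        label=label or "-".join(Y.sessions),
        sem=sem,
        sem_pct=sem_pct,
        swc=swc,
        md=md,
        md_pct=float(md_pct),
        sensitive=sensitivity_verdict(sem, swc),
        icc_estimate=icc.estimate,
        pooled=pm,
    )
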