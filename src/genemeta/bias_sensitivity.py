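"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

Funnel-plot coordinates are the per-study (log OR, SE(log OR)) pairs;
a symmetric funnel is the no-bias expectation. Asymmetry is tested with
Egger's linear regression: ordinary least squares of the standard normal
deviate θ_i/se_i on the precision 1/se_i, where a nonzero intercept
signals small-study effects. The intercept t-test has k-2 degrees of
freedom.

The one-way (leave-one-out) sensitivity analysis re-pools the dataset k
times, omitting each study in turn, to check that no single study drives
the pooled conclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .effect_models import (
    DegenerateTableError,
    EffectEstimate,
    InheritanceModel,
    collapse,
)
from .pooling import PooledResult, select_and_pool
from .study_data import Dataset

__all__ = [
    "FunnelPoint",
    "EggerResult",
    "LeaveOneOutResult",
    "funnel_data",
    "egger_test",
    "leave_one_out",
]


@dataclass(frozen=True)
class FunnelPoint:
    """One funnel-plot coordinate: x = log OR, y = SE(log OR)."""

    study_id: str | None
    x: float
    y: float


@dataclass(frozen=True)
class EggerResult:
    """Egger regression intercept test for funnel asymmetry."""

    intercept: float
    se_intercept: float
    t: float
    df: int
    p: float
    slope: float


@dataclass(frozen=True)
class LeaveOneOutResult:
    """One sensitivity re-pool, tagged with the omitted study."""

    omitted_study_id: str
    result: PooledResult


def funnel_data(estimates: Sequence[EffectEstimate]) -> list[FunnelPoint]:
    """Funnel-plot coordinates, one per study, input order preserved."""
    if len(estimates) == 0:
        raise ValueError("no estimates")
    return [FunnelPoint(e.study_id, e.log_or, e.se) for e in estimates]


def egger_test(estimates: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's linear regression test of funnel-plot asymmetry.

    OLS of y_i = θ_i/se_i on x_i = 1/se_i; the intercept estimates the
    bias component and t = intercept / SE(intercept) is referred to a
    Student t distribution with k-2 df (two-sided). Requires k >= 3.
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("Egger test undefined for fewer than 3 studies")
    y = np.array([e.log_or / e.se for e in estimates])
    x = np.array([1 / e.se for e in estimates])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    se_intercept = float(fit.bse[0])
    t = intercept / se_intercept
    df = k - 2
    p = float(2 * stats.t.sf(abs(t), df))
    return EggerResult(
        intercept=intercept, se_intercept=se_intercept, t=t, df=df, p=p, slope=slope
    )


def leave_one_out(
    ds: Dataset,
    model: InheritanceModel | str,
    het_threshold: float = 0.1,
    cc: float = 0.5,
    conf_level: float = 0.95,
) -> list[LeaveOneOutResult]:
    """One-way sensitivity analysis: re-pool omitting each study in turn.

    Each subset is pooled with :func:`~genemeta.pooling.select_and_pool`,
    so the fixed/random choice is re-made per subset from its own Q-test.
    Studies degenerate under the model (empty collapsed margin) are
    skipped, matching their exclusion from the full analysis.
    """
    model = InheritanceModel.coerce(model)
    if len(ds) < 2:
        raise ValueError("leave-one-out requires at least 2 studies")
    out: list[LeaveOneOutResult] = []
    for omit in ds:
        rest = ds.drop(omit.study_id)
        tables = []
        for r in rest:
            try:
                tables.append(collapse(model, r.cases, r.controls, cc=cc, study_id=r.study_id))
            except DegenerateTableError:
                continue
        res = select_and_pool(
            tables, het_threshold=het_threshold, model=model, conf_level=conf_level
        )
        out.append(LeaveOneOutResult(omitted_study_id=omit.study_id, result=res))
    return out
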