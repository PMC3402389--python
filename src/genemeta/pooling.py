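"""Heterogeneity statistics and pooled odds ratios.

Heterogeneity across studies is quantified on Woolf log-odds-ratio
estimates with inverse-variance weights: Cochran's Q, its chi-square
p-value on k-1 df, the I² percentage, and the DerSimonian-Laird moment
estimator of the between-study variance τ².

Pooling follows the classical meta-analysis pair:

* Mantel-Haenszel fixed effects — pooled OR = Σ(a_i d_i / n_i) / Σ(b_i c_i / n_i),
  with the Robins-Breslow-Greenland variance for its confidence interval;
* DerSimonian-Laird random effects — inverse-variance weights
  1 / (se_i² + τ²) on the log-OR scale.

``select_and_pool`` applies the conventional decision rule: if the Q-test
p-value exceeds a threshold (default 0.1, i.e. no detectable heterogeneity)
the fixed-effect model is used, otherwise the random-effects model.
Significance of the pooled log OR is assessed with a Z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .effect_models import (
    EffectEstimate,
    InheritanceModel,
    TwoByTwoTable,
    Z_95,
    odds_ratio,
)

__all__ = [
    "HeterogeneityResult",
    "PooledResult",
    "cochran_q",
    "pool_fixed_mh",
    "pool_random_dl",
    "select_and_pool",
    "z_test",
    "METHOD_FIXED",
    "METHOD_RANDOM",
]

METHOD_FIXED = "MH-fixed"
METHOD_RANDOM = "DL-random"


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran Q with df, p, I² (percent) and DL τ² on the log-OR scale."""

    q: float
    df: int
    p: float
    i2: float
    tau2: float


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with CI, Z-test and heterogeneity block.

    ``het`` is ``None`` for single-study "pools", where heterogeneity is
    undefined (rendered as a dash in report tables). ``weights`` are the
    per-study pooling weights normalised to sum to 1, aligned with
    ``per_study``.
    """

    method: str
    k: int
    pooled_or: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float
    z: float
    p_z: float
    het: HeterogeneityResult | None
    per_study: tuple[EffectEstimate, ...]
    weights: tuple[float, ...]
    model: InheritanceModel | None = None


def z_test(pooled_log_or: float, se: float) -> tuple[float, float]:
    """Wald Z-test of log OR = 0: returns (z, two-sided p)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = pooled_log_or / se
    return z, float(2 * stats.norm.sf(abs(z)))


def cochran_q(estimates: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran Q, I² and the DerSimonian-Laird τ² moment estimate.

    Computed with inverse-variance weights w_i = 1/se_i² about the
    fixed-effect (inverse-variance) mean of the log ORs:

        Q  = Σ w_i (θ_i - θ̂)²,          p from chi-square(k-1)
        I² = max(0, (Q - df)/Q) * 100
        τ² = max(0, (Q - df) / (Σw - Σw²/Σw))
    """
    k = len(estimates)
    if k < 2:
        raise ValueError("heterogeneity undefined for fewer than 2 studies")
    w = [1 / e.se**2 for e in estimates]
    sw = sum(w)
    theta_hat = sum(wi * e.log_or for wi, e in zip(w, estimates)) / sw
    q = sum(wi * (e.log_or - theta_hat) ** 2 for wi, e in zip(w, estimates))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    denom = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p=p, i2=i2, tau2=tau2)


def _finish(
    method: str,
    log_or: float,
    se: float,
    estimates: Sequence[EffectEstimate],
    weights: Sequence[float],
    het: HeterogeneityResult | None,
    model: InheritanceModel | None,
    conf_level: float,
) -> PooledResult:
    z_mult = Z_95 if conf_level == 0.95 else float(stats.norm.ppf(0.5 + conf_level / 2))
    z, p_z = z_test(log_or, se)
    wsum = sum(weights)
    return PooledResult(
        method=method,
        k=len(estimates),
        pooled_or=math.exp(log_or),
        ci_low=math.exp(log_or - z_mult * se),
        ci_high=math.exp(log_or + z_mult * se),
        log_or=log_or,
        se=se,
        z=z,
        p_z=p_z,
        het=het,
        per_study=tuple(estimates),
        weights=tuple(w / wsum for w in weights),
        model=model,
    )


def pool_fixed_mh(
    tables: Sequence[TwoByTwoTable],
    het: HeterogeneityResult | None = None,
    model: InheritanceModel | None = None,
    conf_level: float = 0.95,
) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled OR with the RBG variance.

    The point estimate is Σ(a_i d_i / n_i) / Σ(b_i c_i / n_i). The variance
    of its log is the Robins-Breslow-Greenland estimator

        Var = ΣPR/(2R²) + Σ(PS+QR)/(2RS) + ΣQS/(2S²),

    with per-study P=(a+d)/n, Q=(b+c)/n, R=ad/n, S=bc/n and R, S their sums.
    Study weights are the MH weights b_i c_i / n_i.
    """
    if len(tables) == 0:
        raise ValueError("no tables to pool")
    R = S = 0.0
    sum_pr = sum_psqr = sum_qs = 0.0
    for t in tables:
        n = t.n
        p, q = (t.a + t.d) / n, (t.b + t.c) / n
        r, s = t.a * t.d / n, t.b * t.c / n
        R += r
        S += s
        sum_pr += p * r
        sum_psqr += p * s + q * r
        sum_qs += q * s
    if R == 0 or S == 0:
        raise ValueError("Mantel-Haenszel estimate degenerate: zero cross-product sum")
    log_or = math.log(R / S)
    var = sum_pr / (2 * R * R) + sum_psqr / (2 * R * S) + sum_qs / (2 * S * S)
    se = math.sqrt(var)
    estimates = [odds_ratio(t, conf_level) for t in tables]
    weights = [t.b * t.c / t.n for t in tables]
    return _finish(METHOD_FIXED, log_or, se, estimates, weights, het, model, conf_level)


def pool_random_dl(
    estimates: Sequence[EffectEstimate],
    het: HeterogeneityResult | None = None,
    model: InheritanceModel | None = None,
    conf_level: float = 0.95,
) -> PooledResult:
    """DerSimonian-Laird random-effects pool of log odds ratios.

    Weights are 1/(se_i² + τ²); with τ² = 0 this reduces exactly to the
    inverse-variance fixed-effect pool. ``het`` (and its τ²) should be
    computed on the same estimates; if omitted it is computed here.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to pool")
    if het is None:
        het = cochran_q(estimates) if len(estimates) >= 2 else None
    tau2 = het.tau2 if het is not None else 0.0
    w = [1 / (e.se**2 + tau2) for e in estimates]
    sw = sum(w)
    log_or = sum(wi * e.log_or for wi, e in zip(w, estimates)) / sw
    se = 1 / math.sqrt(sw)
    return _finish(METHOD_RANDOM, log_or, se, estimates, w, het, model, conf_level)


def select_and_pool(
    tables: Sequence[TwoByTwoTable],
    het_threshold: float = 0.1,
    model: InheritanceModel | None = None,
    conf_level: float = 0.95,
    method: str = "auto",
) -> PooledResult:
    """Pool a set of 2x2 tables with heterogeneity-driven model selection.

    The Q-test is computed on the Woolf per-study estimates; if its p-value
    exceeds ``het_threshold`` (strictly: p > threshold, default 0.1,
    indicating no detectable heterogeneity), the Mantel-Haenszel
    fixed-effect pool is returned, otherwise the DerSimonian-Laird
    random-effects pool. A single study "pools" trivially as fixed with
    heterogeneity undefined.

    ``method`` can force ``"fixed"`` or ``"random"`` regardless of the
    Q-test; ``"auto"`` (default) applies the rule above.
    """
    if method not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown method {method!r}")
    if len(tables) == 0:
        raise ValueError("no tables to pool")
    estimates = [odds_ratio(t, conf_level) for t in tables]
    if len(tables) == 1:
        het = None
        if method == "random":
            return pool_random_dl(estimates, het, model, conf_level)
        return pool_fixed_mh(tables, het, model, conf_level)
    het = cochran_q(estimates)
    use_fixed = het.p > het_threshold if method == "auto" else method == "fixed"
    if use_fixed:
        return pool_fixed_mh(tables, het, model, conf_level)
    return pool_random_dl(estimates, het, model, conf_level)
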