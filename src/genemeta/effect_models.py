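"""Genetic inheritance models, per-study odds ratios and Hardy-Weinberg QC.

Genotype triples are collapsed into 2x2 exposure tables under one of three
inheritance models for a variant allele G against wildtype T:

* additive  — homozygote contrast GG vs TT (heterozygotes excluded; this is
  the homozygote contrast convention, not a per-allele trend test),
* dominant  — carriers (GG+GT) vs TT,
* recessive — GG vs carriers of T (GT+TT).

Per-study effects are odds ratios with Woolf (log-scale) standard errors
and log-symmetric confidence intervals. Control arms are checked against
Hardy-Weinberg equilibrium, both with the chi-square goodness-of-fit
statistic (1 df, no continuity correction) and with the conditional exact
test on the heterozygote count.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy import stats

from .study_data import GenotypeCounts

__all__ = [
    "InheritanceModel",
    "TwoByTwoTable",
    "EffectEstimate",
    "HWEResult",
    "DegenerateTableError",
    "collapse",
    "odds_ratio",
    "swap_arms",
    "hwe_chi_square",
    "hwe_exact",
    "Z_95",
]

#: z multiplier for a 95% interval, kept at full precision internally;
#: report layers round ORs/CIs to 2 dp.
Z_95 = 1.959964


class DegenerateTableError(ValueError):
    """A collapsed table has an empty case or control margin."""


class InheritanceModel(str, enum.Enum):
    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"

    @classmethod
    def coerce(cls, value: "InheritanceModel | str") -> "InheritanceModel":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown inheritance model {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None

    def exposure_indicator(self) -> dict[str, int]:
        """1 if a genotype counts as 'exposed' under this model, else 0.

        Under the additive (homozygote-contrast) model the heterozygote is
        excluded from the table altogether; its indicator is 0 here and
        :func:`collapse` drops it.
        """
        if self is InheritanceModel.DOMINANT:
            return {"gg": 1, "gt": 1, "tt": 0}
        return {"gg": 1, "gt": 0, "tt": 0}


@dataclass(frozen=True)
class TwoByTwoTable:
    """Collapsed exposure table: a/b exposed/unexposed cases, c/d controls.

    Cells are reals because a Haldane-Anscombe continuity correction may
    have been added; ``cc_applied`` records whether it was.
    """

    a: float
    b: float
    c: float
    d: float
    cc_applied: bool = False
    study_id: str | None = None

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study odds ratio on both scales with its Woolf standard error."""

    study_id: str | None
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class HWEResult:
    """Hardy-Weinberg goodness-of-fit result for one control arm."""

    chi2: float
    df: int
    p: float
    g_freq: float
    monomorphic: bool = False
    exact_p: float | None = None


def collapse(
    model: InheritanceModel | str,
    cases: GenotypeCounts,
    controls: GenotypeCounts,
    cc: float = 0.5,
    study_id: str | None = None,
) -> TwoByTwoTable:
    """Collapse genotype triples into a 2x2 table under an inheritance model.

    If any raw cell is zero, the continuity constant ``cc`` is added to all
    four cells (Haldane-Anscombe). A table whose case or control margin is
    zero *before* correction is degenerate: the contrast does not exist for
    this study and :class:`DegenerateTableError` is raised so the caller can
    exclude the study from that model.
    """
    model = InheritanceModel.coerce(model)
    if cases.total == 0 or controls.total == 0:
        raise DegenerateTableError(f"study {study_id!r}: empty arm")
    if model is InheritanceModel.ADDITIVE:
        a, b = cases.gg, cases.tt
        c, d = controls.gg, controls.tt
    elif model is InheritanceModel.DOMINANT:
        a, b = cases.gg + cases.gt, cases.tt
        c, d = controls.gg + controls.gt, controls.tt
    else:
        a, b = cases.gg, cases.gt + cases.tt
        c, d = controls.gg, controls.gt + controls.tt
    if a + b == 0 or c + d == 0:
        raise DegenerateTableError(
            f"study {study_id!r}: margin empty after collapsing under {model.value}"
        )
    if min(a, b, c, d) == 0:
        return TwoByTwoTable(a + cc, b + cc, c + cc, d + cc, True, study_id)
    return TwoByTwoTable(float(a), float(b), float(c), float(d), False, study_id)


def odds_ratio(t: TwoByTwoTable, conf_level: float = 0.95) -> EffectEstimate:
    """Cross-product odds ratio with Woolf SE and log-symmetric CI.

    OR = ad/bc; SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d);
    CI = exp(log OR ± z * SE).
    """
    if min(t.a, t.b, t.c, t.d) <= 0:
        raise ValueError("all four cells must be positive (apply continuity correction)")
    log_or = math.log((t.a * t.d) / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = Z_95 if conf_level == 0.95 else float(stats.norm.ppf(0.5 + conf_level / 2))
    return EffectEstimate(
        study_id=t.study_id,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
    )


def swap_arms(t: TwoByTwoTable) -> TwoByTwoTable:
    """Exchange the case and control rows (a<->c, b<->d)."""
    return TwoByTwoTable(t.c, t.d, t.a, t.b, t.cc_applied, t.study_id)


def hwe_chi_square(controls: GenotypeCounts) -> HWEResult:
    """Chi-square goodness-of-fit test of Hardy-Weinberg equilibrium.

    The variant-allele frequency is estimated as p = (2*GG + GT) / 2n and
    observed genotype counts are compared to the HWE expectation
    (n*p^2, 2n*p*(1-p), n*(1-p)^2) over the three genotype classes with
    1 degree of freedom and no continuity correction — the convention used
    in genotyping quality-control tables.
    """
    n = controls.total
    if n == 0:
        raise ValueError("control arm is empty")
    p = (2 * controls.gg + controls.gt) / (2 * n)
    if p in (0.0, 1.0):
        return HWEResult(chi2=0.0, df=1, p=1.0, g_freq=p, monomorphic=True)
    q = 1 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = controls.as_tuple()
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HWEResult(
        chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)), g_freq=p, monomorphic=False
    )


def hwe_exact(controls: GenotypeCounts) -> float:
    """Conditional exact test of HWE on the heterozygote count.

    Given the sample size n and the variant-allele count nG, the number of
    heterozygotes under HWE follows the standard conditional distribution

        P(het = h | n, nG)  ∝  n! / (n_GG! h! n_TT!) * 2^h,

    with n_GG = (nG - h)/2. The p-value sums the probabilities of all
    heterozygote counts at least as improbable as the observed one.
    """
    n = controls.total
    if n == 0:
        raise ValueError("control arm is empty")
    n_g = 2 * controls.gg + controls.gt
    if n_g == 0 or n_g == 2 * n:
        return 1.0  # monomorphic: a single attainable configuration
    hets = [h for h in range(n_g % 2, min(n_g, 2 * n - n_g) + 1, 2)]

    def log_weight(h: int) -> float:
        n_gg = (n_g - h) // 2
        n_tt = n - n_gg - h
        return (
            math.lgamma(n + 1)
            - math.lgamma(n_gg + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_tt + 1)
            + h * math.log(2.0)
        )

    logw = {h: log_weight(h) for h in hets}
    m = max(logw.values())
    total = sum(math.exp(v - m) for v in logw.values())
    probs = {h: math.exp(v - m) / total for h, v in logw.items()}
    p_obs = probs[controls.gt]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))
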