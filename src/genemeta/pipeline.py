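"""End-to-end orchestration of the meta-analysis and report rendering.

``run_pipeline`` takes a validated dataset and a configuration and
produces a :class:`MetaReport` holding every analysis stage: per-study
odds ratios under each requested inheritance model, Hardy-Weinberg QC of
the control arms, overall and subgroup pooling with heterogeneity-driven
model selection, leave-one-out sensitivity tables, and publication-bias
diagnostics (funnel coordinates + Egger test).

Studies whose control arm departs from HWE at ``hwe_alpha`` are flagged
in the report but never silently dropped — exclusion would be a data
change the reader must opt into. Studies degenerate under a particular
model (an empty collapsed margin) are excluded from that model only,
with the reason logged in the report's exclusion list.

Reports render losslessly to JSON/TSV and to a rounded human-readable
text table (ORs and CI bounds to 2 dp, heterogeneity statistics to 3 dp,
I² to 1 dp; heterogeneity of single-study pools prints as a dash).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .bias_sensitivity import (
    EggerResult,
    FunnelPoint,
    LeaveOneOutResult,
    egger_test,
    funnel_data,
    leave_one_out,
)
from .effect_models import (
    DegenerateTableError,
    EffectEstimate,
    HWEResult,
    InheritanceModel,
    collapse,
    hwe_chi_square,
    hwe_exact,
    odds_ratio,
)
from .pooling import PooledResult, select_and_pool
from .study_data import Dataset

__all__ = [
    "AnalysisConfig",
    "MetaReport",
    "subgroup_analysis",
    "run_pipeline",
    "render_report",
    "write_report_files",
]

ALL_MODELS = (
    InheritanceModel.ADDITIVE,
    InheritanceModel.DOMINANT,
    InheritanceModel.RECESSIVE,
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the pipeline.

    ``het_threshold`` is the Q-test p-value above which fixed effects are
    used (strict inequality; ties go to random effects). ``cc`` is the
    Haldane-Anscombe continuity constant added to all four cells of a
    table containing a zero. ``method`` forces ``"fixed"``/``"random"``
    pooling everywhere; the default ``"auto"`` applies the Q-test rule.
    """

    models: tuple[InheritanceModel, ...] = ALL_MODELS
    subgroup_columns: tuple[str, ...] = ()
    het_threshold: float = 0.1
    conf_level: float = 0.95
    cc: float = 0.5
    hwe_alpha: float = 0.05
    method: str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "models", tuple(InheritanceModel.coerce(m) for m in self.models)
        )
        if not self.models:
            raise ValueError("at least one inheritance model required")
        for name in ("het_threshold", "conf_level", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1), got {v}")


@dataclass(frozen=True)
class Exclusion:
    study_id: str
    model: str
    reason: str


@dataclass(frozen=True)
class MetaReport:
    """Complete analysis output; see module docstring for the sections."""

    config: AnalysisConfig
    provenance: str
    per_study: Mapping[str, tuple[EffectEstimate, ...]]  # model -> estimates
    hwe: Mapping[str, HWEResult]  # study_id -> result
    hwe_flags: Mapping[str, bool]  # study_id -> violates HWE at alpha
    overall: Mapping[str, PooledResult]  # model -> pooled
    subgroups: Mapping[str, Mapping[str, Mapping[str, PooledResult]]]  # col -> level -> model
    sensitivity: Mapping[str, tuple[LeaveOneOutResult, ...]]  # model -> k results
    egger: Mapping[str, EggerResult]  # model -> result
    funnel: Mapping[str, tuple[FunnelPoint, ...]]  # model -> points
    exclusions: tuple[Exclusion, ...]


def _collapse_all(
    ds: Dataset, model: InheritanceModel, cfg: AnalysisConfig
) -> tuple[list, list[Exclusion]]:
    tables, excl = [], []
    for r in ds:
        try:
            tables.append(collapse(model, r.cases, r.controls, cc=cfg.cc, study_id=r.study_id))
        except DegenerateTableError as e:
            excl.append(Exclusion(r.study_id, model.value, str(e)))
    return tables, excl


def subgroup_analysis(
    ds: Dataset,
    column: str,
    model: InheritanceModel | str,
    cfg: AnalysisConfig | None = None,
) -> dict[str, PooledResult]:
    """Pool each level of a categorical column separately.

    Levels with a single study yield single-study results with the
    heterogeneity block absent. Raises ``KeyError`` naming the available
    columns when ``column`` is unknown for any record.
    """
    cfg = cfg or AnalysisConfig()
    model = InheritanceModel.coerce(model)
    out: dict[str, PooledResult] = {}
    for level, sub in ds.partition(column).items():
        tables, _ = _collapse_all(sub, model, cfg)
        if not tables:
            continue
        out[level] = select_and_pool(
            tables,
            het_threshold=cfg.het_threshold,
            model=model,
            conf_level=cfg.conf_level,
            method=cfg.method,
        )
    return out


def run_pipeline(ds: Dataset, cfg: AnalysisConfig | None = None) -> MetaReport:
    """Run every analysis stage; deterministic given (dataset, config)."""
    cfg = cfg or AnalysisConfig()
    if len(ds) == 0:
        raise ValueError("dataset has no records")

    hwe = {r.study_id: _with_exact(r) for r in ds}
    hwe_flags = {sid: res.p <= cfg.hwe_alpha for sid, res in hwe.items()}

    per_study: dict[str, tuple[EffectEstimate, ...]] = {}
    overall: dict[str, PooledResult] = {}
    sensitivity: dict[str, tuple[LeaveOneOutResult, ...]] = {}
    egger: dict[str, EggerResult] = {}
    funnel: dict[str, tuple[FunnelPoint, ...]] = {}
    exclusions: list[Exclusion] = []

    for model in cfg.models:
        tables, excl = _collapse_all(ds, model, cfg)
        exclusions.extend(excl)
        if not tables:
            raise ValueError(f"no usable tables under model {model.value}")
        estimates = tuple(odds_ratio(t, cfg.conf_level) for t in tables)
        per_study[model.value] = estimates
        overall[model.value] = select_and_pool(
            tables,
            het_threshold=cfg.het_threshold,
            model=model,
            conf_level=cfg.conf_level,
            method=cfg.method,
        )
        funnel[model.value] = tuple(funnel_data(estimates))
        if len(estimates) >= 3:
            egger[model.value] = egger_test(estimates)
        if len(ds) >= 2:
            sensitivity[model.value] = tuple(
                leave_one_out(ds, model, cfg.het_threshold, cfg.cc, cfg.conf_level)
            )

    subgroups: dict[str, dict[str, dict[str, PooledResult]]] = {}
    for column in cfg.subgroup_columns:
        by_level: dict[str, dict[str, PooledResult]] = {}
        for model in cfg.models:
            for level, res in subgroup_analysis(ds, column, model, cfg).items():
                by_level.setdefault(level, {})[model.value] = res
        subgroups[column] = by_level

    return MetaReport(
        config=cfg,
        provenance=ds.provenance,
        per_study=per_study,
        hwe=hwe,
        hwe_flags=hwe_flags,
        overall=overall,
        subgroups=subgroups,
        sensitivity=sensitivity,
        egger=egger,
        funnel=funnel,
        exclusions=tuple(exclusions),
    )


def _with_exact(record) -> HWEResult:
    res = hwe_chi_square(record.controls)
    exact = hwe_exact(record.controls)
    return HWEResult(
        chi2=res.chi2,
        df=res.df,
        p=res.p,
        g_freq=res.g_freq,
        monomorphic=res.monomorphic,
        exact_p=exact,
    )


# ---------------------------------------------------------------- rendering


def _pooled_dict(res: PooledResult) -> dict:
    return {
        "method": res.method,
        "k": res.k,
        "or": res.pooled_or,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "log_or": res.log_or,
        "se": res.se,
        "z": res.z,
        "p": res.p_z,
        "het": None
        if res.het is None
        else {
            "q": res.het.q,
            "df": res.het.df,
            "p": res.het.p,
            "i2": res.het.i2,
            "tau2": res.het.tau2,
        },
    }


def report_to_dict(r: MetaReport) -> dict:
    """Loss-free dict form of a report (JSON-serialisable)."""
    return {
        "config": {
            "models": [m.value for m in r.config.models],
            "subgroup_columns": list(r.config.subgroup_columns),
            "het_threshold": r.config.het_threshold,
            "conf_level": r.config.conf_level,
            "cc": r.config.cc,
            "hwe_alpha": r.config.hwe_alpha,
            "method": r.config.method,
            "seed": r.config.seed,
        },
        "provenance": r.provenance,
        "per_study": {
            m: [
                {
                    "study_id": e.study_id,
                    "or": e.or_,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "log_or": e.log_or,
                    "se": e.se,
                }
                for e in ests
            ]
            for m, ests in r.per_study.items()
        },
        "hwe": {
            sid: {
                "chi2": h.chi2,
                "df": h.df,
                "p": h.p,
                "g_freq": h.g_freq,
                "exact_p": h.exact_p,
                "monomorphic": h.monomorphic,
                "violates": r.hwe_flags[sid],
            }
            for sid, h in r.hwe.items()
        },
        "overall": {m: _pooled_dict(res) for m, res in r.overall.items()},
        "subgroups": {
            col: {
                level: {m: _pooled_dict(res) for m, res in by_model.items()}
                for level, by_model in levels.items()
            }
            for col, levels in r.subgroups.items()
        },
        "sensitivity": {
            m: [
                {"omitted": lo.omitted_study_id, **_pooled_dict(lo.result)}
                for lo in los
            ]
            for m, los in r.sensitivity.items()
        },
        "egger": {
            m: {
                "intercept": e.intercept,
                "se_intercept": e.se_intercept,
                "t": e.t,
                "df": e.df,
                "p": e.p,
                "slope": e.slope,
            }
            for m, e in r.egger.items()
        },
        "funnel": {
            m: [{"study_id": p.study_id, "log_or": p.x, "se": p.y} for p in pts]
            for m, pts in r.funnel.items()
        },
        "exclusions": [
            {"study_id": e.study_id, "model": e.model, "reason": e.reason}
            for e in r.exclusions
        ],
    }


def _fmt_pool(res: PooledResult) -> str:
    het = "-" if res.het is None else f"Q={res.het.q:.3f} p={res.het.p:.3f} I2={res.het.i2:.1f}%"
    return (
        f"{res.pooled_or:.2f} ({res.ci_low:.2f}-{res.ci_high:.2f})"
        f"  p={res.p_z:.3f}  [{res.method}, k={res.k}; {het}]"
    )


def _text_report(r: MetaReport) -> str:
    lines = ["Pooled odds ratios", "=" * 18]
    for m, res in r.overall.items():
        lines.append(f"Total  {m:10s} {_fmt_pool(res)}")
    for col, levels in r.subgroups.items():
        lines.append("")
        lines.append(f"Subgroups by {col}")
        for level, by_model in levels.items():
            for m, res in by_model.items():
                lines.append(f"  {level:12s} {m:10s} {_fmt_pool(res)}")
    if r.egger:
        lines.append("")
        lines.append("Egger regression (funnel asymmetry)")
        for m, e in r.egger.items():
            lines.append(f"  {m:10s} t={e.t:.2f} (df={e.df}) p={e.p:.3f}")
    lines.append("")
    lines.append("HWE (controls)")
    for sid, h in r.hwe.items():
        flag = " *violates*" if r.hwe_flags[sid] else ""
        lines.append(f"  {sid:16s} chi2={h.chi2:.3f} p={h.p:.3f}{flag}")
    if r.exclusions:
        lines.append("")
        lines.append("Exclusions")
        for e in r.exclusions:
            lines.append(f"  {e.study_id} [{e.model}]: {e.reason}")
    return "\n".join(lines) + "\n"


def _tsv_rows(r: MetaReport) -> list[list[str]]:
    header = [
        "section", "column", "level", "model", "method", "k",
        "or", "ci_low", "ci_high", "z", "p",
        "het_q", "het_df", "het_p", "i2", "tau2",
    ]
    rows = [header]

    def add(section: str, column: str, level: str, m: str, res: PooledResult) -> None:
        het = res.het
        rows.append(
            [
                section, column, level, m, res.method, str(res.k),
                repr(res.pooled_or), repr(res.ci_low), repr(res.ci_high),
                repr(res.z), repr(res.p_z),
            ]
            + (
                ["", "", "", "", ""]
                if het is None
                else [repr(het.q), str(het.df), repr(het.p), repr(het.i2), repr(het.tau2)]
            )
        )

    for m, res in r.overall.items():
        add("overall", "", "Total", m, res)
    for col, levels in r.subgroups.items():
        for level, by_model in levels.items():
            for m, res in by_model.items():
                add("subgroup", col, level, m, res)
    return rows


def render_report(r: MetaReport, format: str = "json") -> str:
    """Serialize a report: ``json``/``tsv`` loss-free, ``text`` rounded."""
    if format == "json":
        return json.dumps(report_to_dict(r), sort_keys=True, indent=1)
    if format == "tsv":
        return "\n".join("\t".join(row) for row in _tsv_rows(r)) + "\n"
    if format == "text":
        return _text_report(r)
    raise ValueError(f"unknown report format {format!r}; expected json, tsv or text")


def write_report_files(r: MetaReport, outdir: str | Path, formats: Sequence[str] = ("json", "tsv", "text")) -> list[Path]:
    """Write the report sections to files under ``outdir``.

    Produces ``report.json``, ``overall.tsv``+``subgroups.tsv`` (pooled
    tables), ``hwe.tsv``, ``sensitivity.tsv``, one ``funnel_<model>.tsv``
    per model, and ``report.txt`` depending on the requested formats.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, content: str) -> None:
        p = outdir / name
        p.write_text(content)
        written.append(p)

    if "json" in formats:
        emit("report.json", render_report(r, "json"))
    if "text" in formats:
        emit("report.txt", render_report(r, "text"))
    if "tsv" in formats:
        rows = _tsv_rows(r)
        overall = [rows[0]] + [x for x in rows[1:] if x[0] == "overall"]
        sub = [rows[0]] + [x for x in rows[1:] if x[0] == "subgroup"]
        emit("overall.tsv", "\n".join("\t".join(x) for x in overall) + "\n")
        emit("subgroups.tsv", "\n".join("\t".join(x) for x in sub) + "\n")
        hwe_rows = [["study_id", "chi2", "df", "p", "g_freq", "exact_p", "violates"]] + [
            [
                sid, repr(h.chi2), str(h.df), repr(h.p), repr(h.g_freq),
                repr(h.exact_p), str(r.hwe_flags[sid]),
            ]
            for sid, h in r.hwe.items()
        ]
        emit("hwe.tsv", "\n".join("\t".join(x) for x in hwe_rows) + "\n")
        sens_rows = [["model", "omitted", "method", "k", "or", "ci_low", "ci_high", "p"]]
        for m, los in r.sensitivity.items():
            for lo in los:
                res = lo.result
                sens_rows.append(
                    [
                        m, lo.omitted_study_id, res.method, str(res.k),
                        repr(res.pooled_or), repr(res.ci_low), repr(res.ci_high),
                        repr(res.p_z),
                    ]
                )
        emit("sensitivity.tsv", "\n".join("\t".join(x) for x in sens_rows) + "\n")
        for m, pts in r.funnel.items():
            fr = [["study_id", "log_or", "se"]] + [
                [str(p.study_id), repr(p.x), repr(p.y)] for p in pts
            ]
            emit(f"funnel_{m}.tsv", "\n".join("\t".join(x) for x in fr) + "\n")
    return written
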