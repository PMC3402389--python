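"""Seeded generator of case-control genotype-count studies with known truth.

Controls are sampled multinomially from Hardy-Weinberg genotype
proportions (p², 2pq, q²) at a configurable variant-allele frequency p.
Case genotype probabilities are obtained by exposure tilting: with the
exposure indicator e(g) of the chosen inheritance model (1 for genotypes
counted as exposed, 0 otherwise), the study-specific odds ratio ψ_i acts
multiplicatively on the exposed classes,

    P_case(g) ∝ P_ctrl(g) · ψ_i^{e(g)},

renormalised — so the model-matched collapsed 2x2 table has population
odds ratio exactly ψ_i. Between-study heterogeneity is log-normal on the
OR: log ψ_i ~ Normal(log ψ, τ²). Arm sizes are fixed (case-control
design), sampling is multinomial per arm.

Randomness follows numpy best practice: a single ``SeedSequence`` per
dataset is spawned into independent child streams per study, so results
depend only on (config, seed) and never on call order or process state.

``evaluate_recovery`` is the estimator-evaluation harness: it repeatedly
simulates datasets, runs the heterogeneity-gated pooling, and scores
bias, RMSE, CI coverage of the true OR and the Q-test rejection rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .effect_models import InheritanceModel, collapse
from .pooling import select_and_pool
from .study_data import Dataset, GenotypeCounts, StudyRecord

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "RecoverySummary",
    "case_probabilities",
    "simulate_study",
    "simulate_dataset",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated study collection.

    ``n_cases``/``n_controls`` may be scalars (shared by all studies) or
    per-study sequences of length ``k``. ``strata_spec`` maps an extra
    categorical column name to its level-probability dict.
    """

    k: int = 11
    n_cases: int | Sequence[int] = 600
    n_controls: int | Sequence[int] = 800
    p_g: float = 0.4
    true_or: float = 1.5
    gen_model: InheritanceModel = InheritanceModel.DOMINANT
    tau: float = 0.0
    strata_spec: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gen_model", InheritanceModel.coerce(self.gen_model))
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.p_g < 1:
            raise ValueError("p_g must lie in (0,1)")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        for name in ("n_cases", "n_controls"):
            v = getattr(self, name)
            sizes = [v] if np.isscalar(v) else list(v)
            if not np.isscalar(v) and len(sizes) != self.k:
                raise ValueError(f"{name} list must have length k={self.k}")
            if any(int(s) < 1 for s in sizes):
                raise ValueError(f"{name} must be >= 1")

    def arm_size(self, which: str, i: int) -> int:
        v = self.n_cases if which == "cases" else self.n_controls
        return int(v) if np.isscalar(v) else int(v[i])


@dataclass(frozen=True)
class SimulationTruth:
    """Per-study realized parameters, recorded before sampling."""

    config: SimulationConfig
    log_or: tuple[float, ...]  # realized per-study log ψ_i
    control_probs: tuple[tuple[float, float, float], ...]
    case_probs: tuple[tuple[float, float, float], ...]


def control_probabilities(p_g: float) -> np.ndarray:
    """HWE genotype probabilities (GG, GT, TT) at allele frequency p_g."""
    q = 1 - p_g
    return np.array([p_g * p_g, 2 * p_g * q, q * q])


def case_probabilities(
    p_g: float, psi: float, gen_model: InheritanceModel | str
) -> np.ndarray:
    """Case genotype probabilities under exposure tilting (see module doc)."""
    gen_model = InheritanceModel.coerce(gen_model)
    ctrl = control_probabilities(p_g)
    e = gen_model.exposure_indicator()
    tilt = np.array([psi ** e["gg"], psi ** e["gt"], psi ** e["tt"]])
    unnorm = ctrl * tilt
    return unnorm / unnorm.sum()


def simulate_study(
    cfg: SimulationConfig, study_index: int, rng: np.random.Generator
) -> tuple[StudyRecord, dict]:
    """Draw one study from an explicit random stream.

    Returns the record and a per-study truth dict (realized log OR and the
    two genotype probability vectors).
    """
    log_psi = rng.normal(np.log(cfg.true_or), cfg.tau) if cfg.tau > 0 else float(
        np.log(cfg.true_or)
    )
    psi = float(np.exp(log_psi))
    p_ctrl = control_probabilities(cfg.p_g)
    p_case = case_probabilities(cfg.p_g, psi, cfg.gen_model)
    case_counts = rng.multinomial(cfg.arm_size("cases", study_index), p_case)
    ctrl_counts = rng.multinomial(cfg.arm_size("controls", study_index), p_ctrl)
    strata = {}
    if cfg.strata_spec:
        for column, level_probs in cfg.strata_spec.items():
            levels = list(level_probs)
            probs = np.array([level_probs[l] for l in levels], dtype=float)
            strata[column] = levels[rng.choice(len(levels), p=probs / probs.sum())]
    record = StudyRecord(
        study_id=f"sim{study_index:03d}",
        first_author=f"Sim{study_index:03d}",
        year=2000 + study_index,
        ethnicity="Synthetic",
        control_source="PB",
        method="simulated",
        cases=GenotypeCounts(*(int(x) for x in case_counts)),
        controls=GenotypeCounts(*(int(x) for x in ctrl_counts)),
        extra_strata=strata,
    )
    truth = {
        "log_or": log_psi,
        "control_probs": tuple(float(x) for x in p_ctrl),
        "case_probs": tuple(float(x) for x in p_case),
    }
    return record, truth


def simulate_dataset(
    cfg: SimulationConfig, seed_seq: np.random.SeedSequence | None = None
) -> tuple[Dataset, SimulationTruth]:
    """Draw k independent studies from one seeded stream (deterministic per seed)."""
    ss = seed_seq if seed_seq is not None else np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.k)
    records, log_ors, c_probs, a_probs = [], [], [], []
    for i in range(cfg.k):
        rec, truth = simulate_study(cfg, i, np.random.default_rng(children[i]))
        records.append(rec)
        log_ors.append(truth["log_or"])
        c_probs.append(truth["control_probs"])
        a_probs.append(truth["case_probs"])
    ds = Dataset(tuple(records), provenance=f"simulated (seed={cfg.seed}, k={cfg.k})")
    return ds, SimulationTruth(
        config=cfg,
        log_or=tuple(log_ors),
        control_probs=tuple(c_probs),
        case_probs=tuple(a_probs),
    )


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo scores of the pooling pipeline against simulation truth."""

    reps: int
    mean_pooled_or: float
    bias_log_or: float  # mean pooled log OR minus log ψ
    rmse_log_or: float
    ci_coverage: float  # fraction of CIs containing the true ψ
    q_rejection_rate: float  # fraction of Q-tests with p <= het_threshold
    mean_i2: float


def evaluate_recovery(
    cfg: SimulationConfig,
    reps: int,
    model: InheritanceModel | str | None = None,
    het_threshold: float = 0.1,
) -> RecoverySummary:
    """Repeatedly simulate + pool; score estimator recovery of the true OR.

    ``model`` is the analysis (collapsing) model, defaulting to the
    generating model — the matched case in which the collapsed population
    OR equals ψ exactly. Replicate streams are spawned from ``cfg.seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    model = InheritanceModel.coerce(model) if model is not None else cfg.gen_model
    true_log = float(np.log(cfg.true_or))
    root = np.random.SeedSequence(cfg.seed)
    pooled_logs, covered, q_reject, i2s = [], 0, 0, []
    for child in root.spawn(reps):
        ds, _ = simulate_dataset(cfg, seed_seq=child)
        tables = [
            collapse(model, r.cases, r.controls, study_id=r.study_id) for r in ds
        ]
        res = select_and_pool(tables, het_threshold=het_threshold, model=model)
        pooled_logs.append(res.log_or)
        if res.ci_low <= cfg.true_or <= res.ci_high:
            covered += 1
        if res.het is not None:
            if res.het.p <= het_threshold:
                q_reject += 1
            i2s.append(res.het.i2)
    arr = np.array(pooled_logs)
    return RecoverySummary(
        reps=reps,
        mean_pooled_or=float(np.exp(arr).mean()),
        bias_log_or=float(arr.mean() - true_log),
        rmse_log_or=float(np.sqrt(((arr - true_log) ** 2).mean())),
        ci_coverage=covered / reps,
        q_rejection_rate=q_reject / reps if reps else 0.0,
        mean_i2=float(np.mean(i2s)) if i2s else 0.0,
    )
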