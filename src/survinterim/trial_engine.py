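"""Full study runs and the Monte-Carlo replication layer.

One study run simulates a cohort plus expression matrix, schedules all M
looks, and at each look screens every gene, applies BH at the full nominal
level (no interim-specific alpha reduction), computes truth metrics against
the known effect vector, estimates the APR per configured variant, and
records the stop decision.  Stopping is recorded, never enforced: all looks
of all runs are computed so per-look summaries and stop fractions can both
be reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import apr_estimation, cox_screen, error_control
from .apr_estimation import VARIANT_FIXED, VARIANT_SMOOTHER, AprEstimate
from .error_control import TestDecisionSummary
from .study_design import (
    AnalysisSchedule,
    PatientCohort,
    StudyDesign,
    schedule_analyses,
    take_snapshot,
)
from .synthetic_cohort import (
    CorrelationModel,
    EffectModel,
    EffectVector,
    ExpressionMatrix,
    MODE_DISCRETIZED_NORMAL,
    MODE_TABLE,
    SurvivalModel,
    build_effect_vector,
    load_effect_table,
    load_packaged_effect_table,
    simulate_expression,
    simulate_patients,
)

logger = logging.getLogger(__name__)

#: Discretized-normal spread of the "small" and "large" fold-change regimes,
#: on the default grid width of 1.0.  "large" is calibrated so the final-look
#: true APR of the default tau = 50%, M = 4 setting is about 0.82; the coarse
#: grid keeps near-zero effects out of the altered set, which is what keeps
#: the pi0-based APR estimator nearly unbiased in that regime.
EFFECT_SD_SMALL = 1.0
EFFECT_SD_LARGE = 1.6
EFFECT_STEP_DEFAULT = 1.0

DEFAULT_VARIANTS = (VARIANT_FIXED, VARIANT_SMOOTHER)


class AlignmentError(ValueError):
    """Raised when expression columns and patient rows cannot be matched."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one Monte-Carlo experiment."""

    design: StudyDesign
    survival_model: SurvivalModel
    effect_model: EffectModel
    correlation: CorrelationModel
    d: int
    theta: float = 0.5
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    n_runs: int = 50
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        for v in self.variants:
            if v not in (VARIANT_FIXED, VARIANT_SMOOTHER):
                raise ValueError(f"unknown estimator variant: {v!r}")


@dataclass
class AnalysisResult:
    """Outcome of a single interim (or final) analysis."""

    index: int  # 1-based
    time: float
    phase: str
    n_included: int
    n_events: int
    r: int
    alpha_bh: float
    decision: TestDecisionSummary | None
    apr: dict[str, AprEstimate]
    stop: dict[str, bool]


@dataclass
class StudyRun:
    """All M analyses of one simulated study."""

    run_seed: int
    results: list[AnalysisResult]
    first_stop: dict[str, int]  # 1-based look index; M+1 if never stopped

    @property
    def m_total(self) -> int:
        return len(self.results)


@dataclass
class MonteCarloSummary:
    """Across-run aggregation of per-look metrics and first-stop fractions."""

    config: SimulationConfig
    n_runs: int
    times: np.ndarray  # (n_runs, M)
    n_included: np.ndarray
    n_events: np.ndarray
    r: np.ndarray
    fdp: np.ndarray
    apr_true: np.ndarray
    apr_hat: dict[str, np.ndarray]
    first_stop: dict[str, np.ndarray]  # (n_runs,), M+1 sentinel

    @property
    def m_total(self) -> int:
        return self.r.shape[1]

    def stop_fractions(self, variant: str) -> np.ndarray:
        """Fraction of runs first stopping at each look (length M)."""
        fs = self.first_stop[variant]
        return np.array(
            [np.mean(fs == m) for m in range(1, self.m_total + 1)]
        )

    def never_stopped_fraction(self, variant: str) -> float:
        return float(np.mean(self.first_stop[variant] > self.m_total))

    def mean_first_stop(self, variant: str, stopped_only: bool = True) -> float:
        """Mean first-stop look index; by default over runs that stopped."""
        fs = self.first_stop[variant].astype(float)
        if stopped_only:
            fs = fs[fs <= self.m_total]
            if fs.size == 0:
                return float("nan")
        else:
            fs = np.minimum(fs, self.m_total)
        return float(np.mean(fs))

    def to_frame(self) -> pd.DataFrame:
        """Per-look summary table (means and SDs over all runs)."""
        rows = {
            "analysis": np.arange(1, self.m_total + 1),
            "time_mean": self.times.mean(axis=0),
            "n_mean": self.n_included.mean(axis=0),
            "events_mean": self.n_events.mean(axis=0),
            "found_mean": self.r.mean(axis=0),
            "found_sd": self.r.std(axis=0, ddof=1) if self.n_runs > 1 else np.zeros(self.m_total),
            "fdp_mean": self.fdp.mean(axis=0),
            "fdp_sd": self.fdp.std(axis=0, ddof=1) if self.n_runs > 1 else np.zeros(self.m_total),
            "apr_true_mean": self.apr_true.mean(axis=0),
            "apr_true_sd": self.apr_true.std(axis=0, ddof=1) if self.n_runs > 1 else np.zeros(self.m_total),
        }
        for variant, values in self.apr_hat.items():
            key = variant.replace("-", "_")
            rows[f"apr_hat_{key}_mean"] = values.mean(axis=0)
            rows[f"apr_hat_{key}_sd"] = (
                values.std(axis=0, ddof=1) if self.n_runs > 1 else np.zeros(self.m_total)
            )
            rows[f"stop_fraction_{key}"] = self.stop_fractions(variant)
        return pd.DataFrame(rows)

    def runs_frame(self) -> pd.DataFrame:
        """Per-run, per-look log table."""
        records = []
        for run in range(self.n_runs):
            for m in range(self.m_total):
                rec = {
                    "run": run,
                    "analysis": m + 1,
                    "time": self.times[run, m],
                    "n": self.n_included[run, m],
                    "events": self.n_events[run, m],
                    "found": self.r[run, m],
                    "fdp": self.fdp[run, m],
                    "apr_true": self.apr_true[run, m],
                }
                for variant, values in self.apr_hat.items():
                    rec[f"apr_hat_{variant.replace('-', '_')}"] = values[run, m]
                records.append(rec)
        return pd.DataFrame.from_records(records)


def analyze_snapshot(
    snapshot,
    matrix: ExpressionMatrix | np.ndarray,
    fdr_level: float,
    apr_threshold: float,
    variants: tuple[str, ...] = DEFAULT_VARIANTS,
    theta: float = 0.5,
    truth: EffectVector | None = None,
    index: int = 1,
    phase: str = "",
) -> AnalysisResult:
    """Run the per-look pipeline (screen, adjust, estimate, stop) once."""
    p_raw = cox_screen.screen_genes(snapshot, matrix)
    reject = error_control.reject_bh(p_raw, fdr_level)
    alpha_bh = error_control.bh_alpha(p_raw, fdr_level)
    decision = error_control.confusion_metrics(reject, truth) if truth is not None else None
    apr: dict[str, AprEstimate] = {}
    stop: dict[str, bool] = {}
    for variant in variants:
        est = apr_estimation.estimate_apr(p_raw, fdr_level, variant, theta)
        apr[variant] = est
        stop[variant] = apr_estimation.check_stop(est, apr_threshold)
    return AnalysisResult(
        index=index,
        time=snapshot.analysis_time,
        phase=phase,
        n_included=snapshot.n_included,
        n_events=snapshot.n_events,
        r=len(reject),
        alpha_bh=alpha_bh,
        decision=decision,
        apr=apr,
        stop=stop,
    )


def run_study(config: SimulationConfig, run_seed: int) -> StudyRun:
    """Simulate and analyze one complete study, deterministically.

    The random stream is derived from (base_seed, run_seed) so replicate
    runs are independent and reproducible in any order.
    """
    rng = np.random.default_rng([config.base_seed, run_seed])
    cohort = simulate_patients(config.design, config.survival_model, rng)
    effects = build_effect_vector(config.d, config.effect_model, rng)
    matrix = simulate_expression(cohort, effects, config.correlation, rng)
    schedule = schedule_analyses(config.design, cohort.arrivals)

    results = []
    for m, (t, phase) in enumerate(zip(schedule.times, schedule.phases), start=1):
        snapshot = take_snapshot(cohort, t)
        results.append(
            analyze_snapshot(
                snapshot,
                matrix,
                fdr_level=config.design.fdr_level,
                apr_threshold=config.design.apr_threshold,
                variants=config.variants,
                theta=config.theta,
                truth=effects,
                index=m,
                phase=phase,
            )
        )

    sentinel = config.design.m_total + 1
    first_stop = {}
    for variant in config.variants:
        stops = [res.index for res in results if res.stop[variant]]
        first_stop[variant] = stops[0] if stops else sentinel
    return StudyRun(run_seed=run_seed, results=results, first_stop=first_stop)


def run_monte_carlo(
    config: SimulationConfig, progress: bool = False
) -> MonteCarloSummary:
    """Replicate ``run_study`` n_runs times and aggregate per-look metrics."""
    m_total = config.design.m_total
    shape = (config.n_runs, m_total)
    times = np.zeros(shape)
    n_inc = np.zeros(shape)
    n_ev = np.zeros(shape)
    r = np.zeros(shape)
    fdp = np.zeros(shape)
    apr_true = np.zeros(shape)
    apr_hat = {v: np.zeros(shape) for v in config.variants}
    first_stop = {v: np.zeros(config.n_runs, dtype=int) for v in config.variants}

    for run in range(config.n_runs):
        study = run_study(config, run)
        for m, res in enumerate(study.results):
            times[run, m] = res.time
            n_inc[run, m] = res.n_included
            n_ev[run, m] = res.n_events
            r[run, m] = res.r
            fdp[run, m] = res.decision.fdp
            apr_true[run, m] = res.decision.apr_true
            for variant in config.variants:
                apr_hat[variant][run, m] = res.apr[variant].apr_hat
        for variant in config.variants:
            first_stop[variant][run] = study.first_stop[variant]
        if progress and (run + 1) % max(1, config.n_runs // 20) == 0:
            logger.info("run %d/%d complete", run + 1, config.n_runs)

    return MonteCarloSummary(
        config=config,
        n_runs=config.n_runs,
        times=times,
        n_included=n_inc,
        n_events=n_ev,
        r=r,
        fdp=fdp,
        apr_true=apr_true,
        apr_hat=apr_hat,
        first_stop=first_stop,
    )


def run_on_data(
    expression: pd.DataFrame,
    patients: pd.DataFrame,
    design: StudyDesign,
    variants: tuple[str, ...] = DEFAULT_VARIANTS,
    theta: float = 0.5,
    arrival_seed: int = 0,
) -> list[AnalysisResult]:
    """Apply the per-look pipeline to user-supplied data (no truth metrics).

    ``expression`` is genes x samples with gene ids in the index and sample
    ids as columns; ``patients`` needs patient_id, survival_month and
    optionally arrival_month and event.  Missing arrival times are drawn
    Uniform(0, l1_intended) under ``arrival_seed``.
    """
    sample_ids = [str(c) for c in expression.columns]
    patient_ids = [str(x) for x in patients["patient_id"]]
    missing_expr = sorted(set(patient_ids) - set(sample_ids))
    missing_pat = sorted(set(sample_ids) - set(patient_ids))
    if missing_expr or missing_pat:
        raise AlignmentError(
            "expression/patient tables do not align; "
            f"patients without expression: {missing_expr}; "
            f"samples without patient rows: {missing_pat}"
        )
    patients = patients.set_index("patient_id").loc[[c for c in expression.columns]]

    if "arrival_month" in patients.columns and patients["arrival_month"].notna().all():
        arrivals = patients["arrival_month"].to_numpy(dtype=float)
    else:
        rng = np.random.default_rng(arrival_seed)
        arrivals = rng.uniform(0.0, design.l1_intended, size=len(patients))
        logger.info("arrival times absent: drew Uniform(0, %.3g) with seed %d",
                    design.l1_intended, arrival_seed)

    event = (
        patients["event"].to_numpy(dtype=float).astype(bool)
        if "event" in patients.columns
        else np.ones(len(patients), dtype=bool)
    )
    cohort = PatientCohort(
        arrivals=arrivals,
        survival=patients["survival_month"].to_numpy(dtype=float),
        event_observed=event,
        patient_ids=sample_ids,
    )
    schedule = schedule_analyses(design, cohort.arrivals)
    values = expression.to_numpy(dtype=float)

    results = []
    for m, (t, phase) in enumerate(zip(schedule.times, schedule.phases), start=1):
        snapshot = take_snapshot(cohort, t)
        results.append(
            analyze_snapshot(
                snapshot,
                values,
                fdr_level=design.fdr_level,
                apr_threshold=design.apr_threshold,
                variants=variants,
                theta=theta,
                truth=None,
                index=m,
                phase=phase,
            )
        )
    return results


def results_frame(results: list[AnalysisResult]) -> pd.DataFrame:
    """Tabulate a per-look result sequence (analysis path output)."""
    records = []
    for res in results:
        rec = {
            "analysis": res.index,
            "time": res.time,
            "phase": res.phase,
            "n": res.n_included,
            "events": res.n_events,
            "found": res.r,
            "alpha_bh": res.alpha_bh,
        }
        for variant, est in res.apr.items():
            key = variant.replace("-", "_")
            rec[f"pi0_hat_{key}"] = est.pi0_hat
            rec[f"fp_hat_{key}"] = est.fp_hat
            rec[f"d1_hat_{key}"] = est.d1_hat
            rec[f"apr_hat_{key}"] = est.apr_hat
            rec[f"stop_{key}"] = res.stop[variant]
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Configuration files and named profiles.
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "n_patients", "l1", "l2", "m1", "m2", "fdr_level", "apr_threshold",
    "survival_family", "mean_survival", "median_survival", "log_scale",
    "effect_mode", "tau", "effect_sd", "effect_step", "effect_table",
    "rho", "sigma2", "d", "theta", "variants", "n_runs", "seed",
}


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a SimulationConfig from a flat key/value mapping.

    Unknown keys are rejected to catch typos in config files.
    """
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    design = StudyDesign(
        n_patients=int(raw.get("n_patients", 50)),
        l1_intended=float(raw.get("l1", 60.0)),
        l2=float(raw.get("l2", 60.0)),
        m1=int(raw.get("m1", 2)),
        m2=int(raw.get("m2", 2)),
        fdr_level=float(raw.get("fdr_level", 0.05)),
        apr_threshold=float(raw.get("apr_threshold", 0.8)),
    )
    family = raw.get("survival_family", "exponential")
    if family == "exponential":
        survival = SurvivalModel.exponential(float(raw.get("mean_survival", 60.0)))
    elif family == "lognormal":
        survival = SurvivalModel.lognormal(
            median_survival=float(raw.get("median_survival", 84.0)),
            log_scale=float(raw.get("log_scale", 1.0)),
        )
    else:
        raise ValueError(f"unknown survival_family: {family!r}")

    mode = raw.get("effect_mode", MODE_DISCRETIZED_NORMAL)
    table = None
    if mode == MODE_TABLE:
        source = raw.get("effect_table", "packaged")
        table = (
            load_packaged_effect_table()
            if source == "packaged"
            else load_effect_table(source)
        )
    effect = EffectModel(
        mode=mode,
        tau=float(raw.get("tau", 0.5)),
        sd=float(raw.get("effect_sd", EFFECT_SD_LARGE)),
        step=float(raw.get("effect_step", EFFECT_STEP_DEFAULT)),
        table=table,
    )
    correlation = CorrelationModel(
        rho=float(raw.get("rho", 0.5)), sigma2=float(raw.get("sigma2", 1.0))
    )
    variants = tuple(raw.get("variants", list(DEFAULT_VARIANTS)))
    return SimulationConfig(
        design=design,
        survival_model=survival,
        effect_model=effect,
        correlation=correlation,
        d=int(raw.get("d", 1000)),
        theta=float(raw.get("theta", 0.5)),
        variants=variants,
        n_runs=int(raw.get("n_runs", 50)),
        base_seed=int(raw.get("seed", 0)),
    )


def load_config(path: str) -> SimulationConfig:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat key/value mapping")
    return config_from_dict(raw)


def config_to_dict(config: SimulationConfig) -> dict:
    """Flat mapping echoing the configuration (inverse of config_from_dict)."""
    design = config.design
    out = {
        "n_patients": design.n_patients,
        "l1": design.l1_intended,
        "l2": design.l2,
        "m1": design.m1,
        "m2": design.m2,
        "fdr_level": design.fdr_level,
        "apr_threshold": design.apr_threshold,
        "survival_family": config.survival_model.family,
        "effect_mode": config.effect_model.mode,
        "tau": config.effect_model.tau,
        "effect_sd": config.effect_model.sd,
        "effect_step": config.effect_model.step,
        "rho": config.correlation.rho,
        "sigma2": config.correlation.sigma2,
        "d": config.d,
        "theta": config.theta,
        "variants": list(config.variants),
        "n_runs": config.n_runs,
        "seed": config.base_seed,
    }
    if config.survival_model.family == "exponential":
        out["mean_survival"] = config.survival_model.mean_survival
    else:
        out["median_survival"] = float(np.exp(config.survival_model.log_location))
        out["log_scale"] = config.survival_model.log_scale
    if config.effect_model.mode == MODE_TABLE:
        out["effect_table"] = "packaged"
    return out


#: Full-scale named profiles.  Scale d and n_runs down via CLI flags or
#: ``replace`` for desk-scale work.
PROFILES: dict[str, dict] = {
    "m4-tau50": {
        "n_patients": 50, "l1": 60.0, "l2": 60.0, "m1": 2, "m2": 2,
        "mean_survival": 60.0, "tau": 0.5, "effect_sd": EFFECT_SD_LARGE,
        "d": 10000, "n_runs": 1000,
    },
    "m10-tau50": {
        "n_patients": 50, "l1": 60.0, "l2": 60.0, "m1": 5, "m2": 5,
        "mean_survival": 60.0, "tau": 0.5, "effect_sd": EFFECT_SD_LARGE,
        "d": 10000, "n_runs": 1000,
    },
    "m10-tau50-small": {
        "n_patients": 50, "l1": 60.0, "l2": 60.0, "m1": 5, "m2": 5,
        "mean_survival": 60.0, "tau": 0.5, "effect_sd": EFFECT_SD_SMALL,
        "d": 10000, "n_runs": 1000,
    },
    "m10-tau5": {
        "n_patients": 50, "l1": 60.0, "l2": 60.0, "m1": 5, "m2": 5,
        "mean_survival": 60.0, "tau": 0.05, "effect_sd": EFFECT_SD_LARGE,
        "d": 10000, "n_runs": 1000,
    },
    "breast": {
        "n_patients": 295, "l1": 132.0, "l2": 84.0, "m1": 5, "m2": 5,
        "survival_family": "lognormal", "median_survival": 84.0, "log_scale": 1.0,
        "effect_mode": MODE_TABLE, "effect_table": "packaged",
        "sigma2": 0.1, "d": 24496, "n_runs": 1000, "apr_threshold": 0.5,
    },
}


def profile_config(name: str, **overrides) -> SimulationConfig:
    """Instantiate a named profile, optionally overriding flat keys."""
    if name not in PROFILES:
        raise KeyError(f"unknown profile {name!r}; available: {sorted(PROFILES)}")
    raw = dict(PROFILES[name])
    raw.update(overrides)
    return config_from_dict(raw)


def scaled(config: SimulationConfig, d: int | None = None,
           n_runs: int | None = None) -> SimulationConfig:
    """Convenience: shrink gene count and/or run count for desk-scale work."""
    out = config
    if d is not None:
        out = replace(out, d=d)
    if n_runs is not None:
        out = replace(out, n_runs=n_runs)
    return out
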