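"""Two-phase trial geometry: analysis scheduling and censored snapshots.

A study recruits ``N`` patients over an intended window of ``l1_intended``
months and then follows them for ``l2`` further months.  ``M1`` analyses are
performed during recruitment (each time a further ``N/M1`` patients have
arrived) and ``M2`` analyses at equally spaced calendar times during
follow-up.  At any analysis time ``t`` only patients with ``arrival <= t``
are visible, with their survival administratively censored at ``t``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASE_RECRUITMENT = "recruitment"
PHASE_FOLLOW_UP = "follow-up"


class InvalidDesignError(ValueError):
    """Raised when trial geometry parameters are inconsistent."""


@dataclass(frozen=True)
class StudyDesign:
    """Trial geometry plus the per-analysis error/stopping policy.

    Parameters
    ----------
    n_patients : planned total sample size N.
    l1_intended : planned recruitment length in months (actual recruitment
        ends at the last observed arrival, which may be earlier).
    l2 : follow-up length in months.
    m1, m2 : number of analyses during recruitment and follow-up.
    fdr_level : nominal FDR level used by the BH adjustment at every look.
    apr_threshold : estimated-APR level at which the study may stop.
    """

    n_patients: int
    l1_intended: float
    l2: float
    m1: int
    m2: int
    fdr_level: float = 0.05
    apr_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise InvalidDesignError("n_patients must be >= 2")
        if self.m1 < 1 or self.m2 < 1:
            raise InvalidDesignError("m1 and m2 must be >= 1")
        if self.n_patients < self.m1:
            raise InvalidDesignError(
                "more recruitment analyses than patients (m1 > n_patients)"
            )
        if self.l1_intended <= 0:
            raise InvalidDesignError("l1_intended must be > 0")
        if self.l2 < 0:
            raise InvalidDesignError("l2 must be >= 0")
        if not 0.0 < self.fdr_level < 1.0:
            raise InvalidDesignError("fdr_level must be in (0, 1)")
        if not 0.0 < self.apr_threshold <= 1.0:
            raise InvalidDesignError("apr_threshold must be in (0, 1]")

    @property
    def m_total(self) -> int:
        """Total number of analyses M = M1 + M2."""
        return self.m1 + self.m2

    @property
    def total_length(self) -> float:
        """Intended total study length L = l1_intended + l2."""
        return self.l1_intended + self.l2


@dataclass
class PatientCohort:
    """Per-patient arrival and survival data.

    ``survival`` holds the *true* time from arrival to death for simulated
    cohorts, or the observed (possibly right-censored) follow-up time for
    real data, in which case ``event_observed`` flags which patients died
    within their recorded follow-up.  ``short_survivor`` is the latent group
    label used by the expression generator; it may be ``None`` for real data.
    """

    arrivals: np.ndarray
    survival: np.ndarray
    short_survivor: np.ndarray | None = None
    event_observed: np.ndarray | None = None
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.arrivals = np.asarray(self.arrivals, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.arrivals.shape != self.survival.shape:
            raise ValueError("arrivals and survival must have equal length")
        if np.any(self.arrivals < 0):
            raise ValueError("arrival times must be >= 0")
        if np.any(self.survival <= 0):
            raise ValueError("survival times must be > 0")
        if self.short_survivor is not None:
            self.short_survivor = np.asarray(self.short_survivor, dtype=bool)
            if self.short_survivor.shape != self.arrivals.shape:
                raise ValueError("short_survivor length mismatch")
        if self.event_observed is None:
            self.event_observed = np.ones(self.arrivals.shape, dtype=bool)
        else:
            self.event_observed = np.asarray(self.event_observed, dtype=bool)
            if self.event_observed.shape != self.arrivals.shape:
                raise ValueError("event_observed length mismatch")
        if not self.patient_ids:
            self.patient_ids = [f"p{j + 1}" for j in range(len(self.arrivals))]

    @property
    def n(self) -> int:
        return len(self.arrivals)

    @property
    def recruitment_end(self) -> float:
        """Actual end of recruitment: the last arrival time."""
        return float(np.max(self.arrivals))


@dataclass
class AnalysisSchedule:
    """Calendar times of all M analyses with phase tags and sample counts."""

    times: np.ndarray
    phases: list[str]
    sample_counts: np.ndarray

    @property
    def m_total(self) -> int:
        return len(self.times)


@dataclass
class SurvivalSnapshot:
    """The censored view of a cohort at one analysis time.

    ``observed_time`` is ``min(survival, t - arrival)`` and ``event`` is 1
    exactly when the death was observed by time ``t``.  Zero-length records
    (patients arriving exactly at ``t``) are kept here but carry no risk-set
    information and are dropped by the Cox fitter.
    """

    analysis_time: float
    patient_index: np.ndarray
    observed_time: np.ndarray
    event: np.ndarray

    @property
    def n_included(self) -> int:
        return len(self.patient_index)

    @property
    def n_events(self) -> int:
        return int(np.sum(self.event))


def schedule_analyses(design: StudyDesign, arrivals: np.ndarray) -> AnalysisSchedule:
    """Compute the M1 + M2 analysis times for the observed arrival pattern.

    Recruitment analysis ``m`` happens at the arrival of patient
    ``k = round(m * N / M1)`` (round half up) in arrival order; follow-up
    analysis ``m`` at ``max(arrivals) + (m / M2) * l2``.
    """
    arrivals = np.asarray(arrivals, dtype=float)
    if arrivals.shape != (design.n_patients,):
        raise InvalidDesignError(
            f"expected {design.n_patients} arrival times, got {arrivals.shape}"
        )
    if np.any(arrivals < 0) or np.any(arrivals > design.l1_intended):
        raise InvalidDesignError("arrivals must lie in [0, l1_intended]")

    sorted_arrivals = np.sort(arrivals)
    l1_actual = sorted_arrivals[-1]

    times: list[float] = []
    phases: list[str] = []
    for m in range(1, design.m1 + 1):
        k = int(np.floor(m * design.n_patients / design.m1 + 0.5))
        k = min(max(k, 1), design.n_patients)
        times.append(float(sorted_arrivals[k - 1]))
        phases.append(PHASE_RECRUITMENT)
    for m in range(1, design.m2 + 1):
        times.append(float(l1_actual + m / design.m2 * design.l2))
        phases.append(PHASE_FOLLOW_UP)

    times_arr = np.asarray(times)
    counts = np.searchsorted(sorted_arrivals, times_arr, side="right")
    return AnalysisSchedule(times=times_arr, phases=phases, sample_counts=counts)


def take_snapshot(cohort: PatientCohort, t: float) -> SurvivalSnapshot:
    """Administratively censor the cohort at calendar time ``t``.

    Includes exactly the patients with ``arrival <= t``.  An empty snapshot
    is valid and must be handled downstream.
    """
    if t < 0:
        raise ValueError("analysis time must be >= 0")
    included = np.nonzero(cohort.arrivals <= t)[0]
    follow_up = t - cohort.arrivals[included]
    surv = cohort.survival[included]
    observed = np.minimum(surv, follow_up)
    event = (surv <= follow_up) & cohort.event_observed[included]
    return SurvivalSnapshot(
        analysis_time=float(t),
        patient_index=included,
        observed_time=observed,
        event=event.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# Patient-table IO: delimited text, header row required.
# ---------------------------------------------------------------------------

_SEP_BY_EXT = {".csv": ",", ".tsv": "\t", ".tab": "\t", ".txt": "\t"}


def _separator_for(path: str) -> str | None:
    return _SEP_BY_EXT.get(os.path.splitext(path)[1].lower())


def read_patient_table(path: str) -> pd.DataFrame:
    """Read a patient table: patient_id, arrival_month, survival_month[, event]."""
    sep = _separator_for(path)
    if sep is None:
        frame = pd.read_csv(path, sep=None, engine="python")
    else:
        frame = pd.read_csv(path, sep=sep)
    required = {"patient_id", "survival_month"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"patient table missing columns: {sorted(missing)}")
    return frame


def write_patient_table(path: str, cohort: PatientCohort) -> None:
    frame = pd.DataFrame(
        {
            "patient_id": cohort.patient_ids,
            "arrival_month": cohort.arrivals,
            "survival_month": cohort.survival,
            "event": cohort.event_observed.astype(int),
        }
    )
    frame.to_csv(path, sep=_separator_for(path) or ",", index=False)


def cohort_from_table(frame: pd.DataFrame) -> PatientCohort:
    """Build a cohort from a parsed patient table (arrivals may be absent)."""
    arrivals = (
        frame["arrival_month"].to_numpy(dtype=float)
        if "arrival_month" in frame.columns
        else np.full(len(frame), np.nan)
    )
    event = (
        frame["event"].to_numpy(dtype=int).astype(bool)
        if "event" in frame.columns
        else np.ones(len(frame), dtype=bool)
    )
    return PatientCohort(
        arrivals=np.nan_to_num(arrivals, nan=0.0),
        survival=frame["survival_month"].to_numpy(dtype=float),
        event_observed=event,
        patient_ids=[str(x) for x in frame["patient_id"]],
    )
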