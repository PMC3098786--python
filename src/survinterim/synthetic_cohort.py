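"""Generators for patient cohorts and correlated expression matrices.

Two generative settings are supported: exponential survival with a
discretized-normal effect vector (a random fraction ``tau`` of genes gets a
grid-rounded normal mean shift in the long-survivor group), and log-normal
survival with effects taken from a fixed value/count table.  Expression is
multivariate normal with an AR(1) covariance ``sigma2 * rho**|i-k|``, sampled
by the sequential construction so no dense d x d factorization is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .study_design import PatientCohort, StudyDesign

FAMILY_EXPONENTIAL = "exponential"
FAMILY_LOGNORMAL = "lognormal"

MODE_DISCRETIZED_NORMAL = "discretized-normal"
MODE_TABLE = "table"

PACKAGED_EFFECT_TABLE = "breast_effect_table.csv"


class InvalidEffectTableError(ValueError):
    """Raised when a value/count effect table is inconsistent with d."""


@dataclass(frozen=True)
class SurvivalModel:
    """Marginal survival-time distribution plus the short/long split point.

    Exponential mode splits the cohort at the mean ``mean_survival``;
    log-normal mode splits at the distribution median ``exp(log_location)``.
    """

    family: str
    mean_survival: float | None = None
    log_location: float | None = None
    log_scale: float | None = None

    def __post_init__(self) -> None:
        if self.family == FAMILY_EXPONENTIAL:
            if self.mean_survival is None or self.mean_survival <= 0:
                raise ValueError("exponential model needs mean_survival > 0")
        elif self.family == FAMILY_LOGNORMAL:
            if self.log_location is None or self.log_scale is None:
                raise ValueError("log-normal model needs log_location and log_scale")
            if self.log_scale <= 0:
                raise ValueError("log-normal scale must be > 0")
        else:
            raise ValueError(f"unknown survival family: {self.family!r}")

    @classmethod
    def exponential(cls, mean_survival: float) -> "SurvivalModel":
        return cls(family=FAMILY_EXPONENTIAL, mean_survival=mean_survival)

    @classmethod
    def lognormal(cls, median_survival: float, log_scale: float) -> "SurvivalModel":
        return cls(
            family=FAMILY_LOGNORMAL,
            log_location=float(np.log(median_survival)),
            log_scale=log_scale,
        )

    @property
    def group_split(self) -> float:
        """Survival cut below which a patient counts as a short survivor."""
        if self.family == FAMILY_EXPONENTIAL:
            return float(self.mean_survival)
        return float(np.exp(self.log_location))

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == FAMILY_EXPONENTIAL:
            return rng.exponential(self.mean_survival, size=n)
        return rng.lognormal(self.log_location, self.log_scale, size=n)


@dataclass(frozen=True)
class EffectModel:
    """How per-gene mean shifts for the long-survivor group are produced."""

    mode: str = MODE_DISCRETIZED_NORMAL
    tau: float = 0.5
    sd: float = 1.6
    step: float = 1.0
    table: tuple[tuple[float, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in (MODE_DISCRETIZED_NORMAL, MODE_TABLE):
            raise ValueError(f"unknown effect mode: {self.mode!r}")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")
        if self.sd <= 0 or self.step <= 0:
            raise ValueError("sd and step must be > 0")
        if self.mode == MODE_TABLE:
            if self.table is None:
                raise ValueError("table mode needs a value/count table")
            if any(count < 0 for _, count in self.table):
                raise ValueError("table counts must be >= 0")


@dataclass
class EffectVector:
    """Per-gene group-2 mean shift; group-1 means are identically zero."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def d(self) -> int:
        return len(self.values)

    @property
    def alt_set(self) -> np.ndarray:
        """Indices of truly non-null (survival-related) genes."""
        return np.nonzero(self.values != 0.0)[0]

    @property
    def null_set(self) -> np.ndarray:
        return np.nonzero(self.values == 0.0)[0]

    @property
    def d1(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def d0(self) -> int:
        return self.d - self.d1


@dataclass(frozen=True)
class CorrelationModel:
    """AR(1) gene-gene covariance: Sigma_ik = sigma2 * rho**|i-k|."""

    rho: float = 0.5
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with id labels."""

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d, n = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"g{i + 1}" for i in range(d)]
        if not self.sample_ids:
            self.sample_ids = [f"p{j + 1}" for j in range(n)]
        if len(self.gene_ids) != d or len(self.sample_ids) != n:
            raise ValueError("id labels do not match matrix dimensions")

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def simulate_patients(
    design: StudyDesign, survival_model: SurvivalModel, rng: np.random.Generator
) -> PatientCohort:
    """Draw arrivals Uniform(0, l1_intended) and survivals from the model."""
    arrivals = rng.uniform(0.0, design.l1_intended, size=design.n_patients)
    survival = survival_model.draw(design.n_patients, rng)
    # Guard against a measure-zero exact-zero draw.
    survival = np.maximum(survival, np.finfo(float).tiny)
    short = survival < survival_model.group_split
    return PatientCohort(arrivals=arrivals, survival=survival, short_survivor=short)


def _round_to_grid(values: np.ndarray, step: float) -> np.ndarray:
    return np.round(np.asarray(values, dtype=float) / step) * step


def build_effect_vector(
    d: int, model: EffectModel, rng: np.random.Generator
) -> EffectVector:
    """Construct the per-gene mean-shift vector for the long-survivor group.

    Discretized-normal mode: a random round(tau*d) subset of genes receives a
    grid-rounded Normal(0, sd) draw, redrawn until nonzero so the declared
    altered fraction is exact.  Table mode: the multiset of values equals the
    table; assignment to gene indices is randomized.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    values = np.zeros(d)
    if model.mode == MODE_DISCRETIZED_NORMAL:
        n_alt = int(np.floor(model.tau * d + 0.5))
        if n_alt > 0:
            idx = rng.choice(d, size=n_alt, replace=False)
            draws = _round_to_grid(rng.normal(0.0, model.sd, size=n_alt), model.step)
            zero = draws == 0.0
            while np.any(zero):
                draws[zero] = _round_to_grid(
                    rng.normal(0.0, model.sd, size=int(zero.sum())), model.step
                )
                zero = draws == 0.0
            values[idx] = draws
    else:
        counts = np.array([count for _, count in model.table], dtype=int)
        if counts.sum() != d:
            raise InvalidEffectTableError(
                f"effect-table counts sum to {counts.sum()}, expected d={d}"
            )
        pool = np.repeat([value for value, _ in model.table], counts)
        values = pool[rng.permutation(d)]
    return EffectVector(values=values)


def simulate_expression(
    cohort: PatientCohort,
    effects: EffectVector,
    corr: CorrelationModel,
    rng: np.random.Generator,
    shift_group: str = "long",
) -> ExpressionMatrix:
    """Sample the d x n expression matrix with AR(1) gene-gene covariance.

    Column j is MVN(0, Sigma) for one survivor group and MVN(mu2, Sigma) for
    the other (by default long survivors carry the shift; the Cox test is
    sign-symmetric so the convention is arbitrary).  Uses the sequential
    AR(1) construction e_i = rho*e_{i-1} + sqrt(1-rho^2)*z_i, O(d*n).
    """
    if cohort.n == 0:
        raise ValueError("cohort must be nonempty")
    if cohort.short_survivor is None:
        raise ValueError("cohort lacks group labels; cannot place effects")
    if shift_group not in ("long", "short"):
        raise ValueError("shift_group must be 'long' or 'short'")

    d, n = effects.d, cohort.n
    z = rng.standard_normal((d, n))
    if corr.rho > 0.0:
        w = z
        w[1:] *= np.sqrt(1.0 - corr.rho**2)
        z = lfilter([1.0], [1.0, -corr.rho], w, axis=0)
    x = np.sqrt(corr.sigma2) * z
    shifted = ~cohort.short_survivor if shift_group == "long" else cohort.short_survivor
    x[:, shifted] += effects.values[:, None]
    return ExpressionMatrix(values=x, sample_ids=list(cohort.patient_ids))


# ---------------------------------------------------------------------------
# Effect-table and expression-matrix IO.
# ---------------------------------------------------------------------------


def load_effect_table(path_or_buffer) -> tuple[tuple[float, int], ...]:
    """Read a value/count effect table from delimited text."""
    frame = pd.read_csv(path_or_buffer, sep=None, engine="python")
    missing = {"value", "count"} - set(frame.columns)
    if missing:
        raise InvalidEffectTableError(f"effect table missing columns: {sorted(missing)}")
    return tuple(
        (float(v), int(c)) for v, c in zip(frame["value"], frame["count"])
    )


def load_packaged_effect_table() -> tuple[tuple[float, int], ...]:
    """The breast-cancer-derived value/count table shipped with the package."""
    ref = resources.files("survinterim.data").joinpath(PACKAGED_EFFECT_TABLE)
    with ref.open("r") as handle:
        return load_effect_table(handle)


def write_expression_matrix(path: str, matrix: ExpressionMatrix) -> None:
    frame = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids)
    frame.index.name = "gene_id"
    frame.to_csv(path)


def read_expression_matrix(path: str) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ExpressionMatrix(
        values=frame.to_numpy(dtype=float),
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
    )
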