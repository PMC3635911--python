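"""Synthetic patient-response generators.

Three minimal stochastic families cover every outcome type the design
simulators need:

* :class:`BinaryResponseModel` — Bernoulli success/failure per patient-period,
  with an optional first-order carry-over shift on the probability scale when
  the patient's previous period was on an active arm;
* :class:`TrajectoryModel` — Gaussian score trajectories with
  treatment-dependent linear slopes, an immediate symptomatic offset under
  active treatment, and equicorrelated within-patient residuals (shared
  patient-level intercept, correlation ``rho``);
* :class:`LatencyModel` — time-to-response with a piecewise-constant hazard
  that switches from ``hazard_untreated`` to ``hazard_treated`` when active
  treatment starts.

All generators are pure functions of (model, cohort spec, arguments): the
same seed reproduces the same draws bit for bit.  Arm index 0 is the
placebo/control arm by convention; higher indices are active arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinaryResponseModel",
    "TrajectoryModel",
    "LatencyModel",
    "CohortSpec",
    "generate_binary_outcomes",
    "generate_trajectories",
    "generate_latencies",
    "cohort_to_frame",
]


@dataclass(frozen=True)
class BinaryResponseModel:
    """Per-arm success probabilities, optional carry-over shift.

    ``carryover_shift`` is added to the success probability of any
    patient-period whose *previous* period was on an active arm (index >= 1);
    the shifted probability is clipped to [0, 1].
    """

    p_success: tuple[float, ...]
    carryover_shift: float = 0.0

    def __post_init__(self) -> None:
        if len(self.p_success) < 1:
            raise ValueError("at least one arm is required")
        if any(not 0.0 <= p <= 1.0 for p in self.p_success):
            raise ValueError(f"success probabilities must lie in [0, 1]: {self.p_success}")

    @property
    def n_arms(self) -> int:
        return len(self.p_success)


@dataclass(frozen=True)
class TrajectoryModel:
    """Gaussian score trajectory with treatment-dependent linear slopes.

    Mean score at time ``t`` (weeks) for a patient starting active treatment
    at ``s``::

        baseline + symptomatic_offset * 1[t >= s]
                 + slope_placebo * min(t, s) + slope_active * max(0, t - s)

    ``rho`` is the within-patient correlation of the residuals, realised as a
    shared patient-level intercept with variance ``rho * residual_sd**2``.
    """

    baseline_mean: float
    baseline_sd: float
    slope_active: float
    slope_placebo: float
    residual_sd: float
    rho: float = 0.0
    symptomatic_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1): {self.rho}")

    def mean_score(self, t: np.ndarray, active_start: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        s = np.asarray(active_start, dtype=float)[..., None]
        # strict inequality: a measurement taken at the start time itself is
        # pre-dose, so the symptomatic shift has not yet appeared
        on_active = (t > s).astype(float)
        return (
            self.baseline_mean
            + self.symptomatic_offset * on_active
            + self.slope_placebo * np.minimum(t, s)
            + self.slope_active * np.maximum(0.0, t - s)
        )


@dataclass(frozen=True)
class LatencyModel:
    """Piecewise-exponential time-to-response (rates per week)."""

    hazard_untreated: float
    hazard_treated: float

    def __post_init__(self) -> None:
        if self.hazard_untreated < 0 or self.hazard_treated < 0:
            raise ValueError("hazards must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort size, the response model generating it, and a seed."""

    n_patients: int
    model: BinaryResponseModel | TrajectoryModel | LatencyModel
    seed: int

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1: {self.n_patients}")


def generate_binary_outcomes(spec: CohortSpec, assignments: np.ndarray) -> np.ndarray:
    """Success/failure matrix for an (n_patients, n_periods) arm assignment.

    Returns a boolean array of the same shape.  Carry-over: the model's
    ``carryover_shift`` is applied to periods whose previous period was on an
    active arm.
    """
    model = spec.model
    if not isinstance(model, BinaryResponseModel):
        raise TypeError("generate_binary_outcomes needs a BinaryResponseModel")
    assignments = np.atleast_2d(np.asarray(assignments, dtype=int))
    if assignments.shape[0] != spec.n_patients:
        raise ValueError(
            f"assignments have {assignments.shape[0]} rows for {spec.n_patients} patients"
        )
    if assignments.min() < 0 or assignments.max() >= model.n_arms:
        bad = sorted(set(assignments.ravel()) - set(range(model.n_arms)))
        raise ValueError(f"undefined arm index(es) {bad}; model has {model.n_arms} arms")
    p = np.asarray(model.p_success, dtype=float)[assignments]
    if model.carryover_shift != 0.0 and assignments.shape[1] > 1:
        prev_active = np.zeros_like(p, dtype=bool)
        prev_active[:, 1:] = assignments[:, :-1] >= 1
        p = np.clip(p + model.carryover_shift * prev_active, 0.0, 1.0)
    rng = np.random.default_rng(spec.seed)
    return rng.random(p.shape) < p


def generate_trajectories(
    spec: CohortSpec, active_start: np.ndarray, visit_times: np.ndarray
) -> np.ndarray:
    """Score series (n_patients, n_visits) for per-patient treatment starts.

    ``active_start`` gives, per patient, the week active treatment begins
    (``np.inf`` for never); ``visit_times`` must be strictly increasing.
    """
    model = spec.model
    if not isinstance(model, TrajectoryModel):
        raise TypeError("generate_trajectories needs a TrajectoryModel")
    visit_times = np.asarray(visit_times, dtype=float)
    if visit_times.ndim != 1 or len(visit_times) < 1:
        raise ValueError("visit_times must be a non-empty 1-d array")
    if np.any(np.diff(visit_times) <= 0):
        raise ValueError(f"visit times must be strictly increasing: {visit_times}")
    active_start = np.broadcast_to(
        np.asarray(active_start, dtype=float), (spec.n_patients,)
    )
    mean = model.mean_score(visit_times, active_start)
    rng = np.random.default_rng(spec.seed)
    baseline_dev = rng.normal(0.0, model.baseline_sd, size=(spec.n_patients, 1))
    sd_shared = model.residual_sd * np.sqrt(model.rho)
    sd_indep = model.residual_sd * np.sqrt(1.0 - model.rho)
    shared = rng.normal(0.0, 1.0, size=(spec.n_patients, 1)) * sd_shared
    indep = rng.normal(0.0, 1.0, size=mean.shape) * sd_indep
    return mean + baseline_dev + shared + indep


def generate_latencies(spec: CohortSpec, start_of_active: np.ndarray) -> np.ndarray:
    """Response time per patient under the piecewise-constant hazard.

    Hazard is ``hazard_untreated`` before each patient's ``start_of_active``
    and ``hazard_treated`` after.  Patients whose cumulative hazard never
    reaches their exponential draw (both hazards 0, or treated hazard 0 after
    an untreated phase that ends) get ``np.inf``.
    """
    model = spec.model
    if not isinstance(model, LatencyModel):
        raise TypeError("generate_latencies needs a LatencyModel")
    s = np.broadcast_to(np.asarray(start_of_active, dtype=float), (spec.n_patients,))
    if np.any(s < 0):
        raise ValueError("start_of_active times must be >= 0")
    rng = np.random.default_rng(spec.seed)
    e = rng.exponential(1.0, size=spec.n_patients)
    h0, h1 = model.hazard_untreated, model.hazard_treated
    pre_mass = h0 * s  # cumulative hazard available before treatment starts
    t = np.full(spec.n_patients, np.inf)
    before = e < pre_mass
    if h0 > 0:
        t[before] = e[before] / h0
    after = ~before
    if h1 > 0:
        t[after] = s[after] + (e[after] - pre_mass[after]) / h1
    return t


def cohort_to_frame(assignments: np.ndarray, outcomes: np.ndarray) -> pd.DataFrame:
    """Long-format audit table: one row per patient-period."""
    assignments = np.atleast_2d(assignments)
    outcomes = np.atleast_2d(outcomes)
    n, m = assignments.shape
    return pd.DataFrame(
        {
            "patient_id": np.repeat(np.arange(n), m),
            "period": np.tile(np.arange(m), n),
            "arm": assignments.ravel(),
            "outcome": outcomes.ravel().astype(int),
        }
    )
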