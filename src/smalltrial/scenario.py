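"""Scenario description shared by all design simulators.

A :class:`TrialScenario` bundles the response models for one
disease-treatment-outcome situation with the design parameters each
simulator needs.  Not every field is meaningful for every design; each
simulator validates the subset it uses.  Scenarios round-trip to plain
dictionaries (and hence YAML/JSON) for the command-line interface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .response_models import BinaryResponseModel, LatencyModel, TrajectoryModel

__all__ = ["TrialScenario", "scenario_fingerprint"]


@dataclass(frozen=True)
class TrialScenario:
    """Response models plus design parameters for one simulation run.

    Arm convention everywhere: index 0 = placebo/control, index 1+ = active.
    ``binary`` supplies per-period success probabilities; ``relapse``
    supplies phase-2 relapse probabilities for withdrawal-type designs
    (index 0 = randomised to placebo, 1 = continued treatment).
    """

    design: str | None = None
    # response models
    binary: BinaryResponseModel | None = None
    relapse: BinaryResponseModel | None = None
    trajectory: TrajectoryModel | None = None
    latency: LatencyModel | None = None
    # shared sizes / horizon
    n_per_arm: int = 50
    n_patients: int | None = None  # overrides 2 * n_per_arm where set
    followup_weeks: float = 16.0
    ratio: tuple[float, float] = (1.0, 1.0)
    # within-patient designs
    n_periods: int = 2
    period_weeks: float = 4.0
    washout: bool = True
    washout_weeks: float = 2.0
    n_treatments: int = 3  # latin square
    n_pairs: int = 3  # n-of-1 period pairs
    measurements_per_period: int = 2
    period_effect: float = 0.0
    # factorial
    factor_a_effect: float = 0.0
    factor_b_effect: float = 0.0
    interaction_effect: float = 0.0
    outcome_sd: float = 1.0
    # delayed start
    phase1_weeks: float = 36.0
    phase2_weeks: float = 36.0
    visit_spacing_weeks: float = 6.0
    slope_window_offset_weeks: float = 12.0
    ni_margin: float = 0.15
    # placebo phase
    delays: tuple[float, ...] = (2.0, 8.0)
    delay_probs: tuple[float, ...] = (0.5, 0.5)
    # stepped wedge
    n_clusters: int = 5
    n_steps: int = 5
    cluster_size: int = 10
    cluster_sd: float = 1.0
    # withdrawal / three-stage / early escape
    run_in_weeks: float = 8.0
    withdrawal_weeks: float = 16.0
    bridging_weeks: float = 8.0
    stage3_weeks: float = 16.0
    horizon_periods: int = 4
    # adaptive randomisation
    urn_rule: str = "PW"
    # testing / replication
    alpha: float = 0.05
    seed: int = 0
    n_reps: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1): {self.alpha}")
        if self.n_reps < 1 or self.n_per_arm < 1:
            raise ValueError("counts must be >= 1")
        if self.n_patients is not None and self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("followup_weeks", "period_weeks", "phase1_weeks", "phase2_weeks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def total_patients(self) -> int:
        return self.n_patients if self.n_patients is not None else 2 * self.n_per_arm

    def replace(self, **changes) -> "TrialScenario":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("binary", "relapse", "trajectory", "latency"):
            if d[key] is not None:
                d[key] = dict(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "TrialScenario":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario field(s): {sorted(unknown)}")
        converters = {
            "binary": BinaryResponseModel,
            "relapse": BinaryResponseModel,
            "trajectory": TrajectoryModel,
            "latency": LatencyModel,
        }
        for key, ctor in converters.items():
            v = data.get(key)
            if isinstance(v, dict):
                if "p_success" in v:
                    v = {**v, "p_success": tuple(v["p_success"])}
                data[key] = ctor(**v)
        for key in ("ratio", "delays", "delay_probs"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def scenario_fingerprint(scenario: TrialScenario) -> str:
    """Deterministic hash of the scenario configuration (including seed)."""
    payload = json.dumps(scenario.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
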