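import numpy as np
import pytest

from smalltrial.response_models import (
    BinaryResponseModel,
    LatencyModel,
    TrajectoryModel,
)
from smalltrial.scenario import TrialScenario


@pytest.fixture
def null_trajectory() -> TrajectoryModel:
    """Score model with no treatment effect (slopes equal, no offset)."""
    return TrajectoryModel(
        baseline_mean=25.0,
        baseline_sd=8.0,
        slope_active=0.1,
        slope_placebo=0.1,
        residual_sd=4.0,
        rho=0.6,
        symptomatic_offset=0.0,
    )


@pytest.fixture
def null_binary() -> BinaryResponseModel:
    return BinaryResponseModel(p_success=(0.6, 0.6))


@pytest.fixture
def effect_binary() -> BinaryResponseModel:
    return BinaryResponseModel(p_success=(0.3, 0.8))


@pytest.fixture
def null_latency() -> LatencyModel:
    return LatencyModel(hazard_untreated=0.2, hazard_treated=0.2)


@pytest.fixture
def base_scenario() -> TrialScenario:
    return TrialScenario(n_reps=2000, seed=20260101)


def mc_band(rate: float, n_reps: int, k: float = 3.0) -> float:
    """k Monte-Carlo standard errors for a rate estimated from n_reps."""
    return k * float(np.sqrt(rate * (1.0 - rate) / n_reps))
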