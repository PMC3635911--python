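"""Side-by-side comparison of every feasible design under a shared scenario.

A single disease-treatment description (a :class:`TrialScenario` template
holding binary, trajectory and/or latency models) is translated onto each
feasible design's parameters so operating characteristics are comparable:

* binary designs (parallel, early escape, withdrawal, three-stage, adaptive)
  share the per-arm success probabilities; withdrawal-type relapse
  probabilities default to one minus the success probability per arm;
* score-based designs (factorial, crossover, Latin square, N-of-1, delayed
  start, stepped wedge) share the trajectory model; the factorial factor-A
  effect is the trajectory's active-vs-placebo endpoint contrast;
* the placebo-phase design uses the latency model.

Designs for which the template lacks the required model appear as
"not simulable" rows rather than being dropped.  Per-design seeds are spawned
deterministically from the template seed, so each row is independent of the
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision import DecisionContext, SelectionResult, explain_selection, select_designs
from .registry import DESIGN_NAMES
from .response_models import BinaryResponseModel
from .scenario import TrialScenario, scenario_fingerprint
from .summaries import SimulationSummary
from .urn import simulate_adaptive
from .simulators import (
    simulate_delayed_start,
    simulate_early_escape,
    simulate_factorial,
    simulate_parallel,
    simulate_placebo_phase,
    simulate_stepped_wedge,
    simulate_three_stage,
    simulate_withdrawal,
    simulate_within_patient,
)

__all__ = ["ComparisonTable", "compare_designs", "run_design", "translate_scenario"]

_TABLE_COLUMNS = [
    "design",
    "rejection_rate",
    "rejection_se",
    "mean_person_time_on_placebo",
    "proportion_ever_active",
    "mean_n_randomized",
    "simulable",
    "note",
]


@dataclass
class ComparisonTable:
    """One row per feasible design plus a deterministic scenario fingerprint."""

    table: pd.DataFrame
    fingerprint: str
    selection: SelectionResult
    caveats: list[str] = field(default_factory=list)


def _required_models(design: str) -> tuple[str, ...]:
    return {
        "parallel": ("binary",),
        "factorial": ("trajectory",),
        "crossover": ("trajectory",),
        "latin_square": ("trajectory",),
        "n_of_1": ("trajectory",),
        "delayed_start": ("trajectory",),
        "placebo_phase": ("latency",),
        "stepped_wedge": ("trajectory",),
        "randomized_withdrawal": ("binary",),
        "early_escape": ("binary",),
        "three_stage": ("binary",),
        "adaptive_randomization": ("binary",),
    }[design]


def translate_scenario(template: TrialScenario, design: str, seed: int) -> TrialScenario:
    """Specialise the shared template to one design (see module docstring)."""
    if design not in DESIGN_NAMES:
        raise KeyError(f"unknown design {design!r}")
    changes: dict = {"design": design, "seed": seed}
    if design in ("randomized_withdrawal", "three_stage") and template.relapse is None:
        if template.binary is None:
            raise ValueError(f"{design} needs a binary model in the template")
        p = template.binary.p_success
        changes["relapse"] = BinaryResponseModel(p_success=(1.0 - p[0], 1.0 - p[1]))
    if design == "factorial" and template.trajectory is not None:
        tm = template.trajectory
        effect = tm.symptomatic_offset + (tm.slope_active - tm.slope_placebo) * template.followup_weeks
        changes["factor_a_effect"] = effect
        changes["outcome_sd"] = float(np.hypot(tm.baseline_sd, tm.residual_sd))
    return template.replace(**changes)


def run_design(scenario: TrialScenario) -> SimulationSummary:
    """Dispatch one fully-specified scenario to its design's simulator."""
    design = scenario.design
    if design in ("crossover", "latin_square", "n_of_1"):
        return simulate_within_patient(scenario, design)
    if design == "adaptive_randomization":
        return simulate_adaptive(
            rule=scenario.urn_rule,
            model=scenario.binary,
            n_patients=scenario.total_patients,
            seed=scenario.seed,
            n_reps=scenario.n_reps,
            alpha=scenario.alpha,
            period_weeks=scenario.period_weeks,
        )
    dispatch = {
        "parallel": simulate_parallel,
        "factorial": simulate_factorial,
        "delayed_start": simulate_delayed_start,
        "placebo_phase": simulate_placebo_phase,
        "stepped_wedge": simulate_stepped_wedge,
        "randomized_withdrawal": simulate_withdrawal,
        "early_escape": simulate_early_escape,
        "three_stage": simulate_three_stage,
    }
    try:
        fn = dispatch[design]
    except KeyError:
        raise KeyError(
            f"unknown design {design!r}; valid identifiers: {', '.join(DESIGN_NAMES)}"
        ) from None
    return fn(scenario)


def compare_designs(ctx: DecisionContext, template: TrialScenario) -> ComparisonTable:
    """Run the decision engine, then simulate every feasible design.

    Rows follow registry order.  The fingerprint hashes the template
    configuration (including its seed): re-running with an identical
    fingerprint reproduces the table exactly.
    """
    selection = select_designs(ctx)
    report = explain_selection(selection)
    # independent per-design seeds, stable under design-set changes
    seeds = {
        name: int(np.random.SeedSequence([template.seed, i]).generate_state(1)[0] % (2**31))
        for i, name in enumerate(DESIGN_NAMES)
    }
    rows = []
    for name in selection.feasible:
        missing = [m for m in _required_models(name) if getattr(template, m) is None]
        if missing:
            rows.append(
                {
                    "design": name,
                    "rejection_rate": np.nan,
                    "rejection_se": np.nan,
                    "mean_person_time_on_placebo": np.nan,
                    "proportion_ever_active": np.nan,
                    "mean_n_randomized": np.nan,
                    "simulable": False,
                    "note": f"not simulable: template lacks {', '.join(missing)} model",
                }
            )
            continue
        summary = run_design(translate_scenario(template, name, seeds[name]))
        rows.append(
            {
                "design": name,
                "rejection_rate": summary.rejection_rate,
                "rejection_se": summary.rejection_se,
                "mean_person_time_on_placebo": summary.mean_person_time_on_placebo,
                "proportion_ever_active": summary.proportion_ever_active,
                "mean_n_randomized": summary.mean_n_randomized,
                "simulable": True,
                "note": "",
            }
        )
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return ComparisonTable(
        table=table,
        fingerprint=scenario_fingerprint(template),
        selection=selection,
        caveats=list(report["caveats"]),
    )
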