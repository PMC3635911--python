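"""Responder-enrichment designs: randomised withdrawal, early escape, three-stage.

All three trade placebo exposure for conditioning on observed response:

* **randomised withdrawal** — open-label run-in on active treatment;
  responders are randomised to continue or to switch to placebo, and relapse
  rates are compared.
* **early escape** — patients are randomised to active or placebo and leave
  the trial at the first period in which they meet the failure criterion;
  cumulative failure rates at the horizon are compared.
* **three-stage** — a parallel placebo-controlled stage, a randomised
  withdrawal stage in the treatment responders, and a third randomised stage
  in the initial placebo non-responders who respond once switched to
  open-label treatment; the three one-sided stage p-values are combined with
  Fisher's method.
"""

from __future__ import annotations

import numpy as np

from ..scenario import TrialScenario
from ..stats import fisher_combine_rows, two_proportion_pvalue
from ..summaries import SimulationSummary, summarize_rates

__all__ = ["simulate_withdrawal", "simulate_early_escape", "simulate_three_stage"]

_P_FLOOR = 1e-300  # guards Fisher's log against underflowed p-values


def _split_1to1(r: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """1:1 randomisation of r patients per replicate; odd leftover randomised."""
    base = r // 2
    extra = rng.integers(0, 2, size=r.shape) * (r % 2)
    n_a = base + extra
    return n_a, r - n_a


def _needs_models(scenario: TrialScenario, *names: str) -> None:
    for name in names:
        if getattr(scenario, name) is None:
            raise ValueError(f"this design needs a '{name}' response model")


def simulate_withdrawal(scenario: TrialScenario) -> SimulationSummary:
    """Randomised withdrawal: run-in, randomise responders, compare relapse."""
    _needs_models(scenario, "binary", "relapse")
    n = scenario.total_patients
    p_respond = scenario.binary.p_success[1]  # run-in is on active treatment
    rel_placebo, rel_treat = scenario.relapse.p_success[0], scenario.relapse.p_success[1]
    reps, alpha = scenario.n_reps, scenario.alpha
    rng = np.random.default_rng(scenario.seed)

    responders = rng.binomial(n, p_respond, reps)
    n_treat, n_plac = _split_1to1(responders, rng)
    x_plac = rng.binomial(n_plac, rel_placebo)
    x_treat = rng.binomial(n_treat, rel_treat)

    informative = (n_treat >= 1) & (n_plac >= 1)
    pvals = two_proportion_pvalue(x_plac, n_plac, x_treat, n_treat)
    reject = (pvals < alpha) & informative

    d_run, d2 = scenario.run_in_weeks, scenario.withdrawal_weeks
    return summarize_rates(
        design="randomized_withdrawal",
        alpha=alpha,
        reject=reject,
        informative=informative,
        placebo_time=n_plac * d2,
        active_time=n * d_run + n_treat * d2,
        unexposed_time=np.zeros(reps),
        total_time=n * d_run + responders * d2,
        n_randomized=responders.astype(float),
        ever_active=np.ones(reps),  # everyone is treated during the run-in
        allocation={"responder_fraction": float(responders.mean()) / n},
        extra={
            "mean_relapse_diff": float(
                np.where(informative, x_plac / np.maximum(n_plac, 1)
                         - x_treat / np.maximum(n_treat, 1), np.nan)[informative].mean()
            ) if informative.any() else float("nan"),
            "run_in_n": n,
        },
    )


def simulate_early_escape(scenario: TrialScenario) -> SimulationSummary:
    """Early escape: exit at the first failure; compare cumulative failure rates."""
    _needs_models(scenario, "binary")
    if scenario.horizon_periods < 1:
        raise ValueError("failure criterion never evaluable: horizon_periods must be >= 1")
    n = scenario.total_patients // 2
    t_max = scenario.horizon_periods
    q = 1.0 - np.asarray(scenario.binary.p_success[:2], dtype=float)  # per-period failure
    reps, alpha = scenario.n_reps, scenario.alpha
    rng = np.random.default_rng(scenario.seed)

    periods = np.empty((2, reps, n))
    failed = np.empty((2, reps), dtype=int)
    for arm in (0, 1):
        if q[arm] > 0:
            g = rng.geometric(q[arm], (reps, n)).astype(float)  # period of failure
        else:
            g = np.full((reps, n), np.inf)
        fail = g <= t_max
        periods[arm] = np.where(fail, g, t_max)  # exposure truncated at escape
        failed[arm] = fail.sum(axis=1)

    pvals = two_proportion_pvalue(failed[0], n, failed[1], n)
    reject = pvals < alpha

    pw = scenario.period_weeks
    return summarize_rates(
        design="early_escape",
        alpha=alpha,
        reject=reject,
        informative=np.ones(reps, dtype=bool),
        placebo_time=periods[0].sum(axis=1) * pw,
        active_time=periods[1].sum(axis=1) * pw,
        unexposed_time=np.zeros(reps),
        total_time=(periods[0] + periods[1]).sum(axis=1) * pw,
        n_randomized=np.full(reps, 2.0 * n),
        ever_active=np.full(reps, 0.5),
        allocation={"placebo": 0.5, "active": 0.5},
        extra={
            "mean_failures_placebo": float(failed[0].mean()),
            "mean_failures_active": float(failed[1].mean()),
            "horizon_periods": t_max,
        },
    )


def simulate_three_stage(scenario: TrialScenario) -> SimulationSummary:
    """Three-stage design with Fisher-combined stage p-values.

    Stage tests are one-sided pooled two-proportion z-tests in the direction
    of benefit (higher response on treatment; lower relapse on continued
    treatment).  A stage with an empty arm contributes p = 1 (conservative)
    and is flagged in the extras.
    """
    _needs_models(scenario, "binary", "relapse")
    n = scenario.total_patients
    p_placebo, p_active = scenario.binary.p_success[0], scenario.binary.p_success[1]
    rel_placebo, rel_treat = scenario.relapse.p_success[0], scenario.relapse.p_success[1]
    reps, alpha = scenario.n_reps, scenario.alpha
    rng = np.random.default_rng(scenario.seed)

    # stage 1: parallel placebo-controlled response comparison
    n1t, n1p = n // 2, n - n // 2
    x_t = rng.binomial(n1t, p_active, reps)
    x_p = rng.binomial(n1p, p_placebo, reps)
    p1 = two_proportion_pvalue(x_t, n1t, x_p, n1p, alternative="greater")

    # stage 2: randomised withdrawal among stage-1 treatment responders
    n2t, n2p = _split_1to1(x_t, rng)
    r2t = rng.binomial(n2t, rel_treat)
    r2p = rng.binomial(n2p, rel_placebo)
    p2 = two_proportion_pvalue(r2p, n2p, r2t, n2t, alternative="greater")
    stage2_empty = (n2t == 0) | (n2p == 0)

    # stage 3: placebo non-responders bridge onto open-label treatment; those
    # who respond are randomised to continue vs placebo
    m_bridge = n1p - x_p
    r3 = rng.binomial(m_bridge, p_active)
    n3t, n3p = _split_1to1(r3, rng)
    r3t = rng.binomial(n3t, rel_treat)
    r3p = rng.binomial(n3p, rel_placebo)
    p3 = two_proportion_pvalue(r3p, n3p, r3t, n3t, alternative="greater")
    stage3_empty = (n3t == 0) | (n3p == 0)

    p_stack = np.maximum(np.stack([p1, p2, p3], axis=1), _P_FLOOR)
    combined = fisher_combine_rows(p_stack)
    reject = combined < alpha

    d1, d2 = scenario.run_in_weeks, scenario.withdrawal_weeks
    db, d3 = scenario.bridging_weeks, scenario.stage3_weeks
    placebo_time = n1p * d1 + n2p * d2 + n3p * d3
    active_time = n1t * d1 + n2t * d2 + m_bridge * db + n3t * d3
    total_time = placebo_time + active_time  # exits accrue no further time
    return summarize_rates(
        design="three_stage",
        alpha=alpha,
        reject=reject,
        informative=np.ones(reps, dtype=bool),
        placebo_time=placebo_time.astype(float),
        active_time=active_time.astype(float),
        unexposed_time=np.zeros(reps),
        total_time=total_time.astype(float),
        n_randomized=np.full(reps, float(n)),
        ever_active=(n1t + m_bridge) / n,
        allocation={"stage1_treatment": n1t / n, "stage1_placebo": n1p / n},
        extra={
            "mean_stage2_randomized": float((n2t + n2p).mean()),
            "mean_stage3_randomized": float((n3t + n3p).mean()),
            "stage2_empty_rate": float(stage2_empty.mean()),
            "stage3_empty_rate": float(stage3_empty.mean()),
            "mean_combined_p": float(combined.mean()),
        },
    )
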