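"""Parallel-group and 2x2 factorial simulators."""

from __future__ import annotations

import numpy as np

from ..scenario import TrialScenario
from ..stats import two_proportion_pvalue, welch_pvalue
from ..summaries import SimulationSummary, summarize_rates

__all__ = ["simulate_parallel", "simulate_factorial"]


def _arm_sizes(scenario: TrialScenario) -> tuple[int, int]:
    r0, r1 = scenario.ratio
    if r0 <= 0 or r1 <= 0:
        raise ValueError(f"randomisation ratio weights must be > 0: {scenario.ratio}")
    n = scenario.total_patients
    n0 = int(round(n * r0 / (r0 + r1)))
    n0 = min(max(n0, 1), n - 1)
    return n0, n - n0


def simulate_parallel(scenario: TrialScenario) -> SimulationSummary:
    """Two-arm placebo-controlled parallel trial.

    Binary outcomes are compared with the pooled two-proportion z-test;
    continuous outcomes (trajectory model, change score over the follow-up)
    with Welch's t-test.
    """
    n0, n1 = _arm_sizes(scenario)
    rng = np.random.default_rng(scenario.seed)
    reps, alpha = scenario.n_reps, scenario.alpha

    if scenario.binary is not None:
        p0, p1 = scenario.binary.p_success[0], scenario.binary.p_success[1]
        x0 = rng.binomial(n0, p0, reps)
        x1 = rng.binomial(n1, p1, reps)
        pvals = two_proportion_pvalue(x1, n1, x0, n0)
        extra = {"mean_successes": float((x0 + x1).mean())}
    elif scenario.trajectory is not None:
        tm = scenario.trajectory
        w = scenario.followup_weeks
        # endpoint: score at end of follow-up; carries the full between-patient
        # variability (baseline spread plus the shared-intercept share)
        mu0 = tm.baseline_mean + tm.slope_placebo * w
        mu1 = tm.baseline_mean + tm.symptomatic_offset + tm.slope_active * w
        sd_end = np.sqrt(tm.baseline_sd**2 + tm.residual_sd**2)
        y0 = rng.normal(mu0, sd_end, (reps, n0))
        y1 = rng.normal(mu1, sd_end, (reps, n1))
        pvals = welch_pvalue(
            y1.mean(axis=1), y1.var(axis=1, ddof=1), n1,
            y0.mean(axis=1), y0.var(axis=1, ddof=1), n0,
        )
        extra = {}
    else:
        raise ValueError("parallel design needs a binary or trajectory model")

    reject = pvals < alpha
    informative = np.ones(reps, dtype=bool)
    w = scenario.followup_weeks
    n = n0 + n1
    return summarize_rates(
        design="parallel",
        alpha=alpha,
        reject=reject,
        informative=informative,
        placebo_time=np.full(reps, n0 * w),
        active_time=np.full(reps, n1 * w),
        unexposed_time=np.zeros(reps),
        total_time=np.full(reps, n * w),
        n_randomized=np.full(reps, float(n)),
        ever_active=np.full(reps, n1 / n),
        allocation={"placebo": n0 / n, "active": n1 / n},
        extra=extra,
    )


def simulate_factorial(scenario: TrialScenario) -> SimulationSummary:
    """2x2 factorial trial with additive factor effects on a continuous score.

    Patients are randomised to one of four cells (A/placebo-A crossed with
    B/placebo-B).  Each factor margin is tested with Welch's t-test at alpha;
    the interaction contrast is tested as well and reported in the extras.
    The primary rejection rate is the factor-A margin.
    """
    n = scenario.total_patients
    n_cell = n // 4
    if n_cell < 2:
        raise ValueError("factorial design needs at least 8 patients (2 per cell)")
    n = 4 * n_cell
    rng = np.random.default_rng(scenario.seed)
    reps, alpha = scenario.n_reps, scenario.alpha
    a_eff, b_eff, ab_eff = (
        scenario.factor_a_effect,
        scenario.factor_b_effect,
        scenario.interaction_effect,
    )
    sd = scenario.outcome_sd

    # cells in order (A=0,B=0), (A=0,B=1), (A=1,B=0), (A=1,B=1)
    cell_means = np.array([0.0, b_eff, a_eff, a_eff + b_eff + ab_eff])
    y = rng.normal(cell_means[None, :, None], sd, (reps, 4, n_cell))
    m = y.mean(axis=2)
    v = y.var(axis=2, ddof=1)

    def margin_p(hi: list[int], lo: list[int]) -> np.ndarray:
        mh = y[:, hi, :].reshape(reps, -1)
        ml = y[:, lo, :].reshape(reps, -1)
        return welch_pvalue(
            mh.mean(axis=1), mh.var(axis=1, ddof=1), 2 * n_cell,
            ml.mean(axis=1), ml.var(axis=1, ddof=1), 2 * n_cell,
        )

    p_a = margin_p([2, 3], [0, 1])
    p_b = margin_p([1, 3], [0, 2])
    # interaction contrast (m11 - m10 - m01 + m00) with Welch-Satterthwaite df
    contrast = m[:, 3] - m[:, 2] - m[:, 1] + m[:, 0]
    cvar = v.sum(axis=1) / n_cell
    df = cvar**2 / ((v / n_cell) ** 2 / (n_cell - 1.0)).sum(axis=1)
    from scipy import stats as sps

    t = contrast / np.sqrt(cvar)
    p_ab = 2.0 * sps.t.sf(np.abs(t), df)

    w = scenario.followup_weeks
    reps_ones = np.ones(reps, dtype=bool)
    return summarize_rates(
        design="factorial",
        alpha=alpha,
        reject=p_a < alpha,
        informative=reps_ones,
        placebo_time=np.full(reps, n_cell * w),  # double-placebo cell only
        active_time=np.full(reps, 3 * n_cell * w),
        unexposed_time=np.zeros(reps),
        total_time=np.full(reps, n * w),
        n_randomized=np.full(reps, float(n)),
        ever_active=np.full(reps, 0.75),
        allocation={c: 0.25 for c in ("a0b0", "a0b1", "a1b0", "a1b1")},
        extra={
            "factor_b_rejection_rate": float((p_b < alpha).mean()),
            "interaction_rejection_rate": float((p_ab < alpha).mean()),
        },
    )
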