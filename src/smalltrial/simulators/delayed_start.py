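"""Delayed-start design: placebo-controlled phase, then everyone on treatment.

The design separates symptomatic from disease-modifying effects.  Patients
are randomised to an early-start group (active from week 0) or a
delayed-start group (placebo in phase 1, active from the start of phase 2).
Three hypotheses are evaluated sequentially per replicate (gatekeeping —
later tests count only if the earlier ones passed):

1. superiority of treatment over placebo on the phase-1 change from baseline;
2. superiority of early over delayed start on the change from baseline to the
   end of the study;
3. non-inferiority of the early-start group's phase-2 progression slope,
   within a stated margin (score units per week).

A purely symptomatic treatment (offset only) passes (1) but fails (2): once
everyone is treated the groups coincide.  A disease-modifying treatment
(smaller progression slope) passes all three, because the delayed group never
catches up while phase-2 slopes are equal.

Superiority tests are one-sided at alpha/2 in the direction of benefit
(higher scores = worse disease); the non-inferiority test is one-sided at
alpha/2.  Under the global null the all-three-pass probability is therefore
at most alpha/2.
"""

from __future__ import annotations

import numpy as np

from ..scenario import TrialScenario
from ..stats import ls_slopes, welch_pvalue
from ..summaries import SimulationSummary, summarize_rates

__all__ = ["simulate_delayed_start"]


def _visit_grid(scenario: TrialScenario) -> np.ndarray:
    end = scenario.phase1_weeks + scenario.phase2_weeks
    t = np.arange(0.0, end + 1e-9, scenario.visit_spacing_weeks)
    if t[-1] < end:
        t = np.append(t, end)
    return t


def simulate_delayed_start(scenario: TrialScenario) -> SimulationSummary:
    tm = scenario.trajectory
    if tm is None:
        raise ValueError("delayed start needs a trajectory model")
    if scenario.ni_margin <= 0:
        raise ValueError(f"non-inferiority margin must be > 0: {scenario.ni_margin}")
    n = scenario.total_patients // 2
    if n < 3:
        raise ValueError("need at least 3 patients per group")
    reps, alpha = scenario.n_reps, scenario.alpha
    rng = np.random.default_rng(scenario.seed)

    t = _visit_grid(scenario)
    t1 = scenario.phase1_weeks
    t_end = t[-1]
    i_base, i_t1, i_end = 0, int(np.argmin(np.abs(t - t1))), len(t) - 1
    # phase-2 slope window starts after the delayed group's effect stabilises
    w_start = t1 + scenario.slope_window_offset_weeks
    slope_idx = np.flatnonzero(t >= w_start - 1e-9)
    if slope_idx.size < 2:
        raise ValueError("phase-2 slope window contains fewer than 2 visits")

    def group_scores(active_start: float) -> np.ndarray:
        mean = tm.mean_score(t, np.array([active_start]))[0]
        baseline_dev = rng.normal(0.0, tm.baseline_sd, (reps, n, 1))
        shared = rng.normal(0.0, tm.residual_sd * np.sqrt(tm.rho), (reps, n, 1))
        noise = rng.normal(0.0, tm.residual_sd * np.sqrt(1.0 - tm.rho), (reps, n, len(t)))
        return mean[None, None, :] + baseline_dev + shared + noise

    y_early = group_scores(0.0)
    y_delayed = group_scores(t1)

    def change(y: np.ndarray, idx: int) -> np.ndarray:
        return y[:, :, idx] - y[:, :, i_base]

    def one_sided_less(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """p-value for mean(a) < mean(b), Welch, per replicate."""
        return welch_pvalue(
            a.mean(axis=1), a.var(axis=1, ddof=1), n,
            b.mean(axis=1), b.var(axis=1, ddof=1), n,
            alternative="less",
        )

    half = alpha / 2.0
    # H1: less worsening under treatment during phase 1
    pass1 = one_sided_less(change(y_early, i_t1), change(y_delayed, i_t1)) < half
    # H2: early start still better at the end of the study
    pass2 = one_sided_less(change(y_early, i_end), change(y_delayed, i_end)) < half
    # H3: early-start phase-2 slope not worse than delayed by more than the margin
    s_early = ls_slopes(y_early[:, :, slope_idx], t[slope_idx])
    s_delayed = ls_slopes(y_delayed[:, :, slope_idx], t[slope_idx])
    p_ni = welch_pvalue(
        s_early.mean(axis=1) - scenario.ni_margin,
        s_early.var(axis=1, ddof=1), n,
        s_delayed.mean(axis=1), s_delayed.var(axis=1, ddof=1), n,
        alternative="less",
    )
    pass3 = p_ni < half

    reject = pass1 & pass2 & pass3
    reps_ones = np.ones(reps, dtype=bool)
    n_total = 2 * n
    return summarize_rates(
        design="delayed_start",
        alpha=alpha,
        reject=reject,
        informative=reps_ones,
        placebo_time=np.full(reps, n * t1),
        active_time=np.full(reps, n * t_end + n * (t_end - t1)),
        unexposed_time=np.zeros(reps),
        total_time=np.full(reps, n_total * t_end),
        n_randomized=np.full(reps, float(n_total)),
        ever_active=np.ones(reps),
        allocation={"early_start": 0.5, "delayed_start": 0.5},
        extra={
            "pass_h1_rate": float(pass1.mean()),
            "pass_h2_rate": float((pass1 & pass2).mean()),
            "h2_marginal_rate": float(pass2.mean()),
            "h3_marginal_rate": float(pass3.mean()),
            "visit_weeks": t.tolist(),
        },
    )
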