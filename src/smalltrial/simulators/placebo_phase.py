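"""Randomised placebo-phase design.

The randomised quantity is the waiting time between enrolment and the start
of active treatment; every patient is eventually treated.  If the treatment
works, patients who start earlier respond sooner, so the primary analysis
compares response latencies between the shortest- and longest-delay groups
with an exponential-scores (Savage) rank test — the uncensored analogue of
the log-rank test.
"""

from __future__ import annotations

import numpy as np

from ..scenario import TrialScenario
from ..stats import savage_pvalue
from ..summaries import SimulationSummary, summarize_rates

__all__ = ["simulate_placebo_phase"]


def simulate_placebo_phase(scenario: TrialScenario) -> SimulationSummary:
    lm = scenario.latency
    if lm is None:
        raise ValueError("placebo-phase design needs a latency model")
    delays = np.asarray(scenario.delays, dtype=float)
    probs = np.asarray(scenario.delay_probs, dtype=float)
    if delays.size < 2 or np.unique(delays).size < 2:
        raise ValueError(f"delay schedule must contain at least two distinct delays: {delays}")
    if delays.size != probs.size or not np.isclose(probs.sum(), 1.0) or np.any(probs < 0):
        raise ValueError("delay allocation probabilities must be >= 0 and sum to 1")
    if np.any(delays < 0):
        raise ValueError("delays must be >= 0")

    n = scenario.total_patients
    # deterministic group sizes from the allocation probabilities (patients
    # are exchangeable, so which patient lands where is irrelevant)
    sizes = np.floor(probs * n).astype(int)
    for i in np.argsort(-(probs * n - sizes))[: n - sizes.sum()]:
        sizes[i] += 1
    if sizes.min() < 2:
        raise ValueError("every delay group needs at least 2 patients")

    reps, alpha = scenario.n_reps, scenario.alpha
    rng = np.random.default_rng(scenario.seed)
    start = np.repeat(delays, sizes)  # (n,)

    # piecewise-exponential latencies, vectorised over replicates
    e = rng.exponential(1.0, (reps, n))
    h0, h1 = lm.hazard_untreated, lm.hazard_treated
    pre = h0 * start[None, :]
    t_resp = np.full((reps, n), np.inf)
    before = e < pre
    if h0 > 0:
        t_resp[before] = e[before] / h0
    if h1 > 0:
        after = ~before
        t_resp[after] = (start[None, :] + (e - pre) / h1)[after]
    if not np.isfinite(t_resp).all():
        raise ValueError("some patients never respond (both hazards 0); cannot analyse")

    short = np.flatnonzero(start == delays.min())
    long_ = np.flatnonzero(start == delays.max())
    pvals = savage_pvalue(t_resp[:, short], t_resp[:, long_])
    reject = pvals < alpha

    placebo_time = np.minimum(start[None, :], t_resp)  # waiting time, capped at response
    active_time = np.maximum(0.0, t_resp - start[None, :])
    ever_active = (t_resp >= start[None, :]).mean(axis=1)
    total = t_resp.sum(axis=1)
    return summarize_rates(
        design="placebo_phase",
        alpha=alpha,
        reject=reject,
        informative=np.ones(reps, dtype=bool),
        placebo_time=placebo_time.sum(axis=1),
        active_time=active_time.sum(axis=1),
        unexposed_time=np.zeros(reps),
        total_time=total,
        n_randomized=np.full(reps, float(n)),
        ever_active=ever_active,
        allocation={f"delay_{d:g}w": s / n for d, s in zip(delays, sizes)},
        extra={
            "mean_response_week": float(t_resp.mean()),
            "mean_assigned_delay": float(start.mean()),
        },
    )
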