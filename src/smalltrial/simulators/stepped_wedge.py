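"""Stepped-wedge design: sequential rollout of the intervention to clusters.

With S steps there are S+1 periods: every cluster starts on control, one
step's worth of clusters crosses to the intervention at each subsequent
period, and in the final period every cluster is treated.  Cluster-period
mean outcomes follow

    y_ct = mu + period_t + b_c + delta * treated_ct + e_ct

with a Gaussian cluster effect ``b_c`` (sd ``cluster_sd``) and residual
sd ``residual_sd / sqrt(cluster_size)``.  The treatment effect is tested by
OLS with cluster and period fixed effects, which is exactly calibrated under
this generating model.  Randomising which cluster crosses at which step is
equivalent to permuting the exchangeable cluster effects, so the analysis
uses the canonical crossing order.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from ..scenario import TrialScenario
from ..summaries import SimulationSummary, summarize_rates

__all__ = ["simulate_stepped_wedge", "wedge_treatment_matrix"]


def wedge_treatment_matrix(n_clusters: int, n_steps: int) -> np.ndarray:
    """(clusters x periods) 0/1 exposure matrix for an S-step wedge.

    Clusters are split as evenly as possible over the S crossing steps;
    cluster rows are ordered by crossing step.  Period 0 is all-control and
    period S is all-treated.
    """
    if n_clusters < n_steps:
        raise ValueError(
            f"need at least one cluster per step: {n_clusters} clusters, {n_steps} steps"
        )
    if n_steps < 2:
        raise ValueError("a stepped wedge needs at least 2 steps")
    cross_step = np.sort(np.arange(n_clusters) % n_steps) + 1  # period of crossing
    periods = np.arange(n_steps + 1)
    return (periods[None, :] >= cross_step[:, None]).astype(float)


def simulate_stepped_wedge(scenario: TrialScenario) -> SimulationSummary:
    tm = scenario.trajectory
    if tm is None:
        raise ValueError("stepped wedge needs a trajectory model for cluster outcomes")
    c, s = scenario.n_clusters, scenario.n_steps
    x = wedge_treatment_matrix(c, s)
    n_periods = s + 1
    m = scenario.cluster_size
    reps, alpha = scenario.n_reps, scenario.alpha
    rng = np.random.default_rng(scenario.seed)

    delta = tm.symptomatic_offset  # intervention effect on the cluster mean
    period_term = tm.slope_placebo * scenario.period_weeks * np.arange(n_periods)
    mean = tm.baseline_mean + period_term[None, :] + delta * x  # (c, periods)

    sd_cp = np.sqrt(tm.residual_sd**2 / m)
    b = rng.normal(0.0, scenario.cluster_sd, (reps, c, 1))
    y = mean[None, :, :] + b + rng.normal(0.0, sd_cp, (reps, c, n_periods))

    # OLS with cluster + period fixed effects; Frisch-Waugh: residualise the
    # exposure on the fixed effects once (the design is fixed across reps)
    n_cells = c * n_periods
    fe = np.zeros((n_cells, c + n_periods - 1))
    cl = np.repeat(np.arange(c), n_periods)
    pd_ = np.tile(np.arange(n_periods), c)
    fe[np.arange(n_cells), cl] = 1.0
    mask = pd_ > 0
    fe[np.flatnonzero(mask), c + pd_[mask] - 1] = 1.0
    xv = x.ravel()
    q, _ = np.linalg.qr(fe)
    resid = lambda v: v - q @ (q.T @ v)  # noqa: E731
    x_t = resid(xv)
    xtx = float(x_t @ x_t)
    df = n_cells - (c + n_periods - 1) - 1
    if xtx <= 1e-12 or df < 1:
        raise ValueError("wedge design is collinear; increase clusters or steps")

    yv = y.reshape(reps, n_cells)
    y_t = yv - (yv @ q) @ q.T
    delta_hat = (y_t @ x_t) / xtx
    rss = np.einsum("ij,ij->i", y_t, y_t) - delta_hat**2 * xtx
    se = np.sqrt(np.maximum(rss, 0.0) / df / xtx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = delta_hat / se
    t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
    reject = 2.0 * sps.t.sf(np.abs(t_stat), df) < alpha

    pw = scenario.period_weeks
    treated_cells = float(x.sum())
    control_cells = float(n_cells - x.sum())
    n_total = c * m
    return summarize_rates(
        design="stepped_wedge",
        alpha=alpha,
        reject=reject,
        informative=np.ones(reps, dtype=bool),
        placebo_time=np.full(reps, control_cells * m * pw),
        active_time=np.full(reps, treated_cells * m * pw),
        unexposed_time=np.zeros(reps),
        total_time=np.full(reps, n_cells * m * pw),
        n_randomized=np.full(reps, float(n_total)),
        ever_active=np.ones(reps),  # every cluster is treated in the final period
        allocation={"treated_cluster_periods": treated_cells / n_cells},
        extra={
            "final_period_treated_fraction": float(x[:, -1].mean()),
            "mean_effect_estimate": float(delta_hat.mean()),
            "n_periods": n_periods,
        },
    )
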