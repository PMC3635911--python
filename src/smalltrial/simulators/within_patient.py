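"""Within-patient designs: crossover, Latin square, N-of-1.

Period scores follow a shared-intercept Gaussian model

    y_ip = baseline_i + offset * active_ip + period_effect * p
           + carryover * prev_active_ip + e_ip

where ``baseline_i`` carries the between-patient variability (baseline sd
plus the rho-share of the residual variance) and ``e_ip`` the independent
within-patient part.  The treatment effect is the trajectory model's
``symptomatic_offset``; carry-over (the model's additive shift, reused on the
score scale) is zeroed when a wash-out is scheduled.  The primary analysis is
a one-sample t-test on within-patient active-minus-placebo differences, which
eliminates the patient effect.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from ..scenario import TrialScenario
from ..summaries import SimulationSummary, summarize_rates

__all__ = ["simulate_within_patient", "latin_square_sequences"]

_DESIGNS = ("crossover", "latin_square", "n_of_1")


def latin_square_sequences(k: int) -> np.ndarray:
    """Cyclic K x K Latin square: row s gives the treatment order of sequence s.

    Every treatment appears exactly once in each sequence and in each period
    position.
    """
    if k < 2:
        raise ValueError("a Latin square needs at least 2 treatments")
    return (np.arange(k)[None, :] + np.arange(k)[:, None]) % k


def _paired_t(diffs: np.ndarray, alpha: float) -> np.ndarray:
    """Two-sided one-sample t-test on (reps, n) difference arrays."""
    n = diffs.shape[1]
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    m = diffs.mean(axis=1)
    s = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    t = np.where(np.isfinite(t), t, 0.0)
    return 2.0 * sps.t.sf(np.abs(t), n - 1) < alpha


def simulate_within_patient(scenario: TrialScenario, design: str) -> SimulationSummary:
    if design not in _DESIGNS:
        raise ValueError(f"design must be one of {_DESIGNS}, got {design!r}")
    tm = scenario.trajectory
    if tm is None:
        raise ValueError(f"{design} needs a trajectory model for period scores")
    rng = np.random.default_rng(scenario.seed)
    reps, alpha = scenario.n_reps, scenario.alpha
    offset = tm.symptomatic_offset
    # carry-over on the score scale: wash-out removes it entirely
    carry = 0.0
    if not scenario.washout and scenario.binary is not None:
        carry = scenario.binary.carryover_shift
    sd_within = tm.residual_sd * np.sqrt(1.0 - tm.rho)

    if design == "crossover":
        n = scenario.total_patients
        if n < 2:
            raise ValueError("crossover needs at least 2 patients")
        # balanced AB/BA assignment; differences remove patient and period terms
        n_ab = n // 2
        seq_ab = np.zeros((reps, n), dtype=bool)
        seq_ab[:, :n_ab] = True  # exchangeable patients: fixed balanced split
        e = rng.normal(0.0, sd_within, (reps, n, 2))
        # AB patients: active in period 1, placebo (plus carry-over from the
        # active period) in period 2.  BA patients: the reverse; their active
        # period never follows an active one, so no carry-over term.
        active_first = seq_ab
        pe = scenario.period_effect
        y_active = np.where(active_first, offset + e[:, :, 0], offset + pe + e[:, :, 1])
        y_placebo = np.where(active_first, pe + carry + e[:, :, 1], e[:, :, 0])
        diffs = y_active - y_placebo
        reject = _paired_t(diffs, alpha)
        pw = scenario.period_weeks
        washout_t = scenario.washout_weeks if scenario.washout else 0.0
        placebo_time = np.full(reps, n * pw)
        active_time = np.full(reps, n * pw)
        unexposed = np.full(reps, n * washout_t)
        n_randomized = float(n)
        extra = {"n_periods": 2}
    elif design == "latin_square":
        k = scenario.n_treatments
        n = scenario.total_patients
        if n < k:
            raise ValueError(f"need at least {k} patients for {k} sequences")
        square = latin_square_sequences(k)
        seq_of_patient = np.arange(n) % k  # balanced assignment across sequences
        order = square[seq_of_patient]  # (n, k): treatment in each period
        e = rng.normal(0.0, sd_within, (reps, n, k))
        period_term = scenario.period_effect * np.arange(k)[None, :]
        active = (order >= 1).astype(float)  # arm 0 is placebo
        prev_active = np.zeros_like(active)
        prev_active[:, 1:] = active[:, :-1]
        y = offset * active + period_term + carry * prev_active + e
        # primary contrast: treatment 1 vs placebo, within patient
        pos_t1 = np.argmax(order == 1, axis=1)
        pos_pl = np.argmax(order == 0, axis=1)
        rows = np.arange(n)
        diffs = y[:, rows, pos_t1] - y[:, rows, pos_pl]
        reject = _paired_t(diffs, alpha)
        pw = scenario.period_weeks
        washout_t = scenario.washout_weeks * (k - 1) if scenario.washout else 0.0
        placebo_time = np.full(reps, n * pw)
        active_time = np.full(reps, n * pw * (k - 1))
        unexposed = np.full(reps, n * washout_t)
        n_randomized = float(n)
        extra = {"n_treatments": k, "sequences": square.tolist()}
    else:  # n_of_1
        m_pairs = scenario.n_pairs
        m_meas = scenario.measurements_per_period
        if m_pairs * m_meas < 2:
            raise ValueError("n-of-1 needs at least 2 paired measurements")
        # one patient; the patient effect is common to every period and
        # cancels in the differences.  Order within each pair is randomised.
        e = rng.normal(0.0, sd_within, (reps, m_pairs, 2, m_meas))
        active_first = rng.random((reps, m_pairs)) < 0.5
        pair_trend = scenario.period_effect * np.arange(m_pairs)[None, :, None]
        y_first = pair_trend + e[:, :, 0, :]
        y_second = pair_trend + e[:, :, 1, :]
        y_active = np.where(active_first[:, :, None], y_first + offset, y_second + offset)
        y_placebo = np.where(active_first[:, :, None], y_second, y_first)
        if carry:  # placebo period follows active within a pair when active first
            y_placebo = y_placebo + carry * active_first[:, :, None]
        diffs = (y_active - y_placebo).reshape(reps, m_pairs * m_meas)
        reject = _paired_t(diffs, alpha)
        pw = scenario.period_weeks
        washout_t = scenario.washout_weeks * (2 * m_pairs - 1) if scenario.washout else 0.0
        placebo_time = np.full(reps, m_pairs * pw)
        active_time = np.full(reps, m_pairs * pw)
        unexposed = np.full(reps, washout_t)
        n_randomized = 1.0
        extra = {
            "n_pairs": m_pairs,
            "n_paired_measurements": m_pairs * m_meas,
        }

    total = placebo_time + active_time + unexposed
    return summarize_rates(
        design=design,
        alpha=alpha,
        reject=reject,
        informative=np.ones(reps, dtype=bool),
        placebo_time=placebo_time,
        active_time=active_time,
        unexposed_time=unexposed,
        total_time=total,
        n_randomized=np.full(reps, n_randomized),
        ever_active=np.ones(reps),
        allocation={"active_share_of_time": float(active_time[0] / total[0])},
        extra=extra,
    )
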