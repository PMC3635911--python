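"""Operating-characteristic summaries shared by every simulator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimulationSummary", "summarize_rates"]


@dataclass
class SimulationSummary:
    """Monte-Carlo operating characteristics of one design under one scenario.

    Rates are proportions over the informative replicates; each rate ``r``
    carries the binomial Monte-Carlo standard error ``sqrt(r*(1-r)/n)``.
    Person-time quantities are mean totals per replicate, in weeks, and
    satisfy placebo + active + unexposed = total follow-up exactly.
    """

    design: str
    n_reps: int
    alpha: float
    rejection_rate: float
    rejection_se: float
    mean_person_time_on_placebo: float
    mean_person_time_active: float
    mean_person_time_unexposed: float
    mean_person_time_total: float
    proportion_ever_active: float
    mean_n_randomized: float
    allocation: dict[str, float] = field(default_factory=dict)
    n_noninformative: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (drops non-scalar extras)."""
        d = {
            "design": self.design,
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "rejection_rate": self.rejection_rate,
            "rejection_se": self.rejection_se,
            "mean_person_time_on_placebo": self.mean_person_time_on_placebo,
            "mean_person_time_active": self.mean_person_time_active,
            "mean_person_time_unexposed": self.mean_person_time_unexposed,
            "mean_person_time_total": self.mean_person_time_total,
            "proportion_ever_active": self.proportion_ever_active,
            "mean_n_randomized": self.mean_n_randomized,
            "allocation": dict(self.allocation),
            "n_noninformative": self.n_noninformative,
        }
        d["extra"] = {
            k: (float(v) if isinstance(v, (int, float, np.floating, np.integer)) else v)
            for k, v in self.extra.items()
            if np.isscalar(v)
        }
        return d


def rate_se(rate: float, n: int) -> float:
    return float(np.sqrt(rate * (1.0 - rate) / n)) if n > 0 else float("nan")


def summarize_rates(
    design: str,
    alpha: float,
    reject: np.ndarray,
    informative: np.ndarray,
    placebo_time: np.ndarray,
    active_time: np.ndarray,
    unexposed_time: np.ndarray,
    total_time: np.ndarray,
    n_randomized: np.ndarray,
    ever_active: np.ndarray,
    allocation: dict[str, float] | None = None,
    extra: dict | None = None,
) -> SimulationSummary:
    """Collapse per-replicate arrays into a :class:`SimulationSummary`.

    ``reject`` and ``informative`` are boolean per-replicate; the rejection
    rate is computed over informative replicates only.  ``ever_active`` is
    the per-replicate proportion of enrolled patients who were ever on an
    active arm.
    """
    reject = np.asarray(reject, dtype=bool)
    informative = np.asarray(informative, dtype=bool)
    n_reps = reject.size
    n_inf = int(informative.sum())
    rate = float(reject[informative].mean()) if n_inf else float("nan")
    return SimulationSummary(
        design=design,
        n_reps=n_reps,
        alpha=alpha,
        rejection_rate=rate,
        rejection_se=rate_se(rate, n_inf) if n_inf else float("nan"),
        mean_person_time_on_placebo=float(np.mean(placebo_time)),
        mean_person_time_active=float(np.mean(active_time)),
        mean_person_time_unexposed=float(np.mean(unexposed_time)),
        mean_person_time_total=float(np.mean(total_time)),
        proportion_ever_active=float(np.mean(ever_active)),
        mean_n_randomized=float(np.mean(n_randomized)),
        allocation=allocation or {},
        n_noninformative=n_reps - n_inf,
        extra=extra or {},
    )
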