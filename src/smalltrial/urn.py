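"""Urn-model response-adaptive randomisation.

Two urn rules are implemented for K treatment arms:

* **Play-the-winner (PW)** — a success on arm *i* adds one ball of type *i*;
  a failure adds one ball split over the *other* arms in proportion to their
  current counts (fractional balls arise for K >= 3).  The total ball count
  grows by exactly one per treated patient.
* **Drop-the-loser (DL)** — a failure on arm *i* removes one ball of type
  *i* (floored at zero); a success changes nothing.  The urn also holds
  immigration balls: when one is drawn, every treatment type gains one ball,
  no patient is assigned, and the draw is repeated.  Immigration prevents any
  arm's balls from dying out.

Outcomes are assumed observed before the next patient's draw (no delayed
responses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .response_models import BinaryResponseModel
from .stats import two_proportion_pvalue
from .summaries import SimulationSummary, summarize_rates

__all__ = ["IMMIGRATION", "UrnState", "draw", "pw_update", "dl_update", "simulate_adaptive"]

#: Sentinel ball type returned by :func:`draw` for an immigration ball.
IMMIGRATION = -1


@dataclass(frozen=True)
class UrnState:
    """Ball counts (possibly fractional) per treatment, plus immigration balls."""

    treatment: tuple[float, ...]
    immigration: float = 0.0

    def __post_init__(self) -> None:
        if len(self.treatment) < 1:
            raise ValueError("urn needs at least one treatment type")
        if any(c < 0 for c in self.treatment) or self.immigration < 0:
            raise ValueError(f"ball counts must be >= 0: {self}")

    @property
    def total(self) -> float:
        return sum(self.treatment) + self.immigration


def draw(urn: UrnState, rng: np.random.Generator) -> int:
    """Draw one ball at random with replacement; the urn is unchanged.

    Returns a treatment index, or :data:`IMMIGRATION` for an immigration
    ball.  Each type's probability is its count over the total count.
    """
    total = urn.total
    if total <= 0:
        raise ValueError("cannot draw from an empty urn")
    u = rng.random() * total
    acc = 0.0
    for i, c in enumerate(urn.treatment):
        acc += c
        if u < acc:
            return i
    return IMMIGRATION


def pw_update(urn: UrnState, arm: int, success: bool) -> UrnState:
    """Play-the-winner update after treating one patient on ``arm``.

    Success: one ball of type ``arm`` is added.  Failure: one ball is added,
    partitioned over the other arms in proportion to their current counts.
    """
    if urn.immigration != 0:
        raise ValueError("play-the-winner uses no immigration balls")
    k = len(urn.treatment)
    if not 0 <= arm < k:
        raise ValueError(f"arm {arm} out of range for {k} treatments")
    counts = list(urn.treatment)
    if success:
        counts[arm] += 1.0
    else:
        others = sum(c for j, c in enumerate(counts) if j != arm)
        if others <= 0:
            raise ValueError(
                "failure partition undefined: no balls on arms other than "
                f"{arm} ({urn})"
            )
        for j in range(k):
            if j != arm:
                counts[j] += counts[j] / others
    return UrnState(treatment=tuple(counts), immigration=0.0)


def dl_update(urn: UrnState, drawn: int, success: bool | None = None) -> UrnState:
    """Drop-the-loser update for one drawn ball.

    Treatment draw: a failure removes one ball of that type (floored at
    zero); a success leaves the urn unchanged.  Immigration draw: every
    treatment type gains one ball and no patient is assigned (the caller
    redraws).
    """
    if urn.immigration <= 0:
        raise ValueError("drop-the-loser requires immigration balls in the urn")
    counts = list(urn.treatment)
    if drawn == IMMIGRATION:
        counts = [c + 1.0 for c in counts]
        return UrnState(treatment=tuple(counts), immigration=urn.immigration)
    if not 0 <= drawn < len(counts):
        raise ValueError(f"unknown ball type {drawn}")
    if success is None:
        raise ValueError("a treatment draw needs an outcome")
    if not success:
        counts[drawn] = max(0.0, counts[drawn] - 1.0)
    return UrnState(treatment=tuple(counts), immigration=urn.immigration)


def _default_urn(rule: str, k: int) -> UrnState:
    if rule == "PW":
        return UrnState(treatment=(1.0,) * k)
    return UrnState(treatment=(1.0,) * k, immigration=1.0)


def simulate_adaptive(
    rule: str,
    model: BinaryResponseModel,
    n_patients: int,
    initial: UrnState | None = None,
    seed: int = 0,
    n_reps: int = 1000,
    alpha: float = 0.05,
    period_weeks: float = 4.0,
    collect_trajectory: bool = False,
) -> SimulationSummary:
    """Monte-Carlo operating characteristics of a PW or DL urn trial.

    Patients accrue sequentially; each is assigned by an urn draw and the urn
    is updated with the observed Bernoulli outcome before the next draw.  The
    primary test is the two-sided pooled two-proportion z-test on final arm
    success proportions (replicates with an empty arm are non-informative).
    The run is vectorised over replicates.

    With ``collect_trajectory`` the summary's extras include a per-patient
    allocation/outcome/urn-state table for the first replicate.
    """
    if rule not in ("PW", "DL"):
        raise ValueError(f"rule must be 'PW' or 'DL', got {rule!r}")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    k = model.n_arms
    if k < 2:
        raise ValueError("adaptive randomisation needs at least 2 arms")
    urn0 = initial if initial is not None else _default_urn(rule, k)
    if len(urn0.treatment) != k:
        raise ValueError(f"urn has {len(urn0.treatment)} types for {k} arms")
    if rule == "DL" and urn0.immigration <= 0:
        raise ValueError("drop-the-loser requires immigration balls")
    if rule == "PW" and urn0.immigration != 0:
        raise ValueError("play-the-winner uses no immigration balls")

    rng = np.random.default_rng(seed)
    p_arm = np.asarray(model.p_success, dtype=float)
    counts = np.tile(np.asarray(urn0.treatment, dtype=float), (n_reps, 1))
    imm = urn0.immigration
    n_assigned = np.zeros((n_reps, k))
    n_success = np.zeros((n_reps, k))
    trajectory: list[dict] = []

    for patient in range(n_patients):
        if rule == "DL":
            # Redraw until a treatment ball comes up; each immigration draw
            # adds one ball of every treatment type.  The redraw probability
            # shrinks geometrically, so a few sweeps settle all replicates.
            pending = np.ones(n_reps, dtype=bool)
            arm = np.zeros(n_reps, dtype=int)
            while pending.any():
                tot = counts[pending].sum(axis=1) + imm
                u = rng.random(pending.sum()) * tot
                cum = np.cumsum(counts[pending], axis=1)
                a = (u[:, None] >= cum).sum(axis=1)  # == k -> immigration
                idx = np.flatnonzero(pending)
                got_imm = a == k
                counts[idx[got_imm]] += 1.0
                arm[idx[~got_imm]] = a[~got_imm]
                pending[idx[~got_imm]] = False
        else:
            tot = counts.sum(axis=1)
            u = rng.random(n_reps) * tot
            cum = np.cumsum(counts, axis=1)
            arm = np.minimum((u[:, None] >= cum).sum(axis=1), k - 1)

        success = rng.random(n_reps) < p_arm[arm]
        rows = np.arange(n_reps)
        n_assigned[rows, arm] += 1
        n_success[rows, arm] += success

        if rule == "PW":
            others = counts.sum(axis=1) - counts[rows, arm]
            fail = ~success
            # success: +1 on the treated arm
            counts[rows[success], arm[success]] += 1.0
            # failure: +1 split over the other arms proportionally
            if fail.any():
                frac = counts[fail] / others[fail, None]
                frac[np.arange(fail.sum()), arm[fail]] = 0.0
                counts[fail] += frac
        else:
            fail = ~success
            counts[rows[fail], arm[fail]] = np.maximum(
                0.0, counts[rows[fail], arm[fail]] - 1.0
            )
        if collect_trajectory:
            trajectory.append(
                {
                    "patient": patient,
                    "arm": int(arm[0]),
                    "outcome": int(success[0]),
                    **{f"balls_{j}": counts[0, j] for j in range(k)},
                }
            )

    n_failure = n_assigned - n_success
    alloc = n_assigned / n_patients
    if k == 2:
        pvals = two_proportion_pvalue(
            n_success[:, 1], n_assigned[:, 1], n_success[:, 0], n_assigned[:, 0]
        )
        informative = (n_assigned > 0).all(axis=1)
        reject = (pvals < alpha) & informative
    else:  # primary contrast: best-indexed active arm vs control
        pvals = two_proportion_pvalue(
            n_success[:, -1], n_assigned[:, -1], n_success[:, 0], n_assigned[:, 0]
        )
        informative = (n_assigned[:, [0, -1]] > 0).all(axis=1)
        reject = (pvals < alpha) & informative

    extra = {
        "mean_failures": float(n_failure.sum(axis=1).mean()),
        "sd_allocation_arm1": float(alloc[:, -1].std(ddof=1)) if n_reps > 1 else 0.0,
        "allocation_counts_arm1": n_assigned[:, -1].copy(),
        "rule": rule,
    }
    if collect_trajectory:
        extra["trajectory"] = pd.DataFrame(trajectory)
    return summarize_rates(
        design="adaptive_randomization",
        alpha=alpha,
        reject=reject,
        informative=informative,
        placebo_time=n_assigned[:, 0] * period_weeks,
        active_time=n_assigned[:, 1:].sum(axis=1) * period_weeks,
        unexposed_time=np.zeros(n_reps),
        total_time=np.full(n_reps, n_patients * period_weeks),
        n_randomized=np.full(n_reps, float(n_patients)),
        ever_active=alloc[:, 1:].sum(axis=1),
        allocation={f"arm_{j}": float(alloc[:, j].mean()) for j in range(k)},
        extra=extra,
    )
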