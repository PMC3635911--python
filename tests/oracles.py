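"""Independent oracles used by the test suite.

These re-derive expected results by routes separate from the package's
implementation: exact enumeration of urn draw/outcome sequences, and
set-intersection filtering of registry attributes for the decision engine.
"""

from __future__ import annotations

from collections import defaultdict

from smalltrial.registry import load_registry


def enumerate_urn_allocation(
    rule: str,
    p_success: tuple[float, float],
    n_patients: int,
    initial_treatment: tuple[float, ...] = (1.0, 1.0),
    immigration: float = 0.0,
    tol: float = 1e-12,
) -> dict[int, float]:
    """Exact distribution of the number of patients assigned to arm 1.

    Enumerates every draw/outcome sequence with its probability.  For the
    drop-the-loser rule the immigration redraw chain is followed until its
    probability mass drops below ``tol`` (the chain decays geometrically, so
    the truncated mass is negligible).
    """
    k = len(initial_treatment)
    dist: dict[int, float] = defaultdict(float)

    def pw_next(counts: tuple[float, ...], arm: int, success: bool) -> tuple[float, ...]:
        c = list(counts)
        if success:
            c[arm] += 1.0
        else:
            others = sum(x for j, x in enumerate(c) if j != arm)
            for j in range(k):
                if j != arm:
                    c[j] += c[j] / others
        return tuple(c)

    def dl_next(counts: tuple[float, ...], arm: int, success: bool) -> tuple[float, ...]:
        c = list(counts)
        if not success:
            c[arm] = max(0.0, c[arm] - 1.0)
        return tuple(c)

    step = pw_next if rule == "PW" else dl_next

    def recurse(counts, n_arm1, remaining, prob):
        if prob < tol:
            return
        if remaining == 0:
            dist[n_arm1] += prob
            return
        total = sum(counts) + immigration
        if rule == "DL" and immigration > 0:
            recurse(
                tuple(c + 1.0 for c in counts), n_arm1, remaining,
                prob * immigration / total,
            )
        for arm in range(k):
            p_draw = counts[arm] / total
            if p_draw <= 0:
                continue
            for success in (True, False):
                p_out = p_success[arm] if success else 1.0 - p_success[arm]
                if p_out <= 0:
                    continue
                recurse(
                    step(counts, arm, success),
                    n_arm1 + (arm == 1),
                    remaining - 1,
                    prob * p_draw * p_out,
                )

    recurse(tuple(float(c) for c in initial_treatment), 0, n_patients, 1.0)
    return dict(dist)


# -- decision-engine brute force: each node is an allowed SET; intersect ------


def brute_force_feasible(ctx) -> tuple[str, ...]:
    """Feasible set by independent per-node set intersection over attributes."""
    profiles = load_registry()
    names = [p.name for p in profiles]
    allowed = set(names)

    if not ctx.outcome_reversible:
        allowed &= {p.name for p in profiles if not p.requires_reversible_outcome}
    if ctx.response_speed == "slow":
        allowed &= {p.name for p in profiles if not p.requires_fast_response}
    if ctx.minimize_placebo_time == "required":
        minimisers = {p.name for p in profiles if p.minimizes_time_on_placebo}
        if ctx.response_speed == "slow":
            minimisers -= {
                p.name for p in profiles if p.placebo_minimization_requires_fast_response
            }
        allowed &= minimisers
    if ctx.all_active_at_end == "required":
        allowed &= {p.name for p in profiles if p.all_patients_active_at_end}
    if ctx.comparison_preference != "indifferent":
        allowed &= {
            p.name for p in profiles if p.comparison_basis == ctx.comparison_preference
        }
    return tuple(n for n in names if n in allowed)


def all_contexts():
    """All 2 x 2 x 2 x 2 x 3 = 48 decision contexts."""
    from smalltrial.decision import DecisionContext

    for rev in (True, False):
        for speed in ("fast", "slow"):
            for minim in ("required", "indifferent"):
                for active in ("required", "indifferent"):
                    for comp in ("intra_patient", "inter_patient", "indifferent"):
                        yield DecisionContext(
                            outcome_reversible=rev,
                            response_speed=speed,
                            minimize_placebo_time=minim,
                            all_active_at_end=active,
                            comparison_preference=comp,
                        )
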