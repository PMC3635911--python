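"""Selection algorithm: map answers at five decision nodes to feasible designs.

The nodes, applied in fixed order, are

1. outcome reversibility (reversible / irreversible),
2. response speed (fast = observable within a few weeks / slow),
3. whether time on placebo must be minimised,
4. whether all patients must be on active treatment by the end,
5. preference for intra- vs inter-patient comparison.

Each node removes the designs whose registry attributes are incompatible with
the answer; a design's recorded excluding node is the first one that removed
it.  The feasible set itself is a pure intersection of attribute filters, so
it does not depend on the node order.

The engine reproduces the algorithm's output only.  Contextual clinical
judgement (e.g. a placebo phase being impossible when both arms are active
treatments) is deliberately not encoded; reports carry a caveat to that
effect.
"""

from __future__ import annotations

from dataclasses import dataclass

from .registry import DesignProfile, load_registry

__all__ = [
    "FAST",
    "SLOW",
    "REQUIRED",
    "INDIFFERENT",
    "DecisionContext",
    "SelectionResult",
    "select_designs",
    "explain_selection",
]

FAST, SLOW = "fast", "slow"
REQUIRED, INDIFFERENT = "required", "indifferent"
_COMPARISONS = ("intra_patient", "inter_patient", INDIFFERENT)

#: Fixed node order; affects only the "excluded by" attribution.
NODE_ORDER = (
    "outcome_reversibility",
    "response_speed",
    "placebo_minimisation",
    "all_active_at_end",
    "comparison_basis",
)

_CONTEXT_CAVEAT = (
    "Feasibility reflects the decision nodes only; contextual constraints "
    "(ethics, logistics, an active comparator, disease stability) can rule "
    "out further designs and must be judged separately."
)


@dataclass(frozen=True)
class DecisionContext:
    """A user's answers at the five decision nodes."""

    outcome_reversible: bool
    response_speed: str = FAST
    minimize_placebo_time: str = INDIFFERENT
    all_active_at_end: str = INDIFFERENT
    comparison_preference: str = INDIFFERENT

    def __post_init__(self) -> None:
        if self.response_speed not in (FAST, SLOW):
            raise ValueError(f"response_speed must be 'fast' or 'slow', got {self.response_speed!r}")
        for fld in ("minimize_placebo_time", "all_active_at_end"):
            v = getattr(self, fld)
            if v not in (REQUIRED, INDIFFERENT):
                raise ValueError(f"{fld} must be 'required' or 'indifferent', got {v!r}")
        if self.comparison_preference not in _COMPARISONS:
            raise ValueError(
                "comparison_preference must be 'intra_patient', 'inter_patient' "
                f"or 'indifferent', got {self.comparison_preference!r}"
            )


@dataclass(frozen=True)
class SelectionResult:
    """Feasible designs (registry order) and the node that excluded each other design."""

    context: DecisionContext
    feasible: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...]  # (design, node)


def _excluding_node(ctx: DecisionContext, p: DesignProfile) -> str | None:
    """First node (in NODE_ORDER) whose answer is incompatible with profile ``p``."""
    if not ctx.outcome_reversible and p.requires_reversible_outcome:
        return "outcome_reversibility"
    if ctx.response_speed == SLOW and p.requires_fast_response:
        return "response_speed"
    if ctx.minimize_placebo_time == REQUIRED:
        if not p.minimizes_time_on_placebo:
            return "placebo_minimisation"
        if ctx.response_speed == SLOW and p.placebo_minimization_requires_fast_response:
            return "placebo_minimisation"
    if ctx.all_active_at_end == REQUIRED and not p.all_patients_active_at_end:
        return "all_active_at_end"
    if (
        ctx.comparison_preference != INDIFFERENT
        and p.comparison_basis != ctx.comparison_preference
    ):
        return "comparison_basis"
    return None


def select_designs(ctx: DecisionContext) -> SelectionResult:
    """Apply the five decision nodes and return the feasible design set.

    Every context yields a result; an empty feasible set is valid and is
    flagged by :func:`explain_selection`.
    """
    feasible: list[str] = []
    excluded: list[tuple[str, str]] = []
    for p in load_registry():
        node = _excluding_node(ctx, p)
        if node is None:
            feasible.append(p.name)
        else:
            excluded.append((p.name, node))
    return SelectionResult(context=ctx, feasible=tuple(feasible), excluded=tuple(excluded))


def explain_selection(result: SelectionResult) -> dict:
    """Structured report: per-feasible-design pros/cons, per-exclusion node, caveats."""
    profiles = {p.name: p for p in load_registry()}
    feasible = [
        {
            "design": name,
            "advantages": list(profiles[name].advantages),
            "limitations": list(profiles[name].limitations),
        }
        for name in result.feasible
    ]
    excluded = [{"design": name, "node": node} for name, node in result.excluded]
    caveats = [_CONTEXT_CAVEAT]
    binary_only = sorted(
        set(result.feasible) & {p.name for p in profiles.values() if p.requires_binary_outcome}
    )
    if binary_only:
        caveats.append(
            "Designs needing a binary success/failure outcome: " + ", ".join(binary_only)
        )
    if not result.feasible:
        caveats.insert(0, "no catalogued design satisfies the stated constraints")
    return {"feasible": feasible, "excluded": excluded, "caveats": caveats}
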