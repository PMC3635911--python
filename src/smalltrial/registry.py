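"""Knowledge base of randomised comparative trial designs for small populations.

Twelve designs are catalogued (the response-adaptive urn rules — play-the-winner
and drop-the-loser — count as one category, ``adaptive_randomization``).  Each
design carries the attributes that drive the selection algorithm in
:mod:`smalltrial.decision`:

``comparison_basis``
    whether the primary comparison is between patients (``inter_patient``) or
    within patients (``intra_patient``: each patient acts as their own control).
``requires_reversible_outcome``
    the design only makes sense when the outcome can revert once treatment is
    withdrawn (e.g. a symptom score); designs built on period switches,
    withdrawal or delayed starts need this.
``requires_fast_response``
    the design's mechanics need the outcome to be observable within a few
    weeks of treatment, independently of any wish to minimise placebo time
    (outcome-dependent sequential allocation; escape on short-term failure).
``minimizes_time_on_placebo``
    the design structurally reduces cumulative placebo exposure relative to a
    parallel trial of the same horizon.
``placebo_minimization_requires_fast_response``
    the placebo-sparing mechanism only works when responses arrive quickly
    (the design reacts to observed responses patient by patient); meaningful
    only when ``minimizes_time_on_placebo`` is set.
``all_patients_active_at_end``
    every enrolled patient is on active treatment by the end of the trial.
``requires_stable_chronic_disease``
    the patient's state must be comparable at the start of repeated periods
    (within-patient designs) or the condition must persist long enough for
    withdrawal phases to be interpretable.
``requires_binary_outcome``
    the design needs a success/failure endpoint; advisory only — it is
    reported but never used as a decision node.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

__all__ = [
    "DESIGN_NAMES",
    "DesignProfile",
    "RegistryError",
    "load_registry",
    "get_profile",
    "registry_as_json",
]

#: Canonical registry order; also the row order of every report and table.
DESIGN_NAMES: tuple[str, ...] = (
    "parallel",
    "factorial",
    "crossover",
    "latin_square",
    "n_of_1",
    "delayed_start",
    "placebo_phase",
    "stepped_wedge",
    "randomized_withdrawal",
    "early_escape",
    "three_stage",
    "adaptive_randomization",
)

INTER, INTRA = "inter_patient", "intra_patient"


class RegistryError(RuntimeError):
    """Internal inconsistency of the embedded design knowledge base."""


@dataclass(frozen=True)
class DesignProfile:
    """Selection-relevant characteristics of one trial design."""

    name: str
    comparison_basis: str
    requires_reversible_outcome: bool
    requires_fast_response: bool
    requires_stable_chronic_disease: bool
    requires_binary_outcome: bool
    minimizes_time_on_placebo: bool
    placebo_minimization_requires_fast_response: bool
    all_patients_active_at_end: bool
    advantages: tuple[str, ...] = field(default_factory=tuple)
    limitations: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["advantages"] = list(self.advantages)
        d["limitations"] = list(self.limitations)
        return d


def _profiles() -> tuple[DesignProfile, ...]:
    P = DesignProfile
    return (
        P(
            name="parallel",
            comparison_basis=INTER,
            requires_reversible_outcome=False,
            requires_fast_response=False,
            requires_stable_chronic_disease=False,
            requires_binary_outcome=False,
            minimizes_time_on_placebo=False,
            placebo_minimization_requires_fast_response=False,
            all_patients_active_at_end=False,
            advantages=(
                "simple to run, analyse and interpret",
                "applicable to almost any disease-treatment-outcome situation",
            ),
            limitations=(
                "needs a larger sample size than most alternatives",
                "recruitment can suffer when placebo-controlled",
                "cannot separate within- from between-patient variability",
            ),
        ),
        P(
            name="factorial",
            comparison_basis=INTER,
            requires_reversible_outcome=False,
            requires_fast_response=False,
            requires_stable_chronic_disease=False,
            requires_binary_outcome=False,
            minimizes_time_on_placebo=False,
            placebo_minimization_requires_fast_response=False,
            all_patients_active_at_end=False,
            advantages=(
                "answers two (or more) treatment questions in a single trial",
                "fewer patients than running two separate parallel trials",
            ),
            limitations=(
                "valid margins require no interaction between the factors",
                "loss of power if the four cells must be analysed separately",
            ),
        ),
        P(
            name="crossover",
            comparison_basis=INTRA,
            requires_reversible_outcome=True,
            requires_fast_response=False,
            requires_stable_chronic_disease=True,
            requires_binary_outcome=False,
            minimizes_time_on_placebo=False,
            placebo_minimization_requires_fast_response=False,
            all_patients_active_at_end=False,
            advantages=(
                "each patient is their own control, so only within-patient variability enters",
                "smaller sample size than a parallel trial",
            ),
            limitations=(
                "needs a stable chronic disease with a comparable state at each period start",
                "wash-out periods required; carry-over must be absent or handled",
                "follow-up per patient at least twice as long as a parallel trial",
            ),
        ),
        P(
            name="latin_square",
            comparison_basis=INTRA,
            requires_reversible_outcome=True,
            requires_fast_response=False,
            requires_stable_chronic_disease=True,
            requires_binary_outcome=False,
            minimizes_time_on_placebo=False,
            placebo_minimization_requires_fast_response=False,
            all_patients_active_at_end=False,
            advantages=(
                "extends the crossover to more than two treatments or doses",
                "balanced: every treatment appears once per sequence and per period",
            ),
            limitations=(
                "same constraints as the crossover (stability, wash-out, long follow-up)",
            ),
        ),
        P(
            name="n_of_1",
            comparison_basis=INTRA,
            requires_reversible_outcome=True,
            requires_fast_response=False,
            requires_stable_chronic_disease=True,
            requires_binary_outcome=False,
            minimizes_time_on_placebo=False,
            placebo_minimization_requires_fast_response=False,
            all_patients_active_at_end=False,
            advantages=(
                "estimates effectiveness for an individual patient (personalised medicine)",
                "often improves adherence and the patient's understanding of their disease",
            ),
            limitations=(
                "same constraints as the crossover; needs a stable chronic disease",
                "conclusions are for one patient, not a population",
            ),
        ),
        P(
            name="delayed_start",
            comparison_basis=INTER,
            requires_reversible_outcome=True,
            requires_fast_response=False,
            requires_stable_chronic_disease=False,
            requires_binary_outcome=False,
            minimizes_time_on_placebo=True,
            placebo_minimization_requires_fast_response=False,
            all_patients_active_at_end=True,
            advantages=(
                "every patient is on active treatment in the second phase",
                "can separate symptomatic effects from effects on disease evolution",
            ),
            limitations=(
                "groups are no longer comparable at the start of the second phase",
                "blinding is only genuine in the first phase; carry-over possible",
            ),
        ),
        P(
            name="placebo_phase",
            comparison_basis=INTER,
            requires_reversible_outcome=False,
            requires_fast_response=False,
            requires_stable_chronic_disease=False,
            requires_binary_outcome=False,
            minimizes_time_on_placebo=True,
            placebo_minimization_requires_fast_response=False,
            all_patients_active_at_end=True,
            advantages=(
                "randomises only the waiting time before active treatment; everyone is treated",
                "suited to disease-modifying therapies in rapidly evolving diseases",
            ),
            limitations=(
                "assumes responses occur only after effective treatment starts",
                "variable placebo-phase length reduces statistical power",
                "limited ability to estimate the size of the treatment effect",
            ),
        ),
        P(
            name="stepped_wedge",
            comparison_basis=INTER,
            requires_reversible_outcome=False,
            requires_fast_response=False,
            requires_stable_chronic_disease=False,
            requires_binary_outcome=False,
            minimizes_time_on_placebo=True,
            placebo_minimization_requires_fast_response=False,
            all_patients_active_at_end=True,
            advantages=(
                "rolls the intervention out to all individuals or clusters by the final period",
                "useful when the treatment is believed beneficial or cannot be delivered everywhere at once",
            ),
            limitations=(
                "risk of contamination between intervention and control units",
                "outcome assessment must be blinded; time trends must be modelled",
            ),
        ),
        P(
            name="randomized_withdrawal",
            comparison_basis=INTER,
            requires_reversible_outcome=True,
            requires_fast_response=False,
            requires_stable_chronic_disease=True,
            requires_binary_outcome=False,
            minimizes_time_on_placebo=True,
            placebo_minimization_requires_fast_response=True,
            all_patients_active_at_end=False,
            advantages=(
                "only run-in responders are ever randomised to placebo, cutting placebo time",
                "can show whether a treatment needs to be continued",
            ),
            limitations=(
                "chronic, predictable diseases only (no spontaneous remission, not slowly evolving)",
                "treatment effect is overestimated: only responders are compared",
                "carry-over of adverse effects possible after withdrawal",
            ),
        ),
        P(
            name="early_escape",
            comparison_basis=INTER,
            requires_reversible_outcome=True,
            requires_fast_response=True,
            requires_stable_chronic_disease=False,
            requires_binary_outcome=True,
            minimizes_time_on_placebo=True,
            placebo_minimization_requires_fast_response=True,
            all_patients_active_at_end=False,
            advantages=(
                "patients leave as soon as they meet a pre-specified failure criterion",
                "minimises exposure to placebo or to an ineffective treatment",
            ),
            limitations=(
                "a binary failure/success criterion can be hard to define",
                "only short-term efficacy is evaluated",
                "power is lost when many patients escape",
            ),
        ),
        P(
            name="three_stage",
            comparison_basis=INTER,
            requires_reversible_outcome=True,
            requires_fast_response=False,
            requires_stable_chronic_disease=True,
            requires_binary_outcome=True,
            minimizes_time_on_placebo=True,
            placebo_minimization_requires_fast_response=True,
            all_patients_active_at_end=False,
            advantages=(
                "three independent efficacy assessments combined into one overall p-value",
                "fewer patients than a parallel trial; less time on placebo",
                "can target a responder subpopulation",
            ),
            limitations=(
                "chronic conditions only: both response and withdrawal must be assessable",
                "withdrawal phase must be long enough for full wash-out",
                "marginal responders may forgo a treatment that benefits them",
            ),
        ),
        P(
            name="adaptive_randomization",
            comparison_basis=INTER,
            requires_reversible_outcome=False,
            requires_fast_response=True,
            requires_stable_chronic_disease=False,
            requires_binary_outcome=True,
            minimizes_time_on_placebo=True,
            placebo_minimization_requires_fast_response=True,
            all_patients_active_at_end=False,
            advantages=(
                "allocation shifts towards the arm doing better, so fewer patients get the worse arm",
                "can improve recruitment through better expected outcomes",
            ),
            limitations=(
                "needs a binary success/failure outcome observed before the next allocation",
                "unequal arm sizes reduce power; one arm can end up very small",
                "no established methodology for delayed responses",
            ),
        ),
    )


def _check_invariants(profiles: tuple[DesignProfile, ...]) -> None:
    if len(profiles) != 12:
        raise RegistryError(f"invariant 'exactly 12 profiles' violated: {len(profiles)}")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise RegistryError("invariant 'names are unique' violated")
    if set(names) != set(DESIGN_NAMES):
        raise RegistryError("invariant 'names match the canonical identifiers' violated")
    intra = {p.name for p in profiles if p.comparison_basis == INTRA}
    if intra != {"crossover", "latin_square", "n_of_1"}:
        raise RegistryError(f"invariant 'exactly 3 intra-patient designs' violated: {sorted(intra)}")
    n_min = sum(p.minimizes_time_on_placebo for p in profiles)
    if n_min != 7:
        raise RegistryError(f"invariant 'exactly 7 placebo-minimising designs' violated: {n_min}")
    active_end = {p.name for p in profiles if p.all_patients_active_at_end}
    if active_end != {"delayed_start", "placebo_phase", "stepped_wedge"}:
        raise RegistryError(
            f"invariant 'exactly 3 all-active-at-end designs' violated: {sorted(active_end)}"
        )
    for p in profiles:
        if p.all_patients_active_at_end and not p.minimizes_time_on_placebo:
            raise RegistryError(
                "invariant 'all-active-at-end implies placebo-minimising' violated "
                f"for {p.name}"
            )
        if p.comparison_basis not in (INTER, INTRA):
            raise RegistryError(f"invariant 'valid comparison basis' violated for {p.name}")


def load_registry() -> tuple[DesignProfile, ...]:
    """Return the 12 design profiles in canonical order.

    The registry is embedded (not read from user files); its internal
    invariants are re-checked on every load and any violation aborts with a
    diagnostic naming the invariant.
    """
    profiles = _profiles()
    _check_invariants(profiles)
    return profiles


def get_profile(name: str) -> DesignProfile:
    """Return the profile for one design identifier."""
    for p in load_registry():
        if p.name == name:
            return p
    raise KeyError(
        f"unknown design {name!r}; valid identifiers: {', '.join(DESIGN_NAMES)}"
    )


def registry_as_json() -> list[dict]:
    """Registry as JSON-serialisable records (one object per design)."""
    return [p.to_dict() for p in load_registry()]
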