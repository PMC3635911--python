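# Methods

This note records the modelling and numerical choices behind `smalltrial`:
what each component assumes, which parameters matter, and what the test
suite does and does not demonstrate.

## 1. Design knowledge base and selection algorithm

Each of the 12 catalogued designs carries boolean attributes that drive
selection (reversibility requirement, need for fast responses, placebo
minimisation and whether that mechanism needs fast responses, all-active-at-
end, comparison basis, chronic-stability and binary-outcome needs). The
selection engine applies five nodes in a fixed order — reversibility,
response speed, placebo minimisation, all-active-at-end, comparison basis —
and records, per excluded design, the *first* node that removed it. The
feasible set itself is an intersection of attribute filters, so it is
independent of node order; only the exclusion attribution depends on it
(tested).

Two modelling judgements deserve mention:

* *Fast-response requirement.* Outcome-dependent sequential allocation
  (adaptive randomisation) and escape on short-term failure (early escape)
  need outcomes observable within a few weeks regardless of any wish to
  minimise placebo time, so they carry `requires_fast_response` and drop out
  on the slow branch unconditionally. Randomised withdrawal and the
  three-stage design remain *feasible* with slow outcomes (chronic disease),
  but their placebo-sparing mechanism — reacting to observed responses —
  does not operate there, so on the slow branch they do not count as
  placebo-minimising. With fast responses seven designs minimise placebo
  time; with slow responses only the three all-active designs (delayed
  start, placebo phase, stepped wedge) do.
* *Scope of the algorithm.* Contextual feasibility (an active comparator
  making a placebo phase meaningless, ethics, logistics) is deliberately not
  encoded; every report carries a caveat saying so. The binary-outcome need
  is advisory (reported, never filtered on).

## 2. Response models

All stochastic inputs come from three families, all pure functions of
(model, seed); arm 0 is placebo by convention.

* **Binary** — per-arm success probability `p_k ∈ [0,1]`. Carry-over is
  first-order only: an additive shift on the probability scale applied when
  the previous period was on an active arm, clipped to [0,1]; default 0.
* **Trajectory** — Gaussian score with baseline mean/sd (score units),
  placebo and active slopes (score units/week), an immediate symptomatic
  offset under active treatment, residual sd, and within-patient correlation
  ρ ∈ [0,1) realised as a shared patient intercept (equicorrelation).
  A measurement taken exactly at the treatment start time is pre-dose, so
  the offset applies strictly after the start. Defaults used in the
  Parkinson-like scenarios (baseline 25 ± 8 on a UPDRS-type scale where
  higher is worse, progression ≈ 0.1 points/week, residual sd 4, ρ = 0.6)
  are realistic orders of magnitude for an early neurodegenerative cohort.
* **Latency** — time-to-response with piecewise-constant hazard (events per
  week): `h_untreated` before the patient's treatment start, `h_treated`
  after. `h_untreated = 0` encodes the placebo-phase design's premise that
  responses only follow effective treatment.

Not modelled: covariates, dropout, missing data, learning/assessment
effects, non-linear trajectories. Passing tests therefore demonstrate the
operating characteristics of the *designs and analyses under these ideal
generating models*, not robustness to the complications of real data.

## 3. Urn-based adaptive randomisation

Play-the-winner: success on arm *i* adds a type-*i* ball; failure adds one
ball partitioned over the *other* arms proportionally to their current
counts (read as excluding arm *i*; fractional balls arise for K ≥ 3, which
the partition rule forces). Total balls grow by exactly one per treated
patient — an exact invariant the tests check. Drop-the-loser: failures
remove one ball (floored at zero, although immigration makes the floor
unreachable under defaults); an immigration draw adds one ball of every
treatment type and the draw repeats. Default urns: one ball per arm, plus
one immigration ball for DL. Outcomes are observed before the next draw; no
delayed-response generalisation is attempted.

Small trials (n ≤ 4, K = 2) are validated against an exact enumeration of
every draw/outcome sequence (immigration redraw chains truncated below
10⁻¹² path mass); larger trials against qualitative theory: allocation
skews towards the better arm, and DL shows no more allocation variability
than PW.

## 4. Simulators and test statistics

No canonical test statistics exist for several of these designs, so the
simplest tests with known calibration were chosen; all are two-sided at the
scenario's α unless stated:

| design | primary analysis |
|---|---|
| parallel | pooled two-proportion z (binary) / Welch t on end scores (continuous) |
| factorial | Welch t per factor margin; Welch-Satterthwaite interaction contrast |
| crossover / Latin square / N-of-1 | one-sample t on within-patient active−placebo differences |
| delayed start | three gatekept hypotheses, see below |
| placebo phase | exponential-scores (Savage) rank test between shortest- and longest-delay groups — the uncensored log-rank analogue |
| stepped wedge | OLS on cluster-period means with cluster + period fixed effects (exact under the generating model) |
| randomised withdrawal | pooled z on relapse rates among randomised responders |
| early escape | pooled z on cumulative failure rates at the horizon |
| three-stage | one-sided pooled z per stage, Fisher χ²(2k) combination |
| adaptive urn | pooled z on final arm success proportions |

Delayed start evaluates sequentially (gatekeeping, no α-split): (1)
superiority of treatment on the phase-1 change from baseline, (2)
superiority of early over delayed start on the end-of-study change, (3)
non-inferiority of the early group's phase-2 progression slope within a
user margin (default 0.15 score units/week, the order used in delayed-start
Parkinson trials; per-patient least-squares slopes over the visits starting
12 weeks into phase 2, after the delayed group's symptomatic effect has
stabilised). Superiority and non-inferiority tests are one-sided at α/2, so
the all-three-pass rate under the global null is bounded by α/2.

Conventions for degenerate cases: an empty arm or a degenerate pooled
proportion yields p = 1 (no rejection) rather than an error; replicates
that cannot be analysed at all (e.g. zero run-in responders) are counted as
non-informative and excluded from the rejection-rate denominator; a
three-stage stage with no evaluable patients contributes p = 1 and is
flagged. Fisher inputs are floored at 10⁻³⁰⁰ against log underflow.

Person-time accounting is exact per replicate: placebo + active +
unexposed time equals total follow-up (a conservation test runs across all
designs). `proportion_ever_active` counts patients who receive active
treatment at any time — structurally 1 for delayed start and stepped wedge,
1 for the placebo phase when `h_untreated = 0`, and also 1 for withdrawal
designs because of the open-label run-in (which does not contradict the
registry's *all active at the end* attribute — a different property).

## 5. Calibration choices and problem sizes

Binary z-tests have lattice-valued sizes, so the null-calibration suite's
scenario sizes were fixed from exact binomial enumeration, not simulation:
response probability 0.6 at 50/arm (exact size 0.0524), withdrawal with 100
enrolled / 60 % responders / relapse 0.4 (0.0515), early escape with
per-period success 0.7 over 4 periods (0.0508) — all within three
Monte-Carlo standard errors of 0.05 at the 10,000 replicates the suite
uses. An exact conditional mid-p alternative for the three-stage stages was
evaluated and rejected as conservative (combined size 0.036); the one-sided
pooled z combination sits at ≈ 0.052.

For the parallel-design power comparison at p = (0.8, 0.3), n = 25/arm,
exact enumeration puts the z-test's true power at 0.9722 versus 0.9673 for
the standard closed-form normal approximation — the approximation's own
error is the size of three Monte-Carlo standard errors at 10,000
replicates. That comparison therefore runs at 2,500 replicates, where the
Monte-Carlo tolerance dominates the approximation error and the check
genuinely targets the implementation.

Every simulator is vectorised over replicates; the full 13-simulator
calibration suite at 10,000 replicates runs in a few seconds on one CPU.
All randomness flows from a single scenario seed (numpy `default_rng`);
comparison tables spawn one child seed per design from the template seed,
so each row is independent of which other designs are simulated.

## 6. Known limitations

* The feasibility attributes reconstruct a decision tree whose exact
  topology is under-determined; they are constrained to reproduce the four
  published walkthrough examples and the catalogue's own counts, and other
  attribute assignments consistent with those constraints exist.
* Within-patient simulators use period-level scores, not full
  continuous-time trajectories; carry-over is first-order and additive.
* The adaptive-urn z-test conditions on the realised (random) allocation;
  its calibration was verified empirically at n = 100 but is asymptotic, and
  extreme urn configurations at very small n can leave an arm nearly empty.
* The stepped-wedge analysis is at the cluster-period level with known-form
  random effects; individual-level analyses and time-varying effects are out
  of scope, as are sequential monitoring, Bayesian analyses and sample-size
  re-estimation generally.
* No automated "best design" recommendation is produced: the comparison
  table informs, the user decides.
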