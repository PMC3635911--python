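"""Design simulators: structural accounting, effect-direction properties,
determinism, and small calibration smoke checks.

Full 10000-replicate type-I-error calibration for every simulator lives in
the acceptance suite; here the same scenarios are exercised at smaller sizes
together with the properties that distinguish the designs from one another.
"""

import numpy as np
import pytest

import smalltrial as st
from conftest import mc_band
from smalltrial.scenario import TrialScenario
from smalltrial.simulators.within_patient import latin_square_sequences
from smalltrial.simulators.stepped_wedge import wedge_treatment_matrix


def scen(**kw) -> TrialScenario:
    kw.setdefault("n_reps", 2000)
    kw.setdefault("seed", 20260115)
    return TrialScenario(**kw)


# ---------------------------------------------------------------------- parallel


class TestParallel:
    def test_power_exceeds_alpha_under_a_real_effect(self, effect_binary):
        out = st.simulate_parallel(scen(binary=effect_binary, n_per_arm=25))
        assert out.rejection_rate > 0.8

    def test_ever_active_fraction_equals_active_allocation(self, null_binary):
        out = st.simulate_parallel(scen(binary=null_binary, n_per_arm=30))
        assert out.proportion_ever_active == pytest.approx(out.allocation["active"])

    def test_unbalanced_ratio_respected(self, null_binary):
        out = st.simulate_parallel(scen(binary=null_binary, n_patients=90, ratio=(1, 2)))
        assert out.allocation["active"] == pytest.approx(2 / 3)

    def test_zero_ratio_weight_rejected(self, null_binary):
        with pytest.raises(ValueError, match="ratio"):
            st.simulate_parallel(scen(binary=null_binary, ratio=(0, 1)))

    def test_continuous_endpoint_supported(self, null_trajectory):
        out = st.simulate_parallel(scen(trajectory=null_trajectory, n_per_arm=30))
        assert abs(out.rejection_rate - 0.05) < mc_band(0.05, 2000) + 0.01


# --------------------------------------------------------------------- factorial


class TestFactorial:
    def test_null_margins_calibrated(self):
        out = st.simulate_factorial(scen(n_patients=100, n_reps=4000))
        assert abs(out.rejection_rate - 0.05) < mc_band(0.05, 4000) + 0.005
        assert abs(out.extra["factor_b_rejection_rate"] - 0.05) < 0.02

    def test_factor_power_matches_parallel_trial_of_same_total_n(self, null_trajectory):
        # one factorial trial answers the factor-A question with the power of
        # a dedicated parallel trial using all patients
        effect, sd, n = 0.6, 1.0, 128
        fact = st.simulate_factorial(
            scen(n_patients=n, factor_a_effect=effect, outcome_sd=sd, n_reps=4000)
        )
        tm = st.TrajectoryModel(
            baseline_mean=0.0, baseline_sd=0.0, slope_active=0.0, slope_placebo=0.0,
            residual_sd=sd, rho=0.0, symptomatic_offset=effect,
        )
        par = st.simulate_parallel(scen(trajectory=tm, n_patients=n, n_reps=4000, seed=99))
        assert fact.rejection_rate == pytest.approx(par.rejection_rate, abs=0.04)

    def test_interaction_test_gains_power_with_sample_size(self):
        small = st.simulate_factorial(scen(n_patients=40, interaction_effect=1.0))
        large = st.simulate_factorial(scen(n_patients=400, interaction_effect=1.0))
        assert large.extra["interaction_rejection_rate"] > small.extra[
            "interaction_rejection_rate"
        ]
        assert large.extra["interaction_rejection_rate"] > 0.9

    def test_three_quarters_of_patients_ever_active(self):
        out = st.simulate_factorial(scen(n_patients=40, n_reps=50))
        assert out.proportion_ever_active == pytest.approx(0.75)


# ---------------------------------------------------------------- within-patient


class TestWithinPatient:
    def test_crossover_null_calibrated_without_carryover(self, null_trajectory):
        out = st.simulate_within_patient(
            scen(trajectory=null_trajectory, n_patients=20, n_reps=4000), "crossover"
        )
        assert abs(out.rejection_rate - 0.05) < mc_band(0.05, 4000) + 0.005

    def test_crossover_beats_parallel_at_same_total_n_with_high_rho(self):
        tm = st.TrajectoryModel(
            baseline_mean=50.0, baseline_sd=6.0, slope_active=0.0, slope_placebo=0.0,
            residual_sd=4.0, rho=0.7, symptomatic_offset=-2.5,
        )
        cross = st.simulate_within_patient(
            scen(trajectory=tm, n_patients=24, n_reps=3000), "crossover"
        )
        par = st.simulate_parallel(
            scen(trajectory=tm, n_patients=24, n_reps=3000, seed=77)
        )
        assert cross.rejection_rate > par.rejection_rate

    def test_latin_square_sequences_are_balanced(self):
        for k in (2, 3, 4, 5):
            square = latin_square_sequences(k)
            for axis in (0, 1):
                uniq = np.apply_along_axis(lambda r: len(set(r)), axis, square)
                assert (uniq == k).all()

    def test_latin_square_simulation_reports_sequences(self, null_trajectory):
        out = st.simulate_within_patient(
            scen(trajectory=null_trajectory, n_patients=12, n_treatments=3, n_reps=200),
            "latin_square",
        )
        square = np.array(out.extra["sequences"])
        assert square.shape == (3, 3)

    def test_n_of_1_analyses_six_paired_measurements(self, null_trajectory):
        # three treatment pairs with two measurements each
        out = st.simulate_within_patient(
            scen(trajectory=null_trajectory, n_pairs=3, measurements_per_period=2,
                 n_reps=200),
            "n_of_1",
        )
        assert out.extra["n_paired_measurements"] == 6
        assert out.mean_n_randomized == 1.0

    def test_carryover_without_washout_biases_crossover_effect(self):
        # a positive carry-over inflates the placebo period that follows the
        # active one, shrinking the apparent treatment effect
        tm = st.TrajectoryModel(
            baseline_mean=0.0, baseline_sd=0.0, slope_active=0.0, slope_placebo=0.0,
            residual_sd=1.0, rho=0.0, symptomatic_offset=1.0,
        )
        carry = st.BinaryResponseModel((0.5, 0.5), carryover_shift=1.0)
        with_washout = st.simulate_within_patient(
            scen(trajectory=tm, n_patients=20, washout=True, binary=carry), "crossover"
        )
        without = st.simulate_within_patient(
            scen(trajectory=tm, n_patients=20, washout=False, binary=carry), "crossover"
        )
        assert without.rejection_rate < with_washout.rejection_rate

    def test_unknown_design_rejected(self, null_trajectory):
        with pytest.raises(ValueError, match="design"):
            st.simulate_within_patient(scen(trajectory=null_trajectory), "parallel")


# ----------------------------------------------------------------- delayed start


class TestDelayedStart:
    def disease_modifying(self):
        return st.TrajectoryModel(
            baseline_mean=25.0, baseline_sd=8.0, slope_active=0.06,
            slope_placebo=0.14, residual_sd=4.0, rho=0.6, symptomatic_offset=0.0,
        )

    def symptomatic(self):
        return st.TrajectoryModel(
            baseline_mean=25.0, baseline_sd=8.0, slope_active=0.1,
            slope_placebo=0.1, residual_sd=4.0, rho=0.6, symptomatic_offset=-3.0,
        )

    def test_disease_modifying_effect_passes_all_three_hypotheses(self):
        out = st.simulate_delayed_start(
            scen(trajectory=self.disease_modifying(), n_per_arm=100, n_reps=800)
        )
        assert out.rejection_rate > 0.9

    def test_symptomatic_effect_passes_h1_but_not_h2(self):
        out = st.simulate_delayed_start(
            scen(trajectory=self.symptomatic(), n_per_arm=100, n_reps=800)
        )
        assert out.extra["pass_h1_rate"] > 0.9
        # once everyone is treated the groups coincide: end-of-study contrast is null
        assert out.extra["h2_marginal_rate"] < 0.10

    def test_every_patient_ends_on_active_treatment(self, null_trajectory):
        out = st.simulate_delayed_start(scen(trajectory=null_trajectory, n_reps=100))
        assert out.proportion_ever_active == 1.0

    def test_nonpositive_margin_rejected(self, null_trajectory):
        with pytest.raises(ValueError, match="margin"):
            st.simulate_delayed_start(scen(trajectory=null_trajectory, ni_margin=0.0))


# ----------------------------------------------------------------- placebo phase


class TestPlaceboPhase:
    def test_effective_treatment_is_detected(self):
        lat = st.LatencyModel(hazard_untreated=0.0, hazard_treated=0.6)
        out = st.simulate_placebo_phase(
            scen(latency=lat, n_patients=60, delays=(1.0, 10.0), n_reps=1000)
        )
        assert out.rejection_rate > 0.8
        assert out.proportion_ever_active == 1.0

    def test_mean_placebo_time_equals_delay_capped_at_response(self):
        lat = st.LatencyModel(hazard_untreated=0.0, hazard_treated=0.5)
        out = st.simulate_placebo_phase(
            scen(latency=lat, n_patients=40, delays=(2.0, 8.0), n_reps=500)
        )
        # untreated hazard 0: response always after the delay, so placebo time
        # per patient is exactly the assigned delay
        assert out.mean_person_time_on_placebo == pytest.approx(
            40 * out.extra["mean_assigned_delay"]
        )

    def test_identical_delays_rejected(self, null_latency):
        with pytest.raises(ValueError, match="distinct delays"):
            st.simulate_placebo_phase(scen(latency=null_latency, delays=(4.0, 4.0)))


# ----------------------------------------------------------------- stepped wedge


class TestSteppedWedge:
    def test_final_period_has_every_cluster_treated(self, null_trajectory):
        out = st.simulate_stepped_wedge(
            scen(trajectory=null_trajectory, n_clusters=5, n_steps=5, n_reps=100)
        )
        assert out.extra["final_period_treated_fraction"] == 1.0
        assert out.proportion_ever_active == 1.0

    def test_wedge_matrix_rolls_out_monotonically(self):
        x = wedge_treatment_matrix(6, 3)
        assert (np.diff(x, axis=1) >= 0).all()
        assert x[:, 0].sum() == 0 and x[:, -1].sum() == 6

    def test_power_increases_with_cluster_period_size(self):
        def run(size):
            tm = st.TrajectoryModel(
                baseline_mean=10.0, baseline_sd=0.0, slope_active=0.0,
                slope_placebo=0.05, residual_sd=6.0, rho=0.0, symptomatic_offset=-1.5,
            )
            return st.simulate_stepped_wedge(
                scen(trajectory=tm, cluster_size=size, cluster_sd=0.5, n_reps=1500)
            ).rejection_rate

        small, medium, large = run(2), run(10), run(50)
        assert small <= medium + 0.02 and medium <= large + 0.02
        assert large > small

    def test_fewer_clusters_than_steps_rejected(self, null_trajectory):
        with pytest.raises(ValueError, match="cluster"):
            st.simulate_stepped_wedge(
                scen(trajectory=null_trajectory, n_clusters=3, n_steps=5)
            )


# -------------------------------------------------------- withdrawal / enrichment


class TestWithdrawal:
    def test_mean_randomised_matches_binomial_mean(self, null_binary):
        out = st.simulate_withdrawal(
            scen(binary=null_binary, relapse=st.BinaryResponseModel((0.4, 0.4)),
                 n_patients=100, n_reps=2000)
        )
        assert out.mean_n_randomized == pytest.approx(60.0, abs=1.0)

    def test_placebo_time_below_parallel_trial_of_same_size_and_horizon(self, null_binary):
        relapse = st.BinaryResponseModel((0.6, 0.2))
        wd = st.simulate_withdrawal(
            scen(binary=null_binary, relapse=relapse, n_patients=100,
                 run_in_weeks=8.0, withdrawal_weeks=16.0, n_reps=500)
        )
        par = st.simulate_parallel(
            scen(binary=null_binary, n_patients=100, followup_weeks=24.0, n_reps=500)
        )
        assert wd.mean_person_time_on_placebo < par.mean_person_time_on_placebo

    def test_everyone_is_treated_during_run_in(self, null_binary):
        out = st.simulate_withdrawal(
            scen(binary=null_binary, relapse=st.BinaryResponseModel((0.4, 0.4)),
                 n_patients=30, n_reps=200)
        )
        assert out.proportion_ever_active == 1.0

    def test_zero_responder_replicates_counted_noninformative(self):
        no_response = st.BinaryResponseModel((0.0, 0.0))
        out = st.simulate_withdrawal(
            scen(binary=no_response, relapse=st.BinaryResponseModel((0.4, 0.4)),
                 n_patients=10, n_reps=100)
        )
        assert out.n_noninformative == 100
        assert np.isnan(out.rejection_rate)


class TestEarlyEscape:
    def test_placebo_exposure_truncated_by_escapes(self):
        failing = st.BinaryResponseModel((0.5, 0.9))  # placebo fails 0.5/period
        out = st.simulate_early_escape(
            scen(binary=failing, n_per_arm=50, horizon_periods=4, n_reps=500)
        )
        full_exposure = 50 * 4 * 4.0  # n patients x horizon periods x weeks/period
        assert out.mean_person_time_on_placebo < full_exposure

    def test_no_failures_means_no_rejections(self):
        perfect = st.BinaryResponseModel((1.0, 1.0))
        out = st.simulate_early_escape(scen(binary=perfect, n_reps=200))
        assert out.rejection_rate == 0.0
        # nobody escapes: full horizon exposure on both arms
        assert out.mean_person_time_on_placebo == pytest.approx(
            out.mean_person_time_active
        )

    def test_unevaluable_horizon_rejected(self, null_binary):
        with pytest.raises(ValueError, match="horizon"):
            st.simulate_early_escape(scen(binary=null_binary, horizon_periods=0))


class TestThreeStage:
    def models(self, p_active=0.6, relapse_gap=0.0):
        binary = st.BinaryResponseModel((0.6, p_active))
        relapse = st.BinaryResponseModel((0.4 + relapse_gap, 0.4 - relapse_gap))
        return binary, relapse

    def test_effective_treatment_beats_best_single_stage(self):
        binary = st.BinaryResponseModel((0.35, 0.7))
        relapse = st.BinaryResponseModel((0.65, 0.25))
        out = st.simulate_three_stage(
            scen(binary=binary, relapse=relapse, n_patients=60, n_reps=1500)
        )
        stage1_only = st.simulate_parallel(
            scen(binary=binary, n_patients=60, n_reps=1500, seed=55)
        )
        assert out.rejection_rate > stage1_only.rejection_rate

    def test_placebo_time_below_parallel_at_same_n(self):
        binary, relapse = self.models()
        ts = st.simulate_three_stage(
            scen(binary=binary, relapse=relapse, n_patients=100,
                 run_in_weeks=8.0, withdrawal_weeks=8.0, bridging_weeks=8.0,
                 stage3_weeks=8.0, n_reps=400)
        )
        par = st.simulate_parallel(
            scen(binary=binary, n_patients=100, followup_weeks=32.0, n_reps=400)
        )
        assert ts.mean_person_time_on_placebo < par.mean_person_time_on_placebo

    def test_empty_stages_are_flagged_not_fatal(self):
        # nobody responds: stages 2 and 3 have no patients; their p-values are 1
        binary = st.BinaryResponseModel((0.0, 0.0))
        relapse = st.BinaryResponseModel((0.4, 0.4))
        out = st.simulate_three_stage(
            scen(binary=binary, relapse=relapse, n_patients=20, n_reps=100)
        )
        assert out.extra["stage2_empty_rate"] == 1.0
        assert out.extra["stage3_empty_rate"] == 1.0
        assert out.rejection_rate <= 0.05  # stage 1 alone must carry the test


# ----------------------------------------------------------- cross-cutting checks


NULL_RUNS = [
    ("parallel", lambda f: st.simulate_parallel(
        scen(binary=f["binary"], n_per_arm=50, n_reps=1500))),
    ("crossover", lambda f: st.simulate_within_patient(
        scen(trajectory=f["trajectory"], n_patients=20, n_reps=1500), "crossover")),
    ("delayed_start", lambda f: st.simulate_delayed_start(
        scen(trajectory=f["trajectory"], n_per_arm=30, n_reps=300))),
    ("placebo_phase", lambda f: st.simulate_placebo_phase(
        scen(latency=f["latency"], n_patients=60, n_reps=1500))),
    ("stepped_wedge", lambda f: st.simulate_stepped_wedge(
        scen(trajectory=f["trajectory"], n_reps=1500))),
    ("withdrawal", lambda f: st.simulate_withdrawal(
        scen(binary=f["binary"], relapse=st.BinaryResponseModel((0.4, 0.4)),
             n_patients=100, n_reps=1500))),
    ("early_escape", lambda f: st.simulate_early_escape(
        scen(binary=st.BinaryResponseModel((0.7, 0.7)), n_per_arm=50, n_reps=1500))),
    ("three_stage", lambda f: st.simulate_three_stage(
        scen(binary=f["binary"], relapse=st.BinaryResponseModel((0.4, 0.4)),
             n_patients=100, n_reps=1500))),
]


@pytest.mark.parametrize("name, run", NULL_RUNS, ids=[n for n, _ in NULL_RUNS])
def test_person_time_components_sum_to_total_follow_up(
    name, run, null_binary, null_trajectory, null_latency
):
    out = run({"binary": null_binary, "trajectory": null_trajectory,
               "latency": null_latency})
    total = (
        out.mean_person_time_on_placebo
        + out.mean_person_time_active
        + out.mean_person_time_unexposed
    )
    assert total == pytest.approx(out.mean_person_time_total, rel=1e-12)


@pytest.mark.parametrize("name, run", NULL_RUNS, ids=[n for n, _ in NULL_RUNS])
def test_fixed_seed_reproduces_summary_exactly(
    name, run, null_binary, null_trajectory, null_latency
):
    fixtures = {"binary": null_binary, "trajectory": null_trajectory,
                "latency": null_latency}
    assert run(fixtures).to_dict() == run(fixtures).to_dict()


@pytest.mark.parametrize(
    "design_effects",
    [
        ("parallel", [0.0, 0.25, 0.5]),
        ("early_escape", [0.0, 0.2, 0.4]),
    ],
)
def test_rejection_rate_non_decreasing_in_effect_size(design_effects):
    design, gaps = design_effects
    rates = []
    for gap in gaps:
        binary = st.BinaryResponseModel((0.5 - gap / 2, 0.5 + gap / 2))
        s = scen(binary=binary, n_per_arm=50, n_reps=1500)
        out = (st.simulate_parallel(s) if design == "parallel"
               else st.simulate_early_escape(s))
        rates.append(out.rejection_rate)
    slack = mc_band(0.5, 1500)
    assert rates[1] >= rates[0] - slack
    assert rates[2] >= rates[1] - slack
    assert rates[2] > rates[0]
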