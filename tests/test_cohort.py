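import numpy as np
import pytest
from scipy.spatial import ConvexHull

from proprioadapt import (
    DEFAULT_PROTOCOL,
    PrevalenceConfig,
    compute_amm,
    compute_apm,
    generate_cohort,
    min_jerk_trajectory,
    mirror_x,
    simulate_amm_trial,
    simulate_apm_matching,
    simulate_vmr_session,
    summarize_session,
    synthesize_vmr_trajectory,
    trials_to_adapt,
    direction_at_latency,
    detect_onset,
)
from proprioadapt.cohort import simulate_participant
from proprioadapt.pipeline import compute_metrics

from conftest import make_params


@pytest.fixture(scope="module")
def apm_targets(protocol=DEFAULT_PROTOCOL):
    rng = np.random.default_rng(3)
    return protocol.apm_positions()[protocol.apm_sequence(rng)]


class TestSimulateApmMatching:
    def test_noiseless_identity_matches_mirrored_targets(self, apm_targets):
        params = make_params()
        matched = simulate_apm_matching(apm_targets, params)
        assert np.allclose(matched, mirror_x(apm_targets))

    def test_contraction_scales_hull_area_quadratically(self, apm_targets):
        params = make_params(apm_contraction=0.8)
        matched = simulate_apm_matching(apm_targets, params)
        ratio = ConvexHull(matched).volume / ConvexHull(mirror_x(apm_targets)).volume
        assert ratio == pytest.approx(0.64, abs=1e-12)

    def test_pure_translation(self, apm_targets):
        params = make_params(apm_shift=(0.03, -0.02))
        matched = simulate_apm_matching(apm_targets, params)
        delta = matched.mean(axis=0) - mirror_x(apm_targets).mean(axis=0)
        assert np.allclose(delta, [0.03, -0.02])


class TestSimulateAmmTrial:
    def _passive(self, protocol):
        pos = protocol.amm_positions()
        duration = 1.875 * protocol.amm_movement_length / protocol.passive_peak_speed_amm
        return min_jerk_trajectory(pos[0], pos[1], duration, protocol.sample_rate)

    def test_perfect_matcher_round_trip(self, protocol):
        passive = self._passive(protocol)
        active, failed = simulate_amm_trial(passive, make_params())
        assert not failed
        m = compute_amm([(passive, mirror_x(active), failed)])
        assert m.rl == pytest.approx(0.0, abs=1.0 / protocol.sample_rate)
        assert m.psr == pytest.approx(1.0, abs=1e-3)
        assert m.ide == pytest.approx(0.0, abs=1e-6)
        assert m.plr == pytest.approx(1.0, abs=2e-2)
        assert m.n_failed == 0

    def test_latency_round_trip(self, protocol):
        passive = self._passive(protocol)
        active, failed = simulate_amm_trial(passive, make_params(amm_latency=0.3))
        m = compute_amm([(passive, mirror_x(active), failed)])
        assert m.rl == pytest.approx(0.3, abs=1.0 / protocol.sample_rate)

    def test_speed_ratio_round_trip(self, protocol):
        passive = self._passive(protocol)
        active, failed = simulate_amm_trial(passive, make_params(amm_speed_ratio=0.5))
        m = compute_amm([(passive, mirror_x(active), failed)])
        assert m.psr == pytest.approx(0.5, abs=5e-3)


class TestSimulateVmrSession:
    def test_one_step_full_compensation(self, protocol):
        session = simulate_vmr_session(protocol, make_params(learner_rate=1.0))
        assert np.all(session.baseline == 0.0)
        assert session.adaptation[0] == 0.0
        assert np.all(session.adaptation[1:] == 30.0)

    def test_adaptation_asymptote_with_full_retention(self, protocol):
        session = simulate_vmr_session(protocol, make_params(learner_rate=0.3))
        assert session.adaptation[-1] == pytest.approx(30.0, abs=1e-6)

    def test_non_learner_never_adapts(self, protocol):
        session = simulate_vmr_session(protocol, make_params(learner_rate=0.0))
        assert np.all(session.directions == 0.0)
        assert trials_to_adapt(session, threshold=10.0) == 125

    def test_synthesized_reach_round_trips_direction(self, protocol):
        for angle in (-12.0, 0.0, 27.5):
            tr = synthesize_vmr_trajectory(angle, protocol)
            onset = detect_onset(tr, axis="forward_y")
            got = direction_at_latency(
                tr, onset, origin=protocol.vmr_start(), target=protocol.vmr_target()
            )
            assert got == pytest.approx(angle, abs=1e-6)


class TestProtocolSequences:
    def test_trial_counts_are_exact(self, protocol, rng):
        assert protocol.apm_sequence(rng).size == 54
        assert protocol.amm_sequence(rng).shape == (36, 2)
        assert protocol.n_vmr_trials == 175

    def test_no_consecutive_repeats(self, protocol):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            apm = protocol.apm_sequence(rng)
            assert np.all(np.diff(apm) != 0)
            amm = protocol.amm_sequence(rng)
            assert np.all(np.diff(amm[:, 1]) != 0)
            assert np.all(amm[:, 0] != amm[:, 1])

    def test_each_block_is_a_full_permutation(self, protocol, rng):
        apm = protocol.apm_sequence(rng).reshape(protocol.apm_blocks, 9)
        for block in apm:
            assert sorted(block) == list(range(9))
        amm = protocol.amm_sequence(rng).reshape(protocol.amm_blocks, 6, 2)
        for block in amm:
            assert len({tuple(p) for p in block}) == 6


class TestGenerateCohort:
    def test_same_seed_bitwise_identical(self):
        a = generate_cohort(n_stroke=3, n_control=3, seed=99)
        b = generate_cohort(n_stroke=3, n_control=3, seed=99)
        for pa, pb in zip(a.participants, b.participants):
            assert pa.params == pb.params
            assert np.array_equal(pa.apm_matched, pb.apm_matched)
            assert np.array_equal(pa.vmr.directions, pb.vmr.directions)
            for (p1, a1, f1), (p2, a2, f2) in zip(pa.amm_trials, pb.amm_trials):
                assert f1 == f2 and np.array_equal(a1.x, a2.x)

    def test_protocol_counts_per_participant(self):
        cohort = generate_cohort(n_stroke=1, n_control=1, seed=5)
        for p in cohort.participants:
            assert p.apm_targets.shape == (54, 2)
            assert len(p.amm_trials) == 36
            assert p.vmr.directions.size == 175

    def test_noiseless_round_trip_identifiability(self, protocol):
        params = make_params(
            apm_contraction=0.85,
            apm_shift=(0.02, -0.01),
            amm_latency=0.25,
        )
        data = simulate_participant(params)
        apm = compute_apm(data.apm_targets, mirror_x(data.apm_matched))
        assert np.sqrt(apm.area_xy) == pytest.approx(0.85, abs=1e-9)
        # generator shift is in the active-arm frame; mirroring into the
        # passive frame for analysis flips its x-component
        assert (apm.shift_x, apm.shift_y) == pytest.approx((-0.02, -0.01), abs=1e-12)
        amm = compute_amm(
            [(p, mirror_x(a), f) for p, a, f in data.amm_trials]
        )
        assert amm.rl == pytest.approx(0.25, abs=2.0 / protocol.sample_rate)
        assert amm.psr == pytest.approx(1.0, abs=5e-3)
        assert amm.plr == pytest.approx(1.0, abs=2e-2)
        assert amm.ide == pytest.approx(0.0, abs=1e-6)

    def test_latency_with_unequal_durations_shifts_by_threshold_crossing(self, protocol):
        # a slower, longer active movement crosses the 12.5%-of-peak onset
        # threshold later by s* * (T_active - T_passive), where s* is the
        # min-jerk phase at which speed reaches 12.5% of its peak
        params = make_params(amm_latency=0.25, amm_speed_ratio=0.8, amm_path_ratio=1.1)
        data = simulate_participant(params)
        amm = compute_amm([(p, mirror_x(a), f) for p, a, f in data.amm_trials])
        from scipy.optimize import brentq

        s_star = brentq(lambda s: 30 * s**2 * (1 - s) ** 2 - 0.125 * 1.875, 0.0, 0.5)
        t_passive = 1.875 * 0.20 / 0.20
        t_active = t_passive * 1.1 / 0.8
        expected = 0.25 + s_star * (t_active - t_passive)
        assert amm.rl == pytest.approx(expected, abs=2.0 / protocol.sample_rate)
        assert amm.psr == pytest.approx(0.8, abs=5e-3)
        assert amm.plr == pytest.approx(1.1, abs=2e-2)

    def test_zero_prevalence_controls_rarely_flagged(self):
        # stroke drawn from the healthy distribution; controls act as their own
        # normative reference, so each flag should fire near the 5% design rate
        from proprioadapt.pipeline import PipelineConfig, run_pipeline

        cfg = PipelineConfig(
            seed=11, n_stroke=40, n_control=40, n_normative=60,
            p_proprioception=0.0, p_adaptation=0.0, n_boot=200,
        )
        res = run_pipeline(cfg)
        prev = res.prevalence.set_index("flag")["proportion"]
        for flag in ("apm_impaired", "amm_impaired", "initial_impaired",
                     "final_impaired", "trials_impaired"):
            assert prev[flag] < 0.20

    def test_stroke_baseline_sd_calibration_anchor(self):
        # generating stroke baseline noise exceeds control by 3.27 deg on average
        cohort = generate_cohort(n_stroke=48, n_control=40, seed=21)
        adaptation = []
        for p in cohort.participants:
            m = summarize_session(p.vmr)
            adaptation.append((p.params.group, m.baseline_sd))
        stroke = np.mean([v for g, v in adaptation if g == "stroke"])
        control = np.mean([v for g, v in adaptation if g == "control"])
        assert stroke - control == pytest.approx(3.27, abs=1.5)

    def test_tlt_monotone_in_matching_noise(self):
        cohort = generate_cohort(n_stroke=60, n_control=0, seed=31)
        noise = np.array([p.params.apm_noise_sd for p in cohort.participants])
        tlt = np.array([p.params.tlt for p in cohort.participants])
        assert np.mean(noise[tlt >= 2]) > np.mean(noise[tlt == 0])

    def test_coupled_impairments_with_copula_correlation(self):
        prev = PrevalenceConfig(impairment_correlation=0.999)
        cohort = generate_cohort(n_stroke=60, n_control=0, prevalence=prev, seed=41)
        flags = [(p.params.proprio_impaired, p.params.adapt_impaired)
                 for p in cohort.participants]
        agree = np.mean([a == b for a, b in flags])
        assert agree > 0.9
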