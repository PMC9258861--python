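"""Control loop: target regions, delays, feedback, learning, tuning."""

import numpy as np
import pytest

from laryngosim.controller import (ControllerGains, DelayConfig,
                                   FeedforwardWeights, TargetRegion,
                                   TuningError, auditory_error,
                                   run_utterance, step_motor_command,
                                   tune_target, update_feedforward_weights)
from laryngosim.acoustics import hz_to_cents


@pytest.fixture(scope="module")
def tuned_vowel(fmap):
    from laryngosim.controller import tune_target

    f_base, _ = fmap.lookup(0.169, 0.175, 800.0)
    return tune_target(f_base, fmap, ControllerGains(g_fb_aud=1.0, lambda_ff=0.0),
                       DelayConfig())


class TestTargetRegion:
    def test_region_invariants(self):
        with pytest.raises(ValueError):
            TargetRegion(f_min=np.array([140.0]), f_max=np.array([130.0]),
                         spl_min=np.array([68.0]), spl_max=np.array([80.0]))

    def test_error_zero_inside_region(self):
        r = TargetRegion.sustained(134.0, 10)
        f_in = 134.0 * 2 ** (3 / 1200)       # +3 cents, inside +/-5
        e, unv = auditory_error(r, f_in, 74.0, 0)
        assert not unv and np.all(e == 0.0)

    def test_error_detected_outside_region(self):
        r = TargetRegion.sustained(134.0, 10)
        f_out = 134.0 * 2 ** (20 / 1200)
        e, _ = auditory_error(r, f_out, 74.0, 0)
        assert e[0] < 0  # pulls back down toward the region
        assert e[1] == 0.0  # SPL inside [68, 80]

    def test_spl_band_region(self):
        r = TargetRegion.sustained(134.0, 4)
        e, _ = auditory_error(r, 134.0, 74.0, 0)
        assert e[1] == 0.0
        e, _ = auditory_error(r, 134.0, 85.0, 0)
        assert e[1] < 0.0

    def test_unvoiced_flag_zero_error(self):
        r = TargetRegion.sustained(134.0, 4)
        e, unv = auditory_error(r, None, 74.0, 0)
        assert unv and e[0] == 0.0


class TestDelays:
    def test_misaligned_delay_rejected(self):
        with pytest.raises(ValueError):
            DelayConfig(tau_moac=0.052)

    def test_loop_latency_split(self):
        d = DelayConfig()
        assert (d.actuation_steps + d.sensing_steps) * d.control_step == \
            pytest.approx(0.120)


class TestMotorCommand:
    def test_pure_feedforward_when_feedback_zero(self):
        g = ControllerGains()
        ff = np.array([0.2, 0.3])
        cmd, state = step_motor_command(ff, np.zeros(2), np.zeros(2), g,
                                        np.zeros(2))
        assert np.array_equal(cmd, ff)

    def test_rectangle_rule_accumulation(self):
        g = ControllerGains(g_fb_total=1.0)
        v = np.array([0.4, -0.2])
        state = np.zeros(2)
        for _ in range(7):
            cmd, state = step_motor_command(np.zeros(2), v, np.zeros(2), g,
                                            state, dt=0.005)
        assert np.allclose(cmd, 7 * v * 0.005)

    def test_gain_bounds(self):
        with pytest.raises(ValueError):
            ControllerGains(g_fb_aud=1.5)
        with pytest.raises(ValueError):
            ControllerGains(lambda_ff=-0.1)


class TestWeights:
    def test_zero_learning_rate_is_identity(self):
        w = FeedforwardWeights.unit(5)
        e = np.random.default_rng(0).normal(size=(5, 2))
        w2 = update_feedforward_weights(w, e, np.full((5, 2), 0.2), 0.0)
        assert np.array_equal(w2.w, w.w)

    def test_zero_error_is_identity(self):
        w = FeedforwardWeights.unit(5)
        w2 = update_feedforward_weights(w, np.zeros((5, 2)),
                                        np.full((5, 2), 0.2), 0.3)
        assert np.array_equal(w2.w, w.w)

    def test_bounds_projection(self):
        w = FeedforwardWeights.unit(3)
        r = np.full((3, 2), 0.2)
        e = np.full((3, 2), -10.0)   # would drive the command far negative
        w2 = update_feedforward_weights(w, e, r, 1.0,
                                        bounds=(np.zeros(2), np.ones(2)))
        assert np.all(w2.w * r >= -1e-12)


class TestRunUtterance:
    def test_tuned_vowel_stays_in_region(self, fmap, tuned_vowel, delays,
                                         unity_gains):
        res = run_utterance(tuned_vowel, unity_gains, delays, 0.0, fmap,
                            check_tuning=True)
        cents = res.produced_cents(tuned_vowel.baseline_f0)
        assert np.nanmax(np.abs(cents)) <= 5.0
        assert np.all(res.e_aud == 0.0)
        assert np.all(res.fb_correction == 0.0)

    def test_response_latency_equals_loop_latency(self, fmap, tuned_vowel,
                                                  delays, unity_gains):
        n = tuned_vowel.n_steps
        pert = np.zeros(n)
        onset = 100
        pert[onset:] = 100.0
        res0 = run_utterance(tuned_vowel, unity_gains, delays, 0.0, fmap)
        res = run_utterance(tuned_vowel, unity_gains, delays, pert, fmap)
        dev = np.flatnonzero(np.abs(res.f_produced - res0.f_produced) > 1e-12)
        latency_steps = int(round(delays.loop_latency_aud / delays.control_step))
        assert len(dev) > 0
        assert dev[0] == onset + latency_steps

    def test_causality_shift(self, fmap, tuned_vowel, delays, unity_gains):
        n = tuned_vowel.n_steps
        shift = 40
        p1 = np.zeros(n)
        p1[100:] = 100.0
        p2 = np.zeros(n)
        p2[100 + shift:] = 100.0
        r1 = run_utterance(tuned_vowel, unity_gains, delays, p1, fmap)
        r2 = run_utterance(tuned_vowel, unity_gains, delays, p2, fmap)
        assert np.allclose(r1.f_produced[100:n - shift - 24],
                           r2.f_produced[100 + shift:n - 24], equal_nan=True)

    def test_jnd_dead_zone(self, fmap, tuned_vowel, delays, unity_gains):
        res = run_utterance(tuned_vowel, unity_gains, delays, 4.0, fmap)
        assert np.all(res.e_aud == 0.0)
        assert np.all(res.fb_correction == 0.0)

    def test_feedback_disabled_replays_feedforward(self, fmap, tuned_vowel,
                                                   delays):
        g_off = ControllerGains(g_fb_aud=1.0, g_fb_total=0.0, lambda_ff=0.0)
        res0 = run_utterance(tuned_vowel,
                             ControllerGains(g_fb_aud=0.0, lambda_ff=0.0),
                             delays, 100.0, fmap)
        res = run_utterance(tuned_vowel, g_off, delays, 100.0, fmap)
        assert np.allclose(res.f_produced, res0.f_produced, equal_nan=True)

    def test_half_compensation_bound(self, fmap, tuned_vowel, delays):
        """Steady compensation <= p/2, approached at g = 1."""
        n = tuned_vowel.n_steps
        pert = np.zeros(n)
        pert[100:] = 100.0
        comps = []
        for g in (0.25, 0.5, 1.0):
            gains = ControllerGains(g_fb_aud=g, lambda_ff=0.0)
            res = run_utterance(tuned_vowel, gains, delays, pert, fmap)
            cents = res.produced_cents(tuned_vowel.baseline_f0)
            comp = -np.nanmean(cents[-100:])
            assert comp <= 51.0
            comps.append(comp)
        assert comps[0] < comps[1] < comps[2]
        assert comps[2] == pytest.approx(50.0, abs=2.0)

    def test_untuned_target_raises(self, fmap, delays, unity_gains):
        from laryngosim.controller import TargetRegion, TunedTarget

        n = 200
        region = TargetRegion.sustained(150.0, n)  # far from Case-B output
        bad = TunedTarget(r_motor=np.tile([0.169, 0.175], (n, 1)),
                          weights=FeedforwardWeights.unit(n),
                          region=region, baseline_f0=150.0)
        with pytest.raises(TuningError):
            run_utterance(bad, unity_gains, delays, 0.0, fmap,
                          check_tuning=True)


class TestTuneTarget:
    def test_constant_target_converges_immediately(self, fmap):
        f_base, _ = fmap.lookup(0.169, 0.175, 800.0)
        sound = tune_target(f_base, fmap, ControllerGains(), DelayConfig(),
                            n_steps=300)
        assert sound.iterations == 1
        assert np.allclose(sound.weights.w, 1.0)

    def test_ramp_target_converges_to_point_tolerance(self, fine_map):
        f0, _ = fine_map.lookup(0.169, 0.175, 800.0)
        n = 200
        contour = np.linspace(f0, f0 + 14.0, n)
        sound = tune_target(contour, fine_map,
                            ControllerGains(g_fb_aud=1.0, lambda_ff=0.5),
                            DelayConfig(), point_target=True, tol_cents=1.0)
        res = run_utterance(sound, ControllerGains(g_fb_aud=1.0, lambda_ff=0.0),
                            DelayConfig(), 0.0, fine_map)
        resid = 1200 * np.log2(res.f_produced / contour)
        assert np.nanmax(np.abs(resid)) < 1.0

    def test_unreachable_contour_fails_with_residual(self, fmap):
        contour = np.full(150, 300.0)  # far above the voiced range
        with pytest.raises(TuningError):
            tune_target(contour, fmap, ControllerGains(), DelayConfig(),
                        point_target=True, max_iter=5)
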