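"""Perturbation paradigms, fit metrics, and synthetic reference fixtures."""

import numpy as np
import pytest

from laryngosim.controller import ControllerGains
from laryngosim.paradigms import (PerturbationSchedule, demo_contour,
                                  fit_metrics, generate_reference_fixture,
                                  grid_fit, motor_equivalence_sweep,
                                  moving_average, run_adaptive_paradigm,
                                  run_reflexive_paradigm, track_prosody)


@pytest.fixture(scope="module")
def adaptive_result(fmap):
    return run_adaptive_paradigm(ControllerGains(g_fb_aud=0.5, lambda_ff=0.1),
                                 PerturbationSchedule.adaptive(), fmap)


class TestSchedules:
    def test_reflexive_defaults(self):
        s = PerturbationSchedule.reflexive()
        assert s.magnitudes_cents == (100.0,)
        assert s.onset_s == 0.5

    def test_adaptive_phase_structure(self):
        s = PerturbationSchedule.adaptive()
        assert s.n_trials == 108
        m = np.array(s.magnitudes_cents)
        assert np.all(m[:24] == 0.0)
        ramp = m[24:54]
        assert np.allclose(np.diff(ramp), 100.0 / 30.0)
        assert np.all(m[54:84] == 100.0)
        assert np.all(m[84:] == 0.0)

    def test_nonstandard_trial_count_rejected(self, fmap):
        s = PerturbationSchedule.adaptive(n_baseline=2, n_ramp=2, n_hold=2,
                                          n_after=2)
        with pytest.raises(ValueError):
            run_adaptive_paradigm(ControllerGains(), s, fmap)


class TestReflexive:
    def test_null_perturbation_flat_trace(self, fmap):
        s = PerturbationSchedule.reflexive(magnitude_cents=0.0)
        r = run_reflexive_paradigm(ControllerGains(g_fb_aud=1.0), s, fmap)
        assert np.nanmax(np.abs(r.response_cents)) < 1e-9

    def test_pre_perturbation_normalization(self, fmap, unity_gains):
        r = run_reflexive_paradigm(unity_gains,
                                   PerturbationSchedule.reflexive(), fmap)
        pre = r.response_cents[80:100]
        assert np.nanmean(pre) == pytest.approx(0.0, abs=1e-9)
        assert np.nanmax(np.abs(pre)) <= 5.0

    def test_compensation_monotone_in_gain(self, fmap):
        comps = []
        for g in (0.1, 0.4, 0.7, 1.0):
            r = run_reflexive_paradigm(ControllerGains(g_fb_aud=g),
                                       PerturbationSchedule.reflexive(), fmap)
            comps.append(-np.nanmean(r.response_cents[-100:]))
        assert all(a < b for a, b in zip(comps, comps[1:]))


class TestAdaptive:
    def test_no_learning_all_trials_identical(self, fmap):
        r = run_adaptive_paradigm(ControllerGains(g_fb_aud=0.5, lambda_ff=0.0),
                                  PerturbationSchedule.adaptive(), fmap)
        assert np.allclose(r.trial_adaptation_cents, 0.0, atol=1e-9)

    def test_baseline_phase_within_target_region(self, adaptive_result):
        base = adaptive_result.trial_adaptation_cents[:24]
        assert np.all(np.abs(base) <= 5.0)

    def test_learning_phases(self, adaptive_result):
        ad = adaptive_result.trial_adaptation_cents
        ramp, hold, after = ad[24:54], ad[54:84], ad[84:]
        # compensation grows through the ramp (opposing the upward shift)
        assert abs(ramp[-1]) > abs(ramp[4])
        assert np.sign(np.mean(hold)) == -1.0      # opposes +100 cents
        assert np.max(np.abs(hold)) < 100.0        # below full compensation
        # aftereffect decays without resetting instantly
        first5 = np.mean(after[:5])
        assert 0.0 < abs(first5) < abs(np.mean(hold))
        assert abs(after[-1]) < abs(first5)


class TestFitMetrics:
    def test_identity(self):
        x = np.array([0.0, 5.0, 10.0])
        m = fit_metrics(x, x)
        assert (m.rmse, m.r_squared, m.auc_abs_diff) == (0.0, 1.0, 0.0)

    def test_constant_offset_rmse(self):
        ref = np.array([0.0, 10.0, 20.0])
        m = fit_metrics(ref + 3.0, ref)
        assert m.rmse == pytest.approx(3.0)

    def test_hand_computed_three_point(self):
        ref = np.array([0.0, 10.0, 20.0])
        model = np.array([0.0, 12.0, 18.0])
        m = fit_metrics(model, ref)
        # d = (0, 2, -2): rmse = sqrt(8/3); ss_res = 8, ss_tot = 200
        assert m.rmse == pytest.approx(np.sqrt(8.0 / 3.0))
        assert m.r_squared == pytest.approx(1.0 - 8.0 / 200.0)
        # trapezoid AUCs: model (6+15)=21, ref (5+15)=20
        assert m.auc_abs_diff == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_metrics(np.zeros(3), np.zeros(4))


class TestGridFit:
    def test_self_recovery(self, fmap):
        traces = {}
        for g in (0.3, 0.5, 0.7):
            r = run_reflexive_paradigm(ControllerGains(g_fb_aud=g),
                                       PerturbationSchedule.reflexive(), fmap)
            traces[g] = r.response_cents
        table, best = grid_fit([0.3, 0.5, 0.7], lambda g: traces[g],
                               traces[0.5], param_name="gain")
        assert best == 0.5
        assert table.loc[table["gain"] == 0.5, "rmse"].iloc[0] == \
            pytest.approx(0.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_fit([], lambda g: np.zeros(3), np.zeros(3))


class TestFixtures:
    def test_zero_noise_returns_model_trace(self, fmap, unity_gains):
        fix = generate_reference_fixture("reflexive", fmap, unity_gains,
                                         noise_sigma_cents=0.0, seed=1)
        assert np.array_equal(fix["mean"], fix["clean"])
        assert np.all(fix["ci_half_width"] == 0.0)

    def test_seed_determinism(self, fmap, unity_gains):
        f1 = generate_reference_fixture("reflexive", fmap, unity_gains, seed=9)
        f2 = generate_reference_fixture("reflexive", fmap, unity_gains, seed=9)
        assert np.array_equal(f1["mean"], f2["mean"])

    def test_ci_half_width_matches_sampling_theory(self, fmap, unity_gains):
        sigma, n = 5.0, 20
        fix = generate_reference_fixture("reflexive", fmap, unity_gains,
                                         noise_sigma_cents=sigma,
                                         n_subjects=n, seed=3)
        expected = 1.96 * sigma / np.sqrt(n)
        assert np.mean(fix["ci_half_width"]) == pytest.approx(expected,
                                                              rel=0.15)

    def test_negative_sigma_rejected(self, fmap, unity_gains):
        with pytest.raises(ValueError):
            generate_reference_fixture("reflexive", fmap, unity_gains,
                                       noise_sigma_cents=-1.0)


class TestMotorEquivalence:
    def test_cases_share_f0_and_spl_band(self, fmap, case_segments):
        from laryngosim.acoustics import estimate_f0, compute_spl

        f0s = {k: estimate_f0(s) for k, s in case_segments.items()}
        spls = {k: compute_spl(s) for k, s in case_segments.items()}
        assert max(f0s.values()) - min(f0s.values()) < 5.0
        assert max(spls.values()) - min(spls.values()) <= 5.0

    def test_sweep_reports_all_cases(self, fmap):
        sweep = motor_equivalence_sweep(None, 800.0,
                                        ControllerGains(g_fb_aud=0.5), fmap,
                                        duration_ms=1500.0)
        assert set(sweep) == {"A", "B", "C", "D"}
        for entry in sweep.values():
            assert "excluded" not in entry
            assert entry["spl_error_max"] == 0.0

    def test_unvoiced_case_excluded_not_fatal(self, fmap):
        sweep = motor_equivalence_sweep({"X": (0.95, 0.05)}, 800.0,
                                        ControllerGains(), fmap,
                                        duration_ms=1000.0)
        assert "excluded" in sweep["X"]


class TestProsody:
    def test_moving_average_impulse(self):
        x = np.zeros(31)
        x[15] = 1.0
        y = moving_average(x, 5)
        assert y[15] == pytest.approx(0.2)

    def test_flat_contour_already_tuned(self, fine_map):
        f0, _ = fine_map.lookup(0.169, 0.175, 800.0)
        res = track_prosody(demo_contour("flat", base_hz=f0),
                            ControllerGains(g_fb_aud=1.0, lambda_ff=0.5),
                            fine_map, smooth=False)
        assert res["iterations"] <= 2
        assert res["max_abs_residual_cents"] < 1.0

    def test_infeasible_contour_reports_span(self, fine_map):
        contour = demo_contour("flat", base_hz=250.0)
        with pytest.raises(ValueError, match="voiced map range"):
            track_prosody(contour, ControllerGains(), fine_map)
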