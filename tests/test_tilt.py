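"""Relative tilt, equivalent-90 transform, recoding, decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from flowparse.observer import analytic_relative_tilt
from flowparse.tilt import (relative_tilt, equivalent_90,
                            invert_equivalent_90, recode_configuration,
                            collapsed_probe_angle, summarize_participant,
                            gain_from_global_tilt)
from flowparse.geometry import FlowConfig, flow_speed_at_probe_exp2
from flowparse.cohort import simulate_experiment2


class TestRelativeTilt:
    def test_right_probe_inward_positive(self):
        assert relative_tilt(110.0, 90.0, "right") == pytest.approx(20.0)

    def test_left_probe_sign_flip(self):
        assert relative_tilt(70.0, 90.0, "left") == pytest.approx(20.0)

    def test_veridical_report_gives_zero(self):
        assert relative_tilt(75.0, 75.0, "right") == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            relative_tilt(190.0, 90.0, "right")


class TestEquivalent90:
    def test_identity_at_vertical_probe(self):
        for r in (-20.0, 0.0, 13.7, 45.0):
            assert equivalent_90(r, 90.0) == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize("theta", [75.0, 105.0])
    def test_zero_tilt_maps_to_zero(self, theta):
        assert equivalent_90(0.0, theta) == 0.0

    @pytest.mark.parametrize("theta", [75.0, 105.0])
    def test_root_finder_oracle_on_defining_equation(self, theta):
        """Solve tan(theta + relT) = v sin(theta) / (v cos(theta) - h) for
        h numerically and compare atan(h/v) with the closed form."""
        v = 0.8
        for relT in (-20.0, -5.0, 3.0, 17.0, 40.0, 60.0):
            th, r = np.radians(theta), np.radians(relT)

            def residual(h):
                lhs = np.arctan2(v * np.sin(th), v * np.cos(th) - h)
                return lhs - (th + r)

            h = brentq(residual, -50.0, 50.0, xtol=1e-14)
            expected = np.degrees(np.arctan(h / v))
            assert equivalent_90(relT, theta, v) == pytest.approx(
                expected, abs=1e-9)

    @pytest.mark.parametrize("theta", [75.0, 105.0])
    def test_round_trip_through_inverse(self, theta):
        for relT in np.linspace(-30.0, 60.0, 25):
            eq = equivalent_90(relT, theta)
            back = invert_equivalent_90(eq, theta)
            assert back == pytest.approx(relT, abs=1e-9)

    def test_strictly_increasing_in_tilt(self):
        grid = np.linspace(-30.0, 60.0, 400)
        for theta in (75.0, 105.0):
            vals = [equivalent_90(r, theta) for r in grid]
            assert np.all(np.diff(vals) > 0)

    def test_degenerate_horizontal_percept_rejected(self):
        with pytest.raises(ValueError):
            equivalent_90(-75.0, 75.0)


class TestRecoding:
    @pytest.mark.parametrize("mask,side,expected", [
        ("Full", "left", "Full"),
        ("Full", "right", "Full"),
        ("HemiL", "left", "Same"),
        ("HemiR", "right", "Same"),
        ("HemiR", "left", "Opposite"),
        ("HemiL", "right", "Opposite"),
    ])
    def test_mapping(self, mask, side, expected):
        assert recode_configuration(mask, side) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            recode_configuration("Hemi", "left")
        with pytest.raises(ValueError):
            recode_configuration("Full", "up")

    def test_collapsed_angle_mirrors_left_probes(self):
        assert collapsed_probe_angle(75.0, "left") == 105.0
        assert collapsed_probe_angle(75.0, "right") == 75.0


def _participant(g_global, g_local, sigma_report, pid="P1", n_sessions=2):
    return pd.DataFrame([{
        "participant_id": pid, "age": 50.0, "g_global": g_global,
        "g_local": g_local, "sigma_report": sigma_report,
        "sigma_flow": 0.0, "lapse": 0.0, "n_sessions": n_sessions,
    }])


class TestSummarize:
    def test_noiseless_global_only_observer_matches_closed_form(self):
        cfg = FlowConfig()
        flow = flow_speed_at_probe_exp2(cfg)
        trials = simulate_experiment2(_participant(0.5, 0.0, 0.0), cfg, seed=1)
        s = summarize_participant(trials, cfg.probe_speed)
        expected = analytic_relative_tilt([0.0, cfg.probe_speed],
                                          [flow, 0.0], 0.5)
        for val in (s.relT_full, s.relT_same, s.relT_opposite, s.relT_global):
            assert val == pytest.approx(expected, abs=1e-9)
        assert s.relT_local == pytest.approx(0.0, abs=1e-9)
        assert s.n_trials_per_config == 72

    def test_local_gain_raises_same_but_not_opposite(self):
        cfg = FlowConfig()
        flow = flow_speed_at_probe_exp2(cfg)
        trials = simulate_experiment2(_participant(0.5, 0.3, 0.0), cfg, seed=2)
        s = summarize_participant(trials, cfg.probe_speed)
        assert s.relT_opposite == pytest.approx(
            analytic_relative_tilt([0.0, 0.8], [flow, 0.0], 0.5), abs=1e-9)
        assert s.relT_same == pytest.approx(
            analytic_relative_tilt([0.0, 0.8], [flow, 0.0], 0.8), abs=1e-9)
        assert s.relT_local > 0

    def test_decomposition_identity(self):
        trials = simulate_experiment2(_participant(0.6, 0.2, 5.0),
                                      FlowConfig(), seed=3)
        s = summarize_participant(trials)
        assert s.relT_local + s.relT_global == pytest.approx(s.relT_same,
                                                             abs=1e-12)

    def test_veridical_reports_give_zero_summaries(self):
        trials = simulate_experiment2(_participant(0.0, 0.0, 0.0),
                                      FlowConfig(), seed=4)
        s = summarize_participant(trials)
        assert s.relT_full == s.relT_same == s.relT_opposite == 0.0

    def test_side_symmetry(self):
        """Mirroring every trial left<->right leaves all summaries intact."""
        trials = simulate_experiment2(_participant(0.6, 0.2, 5.0),
                                      FlowConfig(), seed=5)
        mirrored = trials.copy()
        mirrored["probe_side"] = trials["probe_side"].map(
            {"left": "right", "right": "left"})
        mirrored["field_mask"] = trials["field_mask"].map(
            {"Full": "Full", "HemiL": "HemiR", "HemiR": "HemiL"})
        mirrored["probe_angle_deg"] = 180.0 - trials["probe_angle_deg"]
        mirrored["reported_angle_deg"] = 180.0 - trials["reported_angle_deg"]
        a = summarize_participant(trials)
        b = summarize_participant(mirrored)
        assert a.relT_full == pytest.approx(b.relT_full, abs=1e-9)
        assert a.relT_same == pytest.approx(b.relT_same, abs=1e-9)
        assert a.relT_opposite == pytest.approx(b.relT_opposite, abs=1e-9)

    def test_single_session_participant_has_36_trials_per_config(self):
        trials = simulate_experiment2(_participant(0.5, 0.0, 0.0,
                                                   n_sessions=1),
                                      FlowConfig(), seed=6)
        s = summarize_participant(trials)
        assert s.n_trials_per_config == 36


class TestGainInversion:
    def test_inverts_closed_form_exactly(self):
        flow = 3.156
        for g in (0.1, 0.5, 0.9, 1.3):
            tilt = analytic_relative_tilt([0.0, 0.8], [flow, 0.0], g)
            assert gain_from_global_tilt(tilt, 0.8, flow) == pytest.approx(
                g, abs=1e-12)

    def test_noisy_recovery_within_tolerance(self, rng):
        """72 Opposite trials with 5 deg report noise recover the gain to
        within 0.05 on average."""
        cfg = FlowConfig()
        flow = flow_speed_at_probe_exp2(cfg)
        errs = []
        for i in range(30):
            trials = simulate_experiment2(_participant(0.65, 0.0, 5.0),
                                          cfg, seed=rng)
            s = summarize_participant(trials, cfg.probe_speed)
            errs.append(abs(gain_from_global_tilt(s.relT_global, 0.8, flow)
                            - 0.65))
        assert np.mean(errs) < 0.05
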