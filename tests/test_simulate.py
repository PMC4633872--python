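"""Generator: rate modulation, event sampling, rendering, responses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fixsig import SimulationConfig
from fixsig.config import ConfigError, InputError
from fixsig.simulate import (
    _render_saccades,
    contrast_drive,
    modulation_profile,
    sample_event_times,
    simulate_responses,
    synthesize_recording,
    _make_trial_table,
)

T = np.arange(-100.0, 1101.0, 2.0)


class TestModulationProfile:
    def test_zero_contrast_identity(self, default_config):
        assert np.all(modulation_profile(default_config, 0.0, T) == 1.0)

    def test_saturation_anchors(self, default_config):
        """At saturating contrast the profile passes through 1 - depth at the
        inhibition latency and 1 + gain at the rebound latency."""
        m = modulation_profile(default_config, 1e4, T)
        assert m[T == 180.0][0] == pytest.approx(0.5, abs=1e-6)
        assert m[T == 420.0][0] == pytest.approx(2.0, abs=1e-6)

    def test_midpoint_half_depth(self, default_config):
        # logistic drive is exactly 1/2 at its midpoint
        c_mid = 10.0 ** default_config.sensitivity_midpoint
        assert contrast_drive(default_config, c_mid) == pytest.approx(0.5)
        m = modulation_profile(default_config, c_mid, T)
        assert m[T == 180.0][0] == pytest.approx(1 - 0.5 / 2, abs=1e-9)

    def test_nonnegative_everywhere(self):
        cfg = SimulationConfig(inhibition_depth_max=1.0)
        for c in (0.5, 2.0, 50.0):
            assert modulation_profile(cfg, c, T).min() >= 0.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(min_value=0.1, max_value=50.0),
           st.floats(min_value=1.01, max_value=4.0))
    def test_monotone_in_contrast_at_latencies(self, c, factor):
        cfg = SimulationConfig()
        t = np.asarray([180.0, 420.0])
        m1 = modulation_profile(cfg, c, t)
        m2 = modulation_profile(cfg, c * factor, t)
        assert m2[0] <= m1[0] + 1e-12   # deeper inhibition
        assert m2[1] >= m1[1] - 1e-12   # larger rebound

    def test_negative_contrast_rejected(self, default_config):
        with pytest.raises(InputError):
            modulation_profile(default_config, -1.0, T)


class TestEventSampling:
    def test_zero_rate_gives_no_events(self):
        cfg = SimulationConfig(baseline_rate=0.0)
        assert len(sample_event_times(cfg, 0.0, seed=0)) == 0

    def test_dead_time_respected(self, default_config):
        rng = np.random.default_rng(5)
        gaps = []
        for _ in range(800):
            ev = sample_event_times(default_config, 4.0, rng=rng)
            if len(ev) > 1:
                gaps.append(np.diff(ev).min())
        assert min(gaps) >= 50.0

    def test_baseline_mean_count_calibrated(self, default_config):
        """Observed baseline rate matches the configured 1.5 /s (1.8 events
        per 1.2 s epoch) thanks to the dead-time-compensated hazard."""
        rng = np.random.default_rng(7)
        counts = [len(sample_event_times(default_config, 0.0, rng=rng))
                  for _ in range(6000)]
        assert np.mean(counts) == pytest.approx(1.8, abs=0.06)

    def test_biphasic_shape_at_high_contrast(self, default_config):
        rng = np.random.default_rng(8)
        t = np.concatenate([sample_event_times(default_config, 8.0, rng=rng)
                            for _ in range(4000)])
        hist, edges = np.histogram(t, bins=np.arange(-100, 1101, 50))
        centers = (edges[:-1] + edges[1:]) / 2
        assert abs(centers[hist.argmin()] - 180) <= 50
        assert abs(centers[hist.argmax()] - 420) <= 50

    def test_flat_psth_at_zero_contrast(self, default_config):
        rng = np.random.default_rng(9)
        t = np.concatenate([sample_event_times(default_config, 0.0, rng=rng)
                            for _ in range(4000)])
        hist, _ = np.histogram(t, bins=np.arange(-100, 1101, 100))
        expected = 4000 * 1.5 * 0.1
        z = (hist - expected) / np.sqrt(expected)
        assert np.abs(z).max() < 4.0


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"inhibition_depth_max": 1.2},
        {"rebound_gain_max": -0.1},
        {"inhibition_width": 0.0},
        {"sample_rate": 1000},
        {"contrasts": [0.0, 0.0, 1.0]},
        {"contrasts": [-1.0, 2.0]},
        {"iti_range": (1.4, 1.0)},
        {"baseline_rate": 15.0},     # violates the dead-time feasibility
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimulationConfig(**kw)

    def test_round_trip_json(self, tmp_path, default_config):
        path = tmp_path / "cfg.json"
        default_config.to_json(path)
        assert SimulationConfig.from_json(path) == default_config


class TestRecordingSynthesis:
    def test_silent_config_constant_trace(self):
        cfg = SimulationConfig(baseline_rate=0.0, noise_sd=0.0, drift_sd=0.0,
                               blink_rate=0.0, contrasts=[0.0], n_passive=3,
                               n_response=0)
        rec, _, truth = synthesize_recording(cfg, seed=0)
        assert len(truth.events) == 0
        assert np.ptp(rec.xl) == 0 and np.ptp(rec.yr) == 0

    def test_single_event_displacement_equals_amplitude(self):
        """The rendered waveform moves the eye by exactly the drawn vector."""
        n = 2000
        x, y = _render_saccades(n, np.asarray([2.0]), np.asarray([20 / 60.0]),
                                np.asarray([0.0]), np.asarray([0.004]),
                                np.random.default_rng(0), jitter_sd_ms=0.0)
        assert x[0] == pytest.approx(0.0, abs=1e-9)
        assert x[-1] == pytest.approx(20 / 60.0, abs=1e-6)
        assert np.all(np.abs(y) < 1e-12)

    def test_bit_reproducible(self):
        cfg = SimulationConfig(contrasts=[0.0, 2.0], n_passive=5,
                               n_response=2)
        r1, t1, g1 = synthesize_recording(cfg, seed=3)
        r2, t2, g2 = synthesize_recording(cfg, seed=3)
        assert np.array_equal(r1.xl, r2.xl) and np.array_equal(r1.pr, r2.pr)
        assert t1.equals(t2)
        assert g1.events.equals(g2.events)
        r3, _, _ = synthesize_recording(cfg, seed=4)
        assert not np.array_equal(r1.xl, r3.xl)

    def test_blinks_zero_pupil_exactly_inside(self):
        cfg = SimulationConfig(contrasts=[0.0], n_passive=30, n_response=0,
                               blink_rate=10.0)
        rec, _, truth = synthesize_recording(cfg, seed=6)
        assert truth.blink_intervals, "expected at least one blink"
        for t0, t1 in truth.blink_intervals:
            i0, i1 = int(round(t0 * 500)), int(round(t1 * 500))
            assert np.all(rec.pl[i0:i1] == 0)
        outside = np.ones(len(rec), dtype=bool)
        for t0, t1 in truth.blink_intervals:
            outside[int(round(t0 * 500)):int(round(t1 * 500))] = False
        assert np.all(rec.pl[outside] > 0)

    def test_truth_events_follow_main_sequence(self):
        cfg = SimulationConfig(contrasts=[0.0], n_passive=100, n_response=0)
        _, _, truth = synthesize_recording(cfg, seed=2)
        la = np.log10(truth.events["amplitude_arcmin"] / 60.0)
        lv = np.log10(truth.events["peak_velocity_deg_s"])
        r = np.corrcoef(la, lv)[0, 1]
        assert r**2 > 0.85

    def test_trial_table_invariants(self, default_config):
        rng = np.random.default_rng(0)
        trials = _make_trial_table(default_config, rng, n_passive=4,
                                   n_response=2)
        onsets = trials["onset_time"].to_numpy()
        assert np.all(np.diff(onsets) > 0)
        blank = trials[trials["contrast"] == 0.0]
        assert set(blank["condition"]) == {"passive"}


class TestResponses:
    def test_guessing_floor_and_midpoint(self, default_config):
        cfg = default_config
        rng = np.random.default_rng(12)
        c_mid = 10.0 ** cfg.sensitivity_midpoint
        trials = _make_trial_table(
            cfg.replace(contrasts=[0.001, c_mid]), rng,
            n_passive=0, n_response=4000)
        filled = simulate_responses(cfg, trials, seed=13)
        resp = filled[filled["condition"] == "response"]
        lo = resp[resp["contrast"] == 0.001]["response_correct"].mean()
        mid = resp[resp["contrast"] == c_mid]["response_correct"].mean()
        assert lo == pytest.approx(0.5, abs=0.03)
        assert mid == pytest.approx(0.75, abs=0.03)

    def test_passive_trials_unscored(self, default_config):
        rng = np.random.default_rng(1)
        trials = _make_trial_table(default_config, rng, n_passive=3,
                                   n_response=1)
        filled = simulate_responses(default_config, trials, seed=0)
        passive = filled[filled["condition"] == "passive"]["response_correct"]
        assert passive.isna().all()
        resp = filled[filled["condition"] == "response"]["response_correct"]
        assert resp.notna().all()
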