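"""Detection: blink masking, velocity, thresholds, filtering, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fixsig.config import DT_S, DegenerateInputError, InputError
from fixsig.detection import (
    GazeRecording,
    binocular_combine,
    build_blink_mask,
    compute_velocity,
    detect_monocular,
    detect_saccades,
    estimate_threshold,
    filter_saccades,
    main_sequence_fit,
    merge_close,
)


def make_recording(x, y=None, pupil=None):
    n = len(x)
    y = np.zeros(n) if y is None else y
    pupil = np.full(n, 1000.0) if pupil is None else pupil
    return GazeRecording(time=np.arange(n) * DT_S,
                         xl=np.asarray(x, float), yl=np.asarray(y, float),
                         pl=pupil.astype(float),
                         xr=np.asarray(x, float), yr=np.asarray(y, float),
                         pr=pupil.astype(float))


def event_row(onset_s, offset_s, amp=10.0, pv=20.0, eye="left"):
    return {"eye": eye, "onset_s": onset_s, "offset_s": offset_s,
            "duration_ms": (offset_s - onset_s) * 1000.0,
            "amplitude_arcmin": amp, "peak_velocity_deg_s": pv}


class TestBlinkMask:
    def test_constant_pupil_empty_mask(self):
        rec = make_recording(np.zeros(1000))
        mask = build_blink_mask(rec)
        assert not mask.samples.any()
        assert mask.intervals == []

    def test_zero_pupil_padded_200ms(self):
        pupil = np.full(2000, 900.0)
        pupil[1000:1050] = 0.0
        rec = make_recording(np.zeros(2000), pupil=pupil)
        mask = build_blink_mask(rec)
        # 200 ms = 100 samples of padding each side; the pupil step at the
        # blink edges is itself a semi-blink sample, widening by one sample
        assert mask.intervals == [(899, 1151)]

    def test_semi_blink_velocity(self):
        pupil = np.full(1000, 500.0)
        pupil[600:] = 560.0      # 60 units in one sample > 50 limit
        rec = make_recording(np.zeros(1000), pupil=pupil)
        mask = build_blink_mask(rec)
        (i0, i1), = mask.intervals
        assert i0 == 499 and i1 == 701

    def test_clipped_to_bounds(self):
        pupil = np.full(300, 800.0)
        pupil[:10] = 0.0
        rec = make_recording(np.zeros(300), pupil=pupil)
        (i0, i1), = build_blink_mask(rec).intervals
        assert i0 == 0 and i1 <= 300


class TestVelocity:
    def test_constant_position_zero_velocity(self):
        rec = make_recording(np.full(100, 3.3))
        vx, vy = compute_velocity(rec, "left")
        assert np.nanmax(np.abs(vx)) == 0.0

    def test_linear_ramp_unit_velocity(self):
        t = np.arange(500) * DT_S
        rec = make_recording(t * 1.0)   # 1 deg/s ramp
        vx, _ = compute_velocity(rec, "left")
        assert np.allclose(vx[2:-2], 1.0)
        assert np.isnan(vx[:2]).all() and np.isnan(vx[-2:]).all()

    def test_too_short_rejected(self):
        rec = make_recording(np.zeros(4))
        with pytest.raises(InputError):
            compute_velocity(rec, "left")

    def test_masked_samples_propagate(self):
        pupil = np.full(1000, 700.0)
        pupil[500:510] = 0.0
        rec = make_recording(np.random.default_rng(0).normal(size=1000) * .01,
                             pupil=pupil)
        mask = build_blink_mask(rec, pad_ms=10.0)
        vx, _ = compute_velocity(rec, "left", mask)
        assert np.isnan(vx[495:515]).all()


class TestThreshold:
    def test_gaussian_consistency(self):
        """For N(0, sigma) velocity noise the median-based estimator
        converges to 0.6745 sigma, hence eta -> 6 * 0.6745 * sigma."""
        rng = np.random.default_rng(0)
        v = rng.normal(0.0, 10.0, size=200_000)
        ex, ey = estimate_threshold(v, v.copy())
        expected = 6.0 * np.sqrt(0.454936) * 10.0
        assert ex == pytest.approx(expected, rel=0.02)

    def test_degenerate_constant_trace(self):
        v = np.zeros(1000)
        with pytest.raises(DegenerateInputError):
            estimate_threshold(v, v)

    def test_too_few_samples(self):
        v = np.random.default_rng(0).normal(size=50)
        with pytest.raises(DegenerateInputError):
            estimate_threshold(v, v)


class TestDetectMonocular:
    @staticmethod
    def _run(vx, x=None):
        n = len(vx)
        time = np.arange(n) * DT_S
        x = np.zeros(n) if x is None else x
        return detect_monocular(time, x, np.zeros(n), vx, np.zeros(n),
                                (10.0, 10.0))

    def test_no_suprathreshold_empty(self):
        assert len(self._run(np.full(100, 1.0))) == 0

    def test_two_sample_excursion_discarded(self):
        vx = np.ones(100)
        vx[50:52] = 50.0      # 4 ms < 6 ms minimum duration
        assert len(self._run(vx)) == 0

    def test_three_sample_run_detected_with_amplitude(self):
        vx = np.ones(200)
        vx[100:110] = 60.0
        x = np.zeros(200)
        x[100:110] = np.linspace(0, 0.3, 10)   # 18 arcmin sweep
        x[110:] = 0.3
        ev = self._run(vx, x)
        assert len(ev) == 1
        assert ev["duration_ms"].iloc[0] == pytest.approx(20.0)
        assert ev["amplitude_arcmin"].iloc[0] == pytest.approx(18.0, abs=0.1)

    def test_injected_synthetic_saccade(self):
        """A rendered 20 arcmin saccade in light noise is recovered once
        with its amplitude."""
        from scipy.special import expit
        rng = np.random.default_rng(3)
        n = 5000
        t = np.arange(n) * DT_S
        x = (20 / 60.0) * expit((t - 5.0) / 0.004) + rng.normal(0, 0.002, n)
        rec = make_recording(x, y=rng.normal(0, 0.002, n))
        events, _ = detect_saccades(rec)
        assert len(events) == 1
        assert events["amplitude_arcmin"].iloc[0] == pytest.approx(20.0, abs=1.0)


class TestFilters:
    @pytest.mark.parametrize("amp,dur,kept", [
        (2.0, 12.0, False),    # too small
        (61.0, 12.0, False),   # too large
        (10.0, 4.0, False),    # too brief
        (10.0, 12.0, True),
        (3.0, 6.0, True),      # inclusive bounds
        (60.0, 6.0, True),
    ])
    def test_bounds(self, amp, dur, kept):
        ev = pd.DataFrame([event_row(1.0, 1.0 + dur / 1000, amp=amp)])
        assert (len(filter_saccades(ev)) == 1) is kept


class TestMerge:
    def test_gap_below_window_merged(self):
        ev = pd.DataFrame([event_row(1.0, 1.02), event_row(1.05, 1.07)])
        out = merge_close(ev)   # 30 ms gap
        assert len(out) == 1
        assert out["offset_s"].iloc[0] == pytest.approx(1.07)

    def test_gap_above_window_untouched(self):
        ev = pd.DataFrame([event_row(1.0, 1.02), event_row(1.08, 1.10)])
        assert len(merge_close(ev)) == 2   # 60 ms gap

    def test_transitive_merge(self):
        ev = pd.DataFrame([event_row(1.0, 1.02), event_row(1.06, 1.08),
                           event_row(1.125, 1.145)])  # gaps 40 and 45 ms
        assert len(merge_close(ev)) == 1

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.floats(0, 10), st.floats(0.006, 0.05)),
                    min_size=0, max_size=12))
    def test_idempotent(self, spans):
        rows = [event_row(o, o + d) for o, d in spans]
        ev = pd.DataFrame(rows, columns=list(event_row(0, 1).keys()))
        once = merge_close(ev)
        twice = merge_close(once)
        assert once.reset_index(drop=True).equals(twice.reset_index(drop=True))


class TestBinocular:
    def test_overlapping_pair_combined(self):
        left = pd.DataFrame([event_row(0.100, 0.120, amp=10, pv=20)])
        right = pd.DataFrame([event_row(0.110, 0.130, amp=14, pv=24)])
        out = binocular_combine(left, right)
        assert len(out) == 1
        assert out["onset_s"].iloc[0] == pytest.approx(0.105)
        assert out["amplitude_arcmin"].iloc[0] == pytest.approx(12.0)
        assert out["peak_velocity_deg_s"].iloc[0] == pytest.approx(22.0)

    def test_monocular_only_dropped(self):
        left = pd.DataFrame([event_row(0.1, 0.12)])
        right = pd.DataFrame([], columns=left.columns)
        assert len(binocular_combine(left, right)) == 0

    def test_touching_intervals_do_not_overlap(self):
        # half-open convention: [100,120) and [120,140) share no sample
        left = pd.DataFrame([event_row(0.100, 0.120)])
        right = pd.DataFrame([event_row(0.120, 0.140)])
        assert len(binocular_combine(left, right)) == 0

    def test_each_event_used_once(self):
        left = pd.DataFrame([event_row(0.1, 0.2)])
        right = pd.DataFrame([event_row(0.10, 0.13), event_row(0.15, 0.18)])
        assert len(binocular_combine(left, right)) == 1


class TestMainSequence:
    def test_exact_power_law(self):
        rng = np.random.default_rng(0)
        amp = rng.uniform(3, 60, 200)
        ev = pd.DataFrame({"amplitude_arcmin": amp,
                           "peak_velocity_deg_s": 80 * (amp / 60.0)})
        fit = main_sequence_fit(ev)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.0)

    def test_shuffled_pairing_destroys_coupling(self):
        rng = np.random.default_rng(1)
        amp = rng.uniform(3, 60, 500)
        pv = 80 * (amp / 60.0)
        ev = pd.DataFrame({"amplitude_arcmin": amp,
                           "peak_velocity_deg_s": rng.permutation(pv)})
        assert main_sequence_fit(ev).r_squared < 0.2

    def test_too_few_events(self):
        ev = pd.DataFrame({"amplitude_arcmin": [10] * 5,
                           "peak_velocity_deg_s": [20] * 5})
        with pytest.raises(InputError):
            main_sequence_fit(ev)


class TestEndToEnd:
    def test_offset_invariance(self, small_session):
        """Adding a constant position offset leaves detections unchanged."""
        _, rec, _, _ = small_session
        events, _ = detect_saccades(rec)
        shifted = GazeRecording(time=rec.time,
                                xl=rec.xl + 5.0, yl=rec.yl - 3.0, pl=rec.pl,
                                xr=rec.xr + 5.0, yr=rec.yr - 3.0, pr=rec.pr)
        events2, _ = detect_saccades(shifted)
        assert np.allclose(events["onset_s"], events2["onset_s"])
        assert np.allclose(events["amplitude_arcmin"],
                           events2["amplitude_arcmin"])

    def test_outputs_respect_filter_bounds(self, small_session):
        _, rec, _, _ = small_session
        events, _ = detect_saccades(rec)
        assert (events["duration_ms"] >= 6.0).all()
        assert events["amplitude_arcmin"].between(3.0, 60.0).all()
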