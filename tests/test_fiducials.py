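"""Detection cascade, R detection, RR validation and delineation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fingerbeat as fb
from fingerbeat import fiducials

from conftest import NOISE_FREE


def brute_force_cascade(x):
    """Triple-loop reference evaluation of the three difference equations."""
    n = len(x)

    def at(v, i):
        return v[i] if i >= 0 else 0.0

    y0 = [at(x, i) - at(x, i - 1) for i in range(n)]
    y1 = [y0[i] - at(y0, i - 4) for i in range(n)]
    c = [1.0, 4.0, 6.0, 4.0, 1.0]
    y2 = [sum(c[k] * at(y1, i - k) for k in range(5)) for i in range(n)]
    return np.array(y0), np.array(y1), np.array(y2)


class TestDetectionTransform:
    def test_impulse_response(self):
        x = np.zeros(20)
        x[0] = 1.0
        d = fb.detection_transform(x)
        expected = [1, 3, 2, -2, -4, -4, -2, 2, 3, 1]
        np.testing.assert_array_equal(d.y2[:10], expected)
        np.testing.assert_array_equal(d.y2[10:], 0.0)

    def test_constant_input_dies_after_warmup(self):
        d = fb.detection_transform(np.full(50, 3.7))
        # After the filters' warm-up transient every stage is zero.
        assert np.allclose(d.y0[1:], 0.0)
        assert np.allclose(d.y1[5:], 0.0)
        assert np.allclose(d.y2[9:], 0.0)

    def test_hand_computed_differentiator(self):
        x = np.zeros(12)
        x[1] = 1.0
        d = fb.detection_transform(x)
        np.testing.assert_array_equal(d.y0[:4], [0, 1, -1, 0])

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        x = np.random.default_rng(seed).normal(size=200)
        d = fb.detection_transform(x)
        y0, y1, y2 = brute_force_cascade(x)
        np.testing.assert_allclose(d.y0, y0, atol=1e-12)
        np.testing.assert_allclose(d.y1, y1, atol=1e-12)
        np.testing.assert_allclose(d.y2, y2, atol=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            fb.detection_transform(np.zeros(5))


class TestDetectCandidates:
    def test_clean_ten_beat_recording(self, clean_short_recording):
        record, truth = clean_short_recording
        d = fb.detection_transform(record.signal)
        cand, _ = fb.detect_r_candidates(record.signal, d, fs=record.fs)
        assert len(cand) == 10
        assert np.all(np.abs(cand - truth.r_indices) <= 10)
        assert np.all(np.diff(cand) > 0)

    def test_all_zero_signal_yields_nothing(self):
        x = np.zeros(4000)
        cand, _ = fb.detect_r_candidates(
            x, fb.detection_transform(x), fs=1000.0
        )
        assert len(cand) == 0

    def test_inverted_polarity_not_detected(self):
        # A lone negated R wave: the y2 pattern flips to a positive main
        # lobe flanked by negative ones, which the detector must not match.
        t = np.arange(4000) / 1000.0
        x = -1.2 * np.exp(-0.5 * ((t - 2.0) / 0.012) ** 2)
        cand, _ = fb.detect_r_candidates(
            x, fb.detection_transform(x), fs=1000.0
        )
        assert len(cand) == 0


class TestValidateRR:
    def test_all_within_band_retained(self):
        out = fb.validate_rr([500, 1500, 2500], fs=1000.0)
        assert out.tolist() == [500, 1500, 2500]

    def test_too_close_pair_drops_weaker(self):
        out = fb.validate_rr(
            [500, 800, 1800], fs=1000.0, strengths=[5.0, 1.0, 4.0]
        )
        assert out.tolist() == [500, 1800]
        # Symmetric case: the later peak is the stronger one.
        out = fb.validate_rr(
            [500, 800, 1800], fs=1000.0, strengths=[1.0, 5.0, 4.0]
        )
        assert out.tolist() == [800, 1800]

    def test_spacing_at_exact_minimum_retained(self):
        # 400 ms at 1000 Hz is exactly the 150 BPM bound: not "closer than".
        assert fb.validate_rr([0, 400], fs=1000.0).tolist() == [0, 400]
        assert fb.validate_rr([0, 399], fs=1000.0).tolist() == [0]

    def test_empty_input(self):
        assert len(fb.validate_rr([], fs=1000.0)) == 0

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            fb.validate_rr([100, 50], fs=1000.0)


class TestDelineate:
    def test_clean_beat_fiducials_near_truth(self, clean_short_recording):
        record, truth = clean_short_recording
        x = record.signal
        d = fb.detection_transform(x)
        tol = int(0.015 * record.fs)
        for k, r in enumerate(truth.r_indices[1:-1], start=1):
            f = fb.delineate(x, d, int(r), record.fs)
            assert f is not None and f.valid
            for wave in "PQRST":
                got = getattr(f, wave)
                want = truth.wave_indices[wave][k]
                assert abs(got - want) <= tol, (wave, got, want)

    def test_edge_beat_skipped_without_exception(self, clean_short_recording):
        record, _ = clean_short_recording
        d = fb.detection_transform(record.signal)
        assert fb.delineate(record.signal, d, 100, record.fs) is None

    def test_ordering_invariant_on_valid_beats(self, clean_short_recording):
        record, truth = clean_short_recording
        x = record.signal
        d = fb.detection_transform(x)
        sets = [
            fb.delineate(x, d, int(r), record.fs)
            for r in truth.r_indices[1:-1]
        ]
        for f in fb.filter_valid_beats(sets, x, record.fs):
            assert f.ordering_ok()


def _toy_beat_set(p_index):
    """A hand-built fiducial set on a simple synthetic trace."""
    x = np.zeros(1000)
    x[p_index] = 0.2  # P
    x[500] = -0.1  # Q trough stays negative
    x[510] = 1.0  # R
    x[520] = -0.2  # S
    x[650] = 0.3  # T
    f = fiducials.FiducialSet(
        P=p_index, Q=500, R=510, S=520, T=650,
        i_start_q=495, i_end_q=505, i_start_s=515, i_end_s=525,
        left_most=260, right_most=910,
    )
    return f, x


class TestValidityRules:
    def test_negative_p_amplitude_rejected(self):
        f, x = _toy_beat_set(430)
        x[430] = -0.01
        assert fb.filter_valid_beats([f], x, 1000.0) == []

    def test_p_lead_boundary(self):
        close, x1 = _toy_beat_set(475)  # 25 ms before Q: too late
        assert fb.filter_valid_beats([close], x1, 1000.0) == []
        early, x2 = _toy_beat_set(465)  # 35 ms before Q: fine
        assert fb.filter_valid_beats([early], x2, 1000.0) == [early]

    def test_negative_t_amplitude_rejected(self):
        f, x = _toy_beat_set(430)
        x[650] = -0.3
        assert fb.filter_valid_beats([f], x, 1000.0) == []

    def test_empty_list(self):
        assert fb.filter_valid_beats([], np.zeros(10), 1000.0) == []


class TestDetectorRecovery:
    @pytest.mark.parametrize("bpm,n_beats", [(45.0, 20), (90.0, 60), (140.0, 120)])
    def test_noise_free_rates(self, bpm, n_beats):
        morph = fb.make_subject(int(bpm))
        duration = n_beats * 60.0 / bpm + 1.0
        cfg = fb.AcquisitionConfig(
            duration_s=duration, hr_profile_bpm=(bpm,), rr_jitter_ms=0.0,
            seed=2, **NOISE_FREE,
        )
        record, truth = fb.synthesize_recording(morph, cfg)
        x = record.signal
        d = fb.detection_transform(x)
        cand, st_ = fb.detect_r_candidates(x, d, fs=record.fs)
        peaks = fb.validate_rr(cand, record.fs, strengths=st_)
        assert len(peaks) == len(truth.r_indices)
        assert np.all(np.abs(peaks - truth.r_indices) <= 10)
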