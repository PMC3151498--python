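"""Evaluation protocol: curves, EER, cross-validation, aggregation."""

import numpy as np
import pytest
from scipy import stats

import fingerbeat as fb
from fingerbeat.evaluate import threshold_grid

from conftest import NOISE_FREE


class TestFarFrrCurves:
    def test_perfect_separation(self):
        grid = np.linspace(0, 1, 11)
        far, frr = fb.far_frr_curves([0.0] * 10, [1.0] * 10, grid)
        inner = slice(1, -1)
        assert np.all(far[inner] == 0.0)
        assert np.all(frr[inner] == 0.0)
        eer, _ = fb.compute_eer(far, frr, grid)
        assert eer == 0.0

    def test_identical_distributions_cross_at_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(1.0, 0.3, size=5000)
        grid = threshold_grid(scores)
        far, frr = fb.far_frr_curves(scores, scores.copy(), grid)
        eer, _ = fb.compute_eer(far, frr, grid)
        assert eer == pytest.approx(0.5, abs=0.02)

    def test_monotonicity(self):
        rng = np.random.default_rng(1)
        genuine = rng.gamma(2.0, 1.0, size=1000)
        impostor = rng.gamma(4.0, 1.0, size=1000)
        grid = threshold_grid(np.concatenate([genuine, impostor]))
        far, frr = fb.far_frr_curves(genuine, impostor, grid)
        assert np.all(np.diff(far) >= 0)
        assert np.all(np.diff(frr) <= 0)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            fb.far_frr_curves([], [1.0], [0.0, 1.0])


class TestComputeEer:
    def test_symmetric_crossing(self):
        eer, th = fb.compute_eer([0, 0.5, 1], [1, 0.5, 0], [0, 1, 2])
        assert (eer, th) == (0.5, 1.0)

    def test_gaussian_closed_form(self):
        # Equal-variance genuine/impostor Gaussians cross midway between
        # their means; the EER there is Phi(-delta / (2 sigma)).
        rng = np.random.default_rng(2)
        sigma, mu_g, mu_i = 0.25, 1.0, 2.0
        genuine = rng.normal(mu_g, sigma, size=100_000)
        impostor = rng.normal(mu_i, sigma, size=100_000)
        grid = threshold_grid(np.concatenate([genuine, impostor]))
        far, frr = fb.far_frr_curves(genuine, impostor, grid)
        eer, th = fb.compute_eer(far, frr, grid)
        expected = stats.norm.cdf(-(mu_i - mu_g) / (2 * sigma))
        assert eer == pytest.approx(expected, abs=0.01)
        assert th == pytest.approx(1.5, abs=0.05)

    def test_matches_dense_brute_force_sweep(self):
        rng = np.random.default_rng(3)
        genuine = rng.normal(1.0, 0.4, size=2000)
        impostor = rng.normal(1.8, 0.5, size=2000)
        pooled = np.concatenate([genuine, impostor])
        grid = threshold_grid(pooled, 256)
        far, frr = fb.far_frr_curves(genuine, impostor, grid)
        eer, _ = fb.compute_eer(far, frr, grid)
        dense = threshold_grid(pooled, 2560)
        far_d, frr_d = fb.far_frr_curves(genuine, impostor, dense)
        brute = float(
            np.min(np.maximum(far_d, frr_d))
        )  # brute-force: best max-error over the dense sweep
        assert eer == pytest.approx(brute, abs=0.01)

    def test_no_crossing_raises(self):
        with pytest.raises(ValueError, match="extend"):
            fb.compute_eer([0.5, 0.7], [0.1, 0.0], [0.0, 1.0])


class TestUserTunedEer:
    def test_homogeneous_subjects_match_global(self):
        rng = np.random.default_rng(4)
        genuine = rng.normal(1.0, 0.3, size=3000)
        impostor = rng.normal(2.0, 0.3, size=3000)
        grid = threshold_grid(np.concatenate([genuine, impostor]))
        far, frr = fb.far_frr_curves(genuine, impostor, grid)
        global_eer, _ = fb.compute_eer(far, frr, grid)
        per = {
            f"s{i}": (genuine[i::3], impostor[i::3]) for i in range(3)
        }
        eers, mean_eer = fb.user_tuned_eer(per, grid)
        assert mean_eer == pytest.approx(global_eer, abs=0.02)

    def test_per_subject_thresholds_dominate(self):
        # One subject's scores sit on a shifted scale; tuning the threshold
        # per subject must do at least as well as one global threshold.
        rng = np.random.default_rng(5)
        per = {}
        genuine_all, impostor_all = [], []
        for i, shift in enumerate((0.0, 0.0, 3.0)):
            g = rng.normal(1.0 + shift, 0.3, size=2000)
            m = rng.normal(2.0 + shift, 0.3, size=2000)
            per[f"s{i}"] = (g, m)
            genuine_all.append(g)
            impostor_all.append(m)
        pooled = np.concatenate(genuine_all + impostor_all)
        grid = threshold_grid(pooled, 2048)
        far, frr = fb.far_frr_curves(
            np.concatenate(genuine_all), np.concatenate(impostor_all), grid
        )
        global_eer, _ = fb.compute_eer(far, frr, grid)
        _, mean_eer = fb.user_tuned_eer(per, grid)
        assert mean_eer <= global_eer + 1e-9

    def test_single_subject(self):
        rng = np.random.default_rng(6)
        g = rng.normal(1.0, 0.2, 500)
        m = rng.normal(2.0, 0.2, 500)
        grid = threshold_grid(np.concatenate([g, m]))
        eers, mean_eer = fb.user_tuned_eer({"only": (g, m)}, grid)
        assert mean_eer == eers["only"]


class TestScaleDistanceMatrix:
    def test_min_max_by_hand(self):
        out = fb.scale_distance_matrix([[0.0, 2.0], [4.0, 2.0]])
        np.testing.assert_array_equal(out, [[0.0, 0.5], [1.0, 0.5]])

    def test_already_scaled_unchanged(self):
        m = np.array([[0.0, 1.0], [0.3, 0.6]])
        np.testing.assert_array_equal(fb.scale_distance_matrix(m), m)

    def test_constant_matrix_maps_to_zero(self):
        np.testing.assert_array_equal(
            fb.scale_distance_matrix(np.full((3, 3), 7.0)), np.zeros((3, 3))
        )


class TestCrossValidate:
    def test_identical_subjects_decided_by_tie_rule(self):
        beat = np.random.default_rng(7).normal(size=300)
        mat = np.tile(beat, (80, 1))
        res = fb.cross_validate(
            {"a": mat, "b": mat.copy()},
            fb.RunConfig(n_runs=10, n_enroll_beats=30, n_test_beats=30, seed=0),
        )
        # All distances are zero; the deterministic tie rule always picks
        # subject "a", so accuracy is exactly the 0.5 chance level.
        assert res.accuracy == 0.5

    def test_same_seed_reproduces_bitwise(self, noisefree_beats):
        cfg = fb.RunConfig(n_runs=5, seed=123)
        r1 = fb.cross_validate(noisefree_beats, cfg)
        r2 = fb.cross_validate(noisefree_beats, cfg)
        np.testing.assert_array_equal(r1.distance_matrix, r2.distance_matrix)
        np.testing.assert_array_equal(r1.confusion_matrix, r2.confusion_matrix)
        assert r1.accuracy == r2.accuracy
        assert r1.eer == r2.eer
        assert r1.subject_eers == r2.subject_eers

    def test_insufficient_beats_excluded(self):
        rng = np.random.default_rng(8)
        beats = {
            "full1": rng.normal(size=(80, 300)),
            "full2": rng.normal(size=(80, 300)) + 3,
            "tiny": rng.normal(size=(10, 300)),
        }
        res = fb.cross_validate(beats, fb.RunConfig(n_runs=2, seed=0))
        assert res.subjects == ["full1", "full2"]

    def test_confusion_trace_equals_accuracy(self, noisefree_beats):
        res = fb.cross_validate(noisefree_beats, fb.RunConfig(n_runs=3, seed=9))
        cm = res.confusion_matrix
        assert res.accuracy == np.trace(cm) / cm.sum()
        assert np.all(cm.sum(axis=1) == 3)  # one decision per subject per run

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            fb.cross_validate(
                {"a": np.zeros((80, 300))}, fb.RunConfig(seed=0)
            )
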