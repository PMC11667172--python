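import itertools

import numpy as np
import pytest
from scipy import stats

from annak.dissim import semantic_dissim
from annak.gaze import preprocess_gaze
from annak.simulate import (GazeSimConfig, SimConfig, canonical_gaze_path,
                            default_template_fc, simulate_cohort,
                            simulate_embedding, simulate_gaze,
                            simulate_subject_fc, simulate_timeseries)


def template_z(n=6):
    C = default_template_fc(n)
    Z = np.arctanh(np.clip(C, -0.999999, 0.999999))
    np.fill_diagonal(Z, 0.0)
    return Z


class TestSubjectFC:
    def test_zero_noise_returns_template(self, rng):
        Z = template_z()
        C = simulate_subject_fc(Z, 0.5, 0.0, 0.0, rng)
        expected = np.tanh(Z)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(C, expected, atol=1e-12)

    def test_valid_correlation_output(self, rng):
        C = simulate_subject_fc(template_z(), 1.0, 0.3, 0.5, rng)
        np.testing.assert_allclose(np.diag(C), 1.0)
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-10
        assert np.all(np.abs(C) <= 1.0 + 1e-12)

    def test_rejections(self, rng):
        bad = template_z()
        bad[0, 1] += 0.5  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            simulate_subject_fc(bad, 0.5, 0.1, 0.1, rng)
        with pytest.raises(ValueError, match="negative"):
            simulate_subject_fc(template_z(), 1.0, 0.1, -0.5, rng)

    def test_deterministic_under_seed(self):
        a = simulate_subject_fc(template_z(), 0.3, 0.1, 0.4,
                                np.random.default_rng(7))
        b = simulate_subject_fc(template_z(), 0.3, 0.1, 0.4,
                                np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    @staticmethod
    def _mean_pairwise_distance(draws):
        iu = np.triu_indices(draws[0].shape[0], 1)
        edges = np.array([np.arctanh(np.clip(C[iu], -0.999999, 0.999999))
                          for C in draws])
        dists = [np.linalg.norm(edges[i] - edges[j])
                 for i, j in itertools.combinations(range(len(edges)), 2)]
        return np.mean(dists)

    def test_null_mode_distance_independent_of_trait(self, rng):
        # sigma1 = 0: expected pairwise FC-profile spread equal across traits
        Z = template_z()
        low = [simulate_subject_fc(Z, 0.0, 0.3, 0.0, rng) for _ in range(200)]
        high = [simulate_subject_fc(Z, 1.0, 0.3, 0.0, rng) for _ in range(200)]
        d_low = self._mean_pairwise_distance(low)
        d_high = self._mean_pairwise_distance(high)
        assert d_high == pytest.approx(d_low, rel=0.05)

    def test_annak_mode_distance_ordering(self, rng):
        Z = template_z()
        low = [simulate_subject_fc(Z, 0.0, 0.1, 0.4, rng) for _ in range(100)]
        high = [simulate_subject_fc(Z, 1.0, 0.1, 0.4, rng) for _ in range(100)]
        assert self._mean_pairwise_distance(high) > self._mean_pairwise_distance(low)


class TestTimeseries:
    def test_identity_correlation(self, rng):
        X = simulate_timeseries(np.eye(4), 10_000, rng)
        r = np.corrcoef(X.T)
        assert np.all(np.abs(r[np.triu_indices(4, 1)]) < 0.05)

    def test_strong_correlation_recovered(self, rng):
        C = np.array([[1.0, 0.9], [0.9, 1.0]])
        X = simulate_timeseries(C, 10_000, rng)
        assert np.corrcoef(X.T)[0, 1] == pytest.approx(0.9, abs=0.02)

    def test_seed_reproducible(self):
        C = default_template_fc(6)
        a = simulate_timeseries(C, 151, np.random.default_rng(3))
        b = simulate_timeseries(C, 151, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_non_psd_rejected_with_hint(self, rng):
        C = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="repair"):
            simulate_timeseries(C, 100, rng)


class TestGazeSim:
    def test_zero_noise_equals_canonical(self, rng):
        cfg = GazeSimConfig(n_frames=500, blink_rate=0.0, offscreen_rate=0.0,
                            dropout_rate=0.0)
        canon = canonical_gaze_path(cfg)
        trace = simulate_gaze(canon, 0.5, 0.0, 0.0, cfg, rng)
        np.testing.assert_allclose(trace.x, canon[:, 0], atol=1e-12)
        np.testing.assert_allclose(trace.y, canon[:, 1], atol=1e-12)

    def test_identical_traces_zero_dissim_after_preprocessing(self, rng):
        from annak.gaze import gaze_dissim

        cfg = GazeSimConfig(n_frames=500, blink_rate=0.0, offscreen_rate=0.0,
                            dropout_rate=0.0)
        canon = canonical_gaze_path(cfg)
        a = preprocess_gaze(simulate_gaze(canon, 0.2, 0.0, 0.0, cfg, rng, "a"))
        b = preprocess_gaze(simulate_gaze(canon, 0.9, 0.0, 0.0, cfg, rng, "b"))
        assert gaze_dissim(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_dissim_rises_with_trait(self, rng):
        from annak.gaze import gaze_dissim

        cfg = GazeSimConfig(n_frames=1000, blink_rate=0.0, offscreen_rate=0.0,
                            dropout_rate=0.0)
        canon = canonical_gaze_path(cfg)

        def mean_dissim(tnorm, k=8):
            traces = [preprocess_gaze(simulate_gaze(canon, tnorm, 40.0, 120.0,
                                                    cfg, rng, f"s{i}"))
                      for i in range(k)]
            return np.mean([gaze_dissim(a, b)
                            for a, b in itertools.combinations(traces, 2)])

        assert mean_dissim(1.0) > mean_dissim(0.0)

    def test_artifacts_inserted(self, rng):
        cfg = GazeSimConfig(n_frames=3000, blink_rate=0.01, offscreen_rate=0.01,
                            dropout_rate=0.01)
        trace = simulate_gaze(canonical_gaze_path(cfg), 0.5, 40.0, 120.0, cfg, rng)
        assert np.isnan(trace.x).any()
        assert (trace.x > cfg.frame_width_px).any()


class TestEmbedding:
    def test_infinite_concentration_returns_mu(self, rng):
        mu = np.zeros(16); mu[0] = 1.0
        np.testing.assert_array_equal(
            simulate_embedding(mu, 0.3, np.inf, 0.0, rng), mu
        )

    def test_unit_norm_always(self, rng):
        mu = rng.standard_normal(64); mu /= np.linalg.norm(mu)
        for tnorm in (0.0, 0.5, 1.0):
            v = simulate_embedding(mu, tnorm, 200.0, 150.0, rng)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-10)

    def test_negative_concentration_rejected(self, rng):
        mu = np.zeros(8); mu[0] = 1.0
        with pytest.raises(ValueError, match="concentration"):
            simulate_embedding(mu, 1.0, 100.0, 200.0, rng)

    def test_dispersion_increases_with_trait(self, rng):
        mu = rng.standard_normal(128); mu /= np.linalg.norm(mu)

        def mean_dissim(tnorm, k=30):
            vs = [simulate_embedding(mu, tnorm, 400.0, 300.0, rng) for _ in range(k)]
            return np.mean([semantic_dissim(a, b)
                            for a, b in itertools.combinations(vs, 2)])

        assert mean_dissim(1.0) > mean_dissim(0.0)


class TestCohort:
    def test_study_scale_shapes(self):
        cohort = simulate_cohort(SimConfig(n_subjects=55, seed=0,
                                           modalities=("fmri",),
                                           conditions=("movie",)))
        assert cohort.n_subjects == 55
        assert len(cohort.timeseries["movie"]) == 55
        assert cohort.timeseries["movie"]["S001"].values.shape == (151, 6)

    def test_seed_reproducible(self):
        cfg = SimConfig(n_subjects=8, seed=42)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.trait.equals(b.trait)
        np.testing.assert_array_equal(
            a.timeseries["movie"]["S003"].values,
            b.timeseries["movie"]["S003"].values,
        )
        np.testing.assert_array_equal(a.gaze["S005"].x, b.gaze["S005"].x)
        np.testing.assert_array_equal(a.embedding["S002"], b.embedding["S002"])

    def test_subjects_stable_under_cohort_growth(self):
        small = simulate_cohort(SimConfig(n_subjects=8, seed=9,
                                          modalities=("fmri",), conditions=("movie",)))
        big = simulate_cohort(SimConfig(n_subjects=12, seed=9,
                                        modalities=("fmri",), conditions=("movie",)))
        assert small.trait.equals(big.trait.iloc[:8])
        np.testing.assert_array_equal(
            small.timeseries["movie"]["S004"].values,
            big.timeseries["movie"]["S004"].values,
        )

    def test_covariate_trait_correlation_targeted(self):
        cohort = simulate_cohort(SimConfig(n_subjects=1500, seed=5,
                                           modalities=(), conditions=()))
        r, _ = stats.pearsonr(cohort.covariates["fantasy"], cohort.trait)
        assert r == pytest.approx(0.40, abs=0.08)
        r_age, _ = stats.pearsonr(cohort.covariates["age"], cohort.trait)
        assert abs(r_age) < 0.08

    def test_trait_range_and_rest_condition(self):
        cohort = simulate_cohort(SimConfig(n_subjects=20, seed=3))
        lo, hi = 10, 28
        assert cohort.trait.between(lo, hi).all()
        assert cohort.timeseries["rest"]["S001"].values.shape == (180, 6)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_subjects=3)
        with pytest.raises(ValueError):
            SimConfig(sigma0=-0.1)
        bad = np.eye(6); bad[0, 1] = 0.5  # asymmetric template
        with pytest.raises(ValueError):
            SimConfig(template_fc=bad)
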