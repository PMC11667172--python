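import numpy as np
import pytest

from annak.connectome import StrengthVector
from annak.dissim import (build_dissim_matrix, centrality_dissim, edge_dissim,
                          exclude_outliers, fc_profile_dissim, semantic_dissim,
                          td_dissim)
from conftest import make_dissim_from_values


class TestTimeDynamics:
    def test_identical_and_anticorrelated(self, rng):
        a = rng.standard_normal(151)
        assert td_dissim(a, a) == pytest.approx(0.0, abs=1e-12)
        assert td_dissim(a, -a) == pytest.approx(2.0, abs=1e-12)

    def test_against_covariance_formula(self, rng):
        # independent oracle: 1 - cov(a,b) / (sd_a * sd_b), population ddof
        a, b = rng.standard_normal((2, 200))
        expected = 1.0 - np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
        assert td_dissim(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            td_dissim(np.ones(10), np.arange(10.0))


class TestProfileAndEdges:
    def test_zero_and_orthonormal(self):
        v = np.arange(15.0)
        assert fc_profile_dissim(v, v) == 0.0
        e1, e2 = np.eye(15)[0], np.eye(15)[1]
        assert fc_profile_dissim(e1, e2) == pytest.approx(np.sqrt(2))

    def test_edge_values(self):
        assert edge_dissim(np.array([0.3]), np.array([0.1]))[0] == pytest.approx(0.2)
        np.testing.assert_array_equal(edge_dissim(np.ones(5), np.ones(5)), 0.0)

    def test_pythagorean_decomposition(self, rng):
        # squared global distance = sum of squared per-edge distances
        for _ in range(100):
            v_i, v_j = rng.standard_normal((2, 15))
            global_d = fc_profile_dissim(v_i, v_j)
            per_edge = edge_dissim(v_i, v_j)
            assert global_d**2 == pytest.approx((per_edge**2).sum(), abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fc_profile_dissim(np.ones(3), np.ones(4))


class TestCentralityDissim:
    def test_three_four_five(self):
        a = StrengthVector("a", [3, 4, 0, 0, 0, 0], list("ABCDEF"))
        b = StrengthVector("b", [0, 0, 0, 0, 0, 0], list("ABCDEF"))
        g, per = centrality_dissim(a, b)
        assert g == pytest.approx(5.0)
        np.testing.assert_allclose(per, [3, 4, 0, 0, 0, 0])

    def test_identity_and_decomposition(self, rng):
        s = rng.standard_normal(6)
        g, per = centrality_dissim(s, s)
        assert g == 0.0 and np.all(per == 0.0)
        for _ in range(100):
            x, y = rng.standard_normal((2, 6))
            g, per = centrality_dissim(x, y)
            assert g**2 == pytest.approx((per**2).sum(), abs=1e-10)

    def test_roi_order_mismatch(self):
        a = StrengthVector("a", [1, 2], ["A", "B"])
        b = StrengthVector("b", [1, 2], ["B", "A"])
        with pytest.raises(ValueError, match="ROI order"):
            centrality_dissim(a, b)


class TestSemantic:
    def test_identical_orthogonal_opposite(self):
        v = np.array([1.0, 0.0, 0.0])
        w = np.array([0.0, 1.0, 0.0])
        assert semantic_dissim(v, v) == pytest.approx(0.0)
        assert semantic_dissim(v, w) == pytest.approx(1.0)
        assert semantic_dissim(v, -v) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            semantic_dissim(np.zeros(3), np.ones(3))

    def test_bounded(self, rng):
        for _ in range(50):
            d = semantic_dissim(rng.standard_normal(10), rng.standard_normal(10))
            assert 0.0 <= d <= 2.0


class TestBuildMatrix:
    def test_dyad_counts(self, rng):
        feats = {f"S{k}": rng.standard_normal(5) for k in range(3)}
        dm = build_dissim_matrix(feats, fc_profile_dissim, "fc")
        assert dm.condensed().shape == (3,)

    def test_invariants(self, rng):
        feats = {f"S{k}": rng.standard_normal(5) for k in range(8)}
        dm = build_dissim_matrix(feats, fc_profile_dissim, "fc")
        np.testing.assert_allclose(dm.d, dm.d.T)
        np.testing.assert_allclose(np.diag(dm.d), 0.0)
        assert np.all(dm.condensed() >= 0.0)

    def test_failure_handling(self, rng):
        feats = {"a": np.ones(10), "b": rng.standard_normal(10),
                 "c": rng.standard_normal(10)}
        with pytest.raises(ValueError, match="dyad"):
            build_dissim_matrix(feats, td_dissim, "td")
        dm = build_dissim_matrix(feats, td_dissim, "td", allow_missing=True)
        assert len(dm.failures) == 2  # both dyads involving the flat series
        assert np.isnan(dm.d[0, 1]) and np.isfinite(dm.d[1, 2])


class TestOutlierExclusion:
    def test_all_equal_no_exclusions(self):
        ids = [f"S{k}" for k in range(5)]
        dm = make_dissim_from_values(np.full(10, 0.7), ids)
        with pytest.warns(RuntimeWarning, match="zero spread"):
            retained, excl = exclude_outliers(dm)
        assert retained == ids and excl.empty

    def test_planted_outlier(self, rng):
        # subject 0 gets inflated distances to everyone; its mean z exceeds 3
        n = 20
        ids = [f"S{k}" for k in range(n)]
        d = np.abs(rng.normal(1.0, 0.05, size=(n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        d[0, 1:] = d[1:, 0] = 5.0
        from annak.dissim import DissimMatrix

        dm = DissimMatrix("x", ids, d)
        means = np.array([d[i][np.arange(n) != i].mean() for i in range(n)])
        z0 = (means[0] - means.mean()) / means.std(ddof=1)
        assert z0 > 3  # construction check
        retained, excl = exclude_outliers(dm, 3.0)
        assert list(excl["subject_id"]) == ["S0"]
        assert "S0" not in retained and len(retained) == n - 1

    def test_infinite_threshold_identity(self, rng):
        ids = [f"S{k}" for k in range(6)]
        dm = make_dissim_from_values(rng.uniform(0.5, 1.5, 15), ids)
        retained, excl = exclude_outliers(dm, np.inf)
        assert retained == ids and excl.empty


class TestRetainedIds:
    def test_excluded_subject_detected_despite_zero_diagonal(self, rng):
        from annak.dissim import DissimMatrix, retained_ids

        n = 6
        ids = [f"S{k}" for k in range(n)]
        d = np.abs(rng.normal(1.0, 0.1, (n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        # subject 2 excluded: all off-diagonal entries NaN, diagonal stays 0
        d[2, :] = np.nan; d[:, 2] = np.nan
        np.fill_diagonal(d, 0.0)
        dm = DissimMatrix("x", ids, d)
        kept = retained_ids(dm)
        assert "S2" not in kept and len(kept) == n - 1
        # the retained submatrix is fully finite, so downstream association
        # tests see real numbers
        sub = dm.subset(kept)
        assert np.isfinite(sub.condensed()).all()


class TestTermFrequencyEmbedder:
    def test_normalized_counts_and_cosine(self):
        from annak.embed import TermFrequencyEmbedder

        emb = TermFrequencyEmbedder(["bird", "cloud", "storm", "happy"])
        v = emb.embed("The bird saw the cloud. The bird was happy!")
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert v[0] == pytest.approx(2 / np.sqrt(6))  # two 'bird' tokens
        # identical texts -> zero semantic dissimilarity
        assert semantic_dissim(v, emb.embed("bird bird cloud happy")) == (
            pytest.approx(0.0, abs=1e-12)
        )
        # disjoint vocabulary usage -> orthogonal -> dissimilarity 1
        a = emb.embed("bird bird")
        b = emb.embed("storm cloud")
        assert semantic_dissim(a, b) == pytest.approx(1.0)

    def test_out_of_vocabulary_rejected(self):
        from annak.embed import TermFrequencyEmbedder

        emb = TermFrequencyEmbedder(["bird"])
        with pytest.raises(ValueError, match="vocabulary"):
            emb.embed("nothing relevant here")
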