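import numpy as np
import pytest

from annak.connectome import (NetworkContrastResult, RoiTimeSeries, compute_fc,
                              fisher_z, network_contrast, segment,
                              strength_centrality, temporal_isc,
                              unvectorize_upper, vectorize_upper)


def make_ts(values, subject_id="S001", condition="movie", roi_names=None):
    values = np.asarray(values, dtype=float)
    roi_names = roi_names or [f"R{k}" for k in range(values.shape[1])]
    return RoiTimeSeries(subject_id, condition, values, roi_names)


class TestFisherZ:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.5, 0.5493061443), (-0.5, -0.5493061443)],
    )
    def test_known_values(self, r, expected):
        assert fisher_z(r) == pytest.approx(expected, abs=1e-9)

    def test_odd_and_increasing(self, rng):
        r = np.sort(rng.uniform(-0.95, 0.95, 50))
        z = fisher_z(r)
        assert np.all(np.diff(z) > 0)
        np.testing.assert_allclose(fisher_z(-r), -z, atol=1e-12)

    def test_inverse_of_tanh(self, rng):
        # arctanh(tanh(z)) = z on |z| <= 5 to high precision
        z = rng.uniform(-5, 5, 200)
        np.testing.assert_allclose(fisher_z(np.tanh(z)), z, atol=1e-9)

    def test_clamping_window(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            z = fisher_z(1.0)
        assert np.isfinite(z)
        with pytest.raises(ValueError, match="not a correlation"):
            fisher_z(1.5)


class TestComputeFC:
    def test_six_rois_fifteen_edges(self, rng):
        ts = make_ts(rng.standard_normal((151, 6)))
        fc = compute_fc(ts)
        assert vectorize_upper(fc).shape == (15,)
        np.testing.assert_allclose(fc.z, fc.z.T)
        np.testing.assert_allclose(np.diag(fc.z), 0.0)

    def test_constant_column_rejected(self, rng):
        X = rng.standard_normal((50, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="R1"):
            compute_fc(make_ts(X))

    def test_identical_columns_clamped_and_flagged(self, rng):
        X = rng.standard_normal((50, 3))
        X[:, 1] = X[:, 0]
        with pytest.warns(RuntimeWarning, match="clamped"):
            fc = compute_fc(make_ts(X))
        assert ("R0", "R1") in fc.clamped_edges
        assert np.isfinite(fc.z).all()

    def test_independent_columns_near_zero(self, rng):
        ts = make_ts(rng.standard_normal((10_000, 4)))
        fc = compute_fc(ts)
        off = fc.z[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.05)


class TestVectorize:
    def test_round_trip(self, rng):
        A = rng.standard_normal((6, 6))
        z = (A + A.T) / 2
        np.fill_diagonal(z, 0.0)
        from annak.connectome import FCMatrix

        fc = FCMatrix("s", z, [f"R{k}" for k in range(6)])
        back = unvectorize_upper(vectorize_upper(fc), fc.roi_names, "s")
        np.testing.assert_allclose(back.z, fc.z, atol=1e-15)

    def test_two_regions(self):
        from annak.connectome import FCMatrix

        fc = FCMatrix("s", np.array([[0.0, 0.7], [0.7, 0.0]]), ["A", "B"])
        v = vectorize_upper(fc)
        assert v.shape == (1,) and v[0] == 0.7


class TestStrength:
    def test_arithmetic(self):
        from annak.connectome import FCMatrix

        # region 0 has edges {0.2, 0.3, 0.1, 0.4, 0.5} to the other five
        z = np.zeros((6, 6))
        z[0, 1:] = [0.2, 0.3, 0.1, 0.4, 0.5]
        z = z + z.T
        fc = FCMatrix("s", z, [f"R{k}" for k in range(6)])
        s = strength_centrality(fc)
        assert s.s[0] == pytest.approx(1.5)

    def test_zero_matrix(self):
        from annak.connectome import FCMatrix

        fc = FCMatrix("s", np.zeros((4, 4)), list("ABCD"))
        np.testing.assert_array_equal(strength_centrality(fc).s, 0.0)

    def test_handshake_identity(self, rng):
        # sum of strengths counts every edge twice
        from annak.connectome import FCMatrix

        for _ in range(20):
            A = rng.standard_normal((5, 5))
            z = (A + A.T) / 2
            np.fill_diagonal(z, 0.0)
            fc = FCMatrix("s", z, list("ABCDE"))
            total = strength_centrality(fc).s.sum()
            assert total == pytest.approx(2 * vectorize_upper(fc).sum(), abs=1e-10)


class TestTemporalISC:
    def test_self_and_negated(self, rng):
        ts = make_ts(rng.standard_normal((100, 6)))
        np.testing.assert_allclose(temporal_isc(ts, ts), 1.0, atol=1e-12)
        neg = make_ts(-ts.values)
        np.testing.assert_allclose(temporal_isc(ts, neg), -1.0, atol=1e-12)

    def test_independent_near_zero(self, rng):
        a = make_ts(rng.standard_normal((10_000, 3)))
        b = make_ts(rng.standard_normal((10_000, 3)))
        assert np.all(np.abs(temporal_isc(a, b)) < 0.05)

    def test_shape_mismatch(self, rng):
        a = make_ts(rng.standard_normal((100, 3)))
        b = make_ts(rng.standard_normal((90, 3)))
        with pytest.raises(ValueError):
            temporal_isc(a, b)


class TestSegment:
    def test_movie_windows_partition(self, rng):
        ts = make_ts(rng.standard_normal((151, 6)))
        parts = [segment(ts, w) for w in ((1, 50), (51, 110), (111, 151))]
        assert [p.n_timepoints for p in parts] == [50, 60, 41]
        np.testing.assert_array_equal(
            np.vstack([p.values for p in parts]), ts.values
        )

    def test_identity_window(self, rng):
        ts = make_ts(rng.standard_normal((151, 6)))
        np.testing.assert_array_equal(segment(ts, (1, 151)).values, ts.values)

    @pytest.mark.parametrize("window", [(0, 50), (1, 152), (60, 50)])
    def test_out_of_range(self, window, rng):
        ts = make_ts(rng.standard_normal((151, 6)))
        with pytest.raises(ValueError):
            segment(ts, window)


class TestNetworkContrast:
    def test_equal_within_outside(self):
        vals = np.tile([0.4, 0.4, 0.4, 0.4], (5, 1))
        res = network_contrast(vals, [True, True, False, False])
        assert isinstance(res, NetworkContrastResult)
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError):
            network_contrast(rng.standard_normal((5, 4)), [True] * 4)

    def test_power_under_shift(self, rng):
        # +0.3 within-network shift, 30 subjects: essentially always detected
        labels = np.array([True] * 3 + [False] * 5)
        hits = 0
        for _ in range(20):
            vals = rng.normal(0.0, 0.2, size=(30, 8))
            vals[:, labels] += 0.3
            res = network_contrast(vals, labels)
            hits += (res.t > 0) and (res.p < 0.01)
        assert hits >= 19
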