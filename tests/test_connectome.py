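import numpy as np
import pandas as pd
import pytest

from episeg import connectome as conn
from episeg import stats
from episeg.synth import Volume4D


def _roi_table(n_pairs=3, klass=("cortical", "subcortical", "subcortical")):
    rows = []
    pid = 1
    for i, k in enumerate(klass):
        for hemi in ("L", "R"):
            rows.append(dict(id=pid, name=f"p{i + 1}-{hemi}", hemisphere=hemi,
                             klass=k))
            pid += 1
    return pd.DataFrame(rows)


def _ts(data, table=None, dt=2.0):
    data = np.asarray(data, float)
    if table is None:
        table = _roi_table()[: data.shape[0]]
    return conn.ParcelTimeseries(data, table.iloc[: data.shape[0]], dt)


class TestParcellate:
    def test_constant_parcel_mean(self):
        labels = np.zeros((4, 4, 1), int)
        labels[:2] = 1; labels[2:] = 2
        data = np.zeros((4, 4, 1, 5)); data[labels == 1] = 7.0
        vol = Volume4D(data, (1, 1, 1), 2.0)
        table = pd.DataFrame([dict(id=1, name="a", hemisphere="L",
                                   klass="cortical"),
                              dict(id=2, name="b", hemisphere="R",
                                   klass="cortical")])
        ts = conn.parcellate(vol, labels, table)
        np.testing.assert_allclose(ts.data[0], 7.0)
        np.testing.assert_allclose(ts.data[1], 0.0)

    def test_two_voxel_hand_mean(self):
        labels = np.array([[[1], [1]]])
        data = np.array([[[[1.0, 3.0]], [[3.0, 5.0]]]])
        table = pd.DataFrame([dict(id=1, name="a", hemisphere="L",
                                   klass="cortical")])
        ts = conn.parcellate(Volume4D(data, (1, 1, 1), 2.0), labels, table)
        np.testing.assert_allclose(ts.data[0], [2.0, 4.0])

    def test_row_order_follows_table(self):
        labels = np.zeros((2, 2, 1), int)
        labels[0] = 3; labels[1] = 9
        data = np.zeros((2, 2, 1, 4)); data[0] = 1.0; data[1] = 2.0
        vol = Volume4D(data, (1, 1, 1), 2.0)
        t1 = pd.DataFrame([dict(id=3, name="a", hemisphere="L", klass="cortical"),
                           dict(id=9, name="b", hemisphere="R", klass="cortical")])
        a = conn.parcellate(vol, labels, t1)
        b = conn.parcellate(vol, labels, t1.iloc[::-1])
        np.testing.assert_allclose(a.data, b.data[::-1])


class TestResample:
    def test_protocol_halving(self):
        ts = _ts(np.random.default_rng(0).random((2, 1800)), dt=1.0)
        out = conn.resample_to_rate(ts, 2.0)
        assert out.data.shape[1] == 900
        assert out.dt_s == 2.0

    def test_boxcar_hand_values(self):
        out = conn.resample_to_rate(_ts(np.array([[1.0, 3.0, 5.0, 7.0]]),
                                        dt=1.0), 2.0)
        np.testing.assert_allclose(out.data, [[2.0, 6.0]])

    def test_identity_when_rates_match(self):
        ts = _ts(np.arange(16.0)[None], dt=2.0)
        out = conn.resample_to_rate(ts, 2.0)
        np.testing.assert_array_equal(out.data, ts.data)

    def test_non_integer_ratio_errors(self):
        with pytest.raises(ValueError):
            conn.resample_to_rate(_ts(np.zeros((1, 16)), dt=2.0), 3.0)


class TestAdjacency:
    def test_diagonal_masked_and_clipped_edges_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(64)
        data = np.stack([base, base, rng.standard_normal(64)])
        adj = conn.adjacency(_ts(data))
        assert np.all(np.isnan(np.diag(adj.z)))
        assert adj.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))
        assert adj.clipped[0, 1]
        assert not adj.clipped[0, 2]

    def test_independent_noise_small_z(self):
        rng = np.random.default_rng(1)
        adj = conn.adjacency(_ts(rng.standard_normal((2, 900))))
        assert abs(adj.z[0, 1]) < 0.2

    def test_zero_variance_parcel_masked(self):
        rng = np.random.default_rng(2)
        data = np.vstack([np.full(32, 5.0), rng.standard_normal((2, 32))])
        adj = conn.adjacency(_ts(data))
        assert np.isnan(adj.z[0, 1]) and np.isnan(adj.z[0, 2])
        assert np.isfinite(adj.z[1, 2])

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        adj = conn.adjacency(_ts(rng.standard_normal((4, 64))[: 4]))
        z = adj.z.copy()
        np.testing.assert_allclose(z, z.T, equal_nan=True)


def _adj_from_matrix(z, table):
    z = np.asarray(z, float).copy()
    np.fill_diagonal(z, np.nan)
    return conn.AdjacencyMatrix(z=z, roi_table=table,
                                clipped=np.zeros_like(z, bool))


class TestGroupConsistency:
    def test_identical_positive_matrices_clamp(self):
        table = _roi_table()
        z = np.full((6, 6), 0.5)
        res = conn.group_consistency([_adj_from_matrix(z, table)] * 4)
        off = ~np.eye(6, dtype=bool)
        assert np.all(res.zstat[off] == stats.Z_CLAMP)

    def test_null_matrices_centered(self):
        rng = np.random.default_rng(0)
        table = _roi_table(klass=("cortical",) * 16 + ("subcortical",) * 7)
        R = len(table)
        mats = []
        for _ in range(20):
            m = rng.standard_normal((R, R))
            m = (m + m.T) / 2
            mats.append(_adj_from_matrix(m, table))
        res = conn.group_consistency(mats)
        vals = res.zstat[np.triu_indices(R, 1)]
        assert abs(np.nanmean(vals)) < 0.1

    def test_sqrt_n_monotonicity(self):
        rng = np.random.default_rng(1)
        table = _roi_table()
        m = rng.standard_normal((6, 6)); m = (m + m.T) / 2
        jit = [m + 0.01 * (i - 1) for i in range(3)]
        small = conn.group_consistency([_adj_from_matrix(x, table)
                                        for x in jit])
        big = conn.group_consistency([_adj_from_matrix(x, table)
                                      for x in jit * 2])
        off = np.triu_indices(6, 1)
        assert np.all(np.abs(big.zstat[off]) >= np.abs(small.zstat[off]) - 1e-9)

    def test_size_mismatch_errors(self):
        table = _roi_table()
        a = _adj_from_matrix(np.zeros((6, 6)), table)
        b = conn.AdjacencyMatrix(z=np.zeros((4, 4)), roi_table=table.iloc[:4],
                                 clipped=np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            conn.group_consistency([a, a, b])


class TestCompareArms:
    def _res(self, shift=0.0, seed=0, n=8):
        rng = np.random.default_rng(seed)
        table = _roi_table(klass=("cortical",) * 4 + ("subcortical",) * 4)
        R = len(table)
        mats = []
        for _ in range(n):
            m = rng.standard_normal((R, R)) * 0.1 + 0.3 + shift
            m = (m + m.T) / 2
            mats.append(_adj_from_matrix(m, table))
        return conn.group_consistency(mats)

    def test_identical_arms_p_one(self):
        res = self._res(seed=1)
        out = conn.compare_arms(res, res)
        for s in ("all", "cortical", "subcortical"):
            assert out[s]["p"] == 1.0
            assert out[s]["ratio_a"] == out[s]["ratio_b"]

    def test_shift_alternative_detected(self):
        a = self._res(shift=0.4, seed=2)
        b = self._res(shift=0.0, seed=3)
        out = conn.compare_arms(a, b)
        assert out["all"]["p"] < 0.01
        assert out["all"]["median_diff"] > 0


class TestSampleSize:
    def _res_with(self, mean, sd):
        table = _roi_table(klass=("subcortical",) * 6)
        R = len(table)
        res = conn.ConsistencyResult(
            zstat=np.full((R, R), 3.0), subject_mean=np.full((R, R), mean),
            subject_sd=np.full((R, R), sd), n_subjects=8, roi_table=table)
        return res

    def test_unit_effect_gives_ten(self):
        out = conn.sample_size_analysis(self._res_with(1.0, 1.0), z0=2.3)
        assert out["plain"]["n"] == 10

    def test_offset_mode_unachievable_when_below_threshold(self):
        out = conn.sample_size_analysis(self._res_with(1.0, 1.0), z0=2.3)
        assert out["offset"]["n"] is None

    def test_larger_z0_never_decreases_n(self):
        res = self._res_with(3.0, 0.5)
        n1 = conn.sample_size_analysis(res, z0=2.0)["offset"]["n"]
        n2 = conn.sample_size_analysis(res, z0=2.5)["offset"]["n"]
        assert n2 >= n1

    def test_identical_arms_identical_n(self):
        res = self._res_with(1.5, 1.0)
        a = conn.sample_size_analysis(res)
        b = conn.sample_size_analysis(res)
        assert a["plain"]["n"] == b["plain"]["n"]
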