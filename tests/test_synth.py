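import math

import numpy as np
import pytest

from episeg import synth
from episeg.synth import (NetworkSpec, SequenceParams, acquire_series,
                          acquisition_time_min, dropout_map, ernst_signal,
                          make_fieldmap, make_phantom, ms_protocol,
                          pe_bandwidth_per_pixel, pe_displacement,
                          simulate_network_timecourses, ss_protocol, warp_pe)


class TestPhantom:
    def test_every_parcel_present_and_brain_nonempty(self):
        ph = make_phantom((48, 48, 12), 6, 6, seed=1)
        present = set(np.unique(ph.labels))
        for pid in ph.parcels["id"]:
            assert pid in present
        assert ph.brain_mask.sum() > 0
        assert np.all(ph.baseline[ph.labels == 0] == 0)
        air = np.isin(ph.labels, ph.parcel_ids("air"))
        assert np.all(ph.baseline[air] == 0)

    def test_deterministic_under_seed(self):
        a = make_phantom((24, 24, 8), 3, 3, seed=1)
        b = make_phantom((24, 24, 8), 3, 3, seed=1)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.baseline, b.baseline)

    def test_oversubscribed_parcellation_raises(self):
        with pytest.raises(ValueError):
            make_phantom((16, 16, 4), 200, 6, seed=1)

    def test_hemisphere_pairs(self, small_phantom):
        t = small_phantom.parcels
        for klass in ("cortical", "subcortical"):
            sel = t[t.klass == klass]
            assert (sel.hemisphere == "L").sum() == (sel.hemisphere == "R").sum()


class TestFieldMap:
    def test_zero_peak_is_zero_field(self, small_phantom):
        fm = make_fieldmap(small_phantom, 0.0, 3.0, seed=1)
        assert np.all(fm.delta_f == 0)

    def test_peak_amplitude_at_cavity_centroid(self, small_phantom):
        fm = make_fieldmap(small_phantom, 60.0, 3.0, seed=1)
        cav = small_phantom.parcel_ids("air")[0]
        cen = np.round(small_phantom.parcel_centroid(int(cav))).astype(int)
        region = np.abs(fm.delta_f[cen[0] - 1:cen[0] + 2,
                                   cen[1] - 1:cen[1] + 2,
                                   cen[2] - 1:cen[2] + 2])
        assert region.max() == pytest.approx(60.0, rel=0.1)

    def test_linearity_in_peak(self, small_phantom):
        f1 = make_fieldmap(small_phantom, 60.0, 3.0, seed=1)
        f2 = make_fieldmap(small_phantom, 120.0, 3.0, seed=1)
        np.testing.assert_allclose(f2.delta_f, 2.0 * f1.delta_f, atol=1e-9)

    def test_no_air_cavity_errors(self, small_phantom):
        ph = small_phantom
        bad = synth.Phantom(labels=np.where(np.isin(ph.labels,
                                                    ph.parcel_ids("air")),
                                            0, ph.labels),
                            baseline=ph.baseline, voxel_size=ph.voxel_size,
                            parcels=ph.parcels[ph.parcels.klass != "air"])
        with pytest.raises(ValueError):
            make_fieldmap(bad, 60.0, 3.0, seed=1)


class TestReadoutPhysics:
    def test_pe_bandwidth_hand_values(self):
        ss = ss_protocol(echo_spacing_ms=0.5)       # ETL = 96/2 = 48
        assert pe_bandwidth_per_pixel(ss) == pytest.approx(1 / 0.024, rel=1e-9)
        ms = ms_protocol(echo_spacing_ms=0.5)       # ETL = 96/8 = 12
        assert pe_bandwidth_per_pixel(ms) == pytest.approx(1 / 0.006, rel=1e-9)
        assert pe_bandwidth_per_pixel(ms) == pytest.approx(
            4 * pe_bandwidth_per_pixel(ss))

    def test_one_line_per_shot_limit(self):
        seq = ss_protocol(n_shots=48, ppi=2)        # ETL = 1
        assert seq.etl == 1
        assert pe_bandwidth_per_pixel(seq) == pytest.approx(1 / 0.0005)

    def test_displacement_quarter_scaling(self, small_phantom, small_fieldmap):
        ms = ms_protocol(matrix=(24, 24, 8))
        ss = ss_protocol(matrix=(24, 24, 8))
        sh_ms = pe_displacement(small_fieldmap, ms).shift_vox
        sh_ss = pe_displacement(small_fieldmap, ss).shift_vox
        np.testing.assert_allclose(sh_ms, sh_ss / 4.0)

    def test_unit_shift_at_bandwidth(self):
        seq = ss_protocol()
        bw = pe_bandwidth_per_pixel(seq)
        fm = synth.FieldMap(np.full((4, 4, 4), bw), (1, 1, 1))
        assert pe_displacement(fm, seq).shift_vox.max() == pytest.approx(1.0)

    def test_dropout_uniform_field_and_zero_kappa(self):
        seq = ss_protocol()
        fm = synth.FieldMap(np.full((6, 6, 6), 40.0), (1, 1, 1))
        np.testing.assert_allclose(dropout_map(fm, seq, 2.0), 1.0)
        ramp = synth.FieldMap(np.arange(6)[None, :, None]
                              * np.ones((6, 1, 6)) * 5.0, (1, 1, 1))
        np.testing.assert_allclose(dropout_map(ramp, seq, 0.0), 1.0, atol=1e-12)
        # nonzero kappa, linear ramp: closed form at interior voxels
        att = dropout_map(ramp, ss_protocol(te_ms=17.0), 3.0)
        expected = math.exp(-0.017 * 3.0 * 5.0)
        np.testing.assert_allclose(att[:, 1:-1, :], expected, rtol=1e-9)


class TestErnst:
    def test_zero_flip_gives_zero(self):
        assert ernst_signal(0.0, 500, 1400) == 0.0

    def test_argmax_is_ernst_angle(self):
        e1 = math.exp(-500 / 1400)
        grid = np.arange(1.0, 90.0, 0.25)
        vals = [ernst_signal(a, 500, 1400) for a in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(
            math.degrees(math.acos(e1)), abs=0.5)

    def test_long_tr_limit(self):
        assert ernst_signal(37.0, 1e6, 1400) == pytest.approx(
            math.sin(math.radians(37.0)), rel=1e-6)


class TestTimecourses:
    SPEC = NetworkSpec(networks=[("a", (1,), 0.02), ("b", (2,), 0.02),
                                 ("c", (3,), 0.02)],
                       band_hz=(0.01, 0.1), cross_network_correlation=0.0)

    def test_uncorrelated_networks(self):
        tcs = simulate_network_timecourses(self.SPEC, 900, 2.0, seed=0)
        r = np.corrcoef(tcs)
        off = r[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.1)

    def test_exact_cross_correlation(self):
        spec = NetworkSpec(self.SPEC.networks, (0.01, 0.1), 0.25)
        tcs = simulate_network_timecourses(spec, 400, 2.0, seed=3)
        r = np.corrcoef(tcs)
        np.testing.assert_allclose(r[np.triu_indices(3, 1)], 0.25, atol=1e-8)

    def test_band_limited(self):
        tcs = simulate_network_timecourses(self.SPEC, 900, 2.0, seed=1)
        f = np.fft.rfftfreq(900, 2.0)
        p = np.abs(np.fft.rfft(tcs, axis=-1)) ** 2
        frac_above = p[:, f > 0.12].sum() / p.sum()
        assert frac_above < 0.05

    def test_deterministic(self):
        a = simulate_network_timecourses(self.SPEC, 128, 2.0, seed=5)
        b = simulate_network_timecourses(self.SPEC, 128, 2.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_band_outside_nyquist_errors(self):
        spec = NetworkSpec(self.SPEC.networks, (0.01, 0.4), 0.0)
        with pytest.raises(ValueError):
            simulate_network_timecourses(spec, 128, 2.0, seed=0)


def _netspec_for(phantom, amp=0.02):
    sub = phantom.parcels[phantom.parcels.klass == "subcortical"]
    members = tuple(int(i) for i in sub.id[:2])
    return NetworkSpec(networks=[("net", members, amp)], band_hz=(0.01, 0.1))


class TestAcquire:
    def test_noiseless_static_volumes_identical(self, small_phantom):
        seq = ms_protocol(matrix=(24, 24, 8), n_rep=16)
        spec = _netspec_for(small_phantom, amp=0.0)
        fm = make_fieldmap(small_phantom, 30.0, 3.0, seed=1)
        vol = acquire_series(small_phantom, fm, seq, spec, seed=0)
        for t in range(1, vol.n_t):
            np.testing.assert_array_equal(vol.data[..., t], vol.data[..., 0])

    def test_multishot_protocol_volume_count_and_tr(self, small_phantom):
        seq = ms_protocol(matrix=(24, 24, 8), n_rep=900)
        spec = _netspec_for(small_phantom, amp=0.0)
        fm = make_fieldmap(small_phantom, 0.0, 3.0, seed=1)
        vol = acquire_series(small_phantom, fm, seq, spec, seed=0)
        assert vol.n_t == 900
        assert vol.tr_vol_s == 2.0

    def test_planted_network_recovered(self, small_phantom):
        seq = ms_protocol(matrix=(24, 24, 8), n_rep=64)
        spec = _netspec_for(small_phantom, amp=0.02)
        fm = make_fieldmap(small_phantom, 0.0, 3.0, seed=1)
        vol = acquire_series(small_phantom, fm, seq, spec, seed=4)
        tcs = simulate_network_timecourses(spec, 64, 2.0,
                                           vol.meta["tc_seed"])
        pid = spec.networks[0][1][0]
        series = vol.data[small_phantom.labels == pid].mean(axis=0)
        r = np.corrcoef(series, tcs[0])[0, 1]
        assert r > 0.99

    def test_spike_time_out_of_range(self, small_phantom, small_fieldmap):
        seq = ms_protocol(matrix=(24, 24, 8), n_rep=16)
        with pytest.raises(IndexError):
            acquire_series(small_phantom, small_fieldmap, seq,
                           _netspec_for(small_phantom),
                           motion_spike_times=(99,), seed=0)

    def test_zero_shift_warp_is_exact_passthrough(self):
        rng = np.random.default_rng(0)
        data = rng.random((8, 8, 4))
        out = warp_pe(data, np.zeros_like(data), pe_axis=1)
        np.testing.assert_array_equal(out, data)


class TestAcquisitionTime:
    def test_printed_protocol_durations(self):
        assert acquisition_time_min(ms_protocol()) == pytest.approx(30.0)
        assert acquisition_time_min(ss_protocol()) == pytest.approx(30.0)

    def test_zero_repetitions(self):
        assert acquisition_time_min(ms_protocol(n_rep=0)) == 0.0


class TestSequenceParams:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            SequenceParams(tr_shot_ms=500, n_shots=5, te_ms=17, flip_deg=60,
                           matrix=(96, 96, 16), fov_mm=(35, 35, 16),
                           bw_hz=250e3, ppi=2, n_rep=10)

    def test_confounds_shape_and_spikes(self):
        conf = synth.make_confounds(32, spike_times=(5,), seed=0, dt_s=2.0)
        assert conf.shape == (32, 12)
        assert conf["trans_y"].abs().idxmax() == 5
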