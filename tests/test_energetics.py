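"""Global energetics: MKE/TKE series, diastole window, E/A peaks, integrals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ventriflow as vf
from ventriflow.datamodel import LVMaskSeries
from ventriflow.energetics import (
    _local_maxima,
    detect_ea_peaks,
    integrate_diastole,
    window_times,
)
from ventriflow.errors import DataError, DegenerateInputError, SizeError


def _uniform_dataset(speed, n=6, shape=(6, 6, 6), spacing=2.0):
    vel = np.zeros((n,) + shape + (3,))
    vel[..., 0] = speed
    times = np.arange(n) / n
    ds = vf.FlowDataset(vel, (spacing,) * 3, times, 1.4, 1.0)
    masks = np.zeros((n,) + shape, dtype=bool)
    masks[:, 1:-1, 1:-1, 1:-1] = True
    series = LVMaskSeries(masks, (spacing,) * 3, times, 1.0, ed_frame=0, es_frame=3)
    return ds, series


class TestMkeSeries:
    def test_uniform_one_meter_per_second_is_530(self):
        ds, masks = _uniform_dataset(1.0)
        total, mkev = vf.compute_mke_series(ds, masks, rho=1060.0)
        assert np.allclose(mkev, 530.0, rtol=1e-9)

    def test_zero_velocity_is_zero(self):
        ds, masks = _uniform_dataset(0.0)
        total, mkev = vf.compute_mke_series(ds, masks, rho=1060.0)
        assert np.all(total == 0.0) and np.all(mkev == 0.0)

    def test_affine_phantom_matches_truth_tabulation(self, small_deform):
        spec, ds, masks, truth = small_deform
        _, mkev = vf.compute_mke_series(ds, masks, rho=spec.rho)
        assert np.allclose(mkev, truth.mke_v, rtol=1e-9)

    def test_plug_phantom_matches_truth(self, small_plug):
        spec, ds, masks, truth = small_plug
        _, mkev = vf.compute_mke_series(ds, masks, rho=spec.rho)
        assert np.allclose(mkev, truth.mke_v, rtol=1e-9)


class TestTkeSeries:
    def test_uniform_density_normalizes_to_itself(self, small_plug):
        _, ds, masks, _ = small_plug
        density = np.full((ds.n_frames,) + ds.grid_shape, 7.25)
        maps = vf.TurbulenceMaps(
            sigma=None, tke_density=density, kv=1.0, rho=1060.0, filtered=False
        )
        total, tkev = vf.compute_tke_series(maps, masks)
        assert np.allclose(tkev, 7.25, rtol=1e-12)

    def test_plateau_half_volume(self, small_plug):
        # sigma plateau covers half the chamber: TKE_V = plateau density / 2
        spec, ds, masks, truth = small_plug
        maps = vf.compute_turbulence_maps(ds, rho=spec.rho, median_filter=False)
        _, tkev = vf.compute_tke_series(maps, masks)
        plateau = 0.5 * spec.rho * 3 * spec.sigma_amplitude**2
        assert np.allclose(tkev, 0.5 * plateau, rtol=1e-12)
        assert np.allclose(tkev, truth.tke_v, rtol=1e-12)


class TestDiastoleWindow:
    @staticmethod
    def _series(n, ed, es):
        masks = np.ones((n, 3, 3, 3), dtype=bool)
        return LVMaskSeries(masks, (1, 1, 1), np.arange(n) / n, 1.0,
                            ed_frame=ed, es_frame=es)

    def test_wrapping_window(self):
        win = vf.detect_diastole(self._series(40, ed=0, es=15))
        assert list(win) == list(range(15, 40)) + [0]

    def test_non_wrapping_window(self):
        win = vf.detect_diastole(self._series(40, ed=39, es=14))
        assert list(win) == list(range(14, 40))

    def test_flat_curve_rejected(self):
        masks = np.ones((8, 3, 3, 3), dtype=bool)
        series = LVMaskSeries(masks, (1, 1, 1), np.arange(8) / 8, 1.0)
        with pytest.raises(DegenerateInputError):
            vf.detect_diastole(series)


class TestEaPeaks:
    def test_two_clear_maxima(self):
        curve = np.zeros(25)
        curve[5], curve[4], curve[6] = 90, 50, 50
        curve[16], curve[15], curve[17] = 40, 20, 20
        e, a = detect_ea_peaks(curve, np.arange(25))
        assert (e, a) == (5, 16)

    def test_equal_maxima_earlier_is_e(self):
        curve = np.zeros(20)
        curve[4] = curve[12] = 10.0
        assert detect_ea_peaks(curve, np.arange(20)) == (4, 12)

    def test_monotone_decreasing_uses_fallback(self):
        curve = np.linspace(50, 0, 20)
        e, a = detect_ea_peaks(curve, np.arange(20), fallback_fraction=0.30)
        assert e == 0
        assert a == 20 - int(np.ceil(0.3 * 20))  # first frame of the final 30%

    def test_window_offset_returns_absolute_frames(self):
        curve = np.zeros(40)
        curve[20] = 5.0
        curve[30] = 3.0
        window = np.arange(15, 40)
        assert detect_ea_peaks(curve, window) == (20, 30)

    def test_short_window_rejected(self):
        with pytest.raises(SizeError):
            detect_ea_peaks(np.zeros(40), np.arange(3))

    def test_plateau_takes_first_frame(self):
        assert _local_maxima(np.array([0.0, 2.0, 2.0, 1.0])) == [1]


class TestIntegration:
    def test_constant_over_duration(self):
        series = np.full(11, 3.0)
        window = np.arange(11)
        times = np.arange(11) * 0.05
        out = integrate_diastole(series, window, times, 1.0)
        assert out == pytest.approx(3.0 * 0.5, rel=1e-12)

    def test_linear_ramp_exact(self):
        series = np.linspace(0, 8.0, 11)
        out = integrate_diastole(series, np.arange(11), np.arange(11) * 0.1, 2.0)
        assert out == pytest.approx(8.0 * 1.0 / 2.0, rel=1e-12)

    def test_matches_brute_force_trapezoid_with_wrap(self):
        rng = np.random.default_rng(9)
        series = rng.uniform(0, 5, 20)
        times = np.arange(20) * 0.05
        window = np.array(list(range(14, 20)) + [0])  # wraps
        t = window_times(window, times, 1.0)
        y = series[window]
        brute = sum(
            0.5 * (y[i] + y[i + 1]) * (t[i + 1] - t[i]) for i in range(len(y) - 1)
        )
        assert integrate_diastole(series, window, times, 1.0) == pytest.approx(
            brute, rel=1e-12
        )

    def test_additive_over_partition(self):
        rng = np.random.default_rng(2)
        series = rng.uniform(0, 5, 30)
        times = np.arange(30) / 30
        window = np.arange(5, 25)
        whole = integrate_diastole(series, window, times, 1.0)
        left = integrate_diastole(series, window[:11], times, 1.0)
        right = integrate_diastole(series, window[10:], times, 1.0)
        assert whole == pytest.approx(left + right, rel=1e-12)


class TestRatio:
    @pytest.mark.parametrize(
        "tke,mke,expected",
        [(5.0, 5.0, 0.5), (0.0, 3.0, 0.0), (3.0, 0.0, 1.0), (15.9, 31.8, 1.0 / 3.0)],
    )
    def test_values(self, tke, mke, expected):
        assert vf.tke_ke_ratio(tke, mke) == pytest.approx(expected, rel=1e-12)

    def test_both_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            vf.tke_ke_ratio(0.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.floats(1e-9, 1e6, allow_nan=False),
        st.floats(0.1, 10.0),
    )
    def test_bounds_and_monotonicity(self, tke, mke, bump):
        r = vf.tke_ke_ratio(tke, mke)
        assert 0.0 <= r <= 1.0
        assert vf.tke_ke_ratio(tke + bump, mke) >= r  # nondecreasing in TKE


def test_e_peak_dominates_a_peak_on_default_phantom(small_plug_bundle):
    e = small_plug_bundle.energetics
    assert e.mke_v[e.e_frame] >= e.mke_v[e.a_frame]
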