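"""Convolution, fit-range, RMSE and grid-search fitting behaviour."""

import numpy as np
import pytest

import wmcfit as wf
from wmcfit.fitting import (
    CurveTrace,
    FitConfig,
    IRF,
    convolve_irf,
    fit_range,
    rmse_in_range,
)
from wmcfit.lut import LUT, LUTGrid, TPSF
from wmcfit.synthetic import impulse_irf, synthesize_irf


def _trace(values, bw=0.3125):
    values = np.asarray(values, dtype=float)
    return CurveTrace(times=np.arange(values.size) * bw, intensities=values)


def _gauss_curve(fwhm, n=960, center=150, bw=0.3125):
    t = np.arange(n) * bw
    s = fwhm / 2.3548200450309493
    return _trace(np.exp(-0.5 * ((t - center * bw) / s) ** 2), bw)


def _measure_fwhm(values, bw):
    y = values / values.max()
    above = np.nonzero(y >= 0.5)[0]
    return (above[-1] - above[0] + 1) * bw


class TestConvolveIRF:
    def test_impulse_identity(self):
        curve = _gauss_curve(5.0)
        out = convolve_irf(curve, impulse_irf())
        assert np.allclose(out.intensities,
                           curve.intensities / curve.intensities.max())

    def test_gaussian_quadrature_fwhm(self):
        f1, f2 = 3.44, 6.0
        irf = synthesize_irf(f1)
        out = convolve_irf(_gauss_curve(f2), irf)
        expect = np.sqrt(f1**2 + f2**2)
        assert _measure_fwhm(out.intensities, 0.3125) == pytest.approx(
            expect, abs=2 * 0.3125)

    def test_linearity_before_normalization(self):
        from scipy.signal import fftconvolve

        a = np.random.default_rng(0).random(100)
        b = np.random.default_rng(1).random(100)
        irf = synthesize_irf(3.44).intensities
        conv = lambda x: fftconvolve(x, irf)[:100]
        assert np.allclose(conv(a + b), conv(a) + conv(b))

    def test_bin_width_mismatch_rejected(self):
        irf = IRF(times=np.array([0.0, 0.5]), intensities=np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="bin width"):
            convolve_irf(_gauss_curve(3.0), irf)


class TestFitRange:
    curve = [0.05, 0.2, 0.6, 1.0, 0.5, 0.08]

    def test_ten_ten_worked_example(self):
        assert fit_range(_trace(self.curve), 0.1, 0.1) == (1, 4)

    def test_forty_forty_worked_example(self):
        assert fit_range(_trace(self.curve), 0.4, 0.4) == (2, 4)

    def test_vanishing_fractions_cover_positive_support(self):
        lo = 1e-9
        assert fit_range(_trace(self.curve), lo, lo) == (0, 5)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            fit_range(_trace(self.curve), 1.0, 0.1)


class TestRMSE:
    def test_identical_curves(self):
        a = _trace([0.1, 0.5, 1.0, 0.4])
        assert rmse_in_range(a, a, (0, 3)) == 0.0

    def test_orthogonal_unit_curves(self):
        assert rmse_in_range(_trace([1.0, 0.0]), _trace([0.0, 1.0]),
                             (0, 1)) == pytest.approx(1.0)

    def test_worked_example(self):
        assert rmse_in_range(_trace([1.0, 0.5]), _trace([1.0, 0.3]),
                             (0, 1)) == pytest.approx(np.sqrt(0.04 / 2))

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            rmse_in_range(_trace([1.0, 0.5]), _trace([1.0, 0.3]), (1, 0))


def _analytic_lut(musp_values, mua_values, n_bins=640, bw=0.3125):
    """Small synthetic LUT built from a smooth diffusion-like family —
    cheap stand-in for MC curves in pure fitting-logic tests."""
    t = (np.arange(n_bins) + 0.5) * bw
    curves = np.empty((len(musp_values), len(mua_values), n_bins))
    for i, musp in enumerate(musp_values):
        for j, mua in enumerate(mua_values):
            y = wf.diffusion_tpsf_semiinf(mua, musp, 1.4, 1.25, t).intensities
            curves[i, j] = y / y.max()
    grid = LUTGrid(musp_values=np.asarray(musp_values),
                   mua_values=np.asarray(mua_values))
    return LUT(grid=grid, tpsf=curves, bin_width=bw, t_max=n_bins * bw)


@pytest.fixture(scope="module")
def toy_lut():
    return _analytic_lut(np.round(np.arange(1.2, 2.21, 0.1), 10),
                         np.round(np.arange(0.02, 0.081, 0.005), 10))


class TestFitOpticalProperties:
    def test_self_consistency_noiseless(self, toy_lut):
        irf = synthesize_irf(3.44)
        truth = (1.7, 0.05)
        curve = convolve_irf(
            TPSF(values=toy_lut.curve(*truth), bin_width=toy_lut.bin_width,
                 t_max=toy_lut.t_max), irf)
        res = wf.fit_optical_properties(curve, irf, toy_lut, FitConfig())
        assert res.best_musp == pytest.approx(1.7)
        assert res.best_mua == pytest.approx(0.05)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)
        assert res.accepted
        assert res.shift_bins == 0

    def test_intensity_scale_invariance(self, toy_lut):
        irf = synthesize_irf(3.44)
        curve = convolve_irf(
            TPSF(values=toy_lut.curve(1.5, 0.04), bin_width=toy_lut.bin_width,
                 t_max=toy_lut.t_max), irf)
        scaled = CurveTrace(times=curve.times,
                            intensities=curve.intensities * 123.4)
        r1 = wf.fit_optical_properties(curve, irf, toy_lut)
        r2 = wf.fit_optical_properties(scaled, irf, toy_lut)
        assert (r1.best_mua, r1.best_musp) == (r2.best_mua, r2.best_musp)
        assert r1.rmse == pytest.approx(r2.rmse, abs=1e-12)

    def test_embedded_shift_recovered(self, toy_lut):
        irf = synthesize_irf(3.44)
        curve = convolve_irf(
            TPSF(values=toy_lut.curve(1.7, 0.05), bin_width=toy_lut.bin_width,
                 t_max=toy_lut.t_max), irf)
        y = np.zeros_like(curve.intensities)
        y[6:] = curve.intensities[:-6]
        shifted = CurveTrace(times=curve.times, intensities=y)
        res = wf.fit_optical_properties(shifted, irf, toy_lut)
        assert abs(res.shift_bins - 6) <= 1
        assert res.best_musp == pytest.approx(1.7)
        assert res.best_mua == pytest.approx(0.05)

    def test_objective_grows_away_from_optimum(self, toy_lut):
        """Coarse unimodality: RMSE is larger >= 3 grid steps away from
        the noiseless optimum along each axis."""
        irf = synthesize_irf(3.44)
        truth_musp, truth_mua = 1.7, 0.05
        target = convolve_irf(
            TPSF(values=toy_lut.curve(truth_musp, truth_mua),
                 bin_width=toy_lut.bin_width, t_max=toy_lut.t_max), irf)
        rng = fit_range(target, 0.1, 0.1)

        def rmse_at(musp, mua):
            cand = convolve_irf(
                TPSF(values=toy_lut.curve(musp, mua),
                     bin_width=toy_lut.bin_width, t_max=toy_lut.t_max), irf)
            return rmse_in_range(target, cand, rng)

        base3 = rmse_at(1.7, 0.065)
        assert rmse_at(1.7, 0.08) > base3
        assert rmse_at(1.7, 0.035) > rmse_at(1.7, 0.05)
        assert rmse_at(2.0, 0.05) < rmse_at(2.2, 0.05)
        assert rmse_at(1.4, 0.05) < rmse_at(1.2, 0.05)

    def test_tie_break_toward_smaller_mua(self):
        # two identical cells -> deterministic choice of the smaller mua
        n = 64
        y = np.zeros(n)
        y[10:20] = np.linspace(0.2, 1.0, 10)
        y[20:30] = np.linspace(1.0, 0.1, 10)
        tpsf = np.tile(y, (1, 2, 1))
        lut = LUT(grid=LUTGrid(musp_values=[1.5], mua_values=[0.01, 0.02]),
                  tpsf=tpsf, bin_width=0.3125, t_max=n * 0.3125)
        curve = CurveTrace(times=np.arange(n) * 0.3125, intensities=y)
        res = wf.fit_optical_properties(curve, impulse_irf(), lut,
                                        FitConfig(shift_search_halfwidth=2))
        assert res.best_mua == 0.01

    def test_curve_file_round_trip(self, tmp_path):
        from wmcfit.fitting import read_curve, write_curve

        curve = _gauss_curve(5.0, n=128)
        curve.meta["source"] = "unit-test"
        p = tmp_path / "curve.tsv"
        write_curve(curve, p)
        back = read_curve(p)
        assert np.allclose(back.times, curve.times)
        assert np.allclose(back.intensities, curve.intensities, atol=1e-8)
        assert back.meta["source"] == "unit-test"
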