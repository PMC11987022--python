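"""Kramers-Kronig separation round trips, wavelet peak detection,
constrained Lorentzian fits, normalization and trend analysis."""

import numpy as np
import pandas as pd
import pytest

from fluorspec.errors import InputError, NormalizationError
from fluorspec.ftir import (
    ExperimentalSpectrum,
    detect_peaks,
    fit_lorentzians,
    kk_separate,
    lorentzian,
    normalize_bands,
    read_spectrum,
    trend_analysis,
)
from fluorspec.spectra import Spectrum
from fluorspec.synth import gen_atr_spectrum

GRID = np.arange(900.0, 1500.0, 0.5)


def _lorentz_spectrum(bands, grid=GRID, noise=0.0, seed=0):
    y = np.zeros_like(grid)
    for area, center, fwhm in bands:
        y += lorentzian(grid, area, center, fwhm)
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0, noise, size=grid.shape)
    return ExperimentalSpectrum(grid, y, "transmission")


class TestKKSeparation:
    def test_forward_model_round_trip(self):
        """Im(eps) recovered from a 90-degree-mixed ATR trace: center
        within 0.5 cm^-1 and area within 2 %."""
        osc = [(1135.0, 1.0, 12.0)]
        exp, truth = gen_atr_spectrum(osc, mixing_phase=90.0, snr=np.inf)
        rec, residue = kk_separate(exp, 90.0)
        k = np.argmax(rec.values)
        assert abs(rec.nu[k] - truth.nu[np.argmax(truth.values)]) < 0.5
        lo, hi = 1135.0 - 60.0, 1135.0 + 60.0
        a_rec = rec.crop(lo, hi).integrate()
        a_true = truth.crop(lo, hi).integrate()
        assert a_rec == pytest.approx(a_true, rel=0.02)

    def test_round_trip_at_snr_20(self):
        """With scan co-addition (as in FTIR practice) the recovered
        band areas agree with the ground truth within 2 %; areas are
        measured with the baseline-aware Lorentzian fit because the
        Hilbert inversion is blind to the spectrum's DC level."""
        osc = [(1135.0, 1.0, 12.0), (1236.0, 0.8, 10.0)]
        acc = None
        for seed in range(8):  # co-added scans at SNR 20 each
            exp, truth = gen_atr_spectrum(
                osc, mixing_phase=90.0, snr=20.0, seed=seed
            )
            acc = exp.absorbance if acc is None else acc + exp.absorbance
        coadded = ExperimentalSpectrum(exp.nu, acc / 8.0, "ATR")
        rec, _ = kk_separate(coadded, 90.0)
        t_rec = fit_lorentzians(rec, [1135.0, 1236.0], baseline=True)
        t_true = fit_lorentzians(truth, [1135.0, 1236.0], baseline=True)
        for i, c in enumerate((1135.0, 1236.0)):
            a_rec = t_rec.bands["area"].iloc[i]
            a_true = t_true.bands["area"].iloc[i]
            assert a_rec == pytest.approx(a_true, rel=0.02)
            from scipy.optimize import curve_fit

            def free_lor(x, a, cen, w, b):
                return lorentzian(x, a, cen, w) + b

            band = np.abs(rec.nu - c) < 30
            p_rec, _ = curve_fit(
                free_lor, rec.nu[band], np.real(rec.values)[band],
                p0=[1.0, c, 10.0, 0.0],
            )
            p_true, _ = curve_fit(
                free_lor, truth.nu[band], truth.values[band],
                p0=[1.0, c, 10.0, 0.0],
            )
            assert abs(p_rec[1] - p_true[1]) <= 0.5

    def test_pure_absorption_passthrough(self):
        osc = [(1200.0, 1.0, 10.0)]
        exp, truth = gen_atr_spectrum(osc, mixing_phase=0.0, snr=np.inf)
        rec, _ = kk_separate(exp, 0.0)
        band = slice(200, 1000)
        denom = np.abs(truth.values[band]).max()
        assert np.abs(rec.values[band] - truth.values[band]).max() / denom < 0.005

    def test_sign_flipped_dispersion_recovered_with_refit_phase(self):
        """Flipping the dispersive admixture is equivalent to phase
        -> -phase; re-fitting the phase recovers the same Im(eps)."""
        osc = [(1150.0, 1.0, 12.0)]
        exp_pos, truth = gen_atr_spectrum(osc, mixing_phase=60.0, snr=np.inf)
        exp_neg, _ = gen_atr_spectrum(osc, mixing_phase=-60.0, snr=np.inf)
        rec_pos, _ = kk_separate(exp_pos, 60.0)
        rec_neg, _ = kk_separate(exp_neg, -60.0)
        band = (truth.nu > 1050) & (truth.nu < 1250)
        assert np.allclose(
            rec_pos.values[band], rec_neg.values[band], atol=0.01 * truth.values.max()
        )

    def test_non_atr_input_passes_through_with_warning(self):
        spec = _lorentz_spectrum([(1.0, 1100.0, 10.0)])
        with pytest.warns(UserWarning, match="skipped"):
            rec, residue = kk_separate(spec, 90.0)
        assert np.allclose(rec.values, spec.absorbance)
        assert np.allclose(residue.values, 0.0)


class TestDetectPeaks:
    def test_four_planted_bands_found_within_1cm(self):
        centers = [1045.0, 1069.0, 1218.0, 1276.0]
        widths = [10.0, 14.0, 20.0, 25.0]
        peak_height = 1.0
        bands = []
        for c, w in zip(centers, widths):
            area = peak_height * np.pi * w / 2.0
            bands.append((area, c, w))
        spec = _lorentz_spectrum(bands, noise=peak_height / 50.0, seed=3)
        found = detect_peaks(spec, (3.0, 6.0))
        assert len(found) == 4
        for c in centers:
            assert np.min(np.abs(found - c)) < 1.0

    def test_unresolved_pair_flagged(self):
        bands = [(1.0, 1100.0, 20.0), (1.0, 1108.0, 20.0)]
        spec = _lorentz_spectrum(bands)
        found, details = detect_peaks(spec, (3.0, 6.0), full_output=True)
        assert 1 <= len(found) <= 2
        in_region = details[(details["center"] > 1080) & (details["center"] < 1128)]
        if len(in_region) == 2:
            assert in_region["unresolved"].all()

    def test_pure_noise_yields_nothing(self):
        rng = np.random.default_rng(0)
        spec = ExperimentalSpectrum(GRID, rng.normal(size=GRID.shape), "transmission")
        assert len(detect_peaks(spec, (3.0, 6.0))) == 0

    def test_translation_equivariance(self):
        bands = [(2.0, 1100.0, 12.0), (1.5, 1250.0, 15.0)]
        spec = _lorentz_spectrum(bands)
        delta = 37.25
        shifted = ExperimentalSpectrum(GRID + delta, spec.absorbance, "transmission")
        f1 = detect_peaks(spec, (3.0, 6.0))
        f2 = detect_peaks(shifted, (3.0, 6.0))
        assert len(f1) == len(f2) == 2
        assert np.allclose(f2 - f1, delta, atol=1e-9)

    def test_coarse_grid_rejected(self):
        nu = np.arange(900.0, 1500.0, 4.0)
        spec = ExperimentalSpectrum(nu, np.zeros_like(nu), "transmission")
        with pytest.raises(InputError, match="too coarse"):
            detect_peaks(spec, (3.0, 6.0))


class TestFitLorentzians:
    def test_single_band_within_1_percent(self):
        spec = _lorentz_spectrum([(1.0, 1135.0, 15.0)])
        table = fit_lorentzians(spec, [1135.0])
        band = table.bands.iloc[0]
        assert band["area"] == pytest.approx(1.0, rel=0.01)
        assert band["fwhm"] == pytest.approx(15.0, rel=0.01)
        assert band["assignment"] == "nu_s(CF2)"

    def test_overlapping_pair_within_3_percent(self):
        spec = _lorentz_spectrum([(1.0, 1200.0, 14.0), (0.7, 1214.0, 14.0)])
        table = fit_lorentzians(spec, [1200.0, 1214.0])
        assert table.bands["area"].iloc[0] == pytest.approx(1.0, rel=0.03)
        assert table.bands["area"].iloc[1] == pytest.approx(0.7, rel=0.03)

    def test_zero_spectrum_flags_degenerate(self):
        spec = ExperimentalSpectrum(GRID, np.zeros_like(GRID), "transmission")
        table = fit_lorentzians(spec, [1100.0])
        band = table.bands.iloc[0]
        assert band["area"] == pytest.approx(0.0, abs=1e-8)
        assert band["degenerate"]

    def test_scale_equivariance(self):
        spec = _lorentz_spectrum([(1.0, 1135.0, 15.0), (2.0, 1236.0, 10.0)])
        scaled = ExperimentalSpectrum(GRID, 7.0 * spec.absorbance, "transmission")
        t1 = fit_lorentzians(spec, [1135.0, 1236.0])
        t2 = fit_lorentzians(scaled, [1135.0, 1236.0])
        assert np.allclose(
            t2.bands["area"], 7.0 * t1.bands["area"], rtol=1e-6
        )
        assert np.allclose(t2.bands["fwhm"], t1.bands["fwhm"], rtol=1e-6)

    def test_center_outside_grid_rejected(self):
        spec = _lorentz_spectrum([(1.0, 1135.0, 15.0)])
        with pytest.raises(InputError):
            fit_lorentzians(spec, [500.0])


class TestNormalization:
    def _table(self):
        spec = _lorentz_spectrum(
            [(2.0, 1135.0, 15.0), (3.0, 1236.0, 12.0)]
        )
        return fit_lorentzians(spec, [1135.0, 1236.0])

    def test_area_ratio(self):
        table = normalize_bands(self._table(), "nu_s(CF2)")
        assert table.band("nu_a_OP(CF3)")["area_norm"] == pytest.approx(1.5, rel=0.01)

    def test_reference_band_is_unity(self):
        table = normalize_bands(self._table(), "nu_s(CF2)")
        assert table.band("nu_s(CF2)")["area_norm"] == pytest.approx(1.0)
        assert table.normalization_reference == "nu_s(CF2)"

    def test_missing_reference_raises(self):
        with pytest.raises(NormalizationError, match="not in table"):
            normalize_bands(self._table(), "nu_s(CF3)")


class TestTrendAnalysis:
    def _series(self, widths_by_label):
        tables = []
        for label, fwhm in widths_by_label:
            spec = _lorentz_spectrum(
                [(2.0, 1135.0, 12.0), (3.0, 1236.0, fwhm)]
            )
            t = fit_lorentzians(spec, [1135.0, 1236.0], label=label)
            tables.append(normalize_bands(t, "nu_s(CF2)"))
        return tables

    def test_linear_fwhm_trend_recovered(self):
        tables = self._series([(n, 10.0 + 0.8 * n) for n in (4, 6, 8, 10)])
        out = trend_analysis(tables)
        fits = out["fits"]
        row = fits[
            (fits["assignment"] == "nu_a_OP(CF3)") & (fits["quantity"] == "fwhm")
        ].iloc[0]
        assert row["slope"] == pytest.approx(0.8, abs=0.02)
        assert row["r_squared"] > 0.999

    def test_constant_series_zero_slope(self):
        tables = self._series([(n, 14.0) for n in (1, 2, 3, 4)])
        out = trend_analysis(tables)
        fits = out["fits"]
        row = fits[
            (fits["assignment"] == "nu_a_OP(CF3)") & (fits["quantity"] == "fwhm")
        ].iloc[0]
        assert abs(row["slope"]) < 0.01

    def test_two_points_omit_fit_with_notice(self):
        tables = self._series([(1, 10.0), (2, 12.0)])
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = trend_analysis(tables)
        assert len(out["fits"]) == 0
        assert len(out["series"]) == 4


class TestReaders:
    def test_csv_round_trip(self, tmp_path):
        spec = _lorentz_spectrum([(1.0, 1135.0, 15.0)])
        p = tmp_path / "s.csv"
        pd.DataFrame({"nu": spec.nu, "abs": spec.absorbance}).to_csv(p, index=False)
        back = read_spectrum(p, acquisition="ATR", compound="H2F4")
        assert back.acquisition == "ATR"
        assert np.allclose(back.absorbance, spec.absorbance)
        assert back.metadata["compound"] == "H2F4"

    def test_jcamp_xydata(self, tmp_path):
        p = tmp_path / "s.jdx"
        p.write_text(
            "##TITLE=synthetic\n##XFACTOR=1.0\n##YFACTOR=0.001\n"
            "##DELTAX=2.0\n##XYDATA=(X++(Y..Y))\n"
            "1000 100 200 300\n1006 400 500 600\n##END=\n"
        )
        spec = read_spectrum(p)
        assert np.allclose(spec.nu, [1000, 1002, 1004, 1006, 1008, 1010])
        assert np.allclose(spec.absorbance, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
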