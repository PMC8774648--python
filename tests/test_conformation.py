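"""Synchronous fluorescence, EEM peak picking, CD deconvolution,
Ellman SH, and ANS/Scatchard surface hydrophobicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specbind import (
    ScatchardFit,
    SHMeasurement,
    ValidationError,
    cd_secondary_structure,
    ellman_sh,
    estimate_B,
    extract_eem_peaks,
    peak_shift,
    psh,
    psh_reduction,
    rsfq,
    scatchard_fit,
    synthetic_cd_basis,
)
from specbind.datatypes import ANSBindingSeries
from specbind.synthetic import (
    gen_ans_series,
    gen_cd,
    gen_eem,
    gen_emission_spectra,
)

WAVE = np.arange(300.0, 380.5, 0.5)


class TestRSFQ:
    def test_scaled_series(self):
        spec = gen_emission_spectra(
            [340.0] * 3, 12.0, [1000.0, 900.0, 800.0], WAVE, delta_lambda=60.0
        )
        assert rsfq(spec) == pytest.approx([0.0, 0.1, 0.2], abs=1e-12)

    def test_unquenched_is_zero(self):
        spec = gen_emission_spectra([340.0] * 2, 12.0, [500.0, 500.0], WAVE)
        assert rsfq(spec) == pytest.approx([0.0, 0.0])

    def test_arithmetic(self):
        spec = gen_emission_spectra([340.0] * 2, 12.0, [500.0, 300.0], WAVE)
        assert rsfq(spec)[1] == pytest.approx(0.4, abs=1e-12)


class TestPeakShift:
    def test_identical_spectra_none(self):
        spec = gen_emission_spectra([340.0] * 2, 12.0, [1.0, 1.0], WAVE)
        call = peak_shift(spec)
        assert call.label == "none" and call.shift_nm == pytest.approx(0.0, abs=1e-9)

    def test_red_shift(self):
        spec = gen_emission_spectra([340.0, 344.0], 12.0, [1.0, 0.8], WAVE)
        call = peak_shift(spec)
        assert call.label == "red"
        assert call.shift_nm == pytest.approx(4.0, abs=0.15)

    def test_blue_shift(self):
        spec = gen_emission_spectra([340.0, 337.0], 12.0, [1.0, 0.9], WAVE)
        assert peak_shift(spec).label == "blue"

    def test_flat_spectrum_errors_with_row(self):
        spec = gen_emission_spectra([340.0, 344.0], 12.0, [1.0, 0.0], WAVE)
        with pytest.raises(ValidationError, match="row 1"):
            peak_shift(spec)


class TestEEMPeaks:
    EX = np.arange(200.0, 401.0, 5.0)
    EM = np.arange(200.0, 501.0, 5.0)

    def test_single_peak_with_ridge(self):
        eem = gen_eem(
            [(280.0, 340.0, 500.0, 15.0, 20.0)], self.EX, self.EM,
            rayleigh_amplitude=800.0,
        )
        peaks = extract_eem_peaks(eem)
        kinds = {p.kind for p in peaks}
        assert "rayleigh" in kinds
        p1 = next(p for p in peaks if p.kind == "peak1")
        assert (p1.excitation, p1.emission) == (280.0, 340.0)

    def test_flat_grid_has_no_peaks(self):
        eem = gen_eem([], self.EX, self.EM)
        assert extract_eem_peaks(eem) == []

    def test_two_peaks_ranked_and_labelled(self):
        eem = gen_eem(
            [(280.0, 340.0, 500.0, 15.0, 20.0), (230.0, 340.0, 300.0, 12.0, 20.0)],
            self.EX, self.EM,
        )
        peaks = extract_eem_peaks(eem)
        p1 = next(p for p in peaks if p.kind == "peak1")
        p2 = next(p for p in peaks if p.kind == "peak2")
        assert p1.intensity > p2.intensity
        assert p2.excitation == 230.0

    def test_ridge_only_grid_warns_and_excludes(self):
        eem = gen_eem([], self.EX, self.EM, rayleigh_amplitude=500.0)
        with pytest.warns(UserWarning, match="exclusion"):
            peaks = extract_eem_peaks(eem)
        assert all(p.kind == "rayleigh" for p in peaks)

    def test_no_peak_inside_exclusion_band(self):
        halfwidth = 10.0
        eem = gen_eem(
            [(280.0, 285.0, 900.0, 10.0, 10.0), (280.0, 340.0, 400.0, 15.0, 20.0)],
            self.EX, self.EM, rayleigh_amplitude=600.0,
        )
        for p in extract_eem_peaks(eem, rayleigh_halfwidth_nm=halfwidth):
            if p.kind != "rayleigh":
                assert abs(p.emission - p.excitation) > halfwidth


FREE_FRACTIONS = (19.21, 39.46, 22.61, 18.72)


class TestCD:
    def test_noiseless_mixture_round_trip(self):
        spec = gen_cd(FREE_FRACTIONS)
        est = cd_secondary_structure(spec)
        assert est.as_tuple() == pytest.approx(FREE_FRACTIONS, abs=1e-6)
        assert sum(est.as_tuple()) == pytest.approx(100.0, abs=1e-9)

    def test_pure_helix(self):
        est = cd_secondary_structure(gen_cd((100.0, 0.0, 0.0, 0.0)))
        assert est.alpha_helix == pytest.approx(100.0, abs=1e-6)

    def test_sheet_has_single_minimum_near_218(self):
        """The synthetic sheet basis reproduces the known single negative
        band near 218 nm inside the fit window."""
        basis = synthetic_cd_basis()
        sheet = basis.components["beta_sheet"]
        w = basis.wavelengths
        assert abs(w[np.argmin(sheet)] - 218.0) <= 2.0

    def test_noisy_recovery_small_sample(self):
        """1% additive noise, 10 seeds: mean absolute fraction error stays
        well under 2 percentage points (full 50-seed sweep runs in the
        acceptance suite)."""
        maes = []
        for seed in range(10):
            est = cd_secondary_structure(gen_cd(FREE_FRACTIONS, noise_sigma=0.01, seed=seed))
            maes.append(
                np.mean(np.abs(np.array(est.as_tuple()) - np.array(FREE_FRACTIONS)))
            )
        assert np.mean(maes) < 2.0


class TestEllman:
    def test_zero_absorbance(self):
        m = SHMeasurement(A412=0.0, protein_mass_conc=0.368)
        assert ellman_sh(m) == 0.0

    def test_worked_example(self):
        # A412/extinction = 1e-5 mol/L TNB; over 0.368 g/L -> 27.17 umol/g
        m = SHMeasurement(A412=0.1436, protein_mass_conc=0.368)
        assert ellman_sh(m) == pytest.approx(27.1739, abs=1e-3)

    def test_molar_intermediate(self):
        m = SHMeasurement(A412=0.1436, protein_mass_conc=1.0)
        assert ellman_sh(m) == pytest.approx(10.0, rel=1e-9)  # umol/L per g/L

    def test_dilution_scales_linearly(self):
        base = SHMeasurement(A412=0.1, protein_mass_conc=0.368)
        diluted = SHMeasurement(A412=0.1, protein_mass_conc=0.368, dilution_factor=2.0)
        assert ellman_sh(diluted) == pytest.approx(2 * ellman_sh(base))


class TestANSScatchard:
    def test_estimate_b_linear(self):
        series = ANSBindingSeries(
            ans_total_concs=[1e-6, 2e-6, 3e-6],
            intensities=[2e7 * 1e-6, 2e7 * 2e-6, 2e7 * 3e-6],
            protein_conc=2e-5,
        )
        assert estimate_B(series) == pytest.approx(2e7, rel=1e-12)

    def test_estimate_b_from_hyperbola_low_conc(self):
        # valid where binding is strong relative to B (Fmax/Kd >> B), so the
        # low-concentration probe is almost entirely bound
        b_true = 1.0
        series = gen_ans_series(4.76, 156.80, b_true, [0.05, 0.1, 0.15] + [1.0 * k for k in range(1, 8)])
        assert estimate_B(series) == pytest.approx(b_true, rel=0.05)

    def test_estimate_b_needs_enough_points(self):
        series = ANSBindingSeries(
            ans_total_concs=[1e-6], intensities=[20.0], protein_conc=2e-5
        )
        with pytest.raises(ValidationError):
            estimate_B(series)

    @pytest.mark.parametrize("kd,fmax", [(4.76, 156.80), (5.92, 154.31)])
    def test_noiseless_round_trip(self, kd, fmax):
        series = gen_ans_series(kd, fmax, 10.0, [0.5 * k for k in range(1, 30)])
        fit = scatchard_fit(series)
        assert fit.Kdapp == pytest.approx(kd, rel=1e-6)
        assert fit.Fmax == pytest.approx(fmax, rel=1e-6)

    def test_constant_intensity_errors(self):
        series = ANSBindingSeries(
            ans_total_concs=[1.0, 2.0, 3.0, 4.0],
            intensities=[50.0] * 4,
            protein_conc=0.1,
            proportionality_B=1e3,
        )
        with pytest.raises(ValidationError):
            scatchard_fit(series)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        kd=st.floats(min_value=0.5, max_value=20.0),
        fmax=st.floats(min_value=10.0, max_value=500.0),
    )
    def test_round_trip_property(self, kd, fmax):
        """scatchard_fit inverts the generator for any positive parameters."""
        series = gen_ans_series(kd, fmax, 20.0, [kd * 0.2 * k for k in range(1, 16)])
        fit = scatchard_fit(series)
        assert fit.Kdapp == pytest.approx(kd, rel=1e-6)
        assert fit.Fmax == pytest.approx(fmax, rel=1e-6)


class TestPSH:
    @pytest.mark.parametrize(
        "fmax,kd,expected",
        [(156.80, 4.76, 329.41), (120.27, 6.00, 200.45), (154.31, 5.92, 260.66)],
    )
    def test_table_rows(self, fmax, kd, expected):
        fit = ScatchardFit(Kdapp=kd, Fmax=fmax, r=1.0)
        assert psh(fit, 0.1) == pytest.approx(expected, abs=5e-3)

    def test_reduction_rows(self):
        assert psh_reduction(329.41, 260.66) == pytest.approx(20.87, abs=5e-3)
        assert psh_reduction(329.41, 200.45) == pytest.approx(39.15, abs=5e-3)
        assert psh_reduction(329.41, 329.41) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_reduction_is_unit_free(self, scale):
        """Jointly rescaling Fmax and Kdapp leaves the reduction unchanged:
        it equals 1 - (Fmax_t * Kd_ref)/(Fmax_ref * Kd_t)."""
        ref = ScatchardFit(Kdapp=4.76, Fmax=156.80, r=1.0)
        treated = ScatchardFit(Kdapp=5.92, Fmax=154.31, r=1.0)
        base = psh_reduction(psh(ref, 0.1), psh(treated, 0.1))
        scaled = psh_reduction(
            psh(ScatchardFit(Kdapp=ref.Kdapp * scale, Fmax=ref.Fmax * scale, r=1.0), 0.1),
            psh(
                ScatchardFit(
                    Kdapp=treated.Kdapp * scale, Fmax=treated.Fmax * scale, r=1.0
                ),
                0.1,
            ),
        )
        assert scaled == pytest.approx(base, rel=1e-9)
        closed = (1 - (treated.Fmax * ref.Kdapp) / (ref.Fmax * treated.Kdapp)) * 100
        assert base == pytest.approx(closed, rel=1e-9)
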