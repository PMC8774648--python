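"""Stern-Volmer analysis, mechanism classification, and the
depletion-corrected double-logarithmic binding fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specbind import (
    GroundTruth,
    QuenchingFit,
    TitrationSeries,
    ValidationError,
    classify_mechanism,
    correct_inner_filter,
    double_log_fit,
    percent_quenching,
    stern_volmer_fit,
)
from specbind.quenching import apply_inner_filter
from specbind.synthetic import STUDY_LIGAND_CONCS, gen_titration


def make_sv_series(ksv, concs=STUDY_LIGAND_CONCS, f0=1000.0, temperature=298.0):
    """Series obeying F0/F = 1 + Ksv [Q] exactly."""
    return TitrationSeries(
        protein_conc=20e-6,
        ligand_concs=list(concs),
        intensities=[f0 / (1.0 + ksv * q) for q in concs],
        temperature=temperature,
    )


class TestInnerFilter:
    @pytest.mark.parametrize(
        "f,aex,aem,expected",
        [
            (100.0, 0.0, 0.0, 100.0),
            (0.0, 0.3, 0.2, 0.0),
            (100.0, 0.1, 0.1, 125.89254117941675),  # 100 * 10**0.1
        ],
    )
    def test_point_values(self, f, aex, aem, expected):
        assert correct_inner_filter(f, aex, aem) == pytest.approx(expected, rel=1e-12)

    def test_correction_never_decreases(self):
        assert correct_inner_filter(50.0, 0.2, 0.05) > 50.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            correct_inner_filter(-1.0, 0.0, 0.0)
        with pytest.raises(ValidationError):
            correct_inner_filter(1.0, -0.1, 0.0)

    def test_series_correction_recovers_attenuated_signal(self):
        gt = GroundTruth(noise_sigma=0.0)
        clean = gen_titration(gt)
        attenuated = gen_titration(
            gt, absorbance_per_molar_ex=5e3, absorbance_per_molar_em=1e3
        )
        corrected = apply_inner_filter(attenuated)
        assert corrected.intensities == pytest.approx(clean.intensities, rel=1e-12)

    def test_series_without_absorbances_passes_through(self):
        s = make_sv_series(5e4)
        assert apply_inner_filter(s) is s


class TestSternVolmer:
    def test_recovers_table_constant(self):
        fit = stern_volmer_fit(make_sv_series(5.75e4))
        assert fit.Ksv == pytest.approx(5.75e4, rel=1e-9)
        assert fit.Kq == pytest.approx(5.75e12, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r == pytest.approx(1.0)

    def test_flat_series_gives_zero(self):
        s = TitrationSeries(
            protein_conc=2e-5,
            ligand_concs=list(STUDY_LIGAND_CONCS),
            intensities=[500.0] * 11,
            temperature=298.0,
        )
        assert stern_volmer_fit(s).Ksv == pytest.approx(0.0, abs=1e-9)

    def test_two_point_hand_slope(self):
        # F0/F of 1.2 at 2 uM and 1.4 at 4 uM -> slope 1e5
        s = TitrationSeries(
            protein_conc=2e-5,
            ligand_concs=[0.0, 2e-6, 4e-6],
            intensities=[100.0, 100.0 / 1.2, 100.0 / 1.4],
            temperature=298.0,
        )
        assert stern_volmer_fit(s).Ksv == pytest.approx(1.0e5, rel=1e-9)

    def test_too_few_points(self):
        s = TitrationSeries(
            protein_conc=2e-5,
            ligand_concs=[0.0, 2e-6],
            intensities=[100.0, 90.0],
            temperature=298.0,
        )
        with pytest.raises(ValidationError):
            stern_volmer_fit(s)

    def test_kq_ksv_ratio_is_inverse_tau0(self):
        for tau0 in (1e-8, 5e-9):
            fit = stern_volmer_fit(make_sv_series(3.1e4), tau0=tau0)
            assert fit.Kq == fit.Ksv / tau0  # exact, by construction

    def test_noise_bias_shrinks_with_sigma(self):
        """Mean |relative error| of Ksv decreases as the noise level does."""
        means = []
        for sigma in (0.02, 0.005):
            errs = []
            for seed in range(40):
                s = gen_titration(
                    GroundTruth(Ka=5.75e4, n=1.0, noise_sigma=sigma, seed=seed),
                    protein_conc=1e-12,  # negligible depletion: pure Stern-Volmer
                )
                errs.append(abs(stern_volmer_fit(s).Ksv / 5.75e4 - 1.0))
            means.append(np.mean(errs))
        assert means[1] < means[0]
        assert means[1] < 0.02


def make_fit(ksv, temperature, tau0=1e-8):
    return QuenchingFit(
        Ksv=ksv, Kq=ksv / tau0, intercept=1.0, r=0.999, temperature=temperature
    )


class TestMechanism:
    def test_table_triple_is_static(self):
        fits = [make_fit(k, t) for t, k in [(298, 5.75e4), (304, 4.76e4), (310, 4.47e4)]]
        call = classify_mechanism(fits)
        assert call.label == "static"
        assert call.evidence["ksv_decreasing_with_T"]
        assert call.evidence["kq_above_limit"]

    def test_increasing_ksv_low_kq_is_dynamic(self):
        fits = [
            QuenchingFit(Ksv=k, Kq=k / 1e1, intercept=1, r=0.99, temperature=t, tau0=1e1)
            for t, k in [(298, 1e10), (304, 2e10), (310, 3e10)]
        ]
        assert classify_mechanism(fits).label == "dynamic"

    def test_non_monotone_is_indeterminate(self):
        fits = [make_fit(k, t) for t, k in [(298, 5e4), (304, 6e4), (310, 5.5e4)]]
        assert classify_mechanism(fits).label == "indeterminate"

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(ValidationError):
            classify_mechanism([make_fit(5e4, 298), make_fit(4e4, 298)])


class TestDoubleLog:
    def test_recovers_table_parameters(self):
        s = gen_titration(GroundTruth(Ka=2.78e5, n=1.03, noise_sigma=0.0))
        fit = double_log_fit(s)
        assert fit.Ka == pytest.approx(2.78e5, rel=1e-6)
        assert fit.n == pytest.approx(1.03, rel=1e-6)
        assert fit.n_points_excluded == 0

    def test_single_site_closed_form_point(self):
        """With Ka=1e5, n=1, [Pt]=2e-5, [Qt]=1e-5 the quench ratio solves
        x^2 + 2x - 1 = 0, so F = F0/(1+x) = 100/sqrt(2)."""
        s = gen_titration(
            GroundTruth(Ka=1e5, n=1.0, noise_sigma=0.0),
            ligand_concs=[0.0, 5e-6, 1e-5, 1.5e-5, 2e-5],
            F0=100.0,
        )
        i = s.ligand_concs.index(1e-5)
        assert s.intensities[i] == pytest.approx(100.0 / math.sqrt(2), rel=1e-10)
        fit = double_log_fit(s)
        assert fit.Ka == pytest.approx(1e5, rel=1e-6)
        assert fit.n == pytest.approx(1.0, rel=1e-6)

    def test_unquenched_series_has_no_usable_points(self):
        s = TitrationSeries(
            protein_conc=2e-5,
            ligand_concs=list(STUDY_LIGAND_CONCS),
            intensities=[100.0] * 11,
            temperature=298.0,
        )
        with pytest.raises(ValidationError, match="usable"):
            double_log_fit(s)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        log_ka=st.floats(min_value=3.0, max_value=7.0),
        n=st.floats(min_value=0.8, max_value=1.5),
    )
    def test_noiseless_round_trip_property(self, log_ka, n):
        """Generator -> fitter is the identity on (Ka, n) at zero noise."""
        ka = 10.0**log_ka
        s = gen_titration(GroundTruth(Ka=ka, n=n, noise_sigma=0.0))
        fit = double_log_fit(s)
        assert fit.Ka == pytest.approx(ka, rel=1e-6)
        assert fit.n == pytest.approx(n, rel=1e-6)

    def test_forward_model_consistency(self):
        """Substituting the fitted (Ka, n) into the forward model reproduces
        the observed intensities within the fit residual."""
        s = gen_titration(GroundTruth(Ka=3e5, n=1.1, noise_sigma=0.005, seed=11))
        fit = double_log_fit(s)
        refit = gen_titration(
            GroundTruth(Ka=fit.Ka, n=fit.n, noise_sigma=0.0), F0=s.f0
        )
        resid = np.abs(np.array(refit.intensities) - np.array(s.intensities))
        assert np.max(resid / s.f0) < 0.03  # few-percent noise level


class TestPercentQuenching:
    def test_examples(self):
        s = TitrationSeries(
            protein_conc=2e-5,
            ligand_concs=[0.0, 1e-5, 2e-5],
            intensities=[100.0, 60.0, 36.8],
            temperature=298.0,
        )
        assert percent_quenching(s) == pytest.approx(63.2)
        s2 = TitrationSeries(
            protein_conc=2e-5,
            ligand_concs=[0.0, 2e-5],
            intensities=[200.0, 82.0],
            temperature=298.0,
        )
        assert percent_quenching(s2) == pytest.approx(59.0)

    def test_no_quench_is_zero(self):
        s = TitrationSeries(
            protein_conc=2e-5,
            ligand_concs=[0.0, 2e-5],
            intensities=[100.0, 100.0],
            temperature=298.0,
        )
        assert percent_quenching(s) == 0.0
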