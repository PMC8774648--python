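"""Synthetic-data generators with known ground truth.

Every assay the package analyses can be emulated here from a parameter
set, so each fitting stage is testable by parameter recovery: generate at
zero noise, fit, and the estimates must round-trip; generate with noise
and the recovery error must shrink with the noise level.

The titration generator inverts the depletion-corrected double-log
binding model exactly.  Writing x = (F0 - F)/F, the model states

    x = Ka^n * ([Qt] - (x/(1+x)) [Pt])^n

whose right side is strictly decreasing in x, so the root is unique and
bracketed by [0, Ka^n [Qt]^n] (the zero-depletion bound); it is found by
scalar root bisection to 1e-12 tolerance.  The ANS generator similarly
solves the self-consistent saturation curve F = Fmax [free]/(Kd + [free])
with [free] = [total] - F/B.

Noise is multiplicative Gaussian on intensities (relative SD,
photomultiplier-like), additive for CD; every noisy generator takes an
explicit seed and is deterministic given (parameters, seed).
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import optimize

from .conformation import CDBasis, synthetic_cd_basis
from .constants import R
from .datatypes import (
    ANSBindingSeries,
    CDSpectrum,
    EEM,
    EmulsionMeasurement,
    FoamMeasurement,
    SecondaryStructure,
    SpectrumSeries,
    TitrationSeries,
    ValidationError,
)

__all__ = [
    "GroundTruth",
    "gen_titration",
    "gen_ka_series",
    "gen_ans_series",
    "gen_emission_spectra",
    "gen_eem",
    "gen_cd",
    "gen_functional_measurements",
    "STUDY_LIGAND_CONCS",
    "STUDY_PROTEIN_CONC",
]

_LN10 = math.log(10.0)

#: The published titration design: 20 uM protein, ligand 0-20 uM in 2 uM steps.
STUDY_PROTEIN_CONC = 20e-6
STUDY_LIGAND_CONCS = tuple(i * 2e-6 for i in range(11))


class GroundTruth(BaseModel):
    """Parameter set driving the generators; the recovery target of tests.

    Defaults are the free-protein / strongest-ligand study conditions:
    Stern-Volmer and binding constants of the baicalein complex at 298 K,
    the native secondary-structure composition, and the free-protein ANS
    parameters (Kdapp in 1e-6 mol/L table units).
    """

    model_config = ConfigDict(validate_assignment=True)

    Ka: float = Field(default=2.78e5, gt=0, description="L/mol")
    n: float = Field(default=1.03, gt=0)
    Ksv: float = Field(default=5.75e4, gt=0, description="L/mol")
    dH: float = Field(default=-5.59, description="kJ/mol")
    dS: float = Field(default=85.44, description="J/(mol K)")
    Kdapp: float = Field(default=4.76, gt=0, description="ANS units (1e-6 mol/L)")
    Fmax: float = Field(default=156.80, gt=0, description="a.u.")
    B: float = Field(default=10.0, gt=0, description="a.u. per ANS unit")
    fractions: tuple[float, float, float, float] = Field(
        default=(19.21, 39.46, 22.61, 18.72),
        description="helix/sheet/turn/coil percentages",
    )
    peak_center: float = Field(default=340.0, description="nm")
    peak_width: float = Field(default=25.0, gt=0, description="nm")
    noise_sigma: float = Field(default=0.01, ge=0, description="relative SD")
    seed: int = Field(default=0, ge=0)

    def model_post_init(self, __context) -> None:
        if abs(sum(self.fractions) - 100.0) > 0.01:
            raise ValidationError("ground-truth fractions must sum to 100")


def _solve_quench_ratio(Ka: float, n: float, qt: float, pt: float) -> float:
    """Root x = (F0-F)/F of x = Ka^n ([Qt] - (x/(1+x)) [Pt])^n."""
    if qt <= 0 or Ka == 0:
        return 0.0

    def h(x: float) -> float:
        free = qt - (x / (1.0 + x)) * pt
        rhs = (Ka * free) ** n if free > 0 else 0.0
        return x - rhs

    upper = (Ka * qt) ** n
    if upper == 0:
        return 0.0
    # h(0) = -upper < 0, h(upper) >= 0 (depletion only lowers the rhs)
    return float(optimize.brentq(h, 0.0, upper, xtol=1e-12, rtol=1e-15, maxiter=200))


def gen_titration(
    gt: GroundTruth,
    protein_conc: float = STUDY_PROTEIN_CONC,
    ligand_concs: Sequence[float] = STUDY_LIGAND_CONCS,
    temperature: float = 298.0,
    F0: float = 1000.0,
    noise_sigma: Optional[float] = None,
    seed: Optional[int] = None,
    absorbance_per_molar_ex: float = 0.0,
    absorbance_per_molar_em: float = 0.0,
) -> TitrationSeries:
    """Forward-simulate a quenching titration from the binding model.

    Per point the quench ratio x is solved exactly (see module docstring)
    and F = F0/(1+x).  With ``absorbance_per_molar_*`` non-zero the series
    carries synthetic ligand absorbances A = coeff * [Qt] and the emitted
    intensities are attenuated by 10^-(A_ex+A_em)/2, so inner-filter
    correction recovers the true signal.  Multiplicative Gaussian noise of
    relative SD ``noise_sigma`` (default: the ground truth's) is applied
    with the given seed.
    """
    if ligand_concs[0] != 0:
        raise ValidationError("ligand concentrations must start at 0")
    sigma = gt.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(gt.seed if seed is None else seed)

    intensities = []
    for qt in ligand_concs:
        x = _solve_quench_ratio(gt.Ka, gt.n, qt, protein_conc)
        intensities.append(F0 / (1.0 + x))
    intensities = np.asarray(intensities)

    abs_ex = abs_em = None
    if absorbance_per_molar_ex or absorbance_per_molar_em:
        q = np.asarray(ligand_concs)
        abs_ex = absorbance_per_molar_ex * q
        abs_em = absorbance_per_molar_em * q
        intensities = intensities * 10.0 ** (-(abs_ex + abs_em) / 2.0)

    if sigma > 0:
        intensities = intensities * (1.0 + sigma * rng.standard_normal(len(intensities)))
        intensities = np.maximum(intensities, 1e-12)

    return TitrationSeries(
        protein_conc=protein_conc,
        ligand_concs=list(map(float, ligand_concs)),
        intensities=list(map(float, intensities)),
        temperature=temperature,
        absorbance_ex=None if abs_ex is None else list(map(float, abs_ex)),
        absorbance_em=None if abs_em is None else list(map(float, abs_em)),
    )


def gen_ka_series(
    dH: float, dS: float, temperatures: Sequence[float]
) -> dict[float, float]:
    """Binding constants implied by (dH, dS) through the Van't Hoff relation,
    Ka(T) = 10^(-dH*1000/(ln10 R T) + dS/(ln10 R)).  dH in kJ/mol, dS in
    J/(mol K)."""
    if len(set(temperatures)) != len(temperatures):
        raise ValidationError("temperatures must be distinct")
    out = {}
    for t in temperatures:
        if t <= 0:
            raise ValidationError("temperatures must be positive")
        out[float(t)] = 10.0 ** (
            -dH * 1000.0 / (_LN10 * R * t) + dS / (_LN10 * R)
        )
    return out


def gen_ans_series(
    Kdapp: float,
    Fmax: float,
    B: float,
    ans_concs: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    protein_conc: float = 0.1,
) -> ANSBindingSeries:
    """Forward-simulate an ANS saturation titration.

    Solves F = Fmax [free]/(Kdapp + [free]) with [free] = [total] - F/B
    (unique root, bisection); concentrations may be in any unit consistent
    with Kdapp and B.
    """
    if Kdapp <= 0 or Fmax <= 0 or B <= 0:
        raise ValidationError("Kdapp, Fmax and B must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for total in ans_concs:
        if total <= 0:
            out.append(0.0)
            continue

        def g(f: float) -> float:
            free = max(total - f / B, 0.0)
            return Fmax * free / (Kdapp + free) - f

        hi = min(Fmax, B * total)
        out.append(float(optimize.brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-15)))
    f = np.asarray(out)
    if noise_sigma > 0:
        f = f * (1.0 + noise_sigma * rng.standard_normal(len(f)))
        f = np.maximum(f, 0.0)
    return ANSBindingSeries(
        ans_total_concs=list(map(float, ans_concs)),
        intensities=list(map(float, f)),
        protein_conc=protein_conc,
        proportionality_B=B,
    )


def gen_emission_spectra(
    peak_centers: Sequence[float],
    widths: Sequence[float] | float,
    amplitudes: Sequence[float],
    wavelengths: Sequence[float],
    delta_lambda: Optional[float] = None,
) -> SpectrumSeries:
    """Gaussian emission bands, one spectrum per titration point
    (deterministic)."""
    if np.isscalar(widths):
        widths = [float(widths)] * len(peak_centers)
    if not (len(peak_centers) == len(widths) == len(amplitudes)):
        raise ValidationError("one center/width/amplitude per titration point")
    w = np.asarray(wavelengths, dtype=float)
    rows = [
        list(map(float, a * np.exp(-((w - c) ** 2) / (2.0 * s**2))))
        for c, s, a in zip(peak_centers, widths, amplitudes)
    ]
    return SpectrumSeries(
        wavelengths=list(map(float, w)),
        intensity_matrix=rows,
        delta_lambda=delta_lambda,
    )


def gen_eem(
    peaks: Sequence[tuple[float, float, float, float, float]],
    excitation_wavelengths: Sequence[float],
    emission_wavelengths: Sequence[float],
    rayleigh_amplitude: float = 0.0,
    rayleigh_width: float = 5.0,
) -> EEM:
    """Sum of 2D Gaussian peaks plus a first-order scattering ridge.

    Each peak is (lambda_ex, lambda_em, amplitude, width_ex, width_em).
    """
    ex = np.asarray(excitation_wavelengths, dtype=float)
    em = np.asarray(emission_wavelengths, dtype=float)
    exg, emg = np.meshgrid(ex, em, indexing="ij")
    grid = np.zeros_like(exg)
    for cx, cm, amp, wx, wm in peaks:
        grid += amp * np.exp(
            -((exg - cx) ** 2) / (2.0 * wx**2) - ((emg - cm) ** 2) / (2.0 * wm**2)
        )
    if rayleigh_amplitude:
        grid += rayleigh_amplitude * np.exp(
            -((emg - exg) ** 2) / (2.0 * rayleigh_width**2)
        )
    return EEM(
        excitation_wavelengths=list(map(float, ex)),
        emission_wavelengths=list(map(float, em)),
        intensities=[list(map(float, row)) for row in grid],
    )


def gen_cd(
    fractions: SecondaryStructure | Sequence[float],
    basis: Optional[CDBasis] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> CDSpectrum:
    """CD spectrum of a secondary-structure mixture on the basis grid.

    Additive Gaussian noise with SD = ``noise_sigma`` times the spectrum's
    maximum absolute ellipticity.
    """
    basis = basis if basis is not None else synthetic_cd_basis()
    if isinstance(fractions, SecondaryStructure):
        frac = fractions.as_tuple()
    else:
        frac = tuple(fractions)
    y = basis.combine(frac)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sigma * np.max(np.abs(y)) * rng.standard_normal(len(y))
    return CDSpectrum(
        wavelengths=list(map(float, basis.wavelengths)),
        ellipticity=list(map(float, y)),
    )


def gen_functional_measurements(
    target_FA: float,
    target_FS: float,
    target_EA: float,
    target_ES: float,
    H0: float = 50.0,
    c: float = 0.001,
    phi: float = 0.1,
    L: float = 1.0,
    D: float = 100.0,
) -> tuple[FoamMeasurement, EmulsionMeasurement]:
    """Raw heights/absorbances that map exactly onto the requested indices
    (inverts the foaming and emulsifying definitions)."""
    if target_FA <= 0:
        raise ValidationError("target FA must be positive to define stability")
    if target_ES <= 10.0:
        raise ValidationError("target ES must exceed 10 min (A10 >= 0)")
    H1 = H0 * (1.0 + target_FA / 100.0)
    H2 = H0 + (H1 - H0) * target_FS / 100.0
    A0 = target_EA * c * phi * L * 1e4 / (2.0 * 2.303 * D)
    A10 = A0 * (1.0 - 10.0 / target_ES)
    return (
        FoamMeasurement(H0=H0, H1=H1, H2=H2),
        EmulsionMeasurement(A0=A0, A10=A10, c=c, phi=phi, L=L, D=D),
    )
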