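"""Conformational probes of the ligand-protein complex.

Covers four orthogonal windows onto protein structure:

* synchronous fluorescence (delta-lambda 15 nm for Tyr, 60 nm for Trp):
  per-point quench ratios (RSFQ = 1 - F/F0) and emission-maximum shifts,
  a red shift marking a more polar fluorophore microenvironment;
* excitation-emission matrices: local-maximum peak picking outside the
  first- and second-order Rayleigh scattering bands, with the Tyr/Trp
  peak (excitation near 280 nm) and the polypeptide-backbone peak
  (excitation near 230 nm) labelled by convention;
* far-UV CD: non-negative least squares of the spectrum on a four-component
  reference basis (helix, sheet, turn, coil) with the coefficients
  renormalised to percentages;
* the Ellman free-sulfhydryl assay and the ANS surface-hydrophobicity
  titration with its Scatchard linearisation and PSH index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize, stats

from .datatypes import (
    ANSBindingSeries,
    CDSpectrum,
    EEM,
    PeakRecord,
    ScatchardFit,
    SecondaryStructure,
    SHMeasurement,
    ShiftCall,
    SpectrumSeries,
    ValidationError,
)

__all__ = [
    "rsfq",
    "peak_shift",
    "extract_eem_peaks",
    "CDBasis",
    "synthetic_cd_basis",
    "CDStructureModel",
    "cd_secondary_structure",
    "ellman_sh",
    "estimate_B",
    "ScatchardModel",
    "scatchard_fit",
    "psh",
    "psh_reduction",
]


# ---------------------------------------------------------------- synchronous


def rsfq(series: SpectrumSeries) -> list[float]:
    """Ratio of synchronous fluorescence quenching per titration point.

    RSFQ = 1 - F/F0 where F is each spectrum's maximum intensity and F0
    that of the first (zero-ligand) spectrum.
    """
    if not series.intensity_matrix:
        raise ValidationError("empty spectrum series")
    f0 = max(series.intensity_matrix[0])
    if f0 <= 0:
        raise ValidationError("zero reference intensity")
    return [1.0 - max(row) / f0 for row in series.intensity_matrix]


def _lambda_max(wavelengths: np.ndarray, intensities: np.ndarray, row: int) -> float:
    """Sub-grid emission maximum by parabolic interpolation around the
    grid argmax.  Errors on a flat spectrum."""
    if np.ptp(intensities) == 0:
        raise ValidationError(f"flat spectrum with no unique maximum (row {row})")
    i = int(np.argmax(intensities))
    if i == 0 or i == len(intensities) - 1:
        return float(wavelengths[i])
    y0, y1, y2 = intensities[i - 1 : i + 2]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(wavelengths[i])
    # vertex of the parabola through the three points (uniform or not: use
    # the local spacing as symmetric to first order)
    h = (wavelengths[i + 1] - wavelengths[i - 1]) / 2.0
    return float(wavelengths[i] + h * 0.5 * (y0 - y2) / denom)


def peak_shift(series: SpectrumSeries, threshold_nm: float = 1.0) -> ShiftCall:
    """Emission-maximum shift between the first and last spectra.

    Positive (red) shifts of at least ``threshold_nm`` are labelled
    ``red``, symmetric for ``blue``; smaller shifts are ``none``.
    """
    if len(series.intensity_matrix) < 2:
        raise ValidationError("peak shift needs >= 2 spectra")
    w = np.asarray(series.wavelengths, dtype=float)
    first = _lambda_max(w, np.asarray(series.intensity_matrix[0], dtype=float), 0)
    last_row = len(series.intensity_matrix) - 1
    last = _lambda_max(
        w, np.asarray(series.intensity_matrix[-1], dtype=float), last_row
    )
    shift = last - first
    if shift >= threshold_nm:
        label = "red"
    elif shift <= -threshold_nm:
        label = "blue"
    else:
        label = "none"
    return ShiftCall(shift_nm=shift, label=label)


# ------------------------------------------------------------------ EEM peaks


def extract_eem_peaks(
    eem: EEM,
    rayleigh_halfwidth_nm: float = 10.0,
    min_prominence: float = 0.05,
) -> list[PeakRecord]:
    """Locate fluorescence peaks in an excitation-emission matrix.

    Local maxima of the grid lying outside the first-order (em = ex) and
    second-order (em = 2 ex) scattering bands (each of half-width
    ``rayleigh_halfwidth_nm``) are ranked by intensity; maxima below
    ``min_prominence`` times the grid maximum are dropped.  Of the two
    strongest survivors, the one with excitation nearer 280 nm is labelled
    ``peak1`` (Tyr/Trp) and the one nearer 230 nm ``peak2`` (polypeptide
    backbone); the rest are ``other``.  The brightest point of the
    first-order scattering ridge is reported as a ``rayleigh`` record.
    """
    grid = np.asarray(eem.intensities, dtype=float)
    ex = np.asarray(eem.excitation_wavelengths, dtype=float)
    em = np.asarray(eem.emission_wavelengths, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty EEM grid")

    exg, emg = np.meshgrid(ex, em, indexing="ij")
    first_order = np.abs(emg - exg) <= rayleigh_halfwidth_nm
    second_order = np.abs(emg - 2.0 * exg) <= rayleigh_halfwidth_nm

    records: list[PeakRecord] = []
    if first_order.any():
        ridge = np.where(first_order, grid, -np.inf)
        i, j = np.unravel_index(int(np.argmax(ridge)), grid.shape)
        if grid[i, j] > 0:
            records.append(
                PeakRecord(
                    excitation=float(ex[i]),
                    emission=float(em[j]),
                    intensity=float(grid[i, j]),
                    kind="rayleigh",
                )
            )

    local_max = (ndimage.maximum_filter(grid, size=3, mode="nearest") == grid) & (
        grid > grid.min()
    )
    candidates = local_max & ~first_order & ~second_order
    candidates &= grid >= min_prominence * grid.max()
    idx = np.argwhere(candidates)
    if idx.size == 0:
        if local_max.any():
            warnings.warn(
                "all EEM maxima fall inside the scattering exclusion bands",
                stacklevel=2,
            )
        return records

    ranked = sorted(
        ((float(grid[i, j]), float(ex[i]), float(em[j])) for i, j in idx),
        reverse=True,
    )
    top = ranked[:2]
    labels: dict[int, str] = {}
    if len(top) == 1:
        labels[0] = "peak1" if abs(top[0][1] - 280.0) <= abs(top[0][1] - 230.0) else "peak2"
    elif len(top) == 2:
        # assign by excitation-region convention
        d0 = abs(top[0][1] - 280.0) - abs(top[0][1] - 230.0)
        d1 = abs(top[1][1] - 280.0) - abs(top[1][1] - 230.0)
        if d0 <= d1:
            labels[0], labels[1] = "peak1", "peak2"
        else:
            labels[0], labels[1] = "peak2", "peak1"
    for rank, (inten, x, m) in enumerate(ranked):
        records.append(
            PeakRecord(
                excitation=x,
                emission=m,
                intensity=inten,
                kind=labels.get(rank, "other"),
            )
        )
    return records


# -------------------------------------------------------------------- CD fit

_COMPONENTS = ("alpha_helix", "beta_sheet", "beta_turn", "random_coil")


@dataclass(frozen=True)
class CDBasis:
    """Four-component CD reference basis on a common wavelength grid.

    ``components`` maps each of alpha_helix / beta_sheet / beta_turn /
    random_coil to the ellipticity curve (mdeg) of the pure structure.
    """

    wavelengths: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(_COMPONENTS) - set(self.components)
        if missing:
            raise ValidationError(f"CD basis missing components: {sorted(missing)}")
        for name, curve in self.components.items():
            if len(curve) != len(self.wavelengths):
                raise ValidationError(f"CD basis component {name} length mismatch")

    def matrix(self) -> np.ndarray:
        """Design matrix with one column per component, in canonical order."""
        return np.column_stack([self.components[c] for c in _COMPONENTS])

    def combine(self, fractions: Sequence[float]) -> np.ndarray:
        """Spectrum of a mixture given percentages in canonical order."""
        return self.matrix() @ (np.asarray(fractions, dtype=float) / 100.0)


def synthetic_cd_basis(wavelengths: Optional[Sequence[float]] = None) -> CDBasis:
    """Synthetic far-UV CD basis with the qualitative band signatures of
    the four secondary-structure classes (analytic Gaussian band shapes;
    not measured reference spectra).

    alpha-helix: double minima at 208 and 222 nm; beta-sheet: single
    minimum near 218 nm; beta-turn: weak positive band near 205 nm with a
    shallow negative near 225 nm; random coil: strong negative band near
    198 nm tailing into the window, slightly positive near 217 nm.
    """
    if wavelengths is None:
        wavelengths = np.arange(200.0, 250.5, 0.5)
    w = np.asarray(wavelengths, dtype=float)

    def g(center, width):
        return np.exp(-((w - center) ** 2) / (2.0 * width**2))

    return CDBasis(
        wavelengths=w,
        components={
            "alpha_helix": -10.0 * g(208, 6) - 10.0 * g(222, 6) + 15.0 * g(193, 7),
            "beta_sheet": -12.0 * g(218, 8) + 10.0 * g(196, 6),
            "beta_turn": 5.0 * g(205, 7) - 3.0 * g(225, 9),
            "random_coil": -15.0 * g(198, 7) + 2.0 * g(217, 10),
        },
    )


class CDStructureModel:
    """Constrained basis fit of a far-UV CD spectrum.

    The spectrum is interpolated onto the basis grid and decomposed by
    non-negative least squares on the four reference curves; the
    coefficients are renormalised to sum to 100 and reported as
    percentages, with the NNLS residual norm attached.
    """

    def __init__(self, spectrum: CDSpectrum, basis: Optional[CDBasis] = None):
        self.spectrum = spectrum
        self.basis = basis if basis is not None else synthetic_cd_basis()
        w = np.asarray(spectrum.wavelengths, dtype=float)
        bw = self.basis.wavelengths
        if bw[0] < w[0] - 1e-9 or bw[-1] > w[-1] + 1e-9:
            raise ValidationError(
                "spectrum does not cover the basis wavelength grid "
                f"(basis {bw[0]}-{bw[-1]} nm, spectrum {w[0]}-{w[-1]} nm)"
            )

    def fit(self) -> SecondaryStructure:
        w = np.asarray(self.spectrum.wavelengths, dtype=float)
        y = np.interp(self.basis.wavelengths, w, self.spectrum.ellipticity)
        coefs, resid = optimize.nnls(self.basis.matrix(), y)
        total = coefs.sum()
        if total <= 0:
            raise ValidationError(
                "degenerate CD spectrum: all basis coefficients are zero"
            )
        pct = 100.0 * coefs / total
        return SecondaryStructure(
            alpha_helix=float(pct[0]),
            beta_sheet=float(pct[1]),
            beta_turn=float(pct[2]),
            random_coil=float(pct[3]),
            residual_norm=float(resid),
        )


def cd_secondary_structure(
    spectrum: CDSpectrum, basis: Optional[CDBasis] = None
) -> SecondaryStructure:
    """NNLS secondary-structure estimate; see :class:`CDStructureModel`."""
    return CDStructureModel(spectrum, basis).fit()


# ------------------------------------------------------------------- Ellman


def ellman_sh(m: SHMeasurement) -> float:
    """Free sulfhydryl content in micromoles SH per gram protein.

    TNB concentration = A412 * dilution / (extinction * path length) in
    mol/L, equated 1:1 to SH and normalised by the protein mass
    concentration in g/L.
    """
    tnb_molar = m.A412 * m.dilution_factor / (m.extinction * m.path_length)
    return tnb_molar * 1e6 / m.protein_mass_conc


# ------------------------------------------------------- ANS / Scatchard / PSH


def estimate_B(series: ANSBindingSeries, k_initial_points: int = 3) -> float:
    """Proportionality coefficient B between fluorescence and bound ANS.

    At low total ANS essentially all probe is bound, so F is linear in
    [ANS]total with slope B.  Estimated as the least-squares slope through
    the origin over the first ``k_initial_points`` non-zero-concentration
    points.
    """
    pairs = [
        (c, f)
        for c, f in zip(series.ans_total_concs, series.intensities)
        if c > 0
    ][:k_initial_points]
    if len(pairs) < k_initial_points:
        raise ValidationError(
            f"B estimation needs {k_initial_points} points with positive "
            f"ANS concentration (got {len(pairs)})"
        )
    c = np.array([p[0] for p in pairs])
    f = np.array([p[1] for p in pairs])
    return float(np.dot(c, f) / np.dot(c, c))


class ScatchardModel:
    """Scatchard linearisation of an ANS saturation titration.

    Bound probe is F/B; free probe is total minus bound.  Regressing
    F/[ANS]free on F gives slope -1/Kdapp and intercept Fmax/Kdapp.  The
    protein surface hydrophobicity index is PSH = Fmax/([P] Kdapp).

    Parameters
    ----------
    series : ANSBindingSeries
    B : float, optional
        Fluorescence-per-bound-ANS coefficient; taken from the series or
        estimated from the initial slope when absent.
    k_initial_points : int
        Points used by the initial-slope B estimator.
    """

    def __init__(
        self,
        series: ANSBindingSeries,
        B: Optional[float] = None,
        k_initial_points: int = 3,
    ):
        self.series = series
        if B is not None:
            self.B = float(B)
        elif series.proportionality_B is not None:
            self.B = float(series.proportionality_B)
        else:
            self.B = estimate_B(series, k_initial_points)

    def fit(self) -> ScatchardFit:
        s = self.series
        xs, ys = [], []
        n_excluded = 0
        for c, f in zip(s.ans_total_concs, s.intensities):
            if c <= 0 or f <= 0:
                continue
            free = c - f / self.B
            if free <= 0:
                n_excluded += 1
                continue
            xs.append(f)
            ys.append(f / free)
        if len(xs) < 3:
            raise ValidationError(
                f"Scatchard fit needs >= 3 points with positive free ANS "
                f"(got {len(xs)}, {n_excluded} excluded)"
            )
        x = np.asarray(xs)
        if np.ptp(x) == 0:
            raise ValidationError("Scatchard fit: fluorescence has zero variance")
        res = stats.linregress(x, np.asarray(ys))
        slope = float(res.slope)
        if slope >= 0:
            raise ValidationError(
                "Scatchard slope must be negative (no saturation in data)"
            )
        kd = -1.0 / slope
        fmax = -float(res.intercept) / slope
        return ScatchardFit(
            Kdapp=kd,
            Fmax=fmax,
            r=float(np.clip(res.rvalue, -1.0, 1.0)),
            B=self.B,
            n_points_used=len(xs),
            n_points_excluded=n_excluded,
        )


def scatchard_fit(
    series: ANSBindingSeries,
    B: Optional[float] = None,
    k_initial_points: int = 3,
) -> ScatchardFit:
    """Fit the Scatchard line to an ANS titration; see :class:`ScatchardModel`."""
    return ScatchardModel(series, B=B, k_initial_points=k_initial_points).fit()


def psh(fit: ScatchardFit, protein_conc: float) -> float:
    """Protein surface hydrophobicity index, Fmax / ([protein] * Kdapp).

    Units follow the caller's convention: with Kdapp in table units
    (1e-6 mol/L) and the protein factor 0.1, the published index scale is
    reproduced.
    """
    if protein_conc <= 0:
        raise ValidationError("protein concentration must be positive")
    if fit.Kdapp <= 0:
        raise ValidationError("Kdapp must be positive")
    return fit.Fmax / (protein_conc * fit.Kdapp)


def psh_reduction(psh_ref: float, psh_treated: float) -> float:
    """Percent reduction of surface hydrophobicity relative to a reference."""
    if psh_ref <= 0:
        raise ValidationError("reference PSH must be positive")
    return (psh_ref - psh_treated) / psh_ref * 100.0
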