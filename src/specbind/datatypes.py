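"""Domain containers for titration, spectral, and assay data, and the
fitted-result types the models return.

Unit convention (enforced here, converted at the IO boundary):
concentrations mol L^-1, temperatures K, wavelengths nm, intensities in
arbitrary units (a.u.), ellipticity in mdeg.  Energies are carried on the
reporting scale: kJ mol^-1 for enthalpy/free energy, J mol^-1 K^-1 for
entropy.

Each result type serialises to JSON with unit-annotated field names
(e.g. ``Ksv_L_per_mol``) via its pydantic alias; see
:func:`specbind.io.write_results_json`.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .constants import TAU0, TNB_EXTINCTION

__all__ = [
    "TitrationSeries",
    "QuenchingFit",
    "BindingFit",
    "ThermoResult",
    "MechanismCall",
    "SpectrumSeries",
    "EEM",
    "CDSpectrum",
    "SecondaryStructure",
    "ANSBindingSeries",
    "ScatchardFit",
    "SHMeasurement",
    "FoamMeasurement",
    "EmulsionMeasurement",
    "PeakRecord",
    "ShiftCall",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when input data violates a domain invariant."""


class _Base(BaseModel):
    model_config = ConfigDict(populate_by_name=True, validate_assignment=True)


class TitrationSeries(_Base):
    """One fluorescence quenching titration at fixed temperature.

    The protein (fluorophore) is held at ``protein_conc`` while the ligand
    (quencher) is stepped through ``ligand_concs``; the first point is the
    ligand-free reference defining F0.  Optional per-point absorbances at
    the excitation and emission wavelengths support inner-filter correction.
    """

    protein_conc: float = Field(gt=0, description="mol/L")
    ligand_concs: list[float] = Field(description="mol/L, strictly increasing from 0")
    intensities: list[float] = Field(description="a.u., strictly positive")
    temperature: float = Field(gt=0, description="K")
    absorbance_ex: Optional[list[float]] = None
    absorbance_em: Optional[list[float]] = None
    excitation_wavelength: float = Field(default=280.0, description="nm")

    @model_validator(mode="after")
    def _check(self) -> "TitrationSeries":
        q = self.ligand_concs
        if not q:
            raise ValidationError("titration series is empty")
        if q[0] != 0.0:
            raise ValidationError(
                f"first ligand concentration must be 0 (got {q[0]!r} at row 0)"
            )
        for i in range(1, len(q)):
            if q[i] <= q[i - 1]:
                raise ValidationError(
                    f"ligand concentrations must be strictly increasing (row {i})"
                )
        if len(self.intensities) != len(q):
            raise ValidationError("intensities and ligand_concs differ in length")
        for i, f in enumerate(self.intensities):
            if f <= 0:
                raise ValidationError(f"non-positive intensity at row {i}")
        for name in ("absorbance_ex", "absorbance_em"):
            a = getattr(self, name)
            if a is not None:
                if len(a) != len(q):
                    raise ValidationError(f"{name} length mismatch")
                if any(x < 0 for x in a):
                    raise ValidationError(f"negative absorbance in {name}")
        return self

    def __len__(self) -> int:
        return len(self.ligand_concs)

    @property
    def f0(self) -> float:
        """Reference intensity at zero ligand."""
        return self.intensities[0]


class QuenchingFit(_Base):
    """Stern-Volmer fit: F0/F = 1 + Ksv [Q], with Kq = Ksv / tau0."""

    Ksv: float = Field(alias="Ksv_L_per_mol")
    Kq: float = Field(alias="Kq_L_per_mol_s")
    intercept: float = Field(alias="intercept")
    r: float = Field(alias="r")
    temperature: float = Field(alias="temperature_K")
    tau0: float = Field(default=TAU0, alias="tau0_s")
    Ksv_stderr: Optional[float] = Field(default=None, alias="Ksv_stderr_L_per_mol")

    @model_validator(mode="after")
    def _check(self) -> "QuenchingFit":
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"correlation coefficient out of range: {self.r}")
        if self.Kq != self.Ksv / self.tau0:
            raise ValidationError("Kq must equal Ksv / tau0 exactly")
        return self

    def summary(self) -> str:
        return (
            f"Stern-Volmer fit @ {self.temperature:g} K\n"
            f"  Ksv       {self.Ksv:.4g} L/mol"
            + (f"  (se {self.Ksv_stderr:.2g})" if self.Ksv_stderr is not None else "")
            + f"\n  Kq        {self.Kq:.4g} L/(mol s)   [tau0 = {self.tau0:g} s]\n"
            f"  intercept {self.intercept:.4f}\n"
            f"  r         {self.r:.4f}"
        )


class BindingFit(_Base):
    """Double-logarithmic (ligand-depletion corrected) binding fit:
    apparent binding constant Ka and binding-site number n."""

    Ka: float = Field(gt=0, alias="Ka_L_per_mol")
    n: float = Field(gt=0, alias="n_sites")
    r: float = Field(alias="r")
    temperature: float = Field(alias="temperature_K")
    n_points_used: int = Field(default=0, alias="n_points_used")
    n_points_excluded: int = Field(default=0, alias="n_points_excluded")
    low_confidence: bool = Field(default=False, alias="low_confidence")
    n_stderr: Optional[float] = Field(default=None, alias="n_stderr")

    @model_validator(mode="after")
    def _check(self) -> "BindingFit":
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"correlation coefficient out of range: {self.r}")
        return self

    def summary(self) -> str:
        flag = "  [low confidence: >30% of points excluded]" if self.low_confidence else ""
        return (
            f"Double-log binding fit @ {self.temperature:g} K\n"
            f"  Ka  {self.Ka:.4g} L/mol\n"
            f"  n   {self.n:.3f}"
            + (f" (se {self.n_stderr:.2g})" if self.n_stderr is not None else "")
            + f"\n  r   {self.r:.4f}\n"
            f"  points used/excluded: {self.n_points_used}/{self.n_points_excluded}{flag}"
        )


class ThermoResult(_Base):
    """Van't Hoff thermodynamics of binding: dH (kJ/mol), dS (J/mol/K),
    per-temperature dG (kJ/mol), and the sign-rule force classification."""

    dH: float = Field(alias="dH_kJ_per_mol")
    dS: float = Field(alias="dS_J_per_mol_K")
    dG_per_T: dict[float, float] = Field(alias="dG_kJ_per_mol_by_T")
    forces: list[str] = Field(alias="forces")
    r: float = Field(alias="r")
    dG_from_ka_per_T: dict[float, float] = Field(
        default_factory=dict, alias="dG_from_Ka_kJ_per_mol_by_T"
    )

    @model_validator(mode="after")
    def _check(self) -> "ThermoResult":
        for t, g in self.dG_per_T.items():
            expect = self.dH - t * self.dS / 1000.0
            if abs(g - expect) > 1e-9 * max(1.0, abs(expect)):
                raise ValidationError(
                    f"dG at {t} K ({g}) inconsistent with dH - T*dS ({expect})"
                )
        return self

    def summary(self) -> str:
        lines = [
            "Van't Hoff thermodynamics",
            f"  dH  {self.dH:.2f} kJ/mol",
            f"  dS  {self.dS:.2f} J/(mol K)",
            f"  r   {self.r:.4f}",
        ]
        for t in sorted(self.dG_per_T):
            alt = self.dG_from_ka_per_T.get(t)
            extra = f"   (-RT ln Ka: {alt:.2f})" if alt is not None else ""
            lines.append(f"  dG({t:g} K)  {self.dG_per_T[t]:.2f} kJ/mol{extra}")
        lines.append(f"  forces: {', '.join(self.forces) if self.forces else '(none)'}")
        return "\n".join(lines)


class MechanismCall(_Base):
    """Quenching-mechanism classification from multi-temperature fits."""

    label: Literal["static", "dynamic", "indeterminate"]
    evidence: dict[str, bool]

    @model_validator(mode="after")
    def _check(self) -> "MechanismCall":
        if self.label == "static" and not self.evidence.get("kq_above_limit", False):
            raise ValidationError("static call requires Kq above the diffusion limit")
        return self


class SpectrumSeries(_Base):
    """A stack of spectra, one row per titration point, on a shared
    wavelength grid.  ``delta_lambda`` marks synchronous-scan mode
    (15 nm probes Tyr, 60 nm probes Trp)."""

    wavelengths: list[float]
    intensity_matrix: list[list[float]]
    delta_lambda: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "SpectrumSeries":
        w = self.wavelengths
        if any(w[i] >= w[i + 1] for i in range(len(w) - 1)):
            raise ValidationError("wavelengths must be strictly increasing")
        for i, row in enumerate(self.intensity_matrix):
            if len(row) != len(w):
                raise ValidationError(f"spectrum row {i} length mismatch")
        return self


class EEM(_Base):
    """Excitation-emission matrix ('3D fluorescence') on a rectangular grid."""

    excitation_wavelengths: list[float]
    emission_wavelengths: list[float]
    intensities: list[list[float]] = Field(
        description="rows indexed by excitation, columns by emission"
    )

    @model_validator(mode="after")
    def _check(self) -> "EEM":
        if len(self.intensities) != len(self.excitation_wavelengths):
            raise ValidationError("EEM row count must match excitation axis")
        for i, row in enumerate(self.intensities):
            if len(row) != len(self.emission_wavelengths):
                raise ValidationError(f"EEM row {i} length must match emission axis")
            if any(v < 0 for v in row):
                raise ValidationError(f"negative EEM intensity in row {i}")
        return self


class CDSpectrum(_Base):
    """Far-UV circular dichroism spectrum (200-250 nm window)."""

    wavelengths: list[float] = Field(description="nm, within [200, 250]")
    ellipticity: list[float] = Field(description="mdeg")
    mean_residue: bool = Field(
        default=False, description="True if ellipticity is mean-residue ellipticity"
    )

    @model_validator(mode="after")
    def _check(self) -> "CDSpectrum":
        w = self.wavelengths
        if len(w) != len(self.ellipticity):
            raise ValidationError("wavelength/ellipticity length mismatch")
        if any(w[i] >= w[i + 1] for i in range(len(w) - 1)):
            raise ValidationError("wavelengths must be strictly increasing")
        if w and (w[0] < 200.0 - 1e-9 or w[-1] > 250.0 + 1e-9):
            raise ValidationError("CD wavelengths must lie within [200, 250] nm")
        return self


class SecondaryStructure(_Base):
    """Protein secondary-structure composition in percent; sums to 100."""

    alpha_helix: float = Field(ge=0, le=100, alias="alpha_helix_pct")
    beta_sheet: float = Field(ge=0, le=100, alias="beta_sheet_pct")
    beta_turn: float = Field(ge=0, le=100, alias="beta_turn_pct")
    random_coil: float = Field(ge=0, le=100, alias="random_coil_pct")
    residual_norm: Optional[float] = Field(default=None, alias="residual_norm")

    @model_validator(mode="after")
    def _check(self) -> "SecondaryStructure":
        total = self.alpha_helix + self.beta_sheet + self.beta_turn + self.random_coil
        if abs(total - 100.0) > 0.01:
            raise ValidationError(f"fractions must sum to 100 +/- 0.01 (got {total})")
        return self

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.alpha_helix, self.beta_sheet, self.beta_turn, self.random_coil)

    def summary(self) -> str:
        return (
            "Secondary structure (%)\n"
            f"  alpha-helix  {self.alpha_helix:6.2f}\n"
            f"  beta-sheet   {self.beta_sheet:6.2f}\n"
            f"  beta-turn    {self.beta_turn:6.2f}\n"
            f"  random coil  {self.random_coil:6.2f}"
        )


class ANSBindingSeries(_Base):
    """ANS hydrophobicity-probe titration: total ANS stepped against a fixed
    protein concentration, fluorescence read at the ANS emission maximum."""

    ans_total_concs: list[float] = Field(description="mol/L")
    intensities: list[float] = Field(description="a.u.")
    protein_conc: float = Field(gt=0, description="mol/L")
    proportionality_B: Optional[float] = Field(
        default=None, description="a.u. per (mol/L) of bound ANS"
    )

    @model_validator(mode="after")
    def _check(self) -> "ANSBindingSeries":
        if len(self.ans_total_concs) != len(self.intensities):
            raise ValidationError("concs/intensities length mismatch")
        if any(c < 0 for c in self.ans_total_concs):
            raise ValidationError("negative ANS concentration")
        if any(f < 0 for f in self.intensities):
            raise ValidationError("negative intensity")
        return self

    def __len__(self) -> int:
        return len(self.ans_total_concs)


class ScatchardFit(_Base):
    """Scatchard fit of an ANS titration: F/[ANS]free = -F/Kdapp + Fmax/Kdapp."""

    Kdapp: float = Field(gt=0, alias="Kdapp")
    Fmax: float = Field(gt=0, alias="Fmax_au")
    PSH: Optional[float] = Field(default=None, alias="PSH")
    r: float = Field(alias="r")
    B: Optional[float] = Field(default=None, alias="B_au_L_per_mol")
    n_points_used: int = Field(default=0, alias="n_points_used")
    n_points_excluded: int = Field(default=0, alias="n_points_excluded")

    def summary(self) -> str:
        return (
            "Scatchard / surface-hydrophobicity fit\n"
            f"  Kdapp {self.Kdapp:.4g}\n"
            f"  Fmax  {self.Fmax:.4g} a.u.\n"
            + (f"  PSH   {self.PSH:.2f}\n" if self.PSH is not None else "")
            + f"  r     {self.r:.4f}\n"
            f"  points used/excluded: {self.n_points_used}/{self.n_points_excluded}"
        )


class SHMeasurement(_Base):
    """Ellman (DTNB) free-sulfhydryl measurement."""

    A412: float = Field(ge=0)
    path_length: float = Field(default=1.0, gt=0, description="cm")
    extinction: float = Field(default=TNB_EXTINCTION, gt=0, description="M^-1 cm^-1")
    protein_mass_conc: float = Field(gt=0, description="g/L")
    dilution_factor: float = Field(default=1.0, gt=0)


class FoamMeasurement(_Base):
    """Foam heights: H0 before shearing, H1 immediately after, H2 at 30 min.
    Any consistent length/volume unit."""

    H0: float = Field(gt=0)
    H1: float
    H2: float = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "FoamMeasurement":
        if self.H1 < self.H0:
            raise ValidationError("H1 must be >= H0")
        return self


class EmulsionMeasurement(_Base):
    """Turbidimetric emulsion measurement at 500 nm (A0 at 0 min, A10 at
    10 min) with protein mass concentration c (g/mL), oil volume fraction
    phi, path length L (cm) and dilution factor D."""

    A0: float = Field(ge=0)
    A10: float = Field(ge=0)
    c: float = Field(gt=0, description="g/mL")
    phi: float = Field(gt=0, lt=1)
    L: float = Field(default=1.0, gt=0, description="cm")
    D: float = Field(default=100.0, gt=0)


class PeakRecord(_Base):
    """One located feature of an excitation-emission matrix."""

    excitation: float
    emission: float
    intensity: float
    kind: Literal["rayleigh", "peak1", "peak2", "other"]


class ShiftCall(_Base):
    """Signed emission-maximum shift between first and last spectra."""

    shift_nm: float
    label: Literal["red", "blue", "none"]

    @model_validator(mode="after")
    def _check(self) -> "ShiftCall":
        # labelling threshold is recorded implicitly: 'none' only for small shifts
        return self
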