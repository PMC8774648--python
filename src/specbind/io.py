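"""Readers and writers for the package's tabular formats.

All input CSVs are comma-separated, dot-decimal, UTF-8, with one header
row.  Concentration columns are micromolar in the files (the bench
convention) and converted to mol/L on read; everything downstream is
molar.  Results serialise to JSON with unit-annotated field names
(``Ksv_L_per_mol`` etc.) and round-trip bit-exactly through
:func:`read_results_json`.

Input schemas
-------------
titration:  ligand_conc_uM, intensity [, abs_ex, abs_em]
spectrum:   wavelength_nm, then one intensity column per titration point
eem:        first column emission_nm, remaining column headers are
            excitation wavelengths in nm
cd:         wavelength_nm, ellipticity_mdeg
ans:        ans_conc, intensity            (ANS units are the caller's)
foam:       H0, H1, H2                     (one row per replicate)
emulsion:   A0, A10, c_g_per_mL, phi, L_cm, D
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .datatypes import (
    ANSBindingSeries,
    BindingFit,
    CDSpectrum,
    EEM,
    EmulsionMeasurement,
    FoamMeasurement,
    MechanismCall,
    QuenchingFit,
    ScatchardFit,
    SecondaryStructure,
    SHMeasurement,
    ShiftCall,
    SpectrumSeries,
    ThermoResult,
    TitrationSeries,
    ValidationError,
)

__all__ = [
    "convert_concentration",
    "read_titration_csv",
    "read_spectrum_series_csv",
    "read_eem_csv",
    "read_cd_csv",
    "read_ans_csv",
    "read_foam_csv",
    "read_emulsion_csv",
    "write_results_json",
    "read_results_json",
]

_RESULT_TYPES = {
    cls.__name__: cls
    for cls in (
        QuenchingFit,
        BindingFit,
        ThermoResult,
        MechanismCall,
        SecondaryStructure,
        ScatchardFit,
        ShiftCall,
    )
}


def convert_concentration(values, from_unit: str = "uM"):
    """Convert concentrations to mol/L.  ``from_unit`` is ``"uM"`` or
    ``"M"``; converting an already-molar sequence is a no-op."""
    factor = {"uM": 1e-6, "M": 1.0}.get(from_unit)
    if factor is None:
        raise ValidationError(f"unknown concentration unit {from_unit!r}")
    return [v * factor for v in values]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df


def read_titration_csv(
    path: Union[str, Path],
    protein_conc_uM: float = 20.0,
    temperature: float = 298.0,
    excitation_wavelength: float = 280.0,
) -> TitrationSeries:
    """Read one titration CSV (columns ``ligand_conc_uM``, ``intensity``,
    optional ``abs_ex``/``abs_em``) into a molar TitrationSeries."""
    df = _read_csv(path, ["ligand_conc_uM", "intensity"])
    concs = convert_concentration(df["ligand_conc_uM"].tolist(), "uM")
    for i in range(1, len(concs)):
        if concs[i] <= concs[i - 1]:
            raise ValidationError(
                f"{path}: ligand concentrations not strictly increasing at row {i}"
            )
    for i, f in enumerate(df["intensity"]):
        if not f > 0:
            raise ValidationError(f"{path}: non-positive intensity at row {i}")
    return TitrationSeries(
        protein_conc=protein_conc_uM * 1e-6,
        ligand_concs=concs,
        intensities=df["intensity"].astype(float).tolist(),
        temperature=temperature,
        absorbance_ex=df["abs_ex"].astype(float).tolist() if "abs_ex" in df else None,
        absorbance_em=df["abs_em"].astype(float).tolist() if "abs_em" in df else None,
        excitation_wavelength=excitation_wavelength,
    )


def read_spectrum_series_csv(
    path: Union[str, Path], delta_lambda: Optional[float] = None
) -> SpectrumSeries:
    """Read a spectrum stack: ``wavelength_nm`` column, then one intensity
    column per titration point (left to right in titration order)."""
    df = _read_csv(path, ["wavelength_nm"])
    cols = [c for c in df.columns if c != "wavelength_nm"]
    if not cols:
        raise ValidationError(f"{path}: no intensity columns")
    return SpectrumSeries(
        wavelengths=df["wavelength_nm"].astype(float).tolist(),
        intensity_matrix=[df[c].astype(float).tolist() for c in cols],
        delta_lambda=delta_lambda,
    )


def read_eem_csv(path: Union[str, Path]) -> EEM:
    """Read an EEM grid: first column ``emission_nm``, remaining headers
    are excitation wavelengths (nm)."""
    df = _read_csv(path, ["emission_nm"])
    ex_cols = [c for c in df.columns if c != "emission_nm"]
    if not ex_cols:
        raise ValidationError(f"{path}: no excitation columns")
    try:
        ex = [float(c) for c in ex_cols]
    except ValueError as e:
        raise ValidationError(f"{path}: excitation headers must be numeric") from e
    return EEM(
        excitation_wavelengths=ex,
        emission_wavelengths=df["emission_nm"].astype(float).tolist(),
        intensities=[df[c].astype(float).tolist() for c in ex_cols],
    )


def read_cd_csv(path: Union[str, Path]) -> CDSpectrum:
    """Read a far-UV CD spectrum (``wavelength_nm``, ``ellipticity_mdeg``)."""
    df = _read_csv(path, ["wavelength_nm", "ellipticity_mdeg"])
    return CDSpectrum(
        wavelengths=df["wavelength_nm"].astype(float).tolist(),
        ellipticity=df["ellipticity_mdeg"].astype(float).tolist(),
    )


def read_ans_csv(
    path: Union[str, Path],
    protein_conc: float = 0.1,
    proportionality_B: Optional[float] = None,
) -> ANSBindingSeries:
    """Read an ANS titration (``ans_conc``, ``intensity``); concentration
    units are whatever convention the caller declares (must match
    ``protein_conc`` and ``proportionality_B``)."""
    df = _read_csv(path, ["ans_conc", "intensity"])
    return ANSBindingSeries(
        ans_total_concs=df["ans_conc"].astype(float).tolist(),
        intensities=df["intensity"].astype(float).tolist(),
        protein_conc=protein_conc,
        proportionality_B=proportionality_B,
    )


def read_foam_csv(path: Union[str, Path]) -> list[FoamMeasurement]:
    """Read replicate foam heights (columns ``H0``, ``H1``, ``H2``)."""
    df = _read_csv(path, ["H0", "H1", "H2"])
    return [
        FoamMeasurement(H0=row.H0, H1=row.H1, H2=row.H2)
        for row in df.itertuples(index=False)
    ]


def read_emulsion_csv(path: Union[str, Path]) -> list[EmulsionMeasurement]:
    """Read replicate emulsion measurements
    (``A0``, ``A10``, ``c_g_per_mL``, ``phi``, ``L_cm``, ``D``)."""
    df = _read_csv(path, ["A0", "A10", "c_g_per_mL", "phi", "L_cm", "D"])
    return [
        EmulsionMeasurement(
            A0=row.A0, A10=row.A10, c=row.c_g_per_mL, phi=row.phi, L=row.L_cm, D=row.D
        )
        for row in df.itertuples(index=False)
    ]


def write_results_json(result_bundle: Mapping[str, object], path: Union[str, Path]) -> None:
    """Write a bundle of fitted results to JSON with unit-annotated keys.

    ``result_bundle`` maps arbitrary names to result objects (QuenchingFit,
    BindingFit, ThermoResult, MechanismCall, SecondaryStructure,
    ScatchardFit, ShiftCall).  An empty bundle yields a valid document
    with an empty results list.
    """
    doc = {"results": []}
    for name, obj in result_bundle.items():
        cls = type(obj).__name__
        if cls not in _RESULT_TYPES:
            raise ValidationError(f"cannot serialize result of type {cls}")
        doc["results"].append(
            {"name": name, "type": cls, "fields": obj.model_dump(by_alias=True, mode="json")}
        )
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_results_json(path: Union[str, Path]) -> dict[str, object]:
    """Read a results bundle written by :func:`write_results_json`."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    out: dict[str, object] = {}
    for entry in doc["results"]:
        cls = _RESULT_TYPES.get(entry["type"])
        if cls is None:
            raise ValidationError(f"unknown result type {entry['type']!r}")
        out[entry["name"]] = cls.model_validate(entry["fields"])
    return out
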