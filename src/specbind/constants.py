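"""Physical constants and package-wide defaults.

All internal quantities are SI-molar: concentrations in mol L^-1,
temperatures in K, energies in J mol^-1 (reported as kJ mol^-1 where the
field convention is kJ).
"""

#: Gas constant, J mol^-1 K^-1.
R = 8.314

#: Unquenched fluorophore lifetime tau_0, seconds. The intrinsic Trp/Tyr
#: fluorescence lifetime of a globular protein in the absence of quencher;
#: used to convert the Stern-Volmer constant into a bimolecular quenching
#: rate constant Kq = Ksv / tau_0.
TAU0 = 1e-8

#: Maximum diffusion-limited collisional quenching rate constant,
#: L mol^-1 s^-1. A fitted Kq above this value cannot be explained by
#: collisional (dynamic) quenching and indicates ground-state complex
#: formation (static quenching).
DIFFUSION_LIMIT = 2.0e10

#: Molar extinction coefficient of the TNB anion at 412 nm, M^-1 cm^-1,
#: from an L-cysteine standard curve; used in the Ellman free-sulfhydryl
#: assay (1:1 TNB:SH stoichiometry).
TNB_EXTINCTION = 14360.0

#: Default turbidimetric dilution factor for the emulsifying activity index.
DEFAULT_DILUTION = 100.0

#: Molar mass of beta-lactoglobulin, g mol^-1 (used to convert molar protein
#: concentrations to mass concentrations in the Ellman assay helpers).
BLG_MOLAR_MASS = 18400.0
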