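# specbind

Spectroscopic analysis of small-molecule binding to carrier proteins, built
for fluorescence-titration studies of flavonoid–β-lactoglobulin (BLG)
complexes and, more generally, any ligand that quenches a protein's
intrinsic Trp/Tyr fluorescence.

Given a titration of fixed protein with increasing ligand, the package
computes the full ladder of quantities such a study reports:

* **Stern–Volmer quenching**: F₀/F = 1 + K_SV[Q], with the bimolecular rate
  constant K_q = K_SV/τ₀ (τ₀ = 10⁻⁸ s) compared against the diffusion-collision
  ceiling (2.0 × 10¹⁰ L mol⁻¹ s⁻¹) to call the mechanism static or dynamic.
* **Binding constant and site number** by the depletion-corrected
  double-logarithmic fit:
  log[(F₀−F)/F] = n·log K_a + n·log([Q_t] − ((F₀−F)/F₀)[P_t]).
* **Van't Hoff thermodynamics**: log K_a regressed on 1/T gives ΔH° and ΔS°;
  ΔG° = ΔH° − TΔS° (with −RT·ln K_a as an independent cross-check channel),
  and a sign-rule classification of the dominant binding forces.
* **Conformational probes**: synchronous-fluorescence quench ratios
  (RSFQ = 1 − F/F₀ at Δλ = 15/60 nm) and red/blue peak shifts;
  excitation–emission-matrix peak picking outside the Rayleigh scattering
  bands; CD secondary-structure estimation by non-negative least squares on a
  four-component basis; Ellman free-sulfhydryl content; and ANS surface
  hydrophobicity via the Scatchard linearisation
  F/[ANS]_free = −F/K_d^app + F_max/K_d^app with PSH = F_max/([P]·K_d^app).
* **Functional indices**: foaming ability/stability from foam heights and
  the turbidimetric emulsifying activity index / emulsion stability.

Every stage has a matching synthetic-data generator with known ground truth
(`specbind.synthetic`), so each estimator is verified by parameter recovery:
noiseless data round-trip exactly, and noisy data quantify the estimator's
precision.

Fluorescence intensities can be corrected for the inner-filter effect,
F_corr = F_obs·10^((A_ex+A_em)/2), when per-point absorbances are available.

## Worked example

```python
from specbind import GroundTruth, double_log_fit, stern_volmer_fit, vant_hoff_fit
from specbind.synthetic import gen_titration

# noiseless titration at the study design: 20 uM protein, 0-20 uM ligand
series = gen_titration(GroundTruth(Ka=2.78e5, n=1.03, noise_sigma=0.0))
print(double_log_fit(series).summary())
print(vant_hoff_fit({298.0: 2.78e5, 304.0: 2.67e5, 310.0: 2.55e5}).summary())
```

```
Double-log binding fit @ 298 K
  Ka  2.78e+05 L/mol
  n   1.030 (se 7.7e-09)
  r   1.0000
  points used/excluded: 10/0
Van't Hoff thermodynamics
  dH  -5.52 kJ/mol
  dS  85.69 J/(mol K)
  r   0.9988
  dG(298 K)  -31.06 kJ/mol   (-RT ln Ka: -31.06)
  dG(304 K)  -31.57 kJ/mol   (-RT ln Ka: -31.58)
  dG(310 K)  -32.09 kJ/mol   (-RT ln Ka: -32.09)
  forces: hydrogen bond, hydrophobic
```

The binding fit recovers the generating parameters exactly (K_a = 2.78 × 10⁵
L mol⁻¹, n = 1.03): the fitter inverts the forward model. The Van't Hoff
regression over the three binding constants gives a small negative enthalpy
with a large positive entropy — an exothermic but entropy-driven binding,
classified as hydrogen bonding plus hydrophobic interaction — and a
spontaneous ΔG° around −31 kJ mol⁻¹ at 298 K, consistent between the
ΔH° − TΔS° and −RT·ln K_a channels.

## Command line

Each analysis is exposed as a subcommand of `specbind`
(`quench fit-sv | fit-binding | classify`, `thermo fit`,
`probe synchronous | eem | cd | sh | psh`, `func foam | emulsion`,
`simulate …`, and `run --config run.yaml` for the whole pipeline).
Input CSV schemas are documented in `specbind/io.py` with one example of
each under `examples/`. All outputs are JSON with unit-annotated keys.

```sh
specbind quench fit-sv examples/titration_298K.csv
specbind thermo fit examples/ka_by_temperature.csv
```

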