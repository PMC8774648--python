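# Methods

## The model

A fluorophore-bearing protein P (here β-lactoglobulin, whose intrinsic
emission comes from two Trp and four Tyr residues, excited at 280 nm) is
titrated with a quenching ligand Q at fixed temperature. Two linearised
regressions extract the binding picture:

**Stern–Volmer.** F₀/F = 1 + K_SV[Q], fitted by unweighted ordinary least
squares of F₀/F on [Q] over the non-zero-ligand points with a free
intercept (the zero-ligand point defines F₀ and does not enter the
regression). K_q = K_SV/τ₀ with τ₀ = 10⁻⁸ s, the canonical unquenched
lifetime of protein Trp/Tyr fluorescence. The mechanism call uses two
criteria jointly: *static* requires K_SV strictly decreasing with
temperature **and** every K_q above the diffusion-collision ceiling
2.0 × 10¹⁰ L mol⁻¹ s⁻¹; *dynamic* requires the opposite of both;
anything else is *indeterminate*, with the per-criterion evidence
returned. The trend test is plain strict monotonicity of the fitted
values — no statistical test of slope differences — because the
multi-temperature design (three points) cannot support more.

**Double-logarithmic binding fit.** For static quenching the quenched
fraction tracks complex formation, giving

log₁₀[(F₀−F)/F] = n·log₁₀K_a + n·log₁₀([Q_t] − ((F₀−F)/F₀)·[P_t]),

an OLS line in log–log space whose slope is the site number n and whose
intercept gives K_a = 10^(intercept/n). The second term corrects the total
ligand [Q_t] for the part bound to protein, using the fractional quench
(F₀−F)/F₀ as the bound-protein fraction — the assumptions are that
quenching is proportional to occupancy and that each protein binds at one
site (n ≈ 1). Points with F ≥ F₀ or a non-positive free-ligand argument
cannot enter the transform; they are excluded, counted, and the fit is
flagged low-confidence when more than 30% of candidates drop out. n is
never constrained; a slope ≤ 0 is an error, not a clamp.

**Van't Hoff.** log₁₀K_a = −ΔH°/(ln10·R·T) + ΔS°/(ln10·R), fitted by OLS
of log₁₀K_a on 1/T (R = 8.314 J mol⁻¹ K⁻¹; the exact ln 10 is used rather
than the rounded 2.303 — a 2 × 10⁻⁴ relative difference). ΔG° is computed
on two channels: ΔH° − TΔS° (primary) and −RT·ln K_a (diagnostic).
For self-consistent data they agree to well under 1%; a disagreement above
5% is flagged, and `consistency_report` additionally checks the sign of
ΔH° against the temperature trend of K_a (K_a falling with rising T
implies an exothermic binding). This matters in practice: published tables
sometimes print a positive ΔH° next to K_a values that fall with
temperature, and the package reports both channels rather than silently
reconciling them.

**Force classification.** The sign pattern of (ΔH°, ΔS°) maps to dominant
non-covalent interactions. The default convention follows the
food-protein binding literature: ΔH° < 0 contributes "hydrogen bond",
ΔS° > 0 contributes "hydrophobic", and (ΔH° < 0, ΔS° < 0) reads
"van der Waals + hydrogen bond"; exact zeros contribute nothing. The
stricter canonical Ross–Subramanian table (under which ΔH° < 0 with
ΔS° > 0 reads "electrostatic") is available via `mode="ross-subramanian"`.
The two conventions disagree precisely in that quadrant; the default was
chosen to match how binding studies of this kind state their conclusions.

## Conformational probes

*Synchronous fluorescence* (Δλ = 15 nm for Tyr, 60 nm for Trp): per-point
quench ratios RSFQ = 1 − F/F₀ from each spectrum's maximum, and the
emission-maximum shift between first and last spectra. λ_max is located by
parabolic interpolation through the grid maximum and its two neighbours;
shifts of at least 1.0 nm (default; the instrument slit width is 2.5 nm,
so sub-nanometre shifts are not meaningful) are labelled red/blue.

*Excitation–emission matrices*: local maxima of the grid (3×3 maximum
filter) outside the first-order (λ_em = λ_ex) and second-order
(λ_em = 2λ_ex) scattering bands, each of half-width 10 nm by default.
Maxima below 5% of the grid maximum are treated as ripple and dropped. Of
the two strongest survivors, the one with excitation nearer 280 nm is the
Tyr/Trp peak ("peak1"), the one nearer 230 nm the polypeptide-backbone
peak ("peak2"). The brightest in-band point is reported separately as the
Rayleigh record.

*CD secondary structure*: the far-UV spectrum (200–250 nm) is decomposed
by non-negative least squares on a four-component reference basis (helix,
sheet, turn, coil) and the coefficients renormalised to sum to 100. The
shipped basis is **synthetic** — analytic Gaussian band shapes carrying
the known qualitative signatures (helix double minima at 208/222 nm,
sheet single minimum near 218 nm, coil negative band near 198 nm tailing
into the window) — not measured reference spectra. It makes the estimator
deterministic and testable by construction; for real spectra a
user-supplied basis should replace it. NNLS guarantees non-negative
fractions; renormalisation guarantees the sum; an all-zero solution
(degenerate spectrum) is an error rather than a division by zero.

*Ellman assay*: SH (µmol g⁻¹) = A₄₁₂·D/(ε·L) · 10⁶ / c_protein, with
ε = 14 360 M⁻¹ cm⁻¹ (L-cysteine standard curve), 1:1 TNB:SH stoichiometry,
and no reagent-blank modelling — blanks are the caller's responsibility.

*ANS surface hydrophobicity*: bound probe is F/B, free probe is total
minus bound, and F/[ANS]_free regressed on F gives K_d^app = −1/slope and
F_max = −intercept/slope. The proportionality coefficient B is taken from
the data's metadata when known; otherwise it is estimated as the
through-origin slope of F against total ANS over the first three points.
That estimator assumes the low-concentration probe is almost entirely
bound, i.e. F_max/K_d^app ≫ B; outside that regime B must be supplied.
PSH = F_max/([P]·K_d^app) in whatever consistent units the caller
declares; with K_d^app in 10⁻⁶ mol/L table units and protein factor 0.1,
the published index scale is reproduced (the `--table-units` CLI switch).
The percentage reduction of PSH between a reference and a treated sample
is unit-free: it equals 1 − (F_max,t·K_d,ref)/(F_max,ref·K_d,t).

## Functional indices

FA = (H₁−H₀)/H₀·100 and FS = (H₂−H₀)/(H₁−H₀)·100 from foam heights in any
consistent unit; EA = 2·2.303·A₀·D/(c·Φ·L·10⁴) m² g⁻¹ (turbidimetric,
Pearce–Kinsella form) and ES = A₀/(A₀−A₁₀)·10 min, with the dilution
factor D defaulting to 100. The formulas are implemented literally;
FS is undefined (an error) when no foam formed, ES when turbidity did not
decay.

## The synthetic generators

The generators emulate each assay's forward model with known ground truth;
defaults are the study conditions (20 µM protein, ligand 0–20 µM in 2 µM
steps, three temperatures 298/304/310 K, and the strongest-ligand
parameter set K_a = 2.78 × 10⁵, n = 1.03, K_SV = 5.75 × 10⁴).

* **Titration**: writing x = (F₀−F)/F, the binding model is the fixed
  point x = K_aⁿ([Q_t] − (x/(1+x))[P_t])ⁿ, whose right side is strictly
  decreasing in x, so the root is unique and bracketed by
  [0, K_aⁿ[Q_t]ⁿ] (the zero-depletion bound). It is solved by Brent's
  method to 10⁻¹² tolerance; F = F₀/(1+x). Optional synthetic absorbances
  (proportional to ligand concentration) attenuate the emitted signal so
  inner-filter correction can be exercised end-to-end.
* **ANS**: F solves F = F_max·[free]/(K_d+[free]) with
  [free] = [total] − F/B, same bracketing argument.
* **Spectra/EEM**: Gaussian bands and 2D Gaussian peaks plus a diagonal
  scattering ridge; deterministic.
* **Noise**: multiplicative Gaussian on intensities (relative SD,
  photomultiplier-like), additive for CD (relative to the spectrum's peak
  ellipticity); the default level is 1% — a fixture convention, not a
  claim about any instrument. All noisy generators are deterministic given
  (parameters, seed).

What the generators do **not** emulate: photobleaching, scattering
backgrounds in 1D spectra, baseline drift, pH/ionic-strength effects, or
replicate structure. Passing recovery tests therefore demonstrate that the
estimators invert their own forward models at realistic noise — not that
the models capture every feature of real instrument output.

## Measured estimator precision

Because the double-log fit is a log–log transform of differences, its
noise sensitivity depends strongly on where K_a sits relative to the
titration window. At the default design (Q_max = 20 µM) with 1%
multiplicative noise, the median relative K_a error over 100 seeds is
about 4% at K_a = 10⁵ L mol⁻¹ (K_a·Q_max ≈ 2, the well-conditioned
regime), but grows to tens of percent at K_a = 10⁴ (the early points
quench only ~2%, so (F₀−F) is noise-dominated) and ~16% at K_a = 10⁶
(ligand depletion makes the free-ligand logarithm fragile). The error
scales linearly with the noise level in all three regimes, as expected for
a consistent estimator. Practical implication: match the titration window
to the expected affinity, or fall back on a direct nonlinear fit of F
against [Q_t] when that is impossible.

## Numerical and interface choices

* All concentrations are mol/L internally; CSV readers convert from the
  bench µM convention. Energies are reported as kJ mol⁻¹ (ΔH°, ΔG°) and
  J mol⁻¹ K⁻¹ (ΔS°).
* Regressions use `scipy.stats.linregress`; correlation coefficients are
  clipped into [−1, 1] against floating-point spill, and a zero-variance
  response reports r = 0 with zero slope.
* The inner-filter form F·10^((A_ex+A_em)/2) is the standard 1 cm-cuvette
  half-absorbance correction; series without absorbance columns pass
  through uncorrected (recorded by the caller's provenance).
* Result objects serialise to JSON with unit-annotated field names and
  round-trip bit-exactly; pipeline reports contain no timestamps, so
  re-running a config reproduces byte-identical output.
* Missing-data and degenerate-input policies are errors, not silent
  defaults: shuffled concentration columns, flat spectra, non-decaying
  turbidity and saturationless Scatchard data all raise with the offending
  row or condition named.

## Known limitations

* The double-log estimate assumes static quenching; applying it to a
  dynamically quenched system yields an apparent constant without
  equilibrium meaning (the mechanism call should gate it).
* No global multi-temperature fit and no ΔCp (nonlinear Van't Hoff); with
  three temperatures the linear model is already at its resolution limit.
* The CD basis is synthetic (above); absolute secondary-structure contents
  from real spectra require a measured basis and are out of scope, as are
  SELCON/CONTIN-style reference-set methods.
* Duncan-style multiple-comparison letters on replicate tables are not
  reproduced; replicate statistics are mean ± SD only.
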