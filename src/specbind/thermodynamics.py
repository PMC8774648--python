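"""Van't Hoff binding thermodynamics and force classification.

Fitting log10 Ka against 1/T gives the binding enthalpy and entropy:

    log10 Ka = -dH / (ln10 R T) + dS / (ln10 R)

so dH = -ln10 * R * slope and dS = ln10 * R * intercept.  Free energy is
computed on two channels: the Van't Hoff identity dG = dH - T dS (primary)
and the direct dG = -RT ln Ka (diagnostic).  For internally consistent
data the two agree; a discrepancy above 5% is flagged, which is exactly
what happens when a printed dH contradicts the temperature trend of the
printed Ka values.

The force classification maps the signs of (dH, dS) to dominant
non-covalent interactions.  Two conventions are offered:

``literature``
    dH < 0 contributes "hydrogen bond"; dS > 0 contributes "hydrophobic";
    (dH < 0, dS < 0) reads "van der Waals + hydrogen bond".  This is the
    interpretation common in the food-protein binding literature.
``ross-subramanian``
    the canonical Ross-Subramanian table, under which (dH < 0, dS > 0)
    reads "electrostatic".
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
from scipy import stats

from .constants import R
from .datatypes import ThermoResult, ValidationError

__all__ = [
    "VantHoffModel",
    "vant_hoff_fit",
    "gibbs",
    "gibbs_from_ka",
    "classify_forces",
]

_LN10 = math.log(10.0)


def gibbs(dH: float, dS: float, T: float) -> float:
    """Gibbs free energy dG = dH - T*dS, with dH in kJ/mol, dS in J/(mol K);
    returns kJ/mol."""
    if T <= 0:
        raise ValidationError("temperature must be positive")
    return dH - T * dS / 1000.0


def gibbs_from_ka(Ka: float, T: float) -> float:
    """Free energy from the binding constant, -R*T*ln(Ka)/1000 in kJ/mol."""
    if Ka <= 0 or T <= 0:
        raise ValidationError("Ka and T must be positive")
    return -R * T * math.log(Ka) / 1000.0


def classify_forces(dH: float, dS: float, mode: str = "literature") -> set[str]:
    """Sign-rule classification of the dominant binding forces.

    See the module docstring for the two conventions.  Exact zeros
    contribute nothing from that term.
    """
    if mode not in ("literature", "ross-subramanian"):
        raise ValueError(f"unknown classifier mode {mode!r}")
    if dH < 0 and dS < 0:
        return {"van der Waals + hydrogen bond"}
    forces: set[str] = set()
    if mode == "literature":
        if dH < 0:
            forces.add("hydrogen bond")
        if dS > 0:
            forces.add("hydrophobic")
    else:
        if dH < 0 and dS > 0:
            forces.add("electrostatic")
        elif dH > 0 and dS > 0:
            forces.add("hydrophobic")
    return forces


class VantHoffModel:
    """Van't Hoff regression over a map of temperature (K) -> Ka (L/mol).

    Parameters
    ----------
    ka_by_temp : mapping
        At least two distinct temperatures with positive Ka.
    classifier : str
        Force-classification convention, ``"literature"`` (default) or
        ``"ross-subramanian"``.
    discrepancy_flag_pct : float
        Relative disagreement between the dH - T dS and -RT ln Ka free
        energy channels (percent) above which a warning flag is set on
        ``self.flags_`` after fitting.
    """

    def __init__(
        self,
        ka_by_temp: Mapping[float, float],
        classifier: str = "literature",
        discrepancy_flag_pct: float = 5.0,
    ):
        if len(ka_by_temp) < 2:
            raise ValidationError("Van't Hoff fit needs >= 2 temperatures")
        if any(k <= 0 for k in ka_by_temp.values()):
            raise ValidationError("all Ka must be positive")
        if any(t <= 0 for t in ka_by_temp):
            raise ValidationError("all temperatures must be positive")
        self.ka_by_temp = {float(t): float(k) for t, k in ka_by_temp.items()}
        self.classifier = classifier
        self.discrepancy_flag_pct = discrepancy_flag_pct
        self.flags_: list[str] = []

    def fit(self) -> ThermoResult:
        temps = np.array(sorted(self.ka_by_temp), dtype=float)
        logka = np.log10([self.ka_by_temp[t] for t in temps])
        if np.ptp(logka) == 0:
            # flat line: dH = 0, dS = R ln Ka
            dH = 0.0
            dS = R * math.log(self.ka_by_temp[temps[0]])
            rval = 1.0
        else:
            res = stats.linregress(1.0 / temps, logka)
            dH = -_LN10 * R * float(res.slope) / 1000.0
            dS = _LN10 * R * float(res.intercept)
            rval = float(np.clip(res.rvalue, -1.0, 1.0))
        dg = {float(t): gibbs(dH, dS, float(t)) for t in temps}
        dg_ka = {float(t): gibbs_from_ka(self.ka_by_temp[t], float(t)) for t in temps}
        self.flags_ = []
        for t in temps:
            a, b = dg[float(t)], dg_ka[float(t)]
            if abs(a - b) > self.discrepancy_flag_pct / 100.0 * max(abs(a), abs(b)):
                self.flags_.append(
                    f"dG channels disagree at {t:g} K: dH-TdS={a:.2f}, -RTlnKa={b:.2f}"
                )
        return ThermoResult(
            dH=dH,
            dS=dS,
            dG_per_T=dg,
            forces=sorted(classify_forces(dH, dS, self.classifier)),
            r=rval,
            dG_from_ka_per_T=dg_ka,
        )


def vant_hoff_fit(
    ka_by_temp: Mapping[float, float], classifier: str = "literature"
) -> ThermoResult:
    """Least squares of log10 Ka on 1/T; returns the thermodynamic result
    with both free-energy channels.  See :class:`VantHoffModel`."""
    return VantHoffModel(ka_by_temp, classifier=classifier).fit()
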