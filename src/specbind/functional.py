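"""Foaming and emulsifying indices of a protein solution.

Foam heights are read before shearing (H0), immediately after (H1) and
after 30 min (H2); turbidimetric emulsion absorbances at 500 nm are read
at 0 min (A0) and 10 min (A10) after dilution into SDS.  All indices are
the standard ratio definitions (emulsifying activity per Pearce-Kinsella).
"""

from __future__ import annotations

from statistics import mean, stdev
from typing import Sequence

from .datatypes import EmulsionMeasurement, FoamMeasurement, ValidationError

__all__ = [
    "foam_ability",
    "foam_stability",
    "emulsifying_ability",
    "emulsion_stability",
    "replicate_stats",
]


def foam_ability(m: FoamMeasurement) -> float:
    """FA (%) = (H1 - H0)/H0 * 100."""
    if m.H0 <= 0:
        raise ValidationError("H0 must be positive")
    return (m.H1 - m.H0) / m.H0 * 100.0


def foam_stability(m: FoamMeasurement) -> float:
    """FS (%) = (H2 - H0)/(H1 - H0) * 100; undefined when no foam formed."""
    if m.H1 <= m.H0:
        raise ValidationError("foam stability undefined: H1 must exceed H0")
    return (m.H2 - m.H0) / (m.H1 - m.H0) * 100.0


def emulsifying_ability(m: EmulsionMeasurement) -> float:
    """Emulsifying activity index in m^2 g^-1,
    EA = 2 * 2.303 * A0 * D / (c * phi * L * 1e4)."""
    denom = m.c * m.phi * m.L * 1e4
    if denom <= 0:
        raise ValidationError("c, phi and L must be positive")
    return 2.0 * 2.303 * m.A0 * m.D / denom


def emulsion_stability(m: EmulsionMeasurement) -> float:
    """Emulsion stability in minutes, ES = A0/(A0 - A10) * 10."""
    if m.A10 >= m.A0:
        raise ValidationError(
            "emulsion stability undefined: turbidity did not decay (A10 >= A0)"
        )
    return m.A0 / (m.A0 - m.A10) * 10.0


def replicate_stats(values: Sequence[float]) -> dict[str, float]:
    """Mean and sample SD over replicate index values (SD 0 for n=1)."""
    if not values:
        raise ValidationError("no replicate values")
    return {
        "mean": mean(values),
        "sd": stdev(values) if len(values) > 1 else 0.0,
        "n": len(values),
    }
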