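"""Fluorescence quenching analysis.

The titration of a fixed protein concentration with increasing ligand is
analysed in two linearised stages:

1. Stern-Volmer: F0/F = 1 + Ksv [Q].  The slope over the non-zero ligand
   points is the quenching constant Ksv; Kq = Ksv / tau0 compares against
   the diffusion-collision ceiling to separate static from dynamic
   quenching.

2. Double-logarithmic binding fit with ligand depletion:

   log10((F0-F)/F) = n log10 Ka + n log10([Qt] - ((F0-F)/F0) [Pt])

   where [Qt], [Pt] are total ligand and protein.  The slope is the
   binding-site number n and Ka = 10^(intercept/n).  The depletion term
   ((F0-F)/F0)*[Pt] subtracts protein-bound ligand from the total, using
   the fractional quench as the bound fraction.

Both fits are ordinary least squares on the transformed variables,
matching the standard spectroscopic treatment.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .constants import DIFFUSION_LIMIT, TAU0
from .datatypes import (
    BindingFit,
    MechanismCall,
    QuenchingFit,
    TitrationSeries,
    ValidationError,
)

__all__ = [
    "correct_inner_filter",
    "apply_inner_filter",
    "SternVolmerModel",
    "stern_volmer_fit",
    "DoubleLogBindingModel",
    "double_log_fit",
    "classify_mechanism",
    "percent_quenching",
]

logger = logging.getLogger(__name__)


def correct_inner_filter(F_obs, A_ex, A_em):
    """Correct observed fluorescence for the inner-filter effect.

    F_corr = F_obs * 10**((A_ex + A_em) / 2), the standard half-absorbance
    correction for attenuation of the excitation beam on the way in and of
    the emitted light on the way out of a 1 cm cuvette.

    Accepts scalars or array-likes (broadcast together).
    """
    F_obs = np.asarray(F_obs, dtype=float)
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(F_obs < 0) or np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValidationError("inner-filter correction requires non-negative inputs")
    out = F_obs * 10.0 ** ((A_ex + A_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def apply_inner_filter(series: TitrationSeries) -> TitrationSeries:
    """Return a copy of the series with inner-filter-corrected intensities.

    If the series carries no absorbances the data are returned unchanged
    (no correction applied — recorded by the caller's provenance, not here).
    """
    if series.absorbance_ex is None or series.absorbance_em is None:
        return series
    corrected = correct_inner_filter(
        series.intensities, series.absorbance_ex, series.absorbance_em
    )
    return series.model_copy(update={"intensities": list(map(float, corrected))})


class SternVolmerModel:
    """Stern-Volmer quenching model for one titration series.

    Parameters
    ----------
    series : TitrationSeries
        Titration with the zero-ligand reference as its first point.
    tau0 : float, optional
        Unquenched fluorophore lifetime in seconds (default 1e-8).
    """

    def __init__(self, series: TitrationSeries, tau0: float = TAU0):
        if len(series) < 3:
            raise ValidationError(
                "Stern-Volmer fit needs >= 3 points including the zero-ligand point"
            )
        self.series = series
        self.tau0 = float(tau0)

    def fit(self) -> QuenchingFit:
        s = self.series
        q = np.asarray(s.ligand_concs[1:], dtype=float)
        f = np.asarray(s.intensities[1:], dtype=float)
        if np.ptp(q) == 0:
            raise ValidationError("zero variance in ligand concentration")
        y = s.f0 / f
        res = stats.linregress(q, y)
        ksv = float(res.slope)
        # zero-variance response (no quenching): r is undefined, report 0
        rval = float(res.rvalue) if math.isfinite(res.rvalue) else 0.0
        return QuenchingFit(
            Ksv=ksv,
            Kq=ksv / self.tau0,
            intercept=float(res.intercept),
            r=float(np.clip(rval, -1.0, 1.0)),
            temperature=s.temperature,
            tau0=self.tau0,
            Ksv_stderr=float(res.stderr) if math.isfinite(res.stderr) else None,
        )


def stern_volmer_fit(series: TitrationSeries, tau0: float = TAU0) -> QuenchingFit:
    """OLS Stern-Volmer fit of F0/F on [Q] over the non-zero ligand points."""
    return SternVolmerModel(series, tau0=tau0).fit()


class DoubleLogBindingModel:
    """Depletion-corrected double-logarithmic binding model.

    Points where F >= F0 or where the free-ligand argument
    [Qt] - ((F0-F)/F0)[Pt] is non-positive cannot enter the log-log
    regression; they are excluded and counted.  If more than 30% of the
    candidate points are excluded the fit is flagged low-confidence.
    """

    EXCLUSION_FLAG_FRACTION = 0.30

    def __init__(self, series: TitrationSeries):
        self.series = series

    def fit(self) -> BindingFit:
        s = self.series
        f0 = s.f0
        pt = s.protein_conc
        xs, ys = [], []
        n_candidates = 0
        n_excluded = 0
        for qt, f in zip(s.ligand_concs[1:], s.intensities[1:]):
            n_candidates += 1
            if f >= f0:
                n_excluded += 1
                logger.info("double-log fit: excluded point [Qt]=%g (F >= F0)", qt)
                continue
            free = qt - ((f0 - f) / f0) * pt
            if free <= 0:
                n_excluded += 1
                logger.info(
                    "double-log fit: excluded point [Qt]=%g (free ligand <= 0)", qt
                )
                continue
            ys.append(math.log10((f0 - f) / f))
            xs.append(math.log10(free))
        if len(xs) < 3:
            raise ValidationError(
                f"double-log fit needs >= 3 usable points (got {len(xs)}, "
                f"{n_excluded} excluded)"
            )
        res = stats.linregress(np.asarray(xs), np.asarray(ys))
        slope = float(res.slope)
        if slope <= 0:
            raise ValidationError(f"double-log fit slope must be positive (got {slope})")
        low_conf = n_excluded > self.EXCLUSION_FLAG_FRACTION * n_candidates
        if low_conf:
            logger.warning(
                "double-log fit: %d/%d points excluded — low confidence",
                n_excluded,
                n_candidates,
            )
        return BindingFit(
            Ka=10.0 ** (float(res.intercept) / slope),
            n=slope,
            r=float(np.clip(res.rvalue, -1.0, 1.0)),
            temperature=s.temperature,
            n_points_used=len(xs),
            n_points_excluded=n_excluded,
            low_confidence=low_conf,
            n_stderr=float(res.stderr) if math.isfinite(res.stderr) else None,
        )


def double_log_fit(series: TitrationSeries) -> BindingFit:
    """Fit the depletion-corrected double-log binding equation; see
    :class:`DoubleLogBindingModel`."""
    return DoubleLogBindingModel(series).fit()


def classify_mechanism(
    fits: Sequence[QuenchingFit], diffusion_limit: float = DIFFUSION_LIMIT
) -> MechanismCall:
    """Classify the quenching mechanism from fits at several temperatures.

    static: Ksv strictly decreases with temperature AND every Kq exceeds
    the diffusion-collision limit.  dynamic: Ksv strictly increases AND
    every Kq is at or below the limit.  Anything else is indeterminate,
    with the per-criterion evidence returned.
    """
    if len(fits) < 2:
        raise ValidationError("mechanism classification needs fits at >= 2 temperatures")
    temps = [f.temperature for f in fits]
    if len(set(temps)) != len(temps):
        raise ValidationError("duplicate temperatures in mechanism classification")
    ordered = sorted(fits, key=lambda f: f.temperature)
    ksv = [f.Ksv for f in ordered]
    kq = [f.Kq for f in ordered]
    decreasing = all(b < a for a, b in zip(ksv, ksv[1:]))
    increasing = all(b > a for a, b in zip(ksv, ksv[1:]))
    above = all(k > diffusion_limit for k in kq)
    below = all(k <= diffusion_limit for k in kq)
    evidence = {
        "ksv_decreasing_with_T": decreasing,
        "ksv_increasing_with_T": increasing,
        "kq_above_limit": above,
        "kq_at_or_below_limit": below,
    }
    if decreasing and above:
        label = "static"
    elif increasing and below:
        label = "dynamic"
    else:
        label = "indeterminate"
    return MechanismCall(label=label, evidence=evidence)


def percent_quenching(series: TitrationSeries) -> float:
    """Total quench at the final titration point, (1 - F_last/F0) * 100."""
    if len(series) == 0:
        raise ValidationError("empty series")
    f0 = series.f0
    if f0 <= 0:
        raise ValidationError("reference intensity must be positive")
    return (1.0 - series.intensities[-1] / f0) * 100.0
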