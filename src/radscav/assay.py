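"""DPPH plate analysis: scavenging percentage, EC50 estimation, unit conversion.

The scavenging percentage of a well is SP% = 100 (OD_0 - OD_1) / OD_0,
with OD_0 the radical-only control absorbance at 517 nm.  Replicates are
aggregated as mean +/- sd per concentration; when the maximum mean SP
reaches 50% a four-parameter logistic (bottom fixed at 0, top free but
<= 100) is fitted by least squares, otherwise the EC50 is censored and
reported as "> C" against the reporting threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .datamodel import AssayPlate, ValidationError

__all__ = ["DoseResponseFit", "sp_percent", "fit_dose_response", "mass_to_molar"]

_MAX_HILL = 15.0  # slope bound; beyond this the curve is a step on any real ladder


@dataclass(frozen=True)
class DoseResponseFit:
    """EC50 estimate (ug/mL) or censored flag, with the aggregated SP curve."""

    compound: str
    ec50: Optional[float]  # None when censored
    censored: bool
    label: str  # e.g. "9.97" or "> 128"
    hill_slope: Optional[float]
    top: Optional[float]
    bottom: float
    sp_by_conc: tuple[tuple[float, float, float], ...]  # (conc, mean SP, sd)
    monotone: bool  # mean SP nondecreasing with concentration

    def __post_init__(self) -> None:
        if self.censored != (self.ec50 is None):
            raise ValidationError("censored flag must be set iff no numeric EC50")
        if self.top is not None and self.bottom > self.top:
            raise ValidationError("bottom must not exceed top")


def sp_percent(od_control: float, od_sample: float) -> float:
    """Scavenging percentage 100 (OD_0 - OD_1) / OD_0.

    May be negative (pro-oxidant reading); clamping happens only in reports.
    """
    if od_control <= 0:
        raise ValidationError("control absorbance must be > 0")
    if od_sample < 0:
        raise ValidationError("sample absorbance must be >= 0")
    return 100.0 * (od_control - od_sample) / od_control


def aggregate_sp(plate: AssayPlate) -> list[tuple[float, float, float]]:
    """Per-concentration (concentration, mean SP%, sd) over replicates."""
    by_conc: dict[float, list[float]] = {}
    for row in plate.rows:
        by_conc.setdefault(row.concentration, []).append(
            sp_percent(plate.od_control, row.od_sample)
        )
    out = []
    for conc in sorted(by_conc):
        values = np.array(by_conc[conc])
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        out.append((conc, float(values.mean()), sd))
    return out


def _logistic(conc: np.ndarray, top: float, ec50: float, hill: float) -> np.ndarray:
    return top / (1.0 + (ec50 / conc) ** hill)


def fit_dose_response(plate: AssayPlate,
                      report_threshold: Optional[float] = None) -> DoseResponseFit:
    """EC50 from a 4-parameter logistic fit, or a censored "> C" result.

    ``report_threshold`` sets the concentration quoted in a censored label;
    it defaults to the largest tested concentration.  Non-monotone SP curves
    are fitted anyway and flagged via ``monotone``.
    """
    sp = aggregate_sp(plate)
    if len(sp) < 3:
        raise ValidationError(
            f"{plate.compound}: need at least 3 distinct concentrations, got {len(sp)}"
        )
    concs = np.array([row[0] for row in sp])
    means = np.array([row[1] for row in sp])
    monotone = bool(np.all(np.diff(means) >= -1e-9))

    if means.max() < 50.0:
        threshold = report_threshold if report_threshold is not None else concs.max()
        return DoseResponseFit(
            compound=plate.compound, ec50=None, censored=True,
            label=f"> {threshold:g}", hill_slope=None, top=None, bottom=0.0,
            sp_by_conc=tuple(sp), monotone=monotone,
        )

    # initial guesses: top from the plateau, EC50 from the half-max crossing
    top0 = min(100.0, max(means.max(), 1.0))
    half = top0 / 2.0
    above = means >= half
    ec50_0 = concs[above][0] if above.any() else float(np.median(concs))
    params, _ = curve_fit(
        _logistic, concs, means,
        p0=[top0, ec50_0, 1.0],
        bounds=([1e-6, 1e-9, 1e-3], [100.0, np.inf, _MAX_HILL]),
        maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    top, ec50, hill = (float(p) for p in params)
    return DoseResponseFit(
        compound=plate.compound, ec50=ec50, censored=False,
        label=f"{ec50:g}", hill_slope=hill, top=top, bottom=0.0,
        sp_by_conc=tuple(sp), monotone=monotone,
    )


def mass_to_molar(concentration_ug_ml: float, molar_mass: float) -> float:
    """Convert ug/mL to mM: c / M (ug/mL divided by g/mol is mmol/L)."""
    if concentration_ug_ml <= 0 or molar_mass <= 0:
        raise ValidationError("concentration and molar mass must be > 0")
    return concentration_ug_ml / molar_mass
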