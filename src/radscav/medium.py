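"""Condensed-phase corrections and aggregation of channel rate constants.

Apparent rate constants in solution interpolate between activation control
and diffusion control through the Collins-Kimball expression

    k_app = k_D * k_act / (k_D + k_act),

with the diffusional encounter rate k_D from Smoluchowski theory,
k_D = 4 pi R_AB (D_A + D_B) N_A, and Stokes-Einstein diffusion
coefficients D = k_B T / (6 pi eta r).  Aggregation over a channel set
yields branching ratios (percent of the total flux) and the overall rate
constant (plain sum of apparent rate constants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from . import constants
from .datamodel import Conditions, RateResult, ValidationError

__all__ = [
    "DiffusionSpec",
    "stokes_einstein_d",
    "smoluchowski_kd",
    "collins_kimball",
    "branching_ratios",
    "overall_rate",
    "diffusion_spec_from_conditions",
]


@dataclass(frozen=True)
class DiffusionSpec:
    """Viscosity (Pa s), Stokes radii (m) and reaction distance R_AB (m)."""

    viscosity: float
    radius_a: float
    radius_b: float
    reaction_distance: float

    def __post_init__(self) -> None:
        for name in ("viscosity", "radius_a", "radius_b", "reaction_distance"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


def diffusion_spec_from_conditions(conditions: Conditions) -> DiffusionSpec:
    if conditions.viscosity is None:
        raise ValidationError("solvent conditions require a viscosity")
    if conditions.solute_radius is None or conditions.radical_radius is None:
        raise ValidationError("solvent conditions require both Stokes radii")
    return DiffusionSpec(
        viscosity=conditions.viscosity,
        radius_a=conditions.solute_radius,
        radius_b=conditions.radical_radius,
        reaction_distance=conditions.effective_reaction_distance,
    )


def stokes_einstein_d(radius: float, viscosity: float, temperature: float = 298.15) -> float:
    """Stokes-Einstein diffusion coefficient D = k_B T / (6 pi eta r), m^2/s."""
    if radius <= 0 or viscosity <= 0 or temperature <= 0:
        raise ValidationError("radius, viscosity and temperature must be > 0")
    return constants.BOLTZMANN_J_PER_K * temperature / (6.0 * math.pi * viscosity * radius)


def smoluchowski_kd(spec: DiffusionSpec, temperature: float = 298.15) -> float:
    """Diffusional encounter rate k_D = 4 pi R_AB (D_A + D_B) N_A in M^-1 s^-1.

    The SI product (m^3 per molecule per second times N_A) is converted to
    per-litre molar units (factor 1000 L/m^3).
    """
    d_total = (stokes_einstein_d(spec.radius_a, spec.viscosity, temperature)
               + stokes_einstein_d(spec.radius_b, spec.viscosity, temperature))
    return (4.0 * math.pi * spec.reaction_distance * d_total
            * constants.AVOGADRO_PER_MOL * 1000.0)


def collins_kimball(k_act: float, k_diff: float) -> float:
    """Apparent rate constant k_app = k_D k_act / (k_D + k_act).

    Symmetric in its arguments and bounded by min(k_act, k_diff).
    """
    if k_act < 0 or k_diff < 0:
        raise ValidationError("rate constants must be >= 0")
    if k_act == 0 and k_diff == 0:
        raise ValidationError("k_act and k_diff cannot both be zero")
    return k_diff * k_act / (k_diff + k_act)


def branching_ratios(rates: Sequence[RateResult]) -> list[RateResult]:
    """Fill gamma_i = 100 * k_app,i / sum_j k_app,j (percent).

    Full precision is retained; rounding to one decimal happens only in
    report writers.  The gammas sum to exactly 100 up to float roundoff.
    """
    total = sum(r.k_app for r in rates)
    if not rates or total <= 0:
        raise ValidationError("branching ratios need at least one positive k_app")
    return [r.with_gamma(100.0 * r.k_app / total) for r in rates]


def overall_rate(rates: Sequence[RateResult]) -> float:
    """Overall rate constant: arithmetic sum of the apparent rate constants."""
    if not rates:
        raise ValidationError("overall rate needs a non-empty channel list")
    return float(sum(r.k_app for r in rates))
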