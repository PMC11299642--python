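"""Domain types for the radical-scavenging evaluation pipeline.

The pipeline evaluates candidate scavenging events ("channels": one reactive
site paired with one mechanism) of an antioxidant toward a free radical.
Mechanisms follow the standard taxonomy:

* FHT — formal hydrogen transfer (H abstraction from a C-H/O-H bond),
* RAF — radical adduct formation (addition to an unsaturated site),
* SET — single electron transfer (screened thermodynamically only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Mechanism",
    "ReactionChannel",
    "Conditions",
    "RateResult",
    "PlateRow",
    "AssayPlate",
    "MoleculeGeometry",
    "ParseError",
    "ValidationError",
]


class ParseError(ValueError):
    """Malformed input file (bad token, count mismatch, unknown enum...)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


class Mechanism(str, Enum):
    FHT = "FHT"
    RAF = "RAF"
    SET = "SET"


@dataclass(frozen=True)
class ReactionChannel:
    """One candidate scavenging event with its thermodynamic/kinetic data.

    Energies are Gibbs free energies in kcal mol^-1 at the 1 M standard
    state; ``kappa`` is a supplied tunneling correction; ``sigma`` is the
    reaction-path degeneracy (e.g. 3 for abstraction from a methyl group);
    ``nu_imag`` (cm^-1) and the forward/reverse barriers ``v_forward``/
    ``v_reverse`` (kcal mol^-1) feed the computed tunneling models.
    """

    site_label: str
    mechanism: Mechanism
    radical: str
    delta_g_rxn: float
    delta_g_act: Optional[float] = None
    kappa: Optional[float] = None
    sigma: int = 1
    nu_imag: Optional[float] = None
    v_forward: Optional[float] = None
    v_reverse: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        if not math.isfinite(self.delta_g_rxn):
            raise ValidationError(f"{self.site_label}: delta_g_rxn must be finite")
        if self.sigma < 1 or int(self.sigma) != self.sigma:
            raise ValidationError(f"{self.site_label}: sigma must be a positive integer")
        if self.kappa is not None and self.kappa < 1.0:
            raise ValidationError(f"{self.site_label}: kappa must be >= 1")
        for name in ("nu_imag", "v_forward", "v_reverse"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValidationError(f"{self.site_label}: {name} must be > 0")
        if self.mechanism is Mechanism.SET and self.delta_g_act is not None:
            raise ValidationError(
                f"{self.site_label}: SET channels are screened on delta_g_rxn only "
                "and must not carry an activation energy"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.site_label, self.mechanism.value, self.radical)


@dataclass(frozen=True)
class Conditions:
    """Temperature and medium for a kinetic evaluation.

    ``medium_name == "gas"`` means no diffusion correction.  For a solvent,
    ``viscosity`` (Pa s) plus Stokes radii (m) parameterize the
    Stokes-Einstein/Smoluchowski encounter rate; ``reaction_distance``
    defaults to the sum of the two radii.
    """

    temperature: float = 298.15
    medium_name: str = "gas"
    viscosity: Optional[float] = None
    solute_radius: Optional[float] = None
    radical_radius: Optional[float] = None
    reaction_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")
        for name in ("viscosity", "solute_radius", "radical_radius", "reaction_distance"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValidationError(f"{name} must be > 0 when present")

    @property
    def is_gas(self) -> bool:
        return self.medium_name.lower() == "gas"

    @property
    def effective_reaction_distance(self) -> Optional[float]:
        if self.reaction_distance is not None:
            return self.reaction_distance
        if self.solute_radius is not None and self.radical_radius is not None:
            return self.solute_radius + self.radical_radius
        return None


_REL_TOL = 1e-9


@dataclass(frozen=True)
class RateResult:
    """Per-channel rate constants (M^-1 s^-1) and branching ratio (percent).

    ``k_tst`` carries no tunneling or degeneracy; ``k_act = sigma*kappa*k_tst``
    (the Eckart-corrected TST rate in gas phase); ``k_app`` is the
    diffusion-corrected apparent rate (equal to ``k_act`` when no medium
    correction applies); ``gamma`` is filled by the aggregation step.
    """

    site_label: str
    mechanism: Mechanism
    k_tst: float
    k_act: float
    k_app: float
    k_diff: Optional[float] = None
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        for name in ("k_tst", "k_act", "k_app"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.site_label}: {name} must be >= 0")
        if self.k_app > self.k_act * (1 + _REL_TOL):
            raise ValidationError(f"{self.site_label}: k_app must not exceed k_act")
        if self.k_diff is not None and self.k_app > self.k_diff * (1 + _REL_TOL):
            raise ValidationError(f"{self.site_label}: k_app must not exceed k_diff")
        if self.gamma is not None and not (0.0 <= self.gamma <= 100.0 + _REL_TOL):
            raise ValidationError(f"{self.site_label}: gamma must lie in [0, 100]")

    def with_gamma(self, gamma: float) -> "RateResult":
        return replace(self, gamma=gamma)


@dataclass(frozen=True)
class PlateRow:
    """One well reading: concentration in ug/mL, sample absorbance, replicate id."""

    concentration: float
    od_sample: float
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValidationError("concentrations must be > 0")
        if self.od_sample < 0:
            raise ValidationError("OD readings must be >= 0")


@dataclass(frozen=True)
class AssayPlate:
    """DPPH plate data for one compound.

    ``od_control`` is the radical-only absorbance OD_0 (averaged over control
    wells by the reader); sample wells carry OD_1 readings at 517 nm.
    """

    compound: str
    rows: tuple[PlateRow, ...]
    od_control: float
    molar_mass: Optional[float] = None
    wavelength: float = 517.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        if self.od_control <= 0:
            raise ValidationError("od_control must be > 0 (at least one control reading)")
        if not self.rows:
            raise ValidationError("plate must contain at least one sample reading")

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(sorted({row.concentration for row in self.rows}))


@dataclass(frozen=True)
class MoleculeGeometry:
    """Labeled Cartesian coordinates (angstrom) for internal-coordinate analysis."""

    labels: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), angstrom

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError("coords must have shape (n_atoms, 3)")
        if len(self.labels) != coords.shape[0] or len(self.elements) != coords.shape[0]:
            raise ValidationError("labels, elements and coords must agree in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("atom labels must be unique")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def position(self, label: str) -> np.ndarray:
        try:
            index = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown atom label {label!r}") from None
        return self.coords[index]

    def subset(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.position(lab) for lab in labels])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MoleculeGeometry":
        """Rigidly moved copy (used by the invariance tests and simulators)."""
        return MoleculeGeometry(
            self.labels, self.elements,
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
        )
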