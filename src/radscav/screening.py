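"""Thermodynamic viability screening of scavenging channels.

A channel is kinetically evaluated only when its reaction free energy is
negative (spontaneous); SET channels are handled at this screening level
only, since computing their rate constants would require reorganization
energies that are not part of the channel tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .datamodel import Mechanism, ReactionChannel, ValidationError

__all__ = ["ScreeningOutcome", "reaction_free_energy", "screen_channels"]


@dataclass(frozen=True)
class ScreeningOutcome:
    channel: ReactionChannel
    viable: bool
    reason: str  # "spontaneous" | "nonspontaneous" | "SET excluded"


def reaction_free_energy(product_g: Sequence[float], reactant_g: Sequence[float]) -> float:
    """Standard combination rule dG = sum G(products) - sum G(reactants).

    Inputs are species Gibbs free energies in kcal mol^-1 (any consistent
    unit works; the difference carries the unit through).
    """
    if not product_g or not reactant_g:
        raise ValidationError("product and reactant energy lists must be non-empty")
    return float(sum(product_g) - sum(reactant_g))


def screen_channels(channels: Sequence[ReactionChannel],
                    threshold: float = 0.0) -> list[ScreeningOutcome]:
    """Pure filter: viable iff delta_g_rxn < threshold (strict inequality).

    The output preserves input order and partitions the input; channel
    parameters are never modified.
    """
    outcomes = []
    for channel in channels:
        if channel.delta_g_rxn is None:  # defensive; the type already requires it
            raise ValidationError(f"{channel.site_label}: missing delta_g_rxn")
        viable = channel.delta_g_rxn < threshold
        if viable:
            reason = "spontaneous"
        elif channel.mechanism is Mechanism.SET:
            reason = "SET excluded"
        else:
            reason = "nonspontaneous"
        outcomes.append(ScreeningOutcome(channel, viable, reason))
    return outcomes


def viable_channels(outcomes: Sequence[ScreeningOutcome]) -> list[ReactionChannel]:
    return [o.channel for o in outcomes if o.viable]
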