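"""Bundled study tables for the pyrrolo[2,3-b]quinoxaline antioxidant 3a.

These small text fixtures encode the computed reaction energetics
(M06-2X/6-311++G(d,p), 1 M standard state, 298.15 K) and the DPPH plate
results for ethyl 1,2-diphenyl-1H-pyrrolo[2,3-b]quinoxaline-3-carboxylate
(compound "3a") reacting with the hydroxyl (HO*) and hydroperoxyl (HOO*)
radicals, so that every pipeline stage can be exercised offline.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterator

from contextlib import contextmanager

from .datamodel import AssayPlate, Conditions, Mechanism, RateResult, ReactionChannel
from . import io as rio

MOLAR_MASS_3A = 393.44  # g/mol, C25H19N3O2
MOLAR_MASS_QUERCETIN = 302.24  # g/mol


@contextmanager
def _data_path(name: str) -> Iterator[Path]:
    with resources.as_file(resources.files("radscav.data").joinpath(name)) as path:
        yield path


def hydroxyl_channels() -> list[ReactionChannel]:
    """All FHT/RAF/SET channels of 3a + HO* with reaction free energies and,
    where kinetically evaluated, activation energies and tunneling factors.

    Gas-phase FHT rows carry the methyl-site path degeneracy sigma = 3.
    """
    with _data_path("channels_3a_hydroxyl.csv") as path:
        return rio.read_channels(path)


def hydroperoxyl_channels() -> list[ReactionChannel]:
    """The 3a + HOO* channel set (no channel is thermodynamically viable)."""
    with _data_path("channels_3a_hydroperoxyl.csv") as path:
        return rio.read_channels(path)


def _rate_rows(name: str, k_column: str) -> list[RateResult]:
    with _data_path(name) as path, open(path, newline="", encoding="utf-8") as handle:
        out = []
        for record in csv.DictReader(handle):
            k = float(record[k_column])
            out.append(RateResult(
                site_label=record["site"],
                mechanism=Mechanism(record["mechanism"]),
                k_tst=k, k_act=k, k_app=k,
            ))
        return out


def gas_rate_table() -> list[RateResult]:
    """Reference Eckart-corrected TST rate constants (M^-1 s^-1) for
    3a + HO* in the gas phase at 298.15 K, as RateResult rows ready for
    aggregation into branching ratios and an overall rate constant."""
    return _rate_rows("rates_3a_hydroxyl_gas.csv", "k")


def lipid_rate_table() -> list[RateResult]:
    """Reference diffusion-corrected apparent rate constants (M^-1 s^-1) for
    the three dominant 3a + HO* channels in pentyl ethanoate at 298.15 K."""
    return _rate_rows("rates_3a_hydroxyl_lipid.csv", "k_app")


def lipid_channels() -> list[ReactionChannel]:
    """The three dominant 3a + HO* channels with their solution-phase
    activation energies and tunneling factors (sigma = 1 throughout)."""
    gas_dg = {(c.site_label, c.mechanism): c.delta_g_rxn for c in hydroxyl_channels()}
    with _data_path("rates_3a_hydroxyl_lipid.csv") as path, \
            open(path, newline="", encoding="utf-8") as handle:
        channels = []
        for record in csv.DictReader(handle):
            mechanism = Mechanism(record["mechanism"])
            channels.append(ReactionChannel(
                site_label=record["site"],
                mechanism=mechanism,
                radical="HO",
                delta_g_rxn=gas_dg[(record["site"], mechanism)],
                delta_g_act=float(record["dG_act"]),
                kappa=float(record["kappa"]),
                sigma=int(record["sigma"]),
            ))
        return channels


def gas_conditions() -> Conditions:
    with _data_path("conditions_gas.yaml") as path:
        return rio.read_conditions(path)


def pentyl_ethanoate_conditions() -> Conditions:
    """Lipid-mimetic medium: pentyl ethanoate at 298.15 K with documented
    viscosity and Stokes radii (see the conditions YAML for provenance)."""
    with _data_path("conditions_pentyl_ethanoate.yaml") as path:
        return rio.read_conditions(path)


def dpph_plates() -> dict[str, AssayPlate]:
    """DPPH plate data (OD at 517 nm) for 3a-3e and quercetin.

    OD readings are reconstructed from the reported mean scavenging
    percentages around a control absorbance of 0.800.
    """
    with _data_path("dpph_plate_3a_series.csv") as path:
        plates = rio.read_plate(path)
    return {plate.compound: plate for plate in plates}
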