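"""Readers and writers for channel tables, condition configs, plates, XYZ files.

CSV dialect is comma-separated UTF-8 with "." decimals and a required header;
blank cells mean "absent".  Writers emit files their own readers accept.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .datamodel import (
    AssayPlate,
    Conditions,
    Mechanism,
    MoleculeGeometry,
    ParseError,
    PlateRow,
    RateResult,
    ReactionChannel,
    ValidationError,
)

PathLike = Union[str, Path]

CHANNEL_COLUMNS = (
    "site", "mechanism", "radical", "dG_rxn", "dG_act",
    "kappa", "sigma", "nu_imag", "v_forward", "v_reverse",
)


def _parse_float(token: str, *, row: int, column: str) -> Optional[float]:
    token = token.strip()
    if not token:
        return None
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"row {row}: non-numeric value {token!r} in column {column!r}") from None


def read_channels(path: PathLike) -> list[ReactionChannel]:
    """Read a reaction-channel table (one row per site x mechanism x radical)."""
    channels: list[ReactionChannel] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        missing = set(CHANNEL_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"channel table missing columns: {sorted(missing)}")
        for i, record in enumerate(reader, start=2):
            mech_token = (record["mechanism"] or "").strip()
            try:
                mechanism = Mechanism(mech_token)
            except ValueError:
                raise ParseError(f"row {i}: unknown mechanism {mech_token!r}") from None
            dg_rxn = _parse_float(record["dG_rxn"], row=i, column="dG_rxn")
            if dg_rxn is None:
                raise ParseError(f"row {i}: dG_rxn is required")
            sigma = _parse_float(record["sigma"], row=i, column="sigma")
            channel = ReactionChannel(
                site_label=record["site"].strip(),
                mechanism=mechanism,
                radical=record["radical"].strip(),
                delta_g_rxn=dg_rxn,
                delta_g_act=_parse_float(record["dG_act"], row=i, column="dG_act"),
                kappa=_parse_float(record["kappa"], row=i, column="kappa"),
                sigma=int(sigma) if sigma is not None else 1,
                nu_imag=_parse_float(record["nu_imag"], row=i, column="nu_imag"),
                v_forward=_parse_float(record["v_forward"], row=i, column="v_forward"),
                v_reverse=_parse_float(record["v_reverse"], row=i, column="v_reverse"),
            )
            if channel.key in seen:
                raise ValidationError(f"row {i}: duplicate channel {channel.key}")
            seen.add(channel.key)
            channels.append(channel)
    return channels


def write_channels(channels: Iterable[ReactionChannel], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CHANNEL_COLUMNS)
        for ch in channels:
            writer.writerow([
                ch.site_label, ch.mechanism.value, ch.radical,
                repr(ch.delta_g_rxn),
                "" if ch.delta_g_act is None else repr(ch.delta_g_act),
                "" if ch.kappa is None else repr(ch.kappa),
                ch.sigma,
                "" if ch.nu_imag is None else repr(ch.nu_imag),
                "" if ch.v_forward is None else repr(ch.v_forward),
                "" if ch.v_reverse is None else repr(ch.v_reverse),
            ])


def read_conditions(path: PathLike) -> Conditions:
    """Read a temperature/medium config (YAML mapping)."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ParseError("conditions file must be a YAML mapping")
    return Conditions(
        temperature=float(raw.get("temperature_K", 298.15)),
        medium_name=str(raw.get("medium", "gas")),
        viscosity=_opt(raw, "viscosity_Pa_s"),
        solute_radius=_opt(raw, "solute_radius_m"),
        radical_radius=_opt(raw, "radical_radius_m"),
        reaction_distance=_opt(raw, "reaction_distance_m"),
    )


def _opt(mapping: dict, key: str) -> Optional[float]:
    value = mapping.get(key)
    return None if value is None else float(value)


def read_plate(path: PathLike) -> list[AssayPlate]:
    """Read a plate CSV (columns compound, concentration_ug_ml, od_sample,
    replicate); control wells are rows with compound == "CONTROL".

    Returns one AssayPlate per non-control compound, all sharing the mean
    control absorbance OD_0.
    """
    controls: list[float] = []
    by_compound: dict[str, list[PlateRow]] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        required = {"compound", "concentration_ug_ml", "od_sample", "replicate"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"plate table missing columns: {sorted(missing)}")
        for i, record in enumerate(reader, start=2):
            compound = record["compound"].strip()
            od = _parse_float(record["od_sample"], row=i, column="od_sample")
            if od is None:
                raise ParseError(f"row {i}: od_sample is required")
            if compound.upper() == "CONTROL":
                controls.append(od)
                continue
            conc = _parse_float(record["concentration_ug_ml"], row=i, column="concentration_ug_ml")
            if conc is None:
                raise ParseError(f"row {i}: concentration_ug_ml is required")
            by_compound.setdefault(compound, []).append(
                PlateRow(conc, od, (record.get("replicate") or "1").strip())
            )
    if not controls:
        raise ValidationError("plate has no CONTROL rows")
    od_control = sum(controls) / len(controls)
    return [
        AssayPlate(compound=name, rows=tuple(rows), od_control=od_control)
        for name, rows in by_compound.items()
    ]


def read_xyz(path: PathLike) -> MoleculeGeometry:
    """Read a standard XYZ file.

    Records are ``element x y z [label]``; when the label column is absent
    atoms are auto-labeled element+index (C1, C2, O1, ...).
    """
    with open(path, encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    if not lines:
        raise ParseError("empty XYZ file")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"malformed atom-count line: {lines[0]!r}") from None
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count:
        raise ParseError(f"XYZ declares {count} atoms but contains {len(body)} records")
    labels, elements, coords = [], [], []
    counters: dict[str, int] = {}
    for i, line in enumerate(body):
        parts = line.split()
        if len(parts) not in (4, 5):
            raise ParseError(f"malformed XYZ record: {line!r}")
        element = parts[0]
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"non-numeric coordinate in record: {line!r}") from None
        if len(parts) == 5:
            label = parts[4]
        else:
            counters[element] = counters.get(element, 0) + 1
            label = f"{element}{counters[element]}"
        labels.append(label)
        elements.append(element)
        coords.append(xyz)
    import numpy as np

    return MoleculeGeometry(tuple(labels), tuple(elements), np.array(coords))


def write_xyz(geometry: MoleculeGeometry, path: PathLike, comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{len(geometry)}\n{comment}\n")
        for label, element, xyz in zip(geometry.labels, geometry.elements, geometry.coords):
            handle.write(
                f"{element} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f} {label}\n"
            )


def write_report(results: Sequence[RateResult], path: PathLike,
                 overall: Optional[float] = None) -> None:
    """Write a kinetics report: one row per channel plus a k_overall summary row.

    Format is chosen by suffix: .json for JSON, anything else CSV.
    """
    path = Path(path)
    if overall is None:
        overall = sum(r.k_app for r in results)
    if path.suffix.lower() == ".json":
        payload = {
            "channels": [
                {
                    "site": r.site_label,
                    "mechanism": r.mechanism.value,
                    "k_tst": r.k_tst,
                    "k_act": r.k_act,
                    "k_diff": r.k_diff,
                    "k_app": r.k_app,
                    "gamma_percent": None if r.gamma is None else round(r.gamma, 1),
                }
                for r in results
            ],
            "k_overall": overall,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["site", "mechanism", "k_tst", "k_act", "k_diff", "k_app", "gamma_percent"])
        for r in results:
            writer.writerow([
                r.site_label, r.mechanism.value,
                f"{r.k_tst:.6e}", f"{r.k_act:.6e}",
                "" if r.k_diff is None else f"{r.k_diff:.6e}",
                f"{r.k_app:.6e}",
                "" if r.gamma is None else f"{r.gamma:.1f}",
            ])
        writer.writerow(["k_overall", "", "", "", "", f"{overall:.6e}", ""])
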