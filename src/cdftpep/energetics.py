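"""Per-species energetics records: schema, validation and unit handling.

The package's canonical input is a flat table with one row per electronic
species — the neutral molecule (N electrons) and its vertical radical cation
(N−1) and radical anion (N+1), both doublets.  Rows are grouped into
:class:`MoleculeEnergetics` triads keyed by (molecule, functional, solvent).
All energies are converted to eV at ingest; eV is the canonical internal
unit because every descriptor this package computes is conventionally
reported in eV.

Required columns
----------------
``molecule_id, functional, solvent_name, solvent_dielectric, charge,
multiplicity, total_energy, energy_unit`` with optional ``homo, lumo, somo``.
The same field names are accepted in a JSON array-of-records dialect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd

from .errors import ConflictError, SchemaError, UnitError

__all__ = [
    "HARTREE_TO_EV",
    "KCAL_PER_MOL_TO_EV",
    "SolventSpec",
    "SpeciesRecord",
    "MoleculeEnergetics",
    "convert_energy",
    "read_energetics_table",
    "write_energetics_table",
]

#: CODATA-style conversion, fixed so that derived values are bit-stable.
HARTREE_TO_EV = 27.211386
KCAL_PER_MOL_TO_EV = 0.0433641

_UNIT_FACTORS = {
    "hartree": HARTREE_TO_EV,
    "ev": 1.0,
    "kcal/mol": KCAL_PER_MOL_TO_EV,
}

_REQUIRED_COLUMNS = (
    "molecule_id",
    "functional",
    "solvent_name",
    "solvent_dielectric",
    "charge",
    "multiplicity",
    "total_energy",
    "energy_unit",
)
_OPTIONAL_COLUMNS = ("homo", "lumo", "somo")


def convert_energy(value: float, unit: str) -> float:
    """Convert an energy to eV.

    Supported units: ``hartree``, ``eV``, ``kcal/mol`` (case-insensitive).
    Conversion is a fixed linear scaling; eV is the identity.
    """
    try:
        factor = _UNIT_FACTORS[unit.strip().lower()]
    except (KeyError, AttributeError):
        raise UnitError(f"unknown energy unit: {unit!r}; expected one of "
                        f"{sorted(_UNIT_FACTORS)}") from None
    return value * factor


@dataclass(frozen=True)
class SolventSpec:
    """A continuum solvent, identified by name and static dielectric ϵ."""

    name: str
    dielectric: float

    def __post_init__(self) -> None:
        if not (self.dielectric >= 1.0):
            raise SchemaError(
                f"solvent {self.name!r}: dielectric must be ≥ 1, "
                f"got {self.dielectric}")


@dataclass
class SpeciesRecord:
    """One electronic species of one molecule.

    Energies are in eV.  ``homo``/``lumo`` are the frontier orbital energies
    of the neutral; ``somo`` is the singly-occupied orbital of the radical
    anion (its highest occupied orbital).  Fields that a given species does
    not carry are ``None``.
    """

    molecule_id: str
    charge: int
    multiplicity: int
    total_energy: float
    homo: float | None = None
    lumo: float | None = None
    somo: float | None = None

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise SchemaError(
                f"{self.molecule_id}: multiplicity must be ≥ 1, "
                f"got {self.multiplicity}")
        for name in ("total_energy", "homo", "lumo", "somo"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise SchemaError(f"{self.molecule_id}: {name} is not finite")
        if (self.charge == 0 and self.homo is not None
                and self.lumo is not None and not (self.homo < self.lumo)):
            raise SchemaError(
                f"{self.molecule_id}: neutral species must have "
                f"HOMO < LUMO (got {self.homo} ≥ {self.lumo})")


@dataclass
class MoleculeEnergetics:
    """The (N, N−1, N+1) species triad of one molecule in one model chemistry.

    A triad may be *partial* (missing the cation and/or anion); global
    descriptors need only the neutral, but Koopmans-compliance indices
    require the full triad and reject partial ones.
    """

    molecule_id: str
    functional: str
    solvent: SolventSpec
    neutral: SpeciesRecord | None = None
    cation: SpeciesRecord | None = None
    anion: SpeciesRecord | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def is_partial(self) -> bool:
        return self.neutral is None or self.cation is None or self.anion is None


def _parse_optional(raw, line_no: int, col: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise SchemaError(f"line {line_no}: column {col!r} is not numeric: "
                          f"{raw!r}") from None


def _rows_from_source(source, dialect: str) -> list[dict]:
    if dialect == "delimited":
        df = pd.read_csv(source, comment="#", skip_blank_lines=True,
                         dtype=str)
        return df.to_dict(orient="records")
    if dialect == "structured-text":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            payload = json.loads(Path(source).read_text())
        if not isinstance(payload, list):
            raise SchemaError("structured-text source must be a JSON array "
                              "of records")
        return payload
    raise SchemaError(f"unknown dialect: {dialect!r}")


def read_energetics_table(
    source: str | Path | IO,
    dialect: str = "delimited",
) -> list[MoleculeEnergetics]:
    """Read an energetics table and group rows into species triads.

    Every row lands in exactly one triad; triads missing a charged species
    are returned with ``'partial'`` in their ``flags`` rather than dropped.
    Energies are converted to eV using each row's ``energy_unit``.

    Raises
    ------
    SchemaError
        On a malformed row (the message names the offending line).
    ConflictError
        If two rows claim the same (molecule, functional, solvent, charge).
    """
    rows = _rows_from_source(source, dialect)
    triads: dict[tuple, MoleculeEnergetics] = {}
    seen: set[tuple] = set()

    for i, row in enumerate(rows):
        line_no = i + 2  # header is line 1 in the delimited dialect
        missing = [c for c in _REQUIRED_COLUMNS if c not in row
                   or row[c] is None
                   or (isinstance(row[c], float) and math.isnan(row[c]))]
        if missing:
            raise SchemaError(f"line {line_no}: missing required column(s) "
                              f"{missing}")
        try:
            mol = str(row["molecule_id"]).strip()
            functional = str(row["functional"]).strip()
            solvent = SolventSpec(str(row["solvent_name"]).strip(),
                                  float(row["solvent_dielectric"]))
            charge = int(row["charge"])
            multiplicity = int(row["multiplicity"])
            unit = str(row["energy_unit"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"line {line_no}: {exc}") from None

        total = convert_energy(
            _parse_optional(row["total_energy"], line_no, "total_energy"),
            unit)
        orbital = {
            col: (None if (v := _parse_optional(row.get(col), line_no, col))
                  is None else convert_energy(v, unit))
            for col in _OPTIONAL_COLUMNS
        }

        slot = {0: "neutral", 1: "cation", -1: "anion"}.get(charge)
        if slot is None:
            raise SchemaError(f"line {line_no}: charge must be one of "
                              f"-1, 0, +1; got {charge}")

        key = (mol, functional, solvent.name, solvent.dielectric)
        dup_key = key + (charge,)
        if dup_key in seen:
            raise ConflictError(
                f"line {line_no}: duplicate species for molecule {mol!r}, "
                f"functional {functional!r}, solvent {solvent.name!r}, "
                f"charge {charge:+d}")
        seen.add(dup_key)

        species = SpeciesRecord(mol, charge, multiplicity, total, **orbital)
        triad = triads.get(key)
        if triad is None:
            triad = triads[key] = MoleculeEnergetics(mol, functional, solvent)
        setattr(triad, slot, species)

    out = sorted(triads.values(),
                 key=lambda t: (t.molecule_id, t.functional, t.solvent.name))
    for triad in out:
        if triad.is_partial:
            triad.flags.append("partial")
    return out


def write_energetics_table(
    triads: Iterable[MoleculeEnergetics],
    path: str | Path,
) -> None:
    """Write triads back out in the delimited schema (energies in eV)."""
    records = []
    for t in triads:
        for sp in (t.neutral, t.cation, t.anion):
            if sp is None:
                continue
            records.append({
                "molecule_id": sp.molecule_id,
                "functional": t.functional,
                "solvent_name": t.solvent.name,
                "solvent_dielectric": t.solvent.dielectric,
                "charge": sp.charge,
                "multiplicity": sp.multiplicity,
                "total_energy": sp.total_energy,
                "energy_unit": "eV",
                "homo": sp.homo,
                "lumo": sp.lumo,
                "somo": sp.somo,
            })
    cols: Sequence[str] = _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS
    pd.DataFrame.from_records(records, columns=cols).to_csv(path, index=False)
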