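"""Species data model and species-table I/O.

One :class:`SpeciesRecord` is the thermochemical summary of a single
quantum-chemistry calculation: one (compound, species form, phase)
combination with its enthalpy, frontier-orbital energies, spin diagnostics
and optional per-atom populations.  A :class:`SpeciesSet` groups the family
of forms (neutral, radical, radical cation, anion, ...) that the
radical-scavenging cycles of one compound in one phase require.

The species table is a plain delimited text file with a ``#``-prefixed
header block that declares the unit of every energy column; there is no
silent unit guessing.  A structured (JSON) dialect carries the same schema.
All energies are stored internally in Hartree.
"""

from __future__ import annotations

import io
import json
import math
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, TextIO, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import (
    DuplicateRecordError,
    InvalidRecordError,
    ParseError,
    SchemaError,
)
from .units import EnergyUnit, convert_energy

__all__ = [
    "Form",
    "Mechanism",
    "PhaseSpec",
    "AtomSite",
    "SpeciesRecord",
    "SpeciesSet",
    "ValidationReport",
    "read_species_table",
    "write_species_table",
    "validate_for_cycles",
    "convert_energy",
]

# Agreement required between H and E_elec + H_corr when all three are given.
ENTHALPY_CONSISTENCY_TOL = 2e-6  # Hartree


class Form(str, Enum):
    """Species forms entering the scavenging cycles.

    ``cation`` and ``radical_anion`` are accepted for completeness (five
    charged/open-shell forms exist for an N-H antioxidant) although only
    neutral, radical, radical cation and anion enter the three cycles.
    """

    NEUTRAL = "neutral"
    RADICAL = "radical"
    RADICAL_CATION = "radical_cation"
    RADICAL_ANION = "radical_anion"
    ANION = "anion"
    CATION = "cation"


RADICAL_FORMS = frozenset({Form.RADICAL, Form.RADICAL_CATION, Form.RADICAL_ANION})

#: Forms that are resolved per abstraction/deprotonation site.
SITE_RESOLVED_FORMS = frozenset({Form.RADICAL, Form.ANION})


class Mechanism(str, Enum):
    """The three thermodynamic radical-scavenging pathways."""

    HAT = "HAT"        # one-step H-atom transfer, governed by BDE
    SETPT = "SETPT"    # electron transfer (IP) then deprotonation (PDE)
    SPLET = "SPLET"    # proton loss (PA) then electron transfer (ETE)


#: Species forms each mechanism needs; site-resolved forms marked True.
REQUIRED_FORMS: dict[Mechanism, tuple[tuple[Form, bool], ...]] = {
    Mechanism.HAT: ((Form.NEUTRAL, False), (Form.RADICAL, True)),
    Mechanism.SETPT: (
        (Form.NEUTRAL, False),
        (Form.RADICAL, True),
        (Form.RADICAL_CATION, False),
    ),
    Mechanism.SPLET: (
        (Form.NEUTRAL, False),
        (Form.RADICAL, True),
        (Form.ANION, True),
    ),
}


class PhaseName(str, Enum):
    GAS = "gas"
    WATER = "water"
    METHANOL = "methanol"
    CYCLOHEXANE = "cyclohexane"
    OTHER = "other"


class PhaseSpec(BaseModel):
    """Phase metadata for a calculation (continuum-solvation phases carry
    their dielectric constant; the solvation model itself is upstream)."""

    model_config = ConfigDict(frozen=True)

    name: PhaseName
    dielectric_constant: Optional[float] = None

    @model_validator(mode="after")
    def _check_dielectric(self) -> "PhaseSpec":
        if (
            self.dielectric_constant is not None
            and self.name is not PhaseName.GAS
            and self.dielectric_constant <= 1
        ):
            raise ValueError(
                f"dielectric constant must exceed 1 for phase {self.name.value}"
            )
        return self

    @classmethod
    def gas(cls) -> "PhaseSpec":
        return cls(name=PhaseName.GAS)

    @classmethod
    def named(cls, name: str, dielectric: Optional[float] = None) -> "PhaseSpec":
        return cls(name=PhaseName(name), dielectric_constant=dielectric)


class AtomSite(BaseModel):
    """Per-atom condensed quantities; 1-based atom indices match the
    labelling convention of the structures (N22, C19, ...)."""

    index: int = Field(ge=1)
    element: str
    population: Optional[float] = Field(default=None, ge=0.0)
    spin_density: Optional[float] = None

    @property
    def label(self) -> str:
        return f"{self.element}{self.index}"


class SpeciesRecord(BaseModel):
    """Quantum-chemistry summary of one (compound, form, phase)."""

    compound_id: str
    form: Form
    site: Optional[str] = None  # bond label, e.g. "N22-H", for site-resolved forms
    phase: PhaseSpec
    enthalpy: float  # Hartree
    electronic_energy: Optional[float] = None  # Hartree
    thermal_correction: Optional[float] = None  # Hartree
    e_homo: Optional[float] = None  # Hartree
    e_lumo: Optional[float] = None  # Hartree
    s2_expectation: Optional[float] = None
    spin_multiplicity: Optional[int] = Field(default=None, ge=1)
    dipole_moment: Optional[float] = None  # Debye
    polarizability: Optional[float] = None  # a.u.
    n_imaginary_freqs: int = Field(default=0, ge=0)
    atoms: Optional[list[AtomSite]] = None
    metadata: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_invariants(self) -> "SpeciesRecord":
        if self.spin_multiplicity is None:
            object.__setattr__(
                self, "spin_multiplicity", 2 if self.form in RADICAL_FORMS else 1
            )
        elif self.form in RADICAL_FORMS and self.spin_multiplicity != 2:
            raise ValueError(
                f"radical-type form {self.form.value} must be a doublet "
                f"(multiplicity 2), got {self.spin_multiplicity}"
            )
        if self.electronic_energy is not None and self.thermal_correction is not None:
            if not math.isclose(
                self.enthalpy,
                self.electronic_energy + self.thermal_correction,
                abs_tol=ENTHALPY_CONSISTENCY_TOL,
            ):
                raise ValueError(
                    "enthalpy inconsistent with electronic_energy + "
                    f"thermal_correction for {self.compound_id}/{self.form.value}"
                )
        if self.e_homo is not None and self.e_lumo is not None:
            if self.e_lumo < self.e_homo:
                raise ValueError(
                    f"e_lumo < e_homo for {self.compound_id}/{self.form.value}"
                )
        return self

    @property
    def key(self) -> tuple[Form, Optional[str]]:
        return (self.form, self.site if self.form in SITE_RESOLVED_FORMS else None)


class SpeciesSet(BaseModel):
    """All species forms of one compound in one phase, keyed by
    (form, site)."""

    compound_id: str
    phase: PhaseSpec
    records: dict[tuple[Form, Optional[str]], SpeciesRecord] = Field(
        default_factory=dict
    )

    @model_validator(mode="after")
    def _check_membership(self) -> "SpeciesSet":
        for rec in self.records.values():
            if rec.compound_id != self.compound_id:
                raise ValueError(
                    f"record compound {rec.compound_id!r} does not match set "
                    f"{self.compound_id!r}"
                )
            if rec.phase != self.phase:
                raise ValueError(
                    f"record phase {rec.phase.name.value} does not match set "
                    f"phase {self.phase.name.value}"
                )
        return self

    def add(self, record: SpeciesRecord) -> None:
        if record.key in self.records:
            form, site = record.key
            raise DuplicateRecordError(
                f"duplicate record ({record.compound_id}, {form.value}, "
                f"{site}, {record.phase.name.value})"
            )
        self._check_record(record)
        self.records[record.key] = record

    def _check_record(self, record: SpeciesRecord) -> None:
        if record.compound_id != self.compound_id or record.phase != self.phase:
            raise InvalidRecordError(
                "record does not belong to this species set "
                f"({record.compound_id}, {record.phase.name.value})"
            )

    def get(self, form: Form, site: Optional[str] = None) -> SpeciesRecord:
        key = (form, site if form in SITE_RESOLVED_FORMS else None)
        try:
            return self.records[key]
        except KeyError:
            from .errors import MissingSpeciesError

            where = f" at site {site}" if key[1] is not None else ""
            raise MissingSpeciesError(
                f"{self.compound_id} ({self.phase.name.value}): missing "
                f"{form.value}{where}"
            ) from None

    def has(self, form: Form, site: Optional[str] = None) -> bool:
        key = (form, site if form in SITE_RESOLVED_FORMS else None)
        return key in self.records

    def sites(self) -> list[str]:
        """Distinct bond sites carried by site-resolved forms, in insertion
        order."""
        seen: dict[str, None] = {}
        for (form, site) in self.records:
            if site is not None:
                seen.setdefault(site)
        return list(seen)


class ValidationReport(BaseModel):
    """Per-mechanism, per-site listing of missing species forms."""

    missing: dict[str, list[str]] = Field(default_factory=dict)
    # key "MECHANISM@site" (or "MECHANISM" when no site applies)

    @property
    def ok(self) -> bool:
        return not self.missing


def validate_for_cycles(
    species_set: SpeciesSet, mechanisms: Iterable[Union[Mechanism, str]]
) -> ValidationReport:
    """Report, per mechanism and per site, the forms a cycle still needs.

    The report is empty exactly when every requested mechanism can be
    evaluated at every site the set knows about.  Adding a record can only
    shrink the report (validation is monotone).
    """
    report: dict[str, list[str]] = {}
    sites = species_set.sites() or [None]
    for mech in mechanisms:
        mech = Mechanism(mech)
        for site in sites:
            missing: list[str] = []
            for form, site_resolved in REQUIRED_FORMS[mech]:
                use_site = site if site_resolved else None
                if not species_set.has(form, use_site):
                    label = form.value
                    if site_resolved and site is not None:
                        label = f"{form.value}@{site}"
                    missing.append(label)
            if missing:
                key = mech.value if site is None else f"{mech.value}@{site}"
                report[key] = missing
    return ValidationReport(missing=report)


# --------------------------------------------------------------------------
# species-table serialization

COLUMNS = [
    "compound_id",
    "form",
    "site",
    "phase",
    "dielectric",
    "enthalpy",
    "electronic_energy",
    "thermal_correction",
    "e_homo",
    "e_lumo",
    "s2",
    "multiplicity",
    "dipole",
    "polarizability",
    "n_imag",
]

ENERGY_COLUMNS = ("enthalpy", "electronic_energy", "thermal_correction", "e_homo", "e_lumo")

_FIELD_OF_COLUMN = {
    "s2": "s2_expectation",
    "multiplicity": "spin_multiplicity",
    "dipole": "dipole_moment",
    "polarizability": "polarizability",
    "n_imag": "n_imaginary_freqs",
}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def _open_maybe(source, mode: str):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(Path(source), mode), True


def write_species_table(
    sets: list[SpeciesSet],
    sink: Union[str, Path, TextIO],
    dialect: str = "delimited",
    delimiter: str = ",",
) -> None:
    """Write SpeciesSets to a species table (round-trip safe)."""
    if not sets:
        raise ValueError("cannot write an empty list of species sets")
    records = [rec for s in sets for rec in s.records.values()]
    if dialect == "structured":
        payload = {
            "format": "radscav-species-table",
            "version": 1,
            "units": {c: "hartree" for c in ENERGY_COLUMNS},
            "records": [_record_to_row(r) for r in records],
        }
        stream, close = _open_maybe(sink, "w")
        try:
            json.dump(payload, stream, indent=1)
        finally:
            if close:
                stream.close()
        return
    if dialect != "delimited":
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = ["# radscav species table v1"]
    for col in ENERGY_COLUMNS:
        lines.append(f"# unit:{col}=hartree")
    lines.append(delimiter.join(COLUMNS))
    for rec in records:
        row = _record_to_row(rec)
        lines.append(delimiter.join(_fmt(row[c]) for c in COLUMNS))
    stream, close = _open_maybe(sink, "w")
    try:
        stream.write("\n".join(lines) + "\n")
    finally:
        if close:
            stream.close()


def _record_to_row(rec: SpeciesRecord) -> dict:
    return {
        "compound_id": rec.compound_id,
        "form": rec.form.value,
        "site": rec.site,
        "phase": rec.phase.name.value,
        "dielectric": rec.phase.dielectric_constant,
        "enthalpy": rec.enthalpy,
        "electronic_energy": rec.electronic_energy,
        "thermal_correction": rec.thermal_correction,
        "e_homo": rec.e_homo,
        "e_lumo": rec.e_lumo,
        "s2": rec.s2_expectation,
        "multiplicity": rec.spin_multiplicity,
        "dipole": rec.dipole_moment,
        "polarizability": rec.polarizability,
        "n_imag": rec.n_imaginary_freqs,
    }


def read_species_table(
    source: Union[str, Path, TextIO],
    dialect: str = "delimited",
    delimiter: str = ",",
) -> list[SpeciesSet]:
    """Read a species table and group records into SpeciesSets.

    Energy columns are converted to Hartree according to the unit
    declarations in the header block; a missing declaration or mandatory
    column raises :class:`SchemaError`, a duplicate (compound, form, site,
    phase) raises :class:`DuplicateRecordError`, and a non-numeric energy
    raises :class:`ParseError` carrying the row number.
    """
    stream, close = _open_maybe(source, "r")
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()

    if dialect == "structured":
        payload = json.loads(text)
        units = {c: EnergyUnit(u) for c, u in payload.get("units", {}).items()}
        rows = payload["records"]
        return _assemble(rows, units, start_row=1)
    if dialect != "delimited":
        raise ValueError(f"unknown dialect {dialect!r}")

    units: dict[str, EnergyUnit] = {}
    header: Optional[list[str]] = None
    rows: list[dict] = []
    row_numbers: list[int] = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("unit:"):
                col, _, unit = body[len("unit:"):].partition("=")
                try:
                    units[col.strip()] = EnergyUnit(unit.strip())
                except ValueError:
                    raise SchemaError(
                        f"unknown unit {unit.strip()!r} for column {col.strip()!r}"
                    ) from None
            continue
        fields = line.split(delimiter)
        if header is None:
            header = [h.strip() for h in fields]
            missing = [c for c in COLUMNS if c not in header]
            if missing:
                raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
            continue
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, got {len(fields)}", row=lineno
            )
        row = {h: (v.strip() or None) for h, v in zip(header, fields)}
        rows.append(row)
        row_numbers.append(lineno)
    if header is None:
        raise SchemaError("species table has no header row")
    for col in ENERGY_COLUMNS:
        if col not in units:
            raise SchemaError(f"no unit declared for energy column {col!r}")
    return _assemble(rows, units, row_numbers=row_numbers)


def _parse_float(value, col: str, row: int) -> Optional[float]:
    if value is None:
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"non-numeric value {value!r} in column {col!r}", row=row) from None


def _assemble(
    rows: list[Mapping],
    units: Mapping[str, EnergyUnit],
    row_numbers: Optional[list[int]] = None,
    start_row: int = 1,
) -> list[SpeciesSet]:
    sets: dict[tuple[str, str], SpeciesSet] = {}
    for i, row in enumerate(rows):
        rowno = row_numbers[i] if row_numbers else start_row + i
        known = {c: row.get(c) for c in COLUMNS}
        extra = {k: str(v) for k, v in row.items() if k not in COLUMNS and v is not None}
        energies = {}
        for col in ENERGY_COLUMNS:
            val = _parse_float(known[col], col, rowno)
            if val is not None:
                val = convert_energy(val, units.get(col, EnergyUnit.HARTREE), EnergyUnit.HARTREE)
            energies[col] = val
        if energies["enthalpy"] is None:
            raise ParseError("missing enthalpy", row=rowno)
        phase = PhaseSpec(
            name=PhaseName(known["phase"]),
            dielectric_constant=_parse_float(known["dielectric"], "dielectric", rowno),
        )
        mult = known["multiplicity"]
        try:
            rec = SpeciesRecord(
                compound_id=str(known["compound_id"]),
                form=Form(known["form"]),
                site=known["site"],
                phase=phase,
                enthalpy=energies["enthalpy"],
                electronic_energy=energies["electronic_energy"],
                thermal_correction=energies["thermal_correction"],
                e_homo=energies["e_homo"],
                e_lumo=energies["e_lumo"],
                s2_expectation=_parse_float(known["s2"], "s2", rowno),
                spin_multiplicity=int(mult) if mult is not None else None,
                dipole_moment=_parse_float(known["dipole"], "dipole", rowno),
                polarizability=_parse_float(known["polarizability"], "polarizability", rowno),
                n_imaginary_freqs=int(known["n_imag"]) if known["n_imag"] is not None else 0,
                metadata=extra,
            )
        except ValueError as exc:
            raise ParseError(str(exc), row=rowno) from None
        key = (rec.compound_id, rec.phase.name.value)
        sset = sets.get(key)
        if sset is None:
            sset = SpeciesSet(compound_id=rec.compound_id, phase=rec.phase)
            sets[key] = sset
        sset.add(rec)
    return list(sets.values())
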