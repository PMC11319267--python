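"""Global conceptual-DFT reactivity descriptors.

From a vertical ionization energy IP and electron affinity EA (eV), the
finite-difference descriptors are

    mu  = -(IP + EA)/2        electronic chemical potential
    chi = -mu                 electronegativity
    eta = IP - EA             chemical hardness (see note below)
    S   = 1/eta               global softness
    omega = mu^2 / (2 eta)    electrophilicity index

Hardness convention: the original Parr-Pearson definition carries a factor
1/2, eta = (IP - EA)/2, but much of the applied literature - and the
reference tables this package reproduces - drops it.  The default here is
the no-half convention (eta = IP - EA); pass ``half_factor=True`` for the
Parr-Pearson form.  omega always uses the same eta convention it is given.

Koopmans route: IP = -e_HOMO and EA = -e_LUMO from frontier-orbital
energies (physically standard signs).
"""

from __future__ import annotations

import warnings
from enum import Enum
from typing import Optional

import pandas as pd
from pydantic import BaseModel

from .errors import ConfigError, InvalidRecordError, RadscavError
from .species import Form, SpeciesRecord, SpeciesSet
from .units import hartree_to_ev

__all__ = [
    "DescriptorRoute",
    "GlobalDescriptors",
    "chemical_potential",
    "electronegativity",
    "hardness",
    "softness",
    "electrophilicity",
    "koopmans_ip_ea",
    "homo_lumo_gap",
    "nucleophilicity",
    "global_table",
]


class DescriptorRoute(str, Enum):
    DELTA_SCF = "delta_scf"  # IP/EA from total-energy differences, supplied as data
    KOOPMANS = "koopmans"    # IP/EA from -e_HOMO / -e_LUMO


class GlobalDescriptors(BaseModel):
    compound_id: str
    ie: float
    ea: float
    mu: float
    chi: float
    eta: float
    softness: float
    omega: float
    nucleophilicity: Optional[float] = None
    gap: Optional[float] = None
    dipole: Optional[float] = None
    polarizability: Optional[float] = None
    route: DescriptorRoute


def chemical_potential(ip: float, ea: float) -> float:
    """Electronic chemical potential mu = -(IP + EA)/2, eV."""
    return -(ip + ea) / 2.0


def electronegativity(mu: float) -> float:
    """Electronegativity chi = -mu, eV."""
    return -mu


def hardness(ip: float, ea: float, half_factor: bool = False) -> float:
    """Chemical hardness, eV.

    ``half_factor=False`` (default) gives eta = IP - EA; ``True`` gives the
    Parr-Pearson eta = (IP - EA)/2.  IP < EA (possible for a compound with
    negative EA convention mismatches) only warns.
    """
    if ip < ea:
        warnings.warn(
            f"IP ({ip}) < EA ({ea}); hardness will be negative", stacklevel=2
        )
    eta = ip - ea
    return eta / 2.0 if half_factor else eta


def softness(eta: float) -> float:
    """Global softness S = 1/eta, eV^-1."""
    if eta <= 0:
        raise RadscavError(f"softness undefined for non-positive hardness {eta}")
    return 1.0 / eta


def electrophilicity(mu: float, eta: float) -> float:
    """Electrophilicity index omega = mu^2/(2 eta), eV."""
    if eta <= 0:
        raise RadscavError(f"electrophilicity undefined for non-positive hardness {eta}")
    return mu * mu / (2.0 * eta)


def koopmans_ip_ea(record: SpeciesRecord) -> tuple[float, float]:
    """Frontier-orbital estimates IP = -e_HOMO, EA = -e_LUMO, in eV."""
    if record.e_homo is None or record.e_lumo is None:
        raise InvalidRecordError(
            f"{record.compound_id}: orbital energies required for the Koopmans route"
        )
    return -hartree_to_ev(record.e_homo), -hartree_to_ev(record.e_lumo)


def homo_lumo_gap(record: SpeciesRecord) -> float:
    """HOMO-LUMO gap e_LUMO - e_HOMO in eV (never negative for valid input)."""
    if record.e_homo is None or record.e_lumo is None:
        raise InvalidRecordError(
            f"{record.compound_id}: orbital energies required for the gap"
        )
    if record.e_lumo < record.e_homo:
        raise InvalidRecordError(f"{record.compound_id}: e_lumo < e_homo")
    return hartree_to_ev(record.e_lumo - record.e_homo)


def nucleophilicity(record: SpeciesRecord, reference_e_homo_ev: Optional[float]) -> float:
    """Relative nucleophilicity N = e_HOMO - e_HOMO(reference), eV.

    The reference is conventionally the HOMO energy of tetracyanoethylene at
    the same level of theory; it must be supplied (there is no universal
    default)."""
    if reference_e_homo_ev is None:
        raise ConfigError("nucleophilicity requires a reference HOMO energy (eV)")
    if record.e_homo is None:
        raise InvalidRecordError(f"{record.compound_id}: e_homo required")
    return hartree_to_ev(record.e_homo) - reference_e_homo_ev


def delta_scf_ip_ea(species_set: SpeciesSet) -> tuple[float, float]:
    """Vertical IP/EA from total-energy differences, in eV.

    IP = E(radical cation) - E(neutral); EA = E(neutral) - E(radical anion).
    Electronic energies are used when present (vertical convention),
    otherwise enthalpies."""

    def energy(rec: SpeciesRecord) -> float:
        return rec.electronic_energy if rec.electronic_energy is not None else rec.enthalpy

    neutral = species_set.get(Form.NEUTRAL)
    cation = species_set.get(Form.RADICAL_CATION)
    anion = species_set.get(Form.RADICAL_ANION)
    ip = hartree_to_ev(energy(cation) - energy(neutral))
    ea = hartree_to_ev(energy(neutral) - energy(anion))
    return ip, ea


def _descriptors_from_ip_ea(
    compound_id: str,
    ip: float,
    ea: float,
    route: DescriptorRoute,
    half_factor: bool = False,
    **extras,
) -> GlobalDescriptors:
    mu = chemical_potential(ip, ea)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eta = hardness(ip, ea, half_factor=half_factor)
    return GlobalDescriptors(
        compound_id=compound_id,
        ie=ip,
        ea=ea,
        mu=mu,
        chi=electronegativity(mu),
        eta=eta,
        softness=softness(eta),
        omega=electrophilicity(mu, eta),
        route=route,
        **extras,
    )


def global_table(
    sets: list[SpeciesSet],
    route: DescriptorRoute | str = DescriptorRoute.KOOPMANS,
    reference_e_homo_ev: Optional[float] = None,
    half_factor: bool = False,
) -> pd.DataFrame:
    """Assemble one global-descriptor row per compound.

    Rows are ordered deterministically by compound_id; per-row failures are
    collected into an ``error`` column instead of aborting the table.
    """
    route = DescriptorRoute(route)
    rows = []
    for sset in sorted(sets, key=lambda s: s.compound_id):
        base = {"compound_id": sset.compound_id, "route": route.value}
        try:
            neutral = sset.get(Form.NEUTRAL)
            if route is DescriptorRoute.KOOPMANS:
                ip, ea = koopmans_ip_ea(neutral)
            else:
                ip, ea = delta_scf_ip_ea(sset)
            desc = _descriptors_from_ip_ea(
                sset.compound_id,
                ip,
                ea,
                route,
                half_factor=half_factor,
                gap=homo_lumo_gap(neutral),
                dipole=neutral.dipole_moment,
                polarizability=neutral.polarizability,
            )
            row = desc.model_dump()
            row["route"] = route.value
            if reference_e_homo_ev is not None:
                row["nucleophilicity"] = nucleophilicity(neutral, reference_e_homo_ev)
            row["error"] = None
        except RadscavError as exc:
            row = {**base, "error": str(exc)}
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("compound_id", kind="stable").reset_index(drop=True)
    return df


def descriptor_table_from_ip_ea(
    table: pd.DataFrame, half_factor: bool = False
) -> pd.DataFrame:
    """Recompute mu, chi, eta, S and omega from an IE/EA table.

    ``table`` needs columns ``compound_id``, ``ie`` and ``ea`` (eV).  This is
    the delta-SCF route applied to tabulated vertical IE/EA values, e.g. for
    checking a published descriptor table against its own inputs.
    """
    out = []
    for _, row in table.iterrows():
        desc = _descriptors_from_ip_ea(
            str(row["compound_id"]),
            float(row["ie"]),
            float(row["ea"]),
            DescriptorRoute.DELTA_SCF,
            half_factor=half_factor,
        )
        out.append(
            {
                "compound_id": desc.compound_id,
                "ie": desc.ie,
                "ea": desc.ea,
                "mu": desc.mu,
                "chi": desc.chi,
                "eta": desc.eta,
                "softness": desc.softness,
                "omega": desc.omega,
            }
        )
    return pd.DataFrame(out)
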