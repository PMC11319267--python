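"""HAT / SET-PT / SPLET thermochemical cycles.

An N-H (or C-H, O-H) antioxidant AH can quench a radical by three
thermodynamic routes, each characterised by the enthalpy of its first step:

* HAT   — AH -> A• + H•,          governed by the bond dissociation enthalpy
          BDE = H(A•) + H(H•) - H(AH);
* SET-PT — AH -> AH•+ + e-  then AH•+ -> A• + H+,
          governed by IP = H(AH•+) + H(e-) - H(AH) and
          PDE = H(A•) + H(H+) - H(AH•+);
* SPLET — AH -> A- + H+  then  A- -> A• + e-,
          governed by PA = H(A-) + H(H+) - H(AH) and
          ETE = H(A•) + H(e-) - H(A-).

Because both two-step routes start from AH and end at A•,
IP + PDE = PA + ETE exactly for any one species set and one set of
reference particle enthalpies, and both totals exceed the BDE by the
constant H(H+) + H(e-) - H(H•).

All arithmetic is done in Hartree; results are reported in kcal/mol.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict

from .errors import ConfigError
from .species import Form, Mechanism, PhaseName, PhaseSpec, SpeciesRecord, SpeciesSet
from .units import EnergyUnit, convert_energy, hartree_to_kcal

__all__ = [
    "ReferenceEnthalpies",
    "GAS_REFERENCES",
    "CycleResult",
    "bde",
    "ionization_potential",
    "pde",
    "proton_affinity",
    "ete",
    "setpt_total",
    "splet_total",
    "compute_cycles",
    "cycle_residual",
    "scale_frequencies",
    "spin_contamination_check",
    "SpinCheck",
    "load_references",
]

DEFAULT_FREQUENCY_SCALE = 0.9669
DEFAULT_S2_DOUBLET = 0.750
DEFAULT_S2_TOLERANCE = 0.05


class ReferenceEnthalpies(BaseModel):
    """Enthalpies of the free particles H•, H+ and e- that close the cycles,
    in Hartree, for one phase.

    Gas-phase defaults: H(H•) = -0.5 Hartree (electronic energy of the
    hydrogen atom with the enthalpy convention used here), H(H+) = +1.483
    kcal/mol and H(e-) = +0.752 kcal/mol (the standard literature gas-phase
    values, i.e. 5/2 RT translational enthalpy terms).  Solvent phases have
    no defaults: solvation enthalpies of H+ and e- are model-dependent and
    must be supplied explicitly.
    """

    model_config = ConfigDict(frozen=True)

    phase: PhaseSpec
    h_hydrogen_atom: float  # Hartree
    h_proton: float  # Hartree
    h_electron: float  # Hartree

    @property
    def cycle_constant_kcal(self) -> float:
        """H(H+) + H(e-) - H(H•) in kcal/mol: the exact offset between the
        two-step totals (IP+PDE = PA+ETE) and the BDE."""
        return hartree_to_kcal(self.h_proton + self.h_electron - self.h_hydrogen_atom)


def _gas_refs() -> ReferenceEnthalpies:
    from .units import kcal_to_hartree

    return ReferenceEnthalpies(
        phase=PhaseSpec.gas(),
        h_hydrogen_atom=-0.5,
        h_proton=kcal_to_hartree(1.483),
        h_electron=kcal_to_hartree(0.752),
    )


#: Documented gas-phase defaults (see :class:`ReferenceEnthalpies`).
GAS_REFERENCES: ReferenceEnthalpies = _gas_refs()


def load_references(source) -> dict[str, ReferenceEnthalpies]:
    """Load per-phase reference enthalpies from a YAML config.

    Expected layout::

        references:
          gas:
            h_hydrogen_atom: {value: -0.5, unit: hartree}
            h_proton: {value: 1.483, unit: kcal_per_mol}
            h_electron: {value: 0.752, unit: kcal_per_mol}
          water:
            dielectric: 78.36
            ...

    Returns a mapping phase-name -> :class:`ReferenceEnthalpies`.
    """
    if hasattr(source, "read"):
        payload = yaml.safe_load(source)
    else:
        with open(source) as fh:
            payload = yaml.safe_load(fh)
    if not payload or "references" not in payload:
        raise ConfigError("config has no 'references' section")
    out: dict[str, ReferenceEnthalpies] = {}
    for phase_name, entries in payload["references"].items():
        dielectric = entries.pop("dielectric", None)
        values = {}
        for key in ("h_hydrogen_atom", "h_proton", "h_electron"):
            if key not in entries:
                raise ConfigError(f"references.{phase_name} missing {key}")
            spec = entries[key]
            if isinstance(spec, dict):
                values[key] = convert_energy(
                    float(spec["value"]), spec.get("unit", "hartree"), EnergyUnit.HARTREE
                )
            else:
                values[key] = float(spec)
        out[phase_name] = ReferenceEnthalpies(
            phase=PhaseSpec(name=PhaseName(phase_name), dielectric_constant=dielectric),
            **values,
        )
    return out


class CycleResult(BaseModel):
    """All five cycle quantities plus the two-step totals for one
    compound/site/phase, in kcal/mol."""

    compound_id: str
    site: Optional[str]
    phase: PhaseSpec
    bde: float
    ip: float
    pde: float
    pa: float
    ete: float
    setpt_total: float
    splet_total: float


def bde(species_set: SpeciesSet, site: Optional[str], refs: ReferenceEnthalpies) -> float:
    """Homolytic X-H bond dissociation enthalpy in kcal/mol (HAT)."""
    neutral = species_set.get(Form.NEUTRAL)
    radical = species_set.get(Form.RADICAL, site)
    return hartree_to_kcal(radical.enthalpy + refs.h_hydrogen_atom - neutral.enthalpy)


def ionization_potential(species_set: SpeciesSet, refs: ReferenceEnthalpies) -> float:
    """Adiabatic ionization potential in kcal/mol (SET-PT step 1)."""
    neutral = species_set.get(Form.NEUTRAL)
    cation = species_set.get(Form.RADICAL_CATION)
    return hartree_to_kcal(cation.enthalpy + refs.h_electron - neutral.enthalpy)


def pde(species_set: SpeciesSet, site: Optional[str], refs: ReferenceEnthalpies) -> float:
    """Proton dissociation enthalpy of the radical cation in kcal/mol
    (SET-PT step 2)."""
    cation = species_set.get(Form.RADICAL_CATION)
    radical = species_set.get(Form.RADICAL, site)
    return hartree_to_kcal(radical.enthalpy + refs.h_proton - cation.enthalpy)


def proton_affinity(
    species_set: SpeciesSet, site: Optional[str], refs: ReferenceEnthalpies
) -> float:
    """Heterolytic X-H cleavage enthalpy (anion + H+) in kcal/mol
    (SPLET step 1)."""
    neutral = species_set.get(Form.NEUTRAL)
    anion = species_set.get(Form.ANION, site)
    return hartree_to_kcal(anion.enthalpy + refs.h_proton - neutral.enthalpy)


def ete(species_set: SpeciesSet, site: Optional[str], refs: ReferenceEnthalpies) -> float:
    """Electron transfer enthalpy from the deprotonated anion in kcal/mol
    (SPLET step 2)."""
    anion = species_set.get(Form.ANION, site)
    radical = species_set.get(Form.RADICAL, site)
    return hartree_to_kcal(radical.enthalpy + refs.h_electron - anion.enthalpy)


def setpt_total(ip: float, pde_value: float) -> float:
    """Total SET-PT enthalpy, IP + PDE (kcal/mol)."""
    return ip + pde_value


def splet_total(pa: float, ete_value: float) -> float:
    """Total SPLET enthalpy, PA + ETE (kcal/mol)."""
    return pa + ete_value


def compute_cycles(
    species_set: SpeciesSet, site: Optional[str], refs: ReferenceEnthalpies
) -> CycleResult:
    """Evaluate all five cycle quantities of one site from one species set."""
    b = bde(species_set, site, refs)
    i = ionization_potential(species_set, refs)
    p = pde(species_set, site, refs)
    a = proton_affinity(species_set, site, refs)
    e = ete(species_set, site, refs)
    return CycleResult(
        compound_id=species_set.compound_id,
        site=site,
        phase=species_set.phase,
        bde=b,
        ip=i,
        pde=p,
        pa=a,
        ete=e,
        setpt_total=setpt_total(i, p),
        splet_total=splet_total(a, e),
    )


def cycle_residual(result: CycleResult, refs: Optional[ReferenceEnthalpies] = None) -> float:
    """(IP + PDE) - (PA + ETE) in kcal/mol.

    Both totals measure the same overall reaction AH -> A• + H+ + e-, so the
    residual is zero (to floating arithmetic) whenever the five quantities
    come from a single species set evaluated with a single set of reference
    enthalpies.  A non-zero residual on externally tabulated rows flags that
    the two cycles were closed with different H+/e- reference values.
    """
    return (result.ip + result.pde) - (result.pa + result.ete)


def scale_frequencies(freqs: Iterable[float], factor: float = DEFAULT_FREQUENCY_SCALE) -> list[float]:
    """Apply a harmonic frequency scaling factor (default 0.9669) elementwise."""
    if factor <= 0:
        raise ValueError(f"scaling factor must be positive, got {factor}")
    return [f * factor for f in freqs]


class SpinCheck(BaseModel):
    """Outcome of a spin-contamination check on a radical record."""

    compound_id: str
    form: str
    status: str  # "pass" | "warn" | "missing"
    s2: Optional[float] = None
    deviation: Optional[float] = None

    @property
    def ok(self) -> bool:
        return self.status == "pass"


def spin_contamination_check(
    record: SpeciesRecord, tolerance: float = DEFAULT_S2_TOLERANCE
) -> SpinCheck:
    """Check <S^2> of a doublet radical against the pure-doublet value 0.750.

    Passes iff \\|<S^2> - 0.750\\| <= tolerance (boundary inclusive); a record
    without <S^2> yields a "missing" report rather than a failure.
    """
    if record.s2_expectation is None:
        return SpinCheck(compound_id=record.compound_id, form=record.form.value, status="missing")
    dev = abs(record.s2_expectation - DEFAULT_S2_DOUBLET)
    status = "pass" if dev <= tolerance + 1e-12 else "warn"
    return SpinCheck(
        compound_id=record.compound_id,
        form=record.form.value,
        status=status,
        s2=record.s2_expectation,
        deviation=dev,
    )
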