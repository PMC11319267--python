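"""Synthetic species generation with known ground truth.

The raw enthalpies behind published scavenging-cycle tables are rarely
printed, so downstream code is validated constructively: this module
inverts the cycle definitions to build a :class:`~radscav.species.SpeciesSet`
whose enthalpies reproduce chosen BDE/IP/PDE/PA/ETE values exactly, and
atomic-population families whose Fukui/Parr condensation recovers chosen
local-descriptor vectors exactly.

Only three of the five cycle quantities are free once the reference particle
enthalpies are fixed: IP + PDE = PA + ETE = BDE + [H(H+) + H(e-) - H(H•)].
The generator therefore takes BDE, IP and PA and derives PDE and ETE;
supplying all five is allowed but they must satisfy the identity.

Randomness is confined to nuisance fields (dipole moments, <S^2> jitter
within the doublet window, the thermal-correction split, the base
populations); the descriptors themselves are seed-invariant.
"""

from __future__ import annotations

import importlib.resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import InconsistentTargetsError, InfeasibleTargetError
from .species import AtomSite, Form, PhaseSpec, SpeciesRecord, SpeciesSet
from .thermochem import GAS_REFERENCES, ReferenceEnthalpies
from .units import ev_to_hartree, kcal_to_hartree

__all__ = [
    "ThermoTargets",
    "LocalTargets",
    "AtomPopulations",
    "make_species_set",
    "make_atom_populations",
    "make_frontier_record",
    "table_fixtures",
]

IDENTITY_TOL_KCAL = 1e-9


class ThermoTargets(BaseModel):
    """Ground-truth cycle quantities (kcal/mol) for one phase.

    ``bde``, ``ip`` and ``pa`` are free; ``pde`` and ``ete`` may be given
    but must satisfy the cycle identity under the reference enthalpies in
    force, otherwise generation fails."""

    bde: float
    ip: float
    pa: float
    pde: Optional[float] = None
    ete: Optional[float] = None
    phase: PhaseSpec = Field(default_factory=PhaseSpec.gas)

    def resolved(self, refs: ReferenceEnthalpies) -> "ThermoTargets":
        """Fill in (or check) PDE and ETE via the cycle identity."""
        c = refs.cycle_constant_kcal  # H(H+)+H(e-)-H(H•), kcal/mol
        pde = self.bde + c - self.ip
        ete = self.bde + c - self.pa
        if self.pde is not None and abs(self.pde - pde) > IDENTITY_TOL_KCAL:
            raise InconsistentTargetsError(
                f"pde={self.pde} violates the cycle identity "
                f"(expected {pde} from bde/ip and the references)"
            )
        if self.ete is not None and abs(self.ete - ete) > IDENTITY_TOL_KCAL:
            raise InconsistentTargetsError(
                f"ete={self.ete} violates the cycle identity "
                f"(expected {ete} from bde/pa and the references)"
            )
        return self.model_copy(update={"pde": pde, "ete": ete})


class LocalTargets(BaseModel):
    """Ground-truth local descriptor vectors; each sums to one electron."""

    n_atoms: int = Field(ge=1)
    fukui_plus: list[float]
    fukui_minus: list[float]
    parr_plus: list[float]
    parr_minus: list[float]

    @model_validator(mode="after")
    def _check(self) -> "LocalTargets":
        for name in ("fukui_plus", "fukui_minus", "parr_plus", "parr_minus"):
            vec = getattr(self, name)
            if len(vec) != self.n_atoms:
                raise ValueError(f"{name} must have length n_atoms={self.n_atoms}")
            if abs(sum(vec) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {sum(vec)!r})")
        return self


class AtomPopulations(BaseModel):
    """Population/spin-density family produced by :func:`make_atom_populations`."""

    pop_nminus1: list[float]
    pop_n: list[float]
    pop_nplus1: list[float]
    asd_radical_cation: list[float]  # condenses to P-
    asd_radical_anion: list[float]   # condenses to P+


def make_species_set(
    targets: ThermoTargets,
    base_enthalpy: float = -1000.0,
    refs: ReferenceEnthalpies = GAS_REFERENCES,
    seed: int = 0,
    compound_id: str = "synthetic",
    site: str = "N22-H",
) -> SpeciesSet:
    """Build a species set whose cycles reproduce ``targets`` exactly.

    Enthalpies (Hartree) are obtained by inverting the cycle definitions:

        H(radical)        = H(neutral) + BDE - H(H•)
        H(radical cation) = H(neutral) + IP  - H(e-)
        H(anion)          = H(neutral) + PA  - H(H+)

    with H(neutral) = ``base_enthalpy``.  The seed only jitters nuisance
    fields: dipole moments, the electronic/thermal split of each enthalpy,
    and <S^2> of the open-shell forms within the doublet window
    [0.750, 0.760].
    """
    if refs.phase.name != targets.phase.name:
        raise InconsistentTargetsError(
            f"references are for phase {refs.phase.name.value!r} but targets "
            f"are for {targets.phase.name.value!r}"
        )
    t = targets.resolved(refs)
    rng = np.random.default_rng(seed)

    h_neutral = base_enthalpy
    h_radical = h_neutral + kcal_to_hartree(t.bde) - refs.h_hydrogen_atom
    h_cation = h_neutral + kcal_to_hartree(t.ip) - refs.h_electron
    h_anion = h_neutral + kcal_to_hartree(t.pa) - refs.h_proton

    def record(form: Form, enthalpy: float, rec_site: Optional[str]) -> SpeciesRecord:
        thermal = float(rng.uniform(0.15, 0.25))
        open_shell = form in (Form.RADICAL, Form.RADICAL_CATION)
        # a plausible closed/open-shell frontier gap; nuisance only
        e_homo = float(rng.uniform(-0.28, -0.22))
        return SpeciesRecord(
            compound_id=compound_id,
            form=form,
            site=rec_site,
            phase=targets.phase,
            enthalpy=enthalpy,
            electronic_energy=enthalpy - thermal,
            thermal_correction=thermal,
            e_homo=e_homo,
            e_lumo=e_homo + float(rng.uniform(0.10, 0.16)),
            s2_expectation=float(rng.uniform(0.750, 0.760)) if open_shell else 0.0,
            spin_multiplicity=2 if open_shell else 1,
            dipole_moment=float(rng.uniform(0.5, 7.0)),
            polarizability=float(rng.uniform(80.0, 380.0)),
            n_imaginary_freqs=0,
        )

    sset = SpeciesSet(compound_id=compound_id, phase=targets.phase)
    sset.add(record(Form.NEUTRAL, h_neutral, None))
    sset.add(record(Form.RADICAL, h_radical, site))
    sset.add(record(Form.RADICAL_CATION, h_cation, None))
    sset.add(record(Form.ANION, h_anion, site))
    return sset


def make_atom_populations(
    targets: LocalTargets, electron_count: int, seed: int = 0
) -> AtomPopulations:
    """Build population/spin vectors whose condensation recovers ``targets``.

    The N-electron base populations are a random (seeded) partition of
    ``electron_count`` over the atoms; the N+1 and N-1 systems are obtained
    by adding f+ and subtracting f-, so the Fukui differences are the
    targets by construction.  The Parr vectors pass through as the spin
    densities of the radical ions.
    """
    if electron_count <= 1:
        raise ValueError("electron_count must exceed 1")
    rng = np.random.default_rng(seed)
    fplus = np.asarray(targets.fukui_plus, float)
    fminus = np.asarray(targets.fukui_minus, float)
    base = rng.dirichlet(np.full(targets.n_atoms, 5.0)) * electron_count
    pop_nplus1 = base + fplus
    pop_nminus1 = base - fminus
    if (pop_nplus1 < 0).any() or (pop_nminus1 < 0).any() or (base < 0).any():
        raise InfeasibleTargetError(
            "targets would require negative atomic populations at this "
            "electron count"
        )
    return AtomPopulations(
        pop_nminus1=pop_nminus1.tolist(),
        pop_n=base.tolist(),
        pop_nplus1=pop_nplus1.tolist(),
        asd_radical_cation=list(targets.parr_minus),
        asd_radical_anion=list(targets.parr_plus),
    )


def make_frontier_record(
    ip_ev: float,
    ea_ev: float,
    compound_id: str = "synthetic",
    phase: Optional[PhaseSpec] = None,
    seed: int = 0,
) -> SpeciesRecord:
    """Neutral record whose Koopmans route recovers (ip_ev, ea_ev) exactly:
    e_HOMO = -IP, e_LUMO = -EA."""
    if ea_ev > ip_ev:
        raise InconsistentTargetsError("EA above IP would put the LUMO below the HOMO")
    rng = np.random.default_rng(seed)
    return SpeciesRecord(
        compound_id=compound_id,
        form=Form.NEUTRAL,
        phase=phase or PhaseSpec.gas(),
        enthalpy=float(rng.uniform(-1500.0, -500.0)),
        e_homo=ev_to_hartree(-ip_ev),
        e_lumo=ev_to_hartree(-ea_ev),
        dipole_moment=float(rng.uniform(0.5, 7.0)),
    )


def attach_atoms(record: SpeciesRecord, elements: list[str], populations, spins=None) -> SpeciesRecord:
    """Return a copy of ``record`` carrying per-atom populations."""
    atoms = [
        AtomSite(
            index=i + 1,
            element=elements[i],
            population=float(populations[i]),
            spin_density=None if spins is None else float(spins[i]),
        )
        for i in range(len(elements))
    ]
    return record.model_copy(update={"atoms": atoms})


# --------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str):
    return importlib.resources.files("radscav.data").joinpath(name)


def table_fixtures() -> dict:
    """Load the packaged descriptor tables (printed-precision values).

    Returns a dict with DataFrames under ``"global"`` (per-compound global
    descriptors), ``"thermo_gas"`` and ``"thermo_solvent"`` (cycle
    quantities in kcal/mol), plus the ``"manifest"`` describing provenance
    and printed precision of each table.
    """
    with _data_path("manifest.yaml").open() as fh:
        manifest = yaml.safe_load(fh)
    out: dict = {"manifest": manifest}
    for key, entry in manifest["tables"].items():
        with _data_path(entry["file"]).open() as fh:
            out[key] = pd.read_csv(fh)
    return out
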