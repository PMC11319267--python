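"""Energy units and conversions.

All cycle arithmetic inside the package is done in Hartree; thermochemical
quantities are reported in kcal/mol and orbital-derived descriptors in eV,
mirroring how these quantities are conventionally tabulated.
"""

from __future__ import annotations

from enum import Enum

#: 1 Hartree in kcal/mol (CODATA-consistent conversion used throughout).
HARTREE_TO_KCAL_PER_MOL: float = 627.5095

#: 1 Hartree in electronvolt.
HARTREE_TO_EV: float = 27.211386


class EnergyUnit(str, Enum):
    HARTREE = "hartree"
    KCAL_PER_MOL = "kcal_per_mol"
    EV = "eV"


# factors to convert FROM hartree TO the unit
_FROM_HARTREE = {
    EnergyUnit.HARTREE: 1.0,
    EnergyUnit.KCAL_PER_MOL: HARTREE_TO_KCAL_PER_MOL,
    EnergyUnit.EV: HARTREE_TO_EV,
}


def convert_energy(value: float, from_unit: EnergyUnit | str, to_unit: EnergyUnit | str) -> float:
    """Convert an energy between hartree, kcal/mol and eV.

    The conversion is an exact linear rescaling through Hartree, so
    ``convert_energy(convert_energy(x, a, b), b, a)`` recovers ``x`` to
    machine precision.

    Raises
    ------
    ValueError
        If either unit name is not one of the supported units.
    """
    try:
        f = EnergyUnit(from_unit)
        t = EnergyUnit(to_unit)
    except ValueError as exc:
        raise ValueError(f"unknown energy unit: {exc}") from None
    if f is t:
        return value
    return value * (_FROM_HARTREE[t] / _FROM_HARTREE[f])


def hartree_to_kcal(value: float) -> float:
    return value * HARTREE_TO_KCAL_PER_MOL


def kcal_to_hartree(value: float) -> float:
    return value / HARTREE_TO_KCAL_PER_MOL


def hartree_to_ev(value: float) -> float:
    return value * HARTREE_TO_EV


def ev_to_hartree(value: float) -> float:
    return value / HARTREE_TO_EV
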