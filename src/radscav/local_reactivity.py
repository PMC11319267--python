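"""Condensed Fukui functions, dual descriptor and Parr functions.

Per-atom electron populations p_k of the N-1, N and N+1 electron systems
condense the Fukui function:

    f+_k = p_k(N+1) - p_k(N)     (propensity for nucleophilic attack)
    f-_k = p_k(N)   - p_k(N-1)   (propensity for electrophilic attack)
    df_k = f+_k - f-_k           (dual descriptor)

Each Fukui vector sums to 1 electron and the dual descriptor to 0 when the
input populations are electron-count consistent.  Parr functions are the
atomic spin densities of the vertical radical ions:

    P-_k = ASD_k(radical cation)   (marks electrophilic-attack sites)
    P+_k = ASD_k(radical anion)    (marks nucleophilic-attack sites)

summing to the total spin of the respective doublet (1 unpaired electron).

Condensation is population-based; atomic charges q_k can be converted via
p_k = Z_k - q_k before use.  The population-analysis scheme
(Mulliken/Hirshfeld/NPA) is whatever produced the inputs and travels as
metadata; the arithmetic here is scheme-agnostic.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ElectronCountWarning, NormalizationWarning

__all__ = [
    "fukui_plus",
    "fukui_minus",
    "dual_descriptor",
    "parr_functions",
    "populations_from_charges",
    "local_descriptor_table",
    "classify_sites",
]

DEFAULT_SITE_THRESHOLD = 0.05  # electrons
SUM_TOLERANCE = 0.01
PARR_SUM_TOLERANCE = 0.05


def _as_vectors(a: Sequence[float], b: Sequence[float], what: str) -> tuple[np.ndarray, np.ndarray]:
    va, vb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if va.shape != vb.shape or va.ndim != 1:
        raise ValueError(f"{what}: vectors must be 1-d and of equal length")
    return va, vb


def _check_difference_sum(diff: np.ndarray, what: str) -> None:
    total = float(diff.sum())
    if abs(total - 1.0) > SUM_TOLERANCE:
        warnings.warn(
            f"{what} sums to {total:.4f}, expected 1 (inputs may not differ "
            "by one electron)",
            ElectronCountWarning,
            stacklevel=3,
        )


def fukui_plus(pop_n: Sequence[float], pop_nplus1: Sequence[float]) -> np.ndarray:
    """Condensed f+ = p(N+1) - p(N), per atom."""
    pn, pp = _as_vectors(pop_n, pop_nplus1, "fukui_plus")
    out = pp - pn
    _check_difference_sum(out, "f+")
    return out


def fukui_minus(pop_n: Sequence[float], pop_nminus1: Sequence[float]) -> np.ndarray:
    """Condensed f- = p(N) - p(N-1), per atom."""
    pn, pm = _as_vectors(pop_n, pop_nminus1, "fukui_minus")
    out = pn - pm
    _check_difference_sum(out, "f-")
    return out


def dual_descriptor(fplus: Sequence[float], fminus: Sequence[float]) -> np.ndarray:
    """Dual descriptor df = f+ - f-.

    Positive entries mark electrophilic atoms (prone to nucleophilic
    attack), negative entries nucleophilic atoms."""
    fp, fm = _as_vectors(fplus, fminus, "dual_descriptor")
    return fp - fm


def parr_functions(
    asd_radical_cation: Sequence[float], asd_radical_anion: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Parr functions (P-, P+) from atomic spin densities of the radical ions.

    Returns ``(p_minus, p_plus)``.  Each vector should sum to ~1 for a
    doublet radical; larger deviations raise a NormalizationWarning."""
    pc, pa = np.asarray(asd_radical_cation, float), np.asarray(asd_radical_anion, float)
    for name, vec in (("P- (radical-cation ASD)", pc), ("P+ (radical-anion ASD)", pa)):
        total = float(vec.sum())
        if abs(total - 1.0) > PARR_SUM_TOLERANCE:
            warnings.warn(
                f"{name} sums to {total:.4f}, expected ~1 for a doublet",
                NormalizationWarning,
                stacklevel=2,
            )
    return pc, pa


def populations_from_charges(charges: Sequence[float], atomic_numbers: Sequence[int]) -> np.ndarray:
    """Convert atomic charges to electron populations, p_k = Z_k - q_k."""
    q, z = np.asarray(charges, float), np.asarray(atomic_numbers, float)
    if q.shape != z.shape:
        raise ValueError("charges and atomic numbers must have equal length")
    return z - q


def local_descriptor_table(
    elements: Sequence[str],
    pop_nminus1: Sequence[float],
    pop_n: Sequence[float],
    pop_nplus1: Sequence[float],
    asd_radical_cation: Optional[Sequence[float]] = None,
    asd_radical_anion: Optional[Sequence[float]] = None,
    indices: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Assemble the per-atom local-descriptor table.

    Columns: atom_index, element, fukui_plus, fukui_minus, dual, and (when
    spin densities are given) parr_minus / parr_plus.  Atom indices are
    1-based by default, matching structure labels like N22."""
    n = len(elements)
    idx = list(indices) if indices is not None else list(range(1, n + 1))
    fp = fukui_plus(pop_n, pop_nplus1)
    fm = fukui_minus(pop_n, pop_nminus1)
    df = pd.DataFrame(
        {
            "atom_index": idx,
            "element": list(elements),
            "fukui_plus": fp,
            "fukui_minus": fm,
            "dual": dual_descriptor(fp, fm),
        }
    )
    if asd_radical_cation is not None and asd_radical_anion is not None:
        p_minus, p_plus = parr_functions(asd_radical_cation, asd_radical_anion)
        df["parr_minus"] = p_minus
        df["parr_plus"] = p_plus
    return df


def classify_sites(
    rows: pd.DataFrame, threshold: float = DEFAULT_SITE_THRESHOLD
) -> pd.DataFrame:
    """Annotate a local-descriptor table with site classes.

    dual > +threshold -> "electrophilic"; dual < -threshold ->
    "nucleophilic"; otherwise "ambiphilic/neutral".  The per-molecule argmax
    of P+ is flagged as the primary nucleophilic-attack site and the argmax
    of P- as the primary electrophilic-attack site.  Classification depends
    only on per-atom values, so it is invariant under atom reordering."""
    out = rows.copy()
    dual = out["dual"].to_numpy(dtype=float)
    site_class = np.where(
        dual > threshold,
        "electrophilic",
        np.where(dual < -threshold, "nucleophilic", "ambiphilic/neutral"),
    )
    out["site_class"] = site_class
    if "parr_plus" in out.columns:
        flags = np.zeros(len(out), dtype=bool)
        flags[int(np.argmax(out["parr_plus"].to_numpy(float)))] = True
        out["primary_nucleophilic_site"] = flags
    if "parr_minus" in out.columns:
        flags = np.zeros(len(out), dtype=bool)
        flags[int(np.argmax(out["parr_minus"].to_numpy(float)))] = True
        out["primary_electrophilic_site"] = flags
    return out
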