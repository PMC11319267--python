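"""Mechanism preference, compound ranking and report rendering.

The thermodynamically preferred scavenging route of a compound/site/phase is
decided by the smallest *first-step* enthalpy among

    HAT:    BDE     (one-step H-atom donation)
    SET-PT: IP      (electron transfer before deprotonation)
    SPLET:  PA      (proton loss before electron transfer)

which is the standard thermodynamic convention: the route whose entry
channel costs least dominates.  The two-step totals (IP+PDE, PA+ETE) are
reported alongside but do not drive the verdict — they both equal
BDE + const and so cannot discriminate between the routes.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence, TextIO, Union

import pandas as pd
from pydantic import BaseModel

from .species import Mechanism, PhaseSpec
from .thermochem import CycleResult

__all__ = ["MechanismVerdict", "preferred_mechanism", "rank_compounds", "render_report"]

#: On exact ties the earlier mechanism in this order wins.
TIE_BREAK_ORDER = (Mechanism.HAT, Mechanism.SPLET, Mechanism.SETPT)

KCAL_DECIMALS = 2
EV_DECIMALS = 3


class MechanismVerdict(BaseModel):
    compound_id: str
    site: Optional[str]
    phase: PhaseSpec
    first_step_enthalpies: dict[Mechanism, float]
    totals: dict[Mechanism, float]
    preferred: Mechanism
    margin: Optional[float]  # kcal/mol; None when only one mechanism is available
    excluded: list[Mechanism] = []


def preferred_mechanism(
    cycle: Union[CycleResult, Mapping[str, Optional[float]]],
) -> MechanismVerdict:
    """Decide the preferred mechanism from one cycle result.

    Accepts a :class:`CycleResult` or a mapping with keys ``bde``, ``ip``,
    ``pa`` (and optionally ``pde``, ``ete``, ``compound_id``, ``site``,
    ``phase``); quantities that are absent exclude their mechanism from the
    verdict and are flagged in ``excluded``.
    """
    if isinstance(cycle, CycleResult):
        first = {
            Mechanism.HAT: cycle.bde,
            Mechanism.SETPT: cycle.ip,
            Mechanism.SPLET: cycle.pa,
        }
        totals = {
            Mechanism.HAT: cycle.bde,
            Mechanism.SETPT: cycle.setpt_total,
            Mechanism.SPLET: cycle.splet_total,
        }
        compound_id, site, phase = cycle.compound_id, cycle.site, cycle.phase
    else:
        getters = {
            Mechanism.HAT: cycle.get("bde"),
            Mechanism.SETPT: cycle.get("ip"),
            Mechanism.SPLET: cycle.get("pa"),
        }
        first = {m: v for m, v in getters.items() if v is not None and math.isfinite(v)}
        totals = dict(first)
        if cycle.get("ip") is not None and cycle.get("pde") is not None:
            totals[Mechanism.SETPT] = cycle["ip"] + cycle["pde"]
        if cycle.get("pa") is not None and cycle.get("ete") is not None:
            totals[Mechanism.SPLET] = cycle["pa"] + cycle["ete"]
        compound_id = str(cycle.get("compound_id", "?"))
        site = cycle.get("site")
        phase = cycle.get("phase") or PhaseSpec.gas()
        if isinstance(phase, str):
            phase = PhaseSpec.named(phase)
    excluded = [m for m in TIE_BREAK_ORDER if m not in first]
    if not first:
        raise ValueError("no first-step enthalpy available for any mechanism")
    best = min(first, key=lambda m: (first[m], TIE_BREAK_ORDER.index(m)))
    others = sorted(v for m, v in first.items() if m is not best)
    margin = (others[0] - first[best]) if others else None
    return MechanismVerdict(
        compound_id=compound_id,
        site=site,
        phase=phase,
        first_step_enthalpies=first,
        totals=totals,
        preferred=best,
        margin=margin,
        excluded=excluded,
    )


def rank_compounds(
    table: pd.DataFrame,
    key: str,
    direction: str = "ascending",
    decimals: int = None,
) -> str:
    """Order compounds by a descriptor column, grouping printed-precision ties.

    Values are rounded to the report precision (3 decimals for eV-scale
    descriptors, 2 for kcal/mol; override with ``decimals``); compounds that
    agree after rounding are joined with `` = `` and groups with `` < ``
    (ascending) or `` > ``.  Equal groups and the whole ordering use the
    compound label as the deterministic secondary sort.  If a compound
    appears on several rows (one per site), its smallest value is ranked.
    """
    if key not in table.columns:
        raise KeyError(f"unknown descriptor column {key!r}")
    if direction not in ("ascending", "descending"):
        raise ValueError(f"direction must be ascending/descending, got {direction!r}")
    if decimals is None:
        decimals = KCAL_DECIMALS if table[key].abs().max() > 50 else EV_DECIMALS
    per_compound = (
        table.groupby("compound_id", sort=False)[key].min().reset_index()
    )
    per_compound["rounded"] = per_compound[key].round(decimals)
    per_compound = per_compound.sort_values(
        ["rounded", "compound_id"],
        ascending=[direction == "ascending", True],
        kind="stable",
    )
    groups: list[list[str]] = []
    last = object()
    for _, row in per_compound.iterrows():
        if row["rounded"] != last:
            groups.append([])
            last = row["rounded"]
        groups[-1].append(str(row["compound_id"]))
    joiner = " < " if direction == "ascending" else " > "
    return joiner.join(" = ".join(sorted(g)) for g in groups)


def _markdown_table(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = []
        for c in df.columns:
            v = row[c]
            if isinstance(v, float):
                cells.append(f"{v:g}")
            else:
                cells.append("" if v is None else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def verdicts_frame(verdicts: Sequence[MechanismVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append(
            {
                "compound_id": v.compound_id,
                "site": v.site,
                "phase": v.phase.name.value,
                "bde": v.first_step_enthalpies.get(Mechanism.HAT),
                "ip": v.first_step_enthalpies.get(Mechanism.SETPT),
                "pa": v.first_step_enthalpies.get(Mechanism.SPLET),
                "preferred": v.preferred.value,
                "margin": v.margin,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["compound_id", "site", "phase", "bde", "ip", "pa", "preferred", "margin"],
    )


def render_report(
    tables: Mapping[str, pd.DataFrame],
    verdicts: Sequence[MechanismVerdict],
    sink: Union[str, Path, TextIO],
    format: str = "markdown",
) -> None:
    """Write named tables plus the mechanism verdicts, byte-deterministically.

    ``format="markdown"`` renders pipe tables with section headings;
    ``format="delimited"`` concatenates CSV blocks, each preceded by a
    ``# table: <name>`` comment."""
    if format not in ("markdown", "delimited"):
        raise ValueError(f"unknown format {format!r}")
    sections: list[tuple[str, pd.DataFrame]] = list(tables.items())
    if verdicts:
        sections.append(("mechanism verdicts", verdicts_frame(list(verdicts))))
    elif not tables:
        sections.append(("mechanism verdicts", verdicts_frame([])))
    parts: list[str] = []
    for name, df in sections:
        if format == "markdown":
            parts.append(f"## {name}\n")
            parts.append(_markdown_table(df) + "\n")
        else:
            parts.append(f"# table: {name}")
            parts.append(df.to_csv(index=False).rstrip("\n"))
    text = "\n".join(parts) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)
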