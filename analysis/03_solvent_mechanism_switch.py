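#!/usr/bin/env python
"""Mechanism preference across phases: where does SPLET take over?

Applies the argmin-of-first-step rule (smallest of BDE, IP, PA) to every
row of the packaged gas and solvent cycle tables.  In the gas phase the
proton affinities are enormous (~320-390 kcal/mol) and HAT wins everywhere;
polar solvation collapses PA (to ~31 kcal/mol for 4k N22-H in water) and
flips the verdict to SPLET, while the nonpolar cyclohexane phase stays HAT.

Writes results/mechanism_verdicts.csv.
"""

from pathlib import Path

import pandas as pd

import radscav as r
from radscav.report import verdicts_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fixtures = r.table_fixtures()
    gas = fixtures["thermo_gas"].copy()
    gas["phase"] = "gas"
    both = pd.concat([gas, fixtures["thermo_solvent"]], ignore_index=True)

    verdicts = [
        r.preferred_mechanism(row.dropna().to_dict()) for _, row in both.iterrows()
    ]
    frame = verdicts_frame(verdicts)

    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "mechanism_verdicts.csv", index=False)

    counts = frame.groupby(["phase", "preferred"]).size()
    print("verdict counts by phase:")
    print(counts.to_string())
    print()
    k4 = frame[(frame.compound_id == "4k") & (frame.site == "N22-H")]
    print("compound 4k, N22-H site:")
    for _, row in k4.iterrows():
        print(
            f"  {row.phase:>11s}: BDE {row.bde:7.2f}  IP {row.ip:7.2f}  "
            f"PA {row.pa:7.2f}  -> {row.preferred} (margin {row.margin:.2f})"
        )
    print("wrote", OUT / "mechanism_verdicts.csv")


if __name__ == "__main__":
    main()
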