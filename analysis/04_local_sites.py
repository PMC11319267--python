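#!/usr/bin/env python
"""Local reactivity: Fukui/dual/Parr site analysis on a synthetic 4k-like
pattern.

The published per-atom descriptor table for these compounds uses an
unstated scale and cannot be reproduced numerically, so this driver works
on a synthetic atom set that encodes the qualitative pattern the structures
show: the exocyclic amine nitrogen (labelled N22) carries the most negative
dual descriptor and the largest P+ — the primary nucleophilic site that
makes it the favoured electron-donation centre.

Writes results/local_sites.csv.
"""

from pathlib import Path

import radscav as r
from radscav.local_reactivity import classify_sites, local_descriptor_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    # synthetic ground truth, 6 atoms around the amine (values are invented
    # to mimic the qualitative 4k ranking, not taken from any publication)
    elements = ["C", "C", "C", "N", "C", "N"]
    indices = [2, 19, 21, 22, 23, 18]
    targets = r.LocalTargets(
        n_atoms=6,
        fukui_plus=[0.32, 0.28, 0.18, 0.04, 0.10, 0.08],
        fukui_minus=[0.06, 0.08, 0.12, 0.52, 0.10, 0.12],
        parr_plus=[0.05, 0.08, 0.07, 0.62, 0.08, 0.10],   # radical-anion ASD
        parr_minus=[0.38, 0.30, 0.12, 0.06, 0.08, 0.06],  # radical-cation ASD
    )
    pops = r.make_atom_populations(targets, electron_count=60, seed=42)
    table = local_descriptor_table(
        elements,
        pops.pop_nminus1, pops.pop_n, pops.pop_nplus1,
        pops.asd_radical_cation, pops.asd_radical_anion,
        indices=indices,
    )
    annotated = classify_sites(table)

    OUT.mkdir(exist_ok=True)
    annotated.to_csv(OUT / "local_sites.csv", index=False)

    print(annotated.round(3).to_string(index=False))
    primary = annotated[annotated.primary_nucleophilic_site].iloc[0]
    print()
    print(
        f"primary nucleophilic site: {primary.element}{primary.atom_index} "
        f"(dual {primary.dual:+.3f}, P+ {primary.parr_plus:.2f})"
    )
    print("wrote", OUT / "local_sites.csv")


if __name__ == "__main__":
    main()
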