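# Packaged reference-table fixtures.
# Values are stored exactly as printed in the source tables (decimal strings),
# so every number carries printed precision, not recomputed precision.
tables:
  global:
    file: table1_global.csv
    description: >
      Gas-phase global reactivity descriptors for compounds 4a-4l and
      ascorbic acid: vertical IE and EA (eV), chemical potential mu,
      electronegativity chi, softness S (eV^-1), hardness eta (eV),
      electrophilicity omega (eV), nucleophilicity N (eV), dipole moment
      (Debye) and isotropic polarizability (a.u.).
    precision:
      energies_ev: 0.005   # printed to 3 decimals (some rows fewer)
      softness_inv_ev: 0.002
    notes: >
      The nucleophilicity column depends on an unstated reference HOMO and
      cannot be recomputed from IE/EA alone; it is carried as data only.
  thermo_gas:
    file: table3_gas.csv
    description: >
      Gas-phase BDE, IP, PDE, PA, ETE and the SET-PT / SPLET totals
      (kcal/mol) for the lowest N-H/O-H and C-H sites of 4a-4l and
      ascorbic acid.
    precision:
      components_kcal: 0.005
      totals_kcal: 0.02    # rounding accumulates in printed sums
    notes: >
      The printed SET-PT and SPLET totals differ by a constant ~0.73
      kcal/mol on every row, showing the source closed the two cycles with
      different H+/e- reference enthalpies.
  thermo_solvent:
    file: table4_solvents.csv
    description: >
      BDE, IP, PDE, PA, ETE and totals (kcal/mol) for compound 4k and
      ascorbic acid in water, methanol and cyclohexane (IEFPCM phases).
    precision:
      components_kcal: 0.005
      totals_kcal: 0.02
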