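# Methods

## Scope and data model

The package analyses *summaries* of quantum-chemistry calculations, never
wavefunctions or geometries. The unit of data is a `SpeciesRecord`: one
(compound, species form, phase) with its enthalpy (298.15 K, 1 atm
convention assumed upstream), electronic energy and thermal correction,
frontier-orbital energies, ⟨S²⟩, multiplicity, dipole, polarizability and
optional per-atom populations/spin densities. A `SpeciesSet` collects the
forms one compound needs in one phase: neutral AH, site-resolved radical
A•, radical cation AH•⁺, site-resolved anion A⁻ (the cation and radical
anion are accepted for completeness but enter no cycle).

Energies are stored and manipulated in Hartree; kcal/mol (thermochemistry)
and eV (orbital-derived descriptors) appear only at reporting boundaries,
using 1 Ha = 627.5095 kcal/mol = 27.211386 eV. The species-table format is
delimited text with an explicit per-column unit declaration in a `#` header
block — no unit guessing — plus an equivalent JSON dialect. Floats are
serialized with shortest round-trip `repr`, so write→read reproduces every
field exactly. Parsing real QC log files is out of scope; the species table
is the contract, and whatever produced it is recorded as metadata.

## Thermochemical cycles

The three scavenging routes are evaluated from enthalpy differences plus
the reference particle enthalpies H(H•), H(H⁺), H(e⁻):

    BDE = H(A•)   + H(H•) − H(AH)          (HAT)
    IP  = H(AH•⁺) + H(e⁻) − H(AH)          (SET-PT, step 1)
    PDE = H(A•)   + H(H⁺) − H(AH•⁺)        (SET-PT, step 2)
    PA  = H(A⁻)   + H(H⁺) − H(AH)          (SPLET, step 1)
    ETE = H(A•)   + H(e⁻) − H(A⁻)          (SPLET, step 2)

Two exact identities follow and are used as invariants: translation of all
enthalpies by a constant changes nothing, and

    IP + PDE = PA + ETE = BDE + [H(H⁺) + H(e⁻) − H(H•)].

`cycle_residual` returns (IP+PDE) − (PA+ETE); it is zero to ≲1e-13 kcal/mol
for any single species set evaluated with one reference set. On the
packaged printed tables it is a *constant* ≈0.73 kcal/mol instead, which is
diagnostic: the source closed its SET-PT and SPLET columns with different
H⁺/e⁻ reference enthalpies. The package surfaces this rather than hiding
it, and therefore treats the references as explicit configuration.

**Reference enthalpies.** Gas-phase defaults: H(H•) = −0.5 Hartree (the
value used in the source calculations; the hydrogen atom's translational
enthalpy is folded into the convention), H(H⁺) = +1.483 kcal/mol and
H(e⁻) = +0.752 kcal/mol (the standard literature gas-phase values). Solvent
phases have *no* defaults: solvated proton/electron enthalpies depend on the
solvation model and must be supplied (YAML `references:` section, per phase,
value+unit). This is deliberate — silent defaults in solvent are the main
way published cycle tables become irreproducible.

**Radical QC.** `spin_contamination_check` passes a doublet iff
|⟨S²⟩ − 0.750| ≤ 0.05 (boundary inclusive); a missing ⟨S²⟩ is reported as
missing data, not failure. Harmonic frequencies, when present, are scaled
by 0.9669 by default before any downstream use.

## Global descriptors

From vertical IE/EA in eV: μ = −(IE+EA)/2, χ = −μ, η, S = 1/η, ω = μ²/2η.
Two conventions for hardness circulate; the package defaults to
**η = IE − EA** (no ½), because the reference table it reproduces uses that
convention on every row, and exposes the Parr–Pearson η = (IE−EA)/2 as
`half_factor=True`. ω always uses whichever η it is handed, keeping the two
self-consistent. A negative EA (ascorbic acid) is legal input.

The Koopmans route uses the physically standard signs IP = −ε_HOMO,
EA = −ε_LUMO and gap = ε_LUMO − ε_HOMO. Relative nucleophilicity
N = ε_HOMO − ε_HOMO(reference) requires an explicit reference orbital
energy; the reference system behind the packaged N column is not stated in
the source, so that column is carried as data and never recomputed (the
test suite checks structurally that IE + N is *not* constant across rows,
i.e. no single reference can regenerate it).

The ΔSCF route computes vertical IP/EA from total-energy differences of the
neutral and its vertical radical ions when those records are present. The
package does not assert that ΔSCF and Koopmans routes agree; both are
exposed.

## Local descriptors

Condensation is population-based: f⁺ = p(N+1) − p(N), f⁻ = p(N) − p(N−1),
Δf = f⁺ − f⁻, with Σf± = 1 and ΣΔf = 0 for electron-count-consistent
inputs (checked at 1e-6; a difference vector whose sum strays from 1 by
more than 0.01 warns). Atomic charges are converted via p = Z − q if
supplied. Parr functions pass through the atomic spin densities of the
radical cation (P⁻) and radical anion (P⁺), warning when a doublet's ASD
sum strays from 1 by more than 0.05.

Site classification uses a threshold rather than bare sign: Δf > +0.05 e →
electrophilic, Δf < −0.05 e → nucleophilic, else ambiphilic/neutral
(sign-only labelling over-classifies near-zero atoms; the threshold is
configurable). The per-molecule argmax of P⁺ and of P⁻ are flagged as
primary attack sites. The published per-atom table for these compounds
prints values far outside the [−1, 1] electron range of normalized
condensation on an unstated scale, so it is *not* used as a numeric target
anywhere; only its qualitative ranking (amine N as primary nucleophilic
site with the most negative Δf and the largest P⁺) informs the synthetic
patterns in tests and `analysis/04_local_sites.py`.

## Mechanism verdicts and rankings

The preferred mechanism is the argmin of the *first-step* enthalpies
{BDE, IP, PA}. The two-step totals cannot discriminate (both equal
BDE + constant), which is why the convention keys on entry channels; totals
are reported alongside. Exact ties break deterministically HAT → SPLET →
SET-PT, and the verdict carries the margin to the runner-up. Missing
quantities exclude their mechanism and are flagged rather than failing.

`rank_compounds` orders compounds by a descriptor at report precision
(2 decimals kcal/mol, 3 decimals eV-scale, overridable), joins
printed-precision ties with `=` (secondary sort: compound label) and groups
with `<`/`>`. On the packaged softness column this yields a three-way tie
`4d = 4g = 4k` at 0.156 eV⁻¹ — sub-precision order is unknowable from
printed data, so the tie is reported as a tie.

## Synthetic generator

Because published cycle tables print derived quantities but not raw
enthalpies, correctness is established constructively. `make_species_set`
inverts the cycle equations: given ground-truth (BDE, IP, PA), a base
neutral enthalpy and reference enthalpies, it places

    H(A•)   = H(AH) + BDE − H(H•)
    H(AH•⁺) = H(AH) + IP  − H(e⁻)
    H(A⁻)   = H(AH) + PA  − H(H⁺)

so re-analysis recovers the targets to ≤1e-9 kcal/mol (measured ≈2e-10 at
enthalpy magnitudes up to 2000 Ha; the bound is double-precision rounding
through the difference arithmetic). Only three of the five quantities are
free once the references are fixed; PDE and ETE are derived, and
explicitly supplied values that violate the identity are rejected.
Randomness touches nuisance fields only — dipole, polarizability, the
electronic/thermal split, orbital placement, and ⟨S²⟩ jittered inside
[0.750, 0.760] so generated doublets always pass the spin QC — and is
governed by a seed; descriptors are seed-invariant.

`make_atom_populations` does the same for local descriptors: a seeded
Dirichlet partition of the electron count forms the N-electron base
populations, f⁺/f⁻ are added/subtracted to form the N±1 systems (negative
populations → infeasible-target error), and the Parr vectors pass through.
Recovery is exact up to floating arithmetic.

What the generator does *not* emulate: correlated noise between forms,
basis-set or solvation-model error, spin contamination beyond the doublet
window, multiple conformers, or realistic orbital structure. Passing the
constructive tests therefore demonstrates that the cycle/descriptor
*arithmetic and bookkeeping* are exact, not that any electronic-structure
protocol is accurate.

## Packaged reference tables

Three delimited fixtures (plus a manifest) store the published values for
compounds 4a–4l and ascorbic acid *as printed*, as decimal strings: global
descriptors (gas), cycle quantities (gas; 13 compounds × 2 sites), and
cycle quantities for 4k and ascorbic acid in water/methanol/cyclohexane.
Comparisons against them use printed-precision tolerances: ±0.005 eV for
energy-scale descriptors, ±0.002 eV⁻¹ for softness, ±0.005 kcal/mol for
cycle components and ±0.02 kcal/mol for the two-step sums (rounding of two
addends accumulates). Known quirks retained as printed: the softness and
hardness columns carry each other's units in the source header (values are
stored under their physically correct names); one compound's dipole is
printed with four decimals; the polarizability column follows the table
over the contradicting prose ordering; the prose list of HOMO–LUMO gaps is
internally inconsistent and is not used as a target.

## Problem sizes and determinism

The full test suite runs in about a second: the reconstruction checks are
closed-form over 13 compounds / 26–38 table rows, and the property tests
use 100 random target draws (hypothesis derandomised, plus a fixed-seed
100-draw loop) — enough to exercise the double-precision error envelope,
which is scale- not sample-limited. `scripts/acceptance.py` repeats the
same computations from scratch; its `--seed` controls all stochastic
draws, and all table-derived outputs are bit-deterministic.
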