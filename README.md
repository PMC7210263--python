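# rxnforge

Automated generation and curation of elementary-reaction datasets for
gas-phase H/C/N/O chemistry.

Quantitative reaction data — activation energies and reaction enthalpies
attached to atom-mapped reaction SMILES — are scarce in the big reaction
databases, yet they are exactly what kinetics-aware synthesis planning and
mechanism generation need. One productive way to build such data is
automated potential-energy-surface exploration: start from a pool of stable
reactant molecules, seed a single-ended string-path optimizer with every
chemically sensible *driving coordinate* (a small set of bonds to break and
non-bonded pairs to form), harvest the transition states and products the
paths discover, and then filter hard, because path optimizers are fallible.

`rxnforge` implements everything around the quantum-chemistry engine in
that workflow, at desk scale and fully testable:

- **Connectivity graphs** (`rxnforge.molgraph`) — element-labeled,
  explicit-hydrogen graphs with topological-symmetry perception,
  per-element degree windows (H = 1, C = 2–4, N = 1–3, O = 1–2), and
  deterministic connectivity-only graph isomorphism.
- **Driving-coordinate enumeration** (`rxnforge.driving`) — exhaustive
  within the counting limits (≤ 2 breaks, ≤ 2 formations, 2–3 total
  changes), valence-screened on the formal product, with
  equivalent-hydrogen deduplication; a literal brute-force oracle ships
  alongside for cross-checking.
- **Engine I/O** (`rxnforge.qcio`) — versioned minimal dialects for
  opt+frequency logs and string-path outputs, XYZ, engine input files, and
  mock-file writers that round-trip exactly.
- **Perception** (`rxnforge.perception`) — covalent-radius connectivity
  from 3D geometries, bond orders by maximum valence saturation,
  fixed-hydrogen InChI identity keys (tautomer-distinguishing), and
  atom-map reconstruction by graph isomorphism into mapped reaction
  SMILES.
- **Verification** (`rxnforge.verify`) — the transition-state filter
  stack: exactly one imaginary frequency, |ν̃‡| ≥ 100 cm⁻¹, ≤ 3 kcal/mol
  energy drift against the string-path maximum, endpoints true minima, and
  the decisive normal-mode check that the imaginary-mode displacements
  along the changing bonds exceed those along every unchanged bond.
- **Energetics** (`rxnforge.energetics`) — harmonic ZPE
  (½·Σ hc·ν̃ over real modes) and 0 K ZPE-corrected barriers
  Ea = E₀(TS) − E₀(R) and enthalpies ΔH = Σ E₀(P) − E₀(R) in kcal/mol.
- **Pipeline** (`rxnforge.pipeline`) — stage-resumable campaign
  orchestration behind a pluggable executor contract, duplicate retention
  (up to four lowest-barrier candidates per reaction), final
  lowest-barrier deduplication, a two-level refinement pass, and dataset
  assembly (`idx,rsmi,psmi,ea,dh` CSV next to `rxn######` directories of
  `r/p/ts######.log` files).
- **Mock engine** (`rxnforge.mocks`) — a deterministic stand-in executor
  that synthesizes physically shaped logs, string paths and planted
  imaginary modes, so the full pipeline runs and is tested without any
  electronic-structure code.
- **Analysis** (`rxnforge.analyze`) — bond-change counting and
  classification, reactive-center templates, template ranking, and
  Gaussian kernel density estimates over (ΔH, Ea).

## Worked example

Enumerate driving coordinates for a few reactants (0-based atom pairs,
breaks then formations):

```text
$ printf "O\nC\nCO\n" > smi.txt
$ rxnforge enumerate smi.txt
C	0-1;0-2	1-2
CO	0-1;0-2	1-2
CO	0-2;0-3	2-3
CO	0-2;1-5	2-5
```

Water admits no feasible multi-change coordinate (every candidate either
strands the oxygen or gives a hydrogen two bonds); methane admits exactly
one equivalence class (detach two hydrogens, pair them); methanol three.

Run a full campaign with the built-in mock engine and inspect the result:

```text
$ rxnforge run smi.txt --workdir run --seed 3 --n-conformers 10
4 reactions -> run/dataset/reactions.csv
$ head -2 run/dataset/reactions.csv
idx,rsmi,psmi,ea,dh
0,[C:1]([H:2])([H:3])([H:4])[H:5],[C:1]([H:4])[H:5].[H:2][H:3],38.866974,12.608831
```

Row 0 is CH₄ → CH₂ + H₂ with a 38.9 kcal/mol barrier and a reaction
enthalpy of +12.6 kcal/mol (synthetic numbers from the mock energy model;
the layout, mapping and arithmetic are the real thing). Each reaction
also gets a `rxn000000/` directory holding its reactant, product and TS
logs. Re-verify any triple from its files:

```text
$ rxnforge verify run/dataset/rxn000000/{r,ts,p}000000.log run/string/gsm0001_0000.out \
      '[C:1]([H:2])([H:3])([H:4])[H:5]' '[C:1]([H:4])[H:5].[H:2][H:3]'
one_imaginary=True
imag_magnitude_ok=True
energy_drift_ok=True
mode_match_ok=True
endpoints_are_minima=True
passed=True
```

`rxnforge analyze run/dataset/reactions.csv` writes template rankings,
bond-change-type counts and density summaries.

The same functionality is available as a library; see
`rxnforge.pipeline.run_generation` and `docs/methods.md` for the model
details and parameter choices.

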