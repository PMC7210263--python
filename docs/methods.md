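# Methods

## The generation model

A campaign starts from a list of closed-shell reactant SMILES over H, C,
N and O. Each reactant is embedded as multiple 3D conformers (ETKDG
distance geometry), relaxed with the MMFF94 force field, and the
lowest-energy conformer is submitted to the engine for geometry
optimization and harmonic frequency analysis. The default conformer count
is 300 per molecule; structures with imaginary frequencies are rejected as
reactants.

For each optimized reactant an exhaustive list of driving-coordinate sets
is generated. A driving coordinate is a connectivity-level instruction —
break these bonds, form those non-bonded pairs — that seeds a single-ended
string-path search direction. The enumeration constraints are:

| constraint | default | rationale |
| --- | --- | --- |
| max bonds broken | 2 | elementary steps change few bonds |
| max bonds formed | 2 | same |
| total changes | 2–3 | single changes are mostly barrierless association/dissociation |
| valence window | H = 1, C = 2–4, N = 1–3, O = 1–2 | the formal product must be a plausible connectivity |
| equivalent-H pruning | on | coordinates differing only by symmetry-equivalent hydrogens duplicate the same search |

The valence window screens only the *formal* product (the reactant graph
with the changes applied); the path optimizer is free to introduce further
changes, so nothing downstream re-applies these limits.

Equivalent hydrogens are detected with iterated neighborhood
(Weisfeiler–Lehman) color refinement over element labels. For molecular
graphs at this scale the refinement reproduces the automorphism orbits
exactly (the test suite cross-checks against brute-force orbit
computation); pathological regular graphs where refinement over-merges do
not occur for H/C/N/O molecules with ≤ ~23 atoms. Pruning works by
signature: each hydrogen index in a coordinate set is replaced by its
symmetry class, and sets with equal signatures collapse to the
lexicographically smallest representative. A config switch extends the
same pruning to all atoms (default off). Output order is canonical
(sorted index tuples), so enumeration is reproducible without randomness.

The string-path search, product optimization and transition-state
optimization are delegated to an executor — any object with
`run(job_text) -> output_text`. Real engines are driven through input
files and parsed logs; the package's mock engine (below) implements the
same contract. After the path search, up to **four** duplicate candidates
per reaction (by identity key, lowest provisional barriers first, ties to
earlier discovery) are retained for TS optimization as insurance against
failed optimizations; after verification and energetics, duplicates are
collapsed again keeping the **lowest-barrier** record.

## Perception and identity

Minimum-energy geometries are converted to molecular identity as follows:

- *Connectivity*: atoms i, j are bonded iff
  d(i,j) ≤ tol · (r_cov(i) + r_cov(j)) with single-bond covalent radii
  H 0.31, C 0.76, N 0.71, O 0.66 Å and tol = 1.2 (configurable). Pairs
  closer than 0.4 Å are a geometry error.
- *Bond orders*: starting from all-single bonds, remaining unsaturation
  (target connection-valence H 1, C 4, N 3, O 2) is consumed by repeated
  maximum-cardinality matching over adjacent unsaturated atoms. This
  merges adjacent radical-like centers into double/triple bonds where
  possible; whatever unsaturation remains is genuine radical character.
  All-single is the universal fallback, so orders are always assignable.
- *Identity*: a fixed-hydrogen InChI, so tautomers get distinct keys
  while bond-order-ambiguous resonance forms with the same hydrogen
  skeleton get equal keys. When no InChI backend is available the package
  falls back to a documented canonical serialization (molecular formula
  plus a Weisfeiler–Lehman hash over element/charge-labeled connectivity
  with explicit hydrogens); tests assert both backends induce the same
  equivalence classes on the fixture corpus.
- *Atom maps*: SMILES map numbers are reconstructed by connectivity-only
  graph isomorphism against the original index-carrying graph (map = index
  + 1; the writer owns the 1-based shift). When several isomorphisms
  exist the lexicographically smallest image sequence is chosen, making
  the mapping deterministic. Transition-state geometries are never
  perceived — bond orders are undefined at saddle points.

A reaction's identity key is the pair (reactant key, sorted multiset of
product-fragment keys); deduplication operates on these keys.

## Verification filter stack

A proposed reactant/TS/product triple passes only if all five hold:

1. exactly one imaginary frequency at the TS;
2. its magnitude is ≥ 100 cm⁻¹ (smaller values typically indicate
   conformational motion; the boundary value passes);
3. the TS-optimization energy differs from the highest string-path node
   by ≤ 3 kcal/mol (the boundary passes);
4. the imaginary-mode displacement along every changing bond strictly
   exceeds that along every unchanged bond;
5. reactant and product have no imaginary frequencies.

The mode-match metric is the relative-displacement projection
|(u_i − u_j)·ê_ij| of the unit-normalized Cartesian imaginary mode onto
the bond axis in the TS geometry. No mass weighting is applied: the
projection isolates bond-stretch character and, being built from relative
displacements and internal directions, is exactly invariant under rigid
rotation/translation and mode sign flips. "Every unchanged bond" means
the bonded pairs of reactant or product outside the changing set — not
all atom pairs — and ties reject (strict inequality keeps the filter
conservative). Any negative frequency counts as imaginary by default
(no near-zero leniency window; one is configurable for noisy inputs).
The comparison is extremal (min over changing vs max over unchanged)
rather than summed; the metric sits behind a single function so other
strategies can be swapped in.

Intrinsic-reaction-coordinate following is deliberately not part of the
stack.

## Energetics

Electronic energies are hartree everywhere until this module; conversion
happens in one place with pinned constants 1 hartree = 627.5095 kcal/mol
and 1 cm⁻¹ = 0.0028591 kcal/mol (both asserted against independent
constants in tests). ZPE is ½·Σ ν̃·(hc) over strictly positive
frequencies, unscaled; imaginary and zero modes contribute nothing.
Barriers and enthalpies are 0 K ZPE-corrected electronic energy
differences — no thermal corrections. Negative barriers (possible after
ZPE correction of very low saddles) are flagged with a warning, not
rejected. Mixing levels of theory raises an error via per-species level
tags.

## The mock engine

The mock executor emulates exactly the engine outputs the pipeline
consumes, with realistic shape but synthetic values:

- *Energy model*: per-element baselines plus a per-bond stabilization and
  a reproducible hash perturbation of the molecular identity, so isomers
  differ and duplicates of a reaction share product energies up to small
  per-job conformer noise.
- *Geometries*: product connectivities are realized by ETKDG embedding
  per fragment, with fragments spaced 8 Å apart; the embedding is
  validated by re-perceiving the connectivity. Failures are reported as
  failed jobs (which the pipeline tolerates by design).
- *String paths*: nine nodes interpolating reactant and product energies
  plus a planted sinusoidal barrier of 5–80 kcal/mol.
- *Transition states*: geometry is the jittered product geometry; the
  imaginary mode is constructed by least squares to give unit projection
  on every changing bond and zero on every unchanged bond, so a clean
  mock TS passes the mode-match filter by construction, and planted
  defects (second imaginary frequency, sub-100 cm⁻¹ magnitude,
  > 3 kcal/mol drift, spectator-localized mode) fail exactly the intended
  check. TS jobs carry a provenance comment (job id, string-reference
  energy, changing/unchanged pairs) so the engine is stateless and
  campaigns resume with a fresh engine instance.

What the mock does **not** emulate: real electronic structure (no
meaningful absolute energies), anharmonicity, path-optimizer drift of the
reactant, TS conformer multiplicity beyond the planted noise, and
rotational/translational null-mode structure in the frequency lists.
Passing tests therefore demonstrate the correctness of everything around
an engine — enumeration, parsing, perception, mapping, filtering,
energetics arithmetic, deduplication, layout, determinism — not the
physical accuracy of any particular engine.

## Pipeline mechanics

Campaign state lives in a work directory: `state.json` plus job inputs,
logs and string outputs as files. Each stage (prepare → enumerate → gsm →
prodopt → retain → tsopt → extract → finalize) marks itself done in the
state file, so a killed campaign resumes from the last completed stage and
produces the same dataset as an uninterrupted run. With the mock engine
all randomness derives from the campaign seed, and the final CSV is
byte-reproducible. Failed jobs are recorded statuses, never exceptions.

Records are indexed contiguously after final deduplication and written as
a CSV with header exactly `idx,rsmi,psmi,ea,dh` (energies printed with
six decimals) beside `rxn%06d/` directories containing `r/p/ts%06d.log`;
CSV row order equals directory order. A refinement pass re-optimizes
products and TSs at a second level of theory, re-extracts and re-verifies
against the original string paths, and re-deduplicates by lowest barrier.
Forward and reverse reactions are distinct records; reverse records are
not auto-generated.

If the perceived reactant connectivity no longer matches the input
molecule (path-search drift), atom-map reconstruction fails and the
candidate is dropped with an `extraction_failed` status rather than
silently reassigned.

## Analysis definitions

Two deliberately different change definitions coexist: the *number* of
bond changes counts connectivity changes only, while the bond-change
*type* multiset also includes bonded pairs whose perceived order differs
between the sides. The reactive center is the set of atoms incident to
either kind of change; templates are the center-induced fragments of each
side, serialized canonically (lexicographically minimal labeling within
Weisfeiler–Lehman color blocks) over exactly four features: element,
formal charge, aromatic flag, bond type. Because only center atoms enter,
templates are spectator-invariant by construction — e.g. O–H homolysis in
water, methanol and ethanol all share one template. The serialization is
a compact edge-list dialect rather than toolkit SMARTS; template
*partitions* are well-defined and tested, string compatibility with any
particular SMARTS writer is not a goal.

Kernel density estimates use product Gaussian kernels with Scott's
per-dimension bandwidth (σ·n^(−1/5) in 1D, σ·n^(−1/6) in 2D, floored at
10⁻³ for degenerate samples) on grids extending eight bandwidths past the
data, so each density integrates to 1 on its grid to high accuracy.

## Problem sizes and tolerances

The shipped tests and the acceptance script run the campaign on 4–5 small
reactants with 10–30 conformers each, the enumeration cross-check on 25
molecules with ≤ 4 heavy atoms (the literal oracle iterates all subsets,
so it is kept to small graphs), the perception round-trip on 37–40
molecules up to 7 heavy atoms, and the verification suite on 50 planted
triples. Numerical contracts: mode-score invariances hold to 1e-10;
barrier/enthalpy cycle closure to 1e-9 kcal/mol; ZPE arithmetic matches
an independent table computation to 1e-6 kcal/mol (and CODATA-derived
constants to ~2e-5 relative, the precision of the five-digit table
values); KDE normalization to 1e-6 in 1D. Energies are formatted, not
truncated: determinism claims are at the byte level.

## Known limitations

- Symmetry classes come from color refinement, not a certified
  canonical-labeling algorithm; correct for chemistry-sized graphs,
  validated by brute force in tests, but not a general-graph guarantee.
- Bond-order assignment is connectivity-greedy and charge-naive beyond a
  formal-charge offset; exotic charged species are passed through, not
  modeled.
- The best-effort reader for engine-native logs covers one common layout
  and only the five quantities the pipeline consumes.
- Stereochemistry is entirely out of scope, as are rate theories,
  tunneling, and thermal corrections.
- The mock engine's energies are synthetic; datasets it produces exercise
  the machinery, not chemistry.
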