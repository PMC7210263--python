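"""Exhaustive enumeration of driving-coordinate sets for a reactant.

A driving-coordinate set is a search direction for a single-ended
reaction-path optimizer: a set of reactant bonds to break plus a set of
currently non-bonded atom pairs to form.  Enumeration is exhaustive
subject to the constraints that keep the search tractable and chemically
sensible:

* at most two breaks, at most two formations, and between two and three
  total changes (single-bond changes are excluded because they would
  mostly correspond to barrierless associations/dissociations);
* the *formal* product graph -- the reactant with the changes applied --
  must satisfy the per-element degree window (H exactly 1, C 2-4, N 1-3,
  O 1-2).  The window screens only the search direction; the real path
  optimizer is free to add further changes downstream;
* sets that differ only by substituting topologically equivalent
  hydrogens (e.g. the three hydrogens of a methyl group) are collapsed to
  one canonical representative.

The counting limits apply to the initial search direction only; nothing
downstream of path optimization re-applies them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

from rxnforge.molgraph import (
    DEFAULT_VALENCES,
    Bond,
    MolGraph,
    MolGraphError,
    ValenceTable,
    apply_changes,
    is_valence_feasible,
    symmetry_class_index,
)


class EnumerationError(MolGraphError):
    """Invalid input to the driving-coordinate enumerator."""


@dataclass(frozen=True)
class DrivingCoordinateSet:
    """Bonds to break plus non-bonded pairs to form, both as sorted tuples of sorted pairs."""

    breaks: Tuple[Bond, ...]
    forms: Tuple[Bond, ...]

    @staticmethod
    def make(breaks, forms) -> "DrivingCoordinateSet":
        canon = lambda pairs: tuple(sorted(tuple(sorted(p)) for p in pairs))
        return DrivingCoordinateSet(canon(breaks), canon(forms))

    @property
    def n_changes(self) -> int:
        return len(self.breaks) + len(self.forms)

    def sort_key(self):
        return (self.breaks, self.forms)


@dataclass(frozen=True)
class EnumerationConstraints:
    """Counting limits and screening switches for the enumeration."""

    max_breaks: int = 2
    max_forms: int = 2
    max_total: int = 3
    min_total: int = 2
    valences: ValenceTable = field(default_factory=lambda: DEFAULT_VALENCES)
    prune_equivalent_hydrogens: bool = True
    # optional stronger pruning: collapse sets equivalent under *any*
    # topologically equivalent atoms, not just hydrogens
    prune_all_equivalent: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.min_total <= self.max_total):
            raise EnumerationError("need 1 <= min_total <= max_total")
        if self.max_breaks < 0 or self.max_forms < 0:
            raise EnumerationError("max_breaks/max_forms must be >= 0")


def _signature(
    dcs: DrivingCoordinateSet, g: MolGraph, classes: Sequence[int], all_atoms: bool
):
    """Equivalence signature: hydrogen indices (or all, if all_atoms) replaced by class id."""

    def atom_sig(i: int):
        if all_atoms or g.atoms[i].element == "H":
            return ("cls", classes[i])
        return ("idx", i)

    def pair_sig(p: Bond):
        return tuple(sorted((atom_sig(p[0]), atom_sig(p[1])), key=repr))

    return (
        tuple(sorted((pair_sig(b) for b in dcs.breaks), key=repr)),
        tuple(sorted((pair_sig(f) for f in dcs.forms), key=repr)),
    )


def _dedup_by_signature(
    sets: List[DrivingCoordinateSet],
    g: MolGraph,
    constraints: EnumerationConstraints,
) -> List[DrivingCoordinateSet]:
    if not (constraints.prune_equivalent_hydrogens or constraints.prune_all_equivalent):
        return sorted(sets, key=DrivingCoordinateSet.sort_key)
    classes = symmetry_class_index(g)
    best: Dict[object, DrivingCoordinateSet] = {}
    for dcs in sorted(sets, key=DrivingCoordinateSet.sort_key):
        sig = _signature(dcs, g, classes, constraints.prune_all_equivalent)
        if sig not in best:  # sorted iteration -> lexicographically smallest kept
            best[sig] = dcs
    return sorted(best.values(), key=DrivingCoordinateSet.sort_key)


def enumerate_driving_coordinates(
    reactant: MolGraph, constraints: EnumerationConstraints = EnumerationConstraints()
) -> List[DrivingCoordinateSet]:
    """All driving-coordinate sets for `reactant` under `constraints`.

    The valence screen is evaluated incrementally on atom degrees (only
    endpoints of changed pairs can move), which keeps the enumeration fast;
    the brute-force oracle below rebuilds each formal product graph
    instead, so the two implementations share no screening code.
    Output order is deterministic: sorted by canonical (breaks, forms)
    index tuples.
    """
    if not is_valence_feasible(reactant, constraints.valences):
        raise EnumerationError("reactant itself violates the valence window")
    n = reactant.n_atoms
    bonds = sorted(reactant.bonds)
    nonbonded = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if (i, j) not in reactant.bonds
    ]
    degrees = [reactant.degree(i) for i in range(n)]
    bounds = [constraints.valences.bounds(a.element) for a in reactant.atoms]

    found: List[DrivingCoordinateSet] = []
    for nb in range(min(constraints.max_breaks, len(bonds)) + 1):
        for breaks in combinations(bonds, nb):
            lo_forms = max(constraints.min_total - nb, 0)
            hi_forms = min(constraints.max_forms, constraints.max_total - nb)
            if lo_forms > hi_forms:
                continue
            for nf in range(lo_forms, hi_forms + 1):
                if nb + nf < constraints.min_total:
                    continue
                for forms in combinations(nonbonded, nf):
                    delta = [0] * n
                    for i, j in breaks:
                        delta[i] -= 1
                        delta[j] -= 1
                    for i, j in forms:
                        delta[i] += 1
                        delta[j] += 1
                    ok = True
                    for i in range(n):
                        if delta[i]:
                            d = degrees[i] + delta[i]
                            if not bounds[i][0] <= d <= bounds[i][1]:
                                ok = False
                                break
                    if ok:
                        found.append(DrivingCoordinateSet.make(breaks, forms))
    return _dedup_by_signature(found, reactant, constraints)


def brute_force_oracle(
    reactant: MolGraph, constraints: EnumerationConstraints = EnumerationConstraints()
) -> List[DrivingCoordinateSet]:
    """Literal-definition enumerator used as an independent test oracle.

    Iterates over *all* subsets of bonds and non-bonded pairs within the
    counting limits, materializes every formal product with
    ``apply_changes`` and filters with ``is_valence_feasible``.  Intended
    for small molecules (<= ~6 atoms is comfortable).
    """
    n = reactant.n_atoms
    bonds = sorted(reactant.bonds)
    nonbonded = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if (i, j) not in reactant.bonds
    ]
    found: List[DrivingCoordinateSet] = []
    for nb in range(min(len(bonds), constraints.max_breaks) + 1):
        for breaks in combinations(bonds, nb):
            for nf in range(min(len(nonbonded), constraints.max_forms) + 1):
                for forms in combinations(nonbonded, nf):
                    total = nb + nf
                    if not constraints.min_total <= total <= constraints.max_total:
                        continue
                    product = apply_changes(reactant, breaks, forms)
                    if is_valence_feasible(product, constraints.valences):
                        found.append(DrivingCoordinateSet.make(breaks, forms))
    return _dedup_by_signature(found, reactant, constraints)


# ---------------------------------------------------------------------------
# text interface used by the string-method driver
# ---------------------------------------------------------------------------


def format_isomers_file(dcs: DrivingCoordinateSet) -> str:
    """Coordinate-specification text consumed by the path-search driver.

    One line per change, 1-based atom indices:
    ``BREAK i j`` for each bond to break, ``ADD i j`` for each to form.
    """
    lines = ["NEW"]
    for i, j in dcs.breaks:
        lines.append(f"BREAK {i + 1} {j + 1}")
    for i, j in dcs.forms:
        lines.append(f"ADD {i + 1} {j + 1}")
    return "\n".join(lines) + "\n"


def parse_isomers_file(text: str) -> DrivingCoordinateSet:
    """Inverse of :func:`format_isomers_file` (back to 0-based indices)."""
    breaks, forms = [], []
    for line in text.splitlines():
        parts = line.split()
        if not parts or parts[0] == "NEW":
            continue
        kind, i, j = parts[0], int(parts[1]) - 1, int(parts[2]) - 1
        if kind == "BREAK":
            breaks.append((i, j))
        elif kind == "ADD":
            forms.append((i, j))
        else:
            raise EnumerationError(f"unknown coordinate line: {line!r}")
    return DrivingCoordinateSet.make(breaks, forms)


def format_record(reactant_smiles: str, dcs: DrivingCoordinateSet) -> str:
    """One-line record: SMILES, break pairs and form pairs as 0-based tuples."""
    b = ";".join(f"{i}-{j}" for i, j in dcs.breaks) or "-"
    f = ";".join(f"{i}-{j}" for i, j in dcs.forms) or "-"
    return f"{reactant_smiles}\t{b}\t{f}"
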