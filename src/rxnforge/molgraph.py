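"""Element-labeled molecular connectivity graphs.

This is the universal identity carrier of the package: a molecule (or a
multi-molecular product set) is a set of atoms with stable 0-based indices
and a set of unordered bonded index pairs.  Bond *orders* are deliberately
absent at this layer -- a "bond" only records whether two atoms are
connected, which is the notion of connectivity the whole search operates
on.  Hydrogens are always explicit atoms; there is no implicit-hydrogen
bookkeeping anywhere in the core.

Supported elements are H, C, N and O.  Degree (valence) feasibility is
judged against per-element minimum/maximum connection counts: H must have
exactly one bond, C between two and four, N between one and three, O
between one and two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

SUPPORTED_ELEMENTS: Tuple[str, ...] = ("H", "C", "N", "O")

Bond = Tuple[int, int]


class MolGraphError(ValueError):
    """Base error for molecular-graph operations."""


class InvalidChangeError(MolGraphError):
    """A requested bond break/formation violates its precondition."""


class UnsupportedElementError(MolGraphError):
    """An atom's element is outside the supported H/C/N/O set."""


class MappingMismatchError(MolGraphError):
    """Two graphs expected to share an atom index space do not."""


def _canon_bond(i: int, j: int) -> Bond:
    if i == j:
        raise MolGraphError(f"self-bond on atom {i}")
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class Atom:
    """A single atom: stable index, element symbol, formal charge, optional coordinates (A)."""

    index: int
    element: str
    formal_charge: int = 0
    coords: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"element {self.element!r} not in supported set {SUPPORTED_ELEMENTS}"
            )


@dataclass(frozen=True)
class ValenceTable:
    """Per-element (min_degree, max_degree) connection limits."""

    limits: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {"H": (1, 1), "C": (2, 4), "N": (1, 3), "O": (1, 2)}
    )

    def __post_init__(self) -> None:
        for el in SUPPORTED_ELEMENTS:
            if el not in self.limits:
                raise MolGraphError(f"valence table missing element {el}")
            lo, hi = self.limits[el]
            if lo > hi:
                raise MolGraphError(f"valence table for {el}: min {lo} > max {hi}")

    def bounds(self, element: str) -> Tuple[int, int]:
        try:
            return self.limits[element]
        except KeyError:
            raise UnsupportedElementError(f"no valence limits for element {element!r}")


DEFAULT_VALENCES = ValenceTable()


class MolGraph:
    """An element-labeled connectivity graph with stable atom indices.

    The graph may be disconnected (multi-molecular product sets).  Bonds
    are stored as a frozenset of sorted index pairs; no self-bonds, no
    duplicates.
    """

    __slots__ = ("atoms", "bonds", "_adj")

    def __init__(self, atoms: Sequence[Atom], bonds: Iterable[Bond]):
        atoms = list(atoms)
        indices = [a.index for a in atoms]
        if sorted(indices) != list(range(len(atoms))):
            raise MolGraphError("atom indices must be exactly 0..n-1 and unique")
        atoms.sort(key=lambda a: a.index)
        canon: Set[Bond] = set()
        for i, j in bonds:
            b = _canon_bond(int(i), int(j))
            if b[0] < 0 or b[1] >= len(atoms):
                raise MolGraphError(f"bond {b} references a missing atom")
            canon.add(b)
        self.atoms: Tuple[Atom, ...] = tuple(atoms)
        self.bonds: FrozenSet[Bond] = frozenset(canon)
        adj: List[Set[int]] = [set() for _ in atoms]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        self._adj: Tuple[FrozenSet[int], ...] = tuple(frozenset(s) for s in adj)

    # -- basic accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> Tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    def neighbors(self, i: int) -> FrozenSet[int]:
        return self._adj[i]

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def has_bond(self, i: int, j: int) -> bool:
        return _canon_bond(i, j) in self.bonds

    def coordinates(self) -> np.ndarray:
        if any(a.coords is None for a in self.atoms):
            raise MolGraphError("graph has atoms without coordinates")
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coordinates(self, geometry: np.ndarray) -> "MolGraph":
        geometry = np.asarray(geometry, dtype=float)
        if geometry.shape != (self.n_atoms, 3):
            raise MolGraphError("geometry shape mismatch")
        atoms = [
            Atom(a.index, a.element, a.formal_charge, tuple(float(x) for x in row))
            for a, row in zip(self.atoms, geometry)
        ]
        return MolGraph(atoms, self.bonds)

    def relabel(self, perm: Sequence[int]) -> "MolGraph":
        """Return a copy with atom i renamed to perm[i] (perm is a bijection)."""
        if sorted(perm) != list(range(self.n_atoms)):
            raise MolGraphError("perm must be a permutation of 0..n-1")
        atoms = [
            Atom(perm[a.index], a.element, a.formal_charge, a.coords) for a in self.atoms
        ]
        bonds = [(perm[i], perm[j]) for i, j in self.bonds]
        return MolGraph(atoms, bonds)

    def connected_components(self) -> List[Tuple[int, ...]]:
        """Connected components as sorted index tuples, ordered by smallest member."""
        seen: Set[int] = set()
        comps: List[Tuple[int, ...]] = []
        for start in range(self.n_atoms):
            if start in seen:
                continue
            stack = [start]
            comp = []
            while stack:
                v = stack.pop()
                if v in seen:
                    continue
                seen.add(v)
                comp.append(v)
                stack.extend(self._adj[v] - seen)
            comps.append(tuple(sorted(comp)))
        return comps

    def subgraph(self, indices: Sequence[int]) -> Tuple["MolGraph", Tuple[int, ...]]:
        """Induced subgraph with local 0-based indices; also returns the parent-index map."""
        parent = tuple(sorted(indices))
        local = {p: k for k, p in enumerate(parent)}
        atoms = [
            Atom(local[p], self.atoms[p].element, self.atoms[p].formal_charge, self.atoms[p].coords)
            for p in parent
        ]
        bonds = [
            (local[i], local[j]) for i, j in self.bonds if i in local and j in local
        ]
        return MolGraph(atoms, bonds), parent

    # -- equality / hashing ---------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolGraph):
            return NotImplemented
        return (
            self.elements == other.elements
            and tuple(a.formal_charge for a in self.atoms)
            == tuple(a.formal_charge for a in other.atoms)
            and self.bonds == other.bonds
        )

    def __hash__(self) -> int:
        return hash((self.elements, self.bonds))

    def __repr__(self) -> str:
        return f"MolGraph({''.join(self.elements)}, {sorted(self.bonds)})"


# ---------------------------------------------------------------------------
# symmetry perception
# ---------------------------------------------------------------------------


def symmetry_classes(g: MolGraph) -> List[FrozenSet[int]]:
    """Partition atoms into topological-equivalence classes.

    Two atoms share a class iff they receive identical stable colors under
    iterated neighborhood (Weisfeiler-Lehman style) refinement starting
    from element labels over the connectivity graph.  For the H/C/N/O
    graphs in scope this coincides with the automorphism orbits; the
    refinement never merges distinguishable atoms, so it is at worst a
    conservative over-merge on pathological regular graphs that do not
    occur for molecules of this size.

    Returns the classes as a list of frozensets ordered by smallest member.
    """
    colors: List = [(a.element, a.formal_charge) for a in g.atoms]
    for _ in range(g.n_atoms + 1):
        new = [
            (colors[i], tuple(sorted(colors[j] for j in g.neighbors(i))))
            for i in range(g.n_atoms)
        ]
        # compress to small ints so tuples stay shallow
        palette = {c: k for k, c in enumerate(sorted(set(new), key=repr))}
        new_ids = [palette[c] for c in new]
        if len(set(new_ids)) == len(set(colors)):
            colors = new_ids
            break
        colors = new_ids
    groups: Dict[int, List[int]] = {}
    for i, c in enumerate(colors):
        groups.setdefault(c, []).append(i)
    return sorted((frozenset(v) for v in groups.values()), key=min)


def symmetry_class_index(g: MolGraph) -> List[int]:
    """Map each atom index to the id (smallest member) of its symmetry class."""
    out = [0] * g.n_atoms
    for cls in symmetry_classes(g):
        rep = min(cls)
        for i in cls:
            out[i] = rep
    return out


# ---------------------------------------------------------------------------
# change application and feasibility
# ---------------------------------------------------------------------------


def apply_changes(g: MolGraph, breaks: Iterable[Bond], forms: Iterable[Bond]) -> MolGraph:
    """Return a new graph with `breaks` removed and `forms` added.

    Every break must be an existing bond, every form a currently non-bonded
    pair, and the two sets must be disjoint; the input graph is unchanged.
    """
    br = {_canon_bond(*b) for b in breaks}
    fo = {_canon_bond(*b) for b in forms}
    if br & fo:
        raise InvalidChangeError("breaks and forms overlap")
    missing = br - g.bonds
    if missing:
        raise InvalidChangeError(f"cannot break non-bonds: {sorted(missing)}")
    present = fo & g.bonds
    if present:
        raise InvalidChangeError(f"cannot form existing bonds: {sorted(present)}")
    return MolGraph(g.atoms, (g.bonds - br) | fo)


def is_valence_feasible(g: MolGraph, valences: ValenceTable = DEFAULT_VALENCES) -> bool:
    """True iff every atom's degree lies within its element's [min, max] window."""
    for a in g.atoms:
        lo, hi = valences.bounds(a.element)
        if not lo <= g.degree(a.index) <= hi:
            return False
    return True


# ---------------------------------------------------------------------------
# isomorphism
# ---------------------------------------------------------------------------


def connectivity_isomorphism(g1: MolGraph, g2: MolGraph) -> Optional[List[int]]:
    """Element-preserving, adjacency-preserving bijection g1 -> g2, or None.

    Bond orders do not exist at this layer so matching is connectivity-only.
    When several isomorphisms exist, the one returned is the
    lexicographically smallest image sequence (images of g1's atoms in
    index order), which makes downstream atom-map reconstruction
    deterministic.
    """
    n = g1.n_atoms
    if n != g2.n_atoms:
        return None
    if sorted(g1.elements) != sorted(g2.elements):
        return None
    if sorted(map(len, g1._adj)) != sorted(map(len, g2._adj)):
        return None
    # WL colors give a strong compatibility filter: candidate images must
    # share the refined color of their preimage.
    c1 = _wl_colors_joint(g1, g2)
    if c1 is None:
        return None
    col1, col2 = c1

    mapping: List[int] = [-1] * n
    used = [False] * n

    def feasible(i: int, cand: int) -> bool:
        if col1[i] != col2[cand]:
            return False
        if g1.atoms[i].element != g2.atoms[cand].element:
            return False
        if g1.degree(i) != g2.degree(cand):
            return False
        for j in g1.neighbors(i):
            if j < i:  # already mapped
                if mapping[j] not in g2.neighbors(cand):
                    return False
        # non-adjacency must also be preserved among mapped atoms
        for j in range(i):
            if j not in g1.neighbors(i) and mapping[j] in g2.neighbors(cand):
                return False
        return True

    def backtrack(i: int) -> bool:
        if i == n:
            return True
        for cand in range(n):  # ascending -> first solution is lex-smallest
            if not used[cand] and feasible(i, cand):
                mapping[i] = cand
                used[cand] = True
                if backtrack(i + 1):
                    return True
                used[cand] = False
                mapping[i] = -1
        return False

    return list(mapping) if backtrack(0) else None


def _wl_colors_joint(g1: MolGraph, g2: MolGraph):
    """Jointly refined WL colors for two graphs; None if color histograms diverge."""
    n = g1.n_atoms
    colors = [(a.element,) for a in g1.atoms] + [(a.element,) for a in g2.atoms]

    def nbrs(k: int):
        return g1.neighbors(k) if k < n else {n + j for j in g2.neighbors(k - n)}

    for _ in range(n + 1):
        new = [
            (colors[k], tuple(sorted(colors[j] for j in nbrs(k))))
            for k in range(2 * n)
        ]
        palette = {c: k for k, c in enumerate(sorted(set(new), key=repr))}
        ids = [palette[c] for c in new]
        if sorted(ids[:n]) != sorted(ids[n:]):
            return None
        if len(set(ids)) == len(set(colors)):
            return ids[:n], ids[n:]
        colors = ids
    return colors[:n], colors[n:]


# ---------------------------------------------------------------------------
# bond-change diff
# ---------------------------------------------------------------------------


def bond_changes(reactant: MolGraph, product: MolGraph) -> Tuple[Set[Bond], Set[Bond]]:
    """Connectivity diff over a shared (atom-mapped) index space.

    Returns (broken, formed): bonds present only in the reactant and bonds
    present only in the product.  Bond orders play no role.
    """
    if reactant.n_atoms != product.n_atoms:
        raise MappingMismatchError("atom counts differ between reactant and product")
    if reactant.elements != product.elements:
        raise MappingMismatchError("element labels differ at some shared index")
    broken = set(reactant.bonds - product.bonds)
    formed = set(product.bonds - reactant.bonds)
    return broken, formed
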