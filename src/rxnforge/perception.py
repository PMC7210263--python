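"""Perception of molecular identity from 3D geometries.

Converts optimized minimum geometries into graph connectivity (covalent
radii with a scale-factor tolerance), integer bond orders (maximum
valence saturation), a tautomer-distinguishing identity key (fixed-
hydrogen InChI, with a connectivity-hash fallback), atom-mapped SMILES
(map reconstructed by connectivity-only graph isomorphism against the
original index-carrying graph), and assembled reaction SMILES.

Transition-state geometries are never perceived: bond orders are
undefined at saddle points, so identity applies only to minima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from rxnforge.molgraph import (
    Atom,
    Bond,
    MolGraph,
    MolGraphError,
    connectivity_isomorphism,
)

RDLogger.DisableLog("rdApp.*")

#: Single-bond covalent radii (angstrom) used for distance-based connectivity.
COVALENT_RADII: Dict[str, float] = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66}

#: Target connection-valences for bond-order saturation.
VALENCE_TARGETS: Dict[str, int] = {"H": 1, "C": 4, "N": 3, "O": 2}

DEFAULT_TOLERANCE = 1.2
MIN_ATOM_SEPARATION = 0.4  # angstrom; anything closer is a broken geometry


class PerceptionError(MolGraphError):
    """Base error for perception failures."""


class GeometryError(PerceptionError):
    """Physically impossible geometry (overlapping atoms)."""


class MappingFailureError(PerceptionError):
    """Atom-map reconstruction failed (no connectivity isomorphism)."""


# ---------------------------------------------------------------------------
# connectivity from distances
# ---------------------------------------------------------------------------


def perceive_connectivity(
    elements: Sequence[str],
    geometry: np.ndarray,
    tol: float = DEFAULT_TOLERANCE,
    charges: Optional[Sequence[int]] = None,
) -> MolGraph:
    """Bond atoms i,j iff dist(i,j) <= tol * (r_cov(i) + r_cov(j)).

    `tol` is a dimensionless scale factor (default 1.2) on the sum of
    single-bond covalent radii.  Pairs closer than 0.4 A raise
    :class:`GeometryError`.
    """
    geometry = np.asarray(geometry, dtype=float)
    if not np.all(np.isfinite(geometry)):
        raise GeometryError("non-finite coordinates")
    n = len(elements)
    charges = list(charges) if charges is not None else [0] * n
    radii = np.array([COVALENT_RADII[el] for el in elements])
    diff = geometry[:, None, :] - geometry[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < MIN_ATOM_SEPARATION:
                raise GeometryError(
                    f"atoms {i} and {j} are {dist[i, j]:.3f} A apart"
                )
            if dist[i, j] <= tol * (radii[i] + radii[j]):
                bonds.append((i, j))
    atoms = [
        Atom(i, elements[i], charges[i], tuple(float(x) for x in geometry[i]))
        for i in range(n)
    ]
    return MolGraph(atoms, bonds)


# ---------------------------------------------------------------------------
# bond orders by valence saturation
# ---------------------------------------------------------------------------


def assign_bond_orders(g: MolGraph) -> Dict[Bond, int]:
    """Integer bond orders maximizing valence saturation.

    All bonds start single.  Unsaturation (target connection-valence minus
    current bond-order sum, floored at zero) is then consumed by repeated
    maximum-cardinality matching over adjacent unsaturated atom pairs;
    each matched edge gains one order unit per round.  Adjacent leftover
    radical pairs are therefore merged into double/triple bonds wherever
    possible, and whatever unsaturation remains is genuine radical
    character.  An all-single assignment is the universal fallback, so
    orders are always assignable.
    """
    orders: Dict[Bond, int] = {b: 1 for b in g.bonds}

    def unsat(i: int) -> int:
        total = sum(orders[b] for b in g.bonds if i in b)
        return max(VALENCE_TARGETS[g.atoms[i].element] - g.atoms[i].formal_charge - total, 0)

    while True:
        h = nx.Graph()
        h.add_nodes_from(range(g.n_atoms))
        for i, j in g.bonds:
            if unsat(i) > 0 and unsat(j) > 0:
                h.add_edge(i, j)
        matching = nx.max_weight_matching(h, maxcardinality=True)
        if not matching:
            return orders
        for i, j in matching:
            orders[(min(i, j), max(i, j))] += 1


def radical_electrons(g: MolGraph, orders: Dict[Bond, int]) -> List[int]:
    """Leftover unsaturation per atom after bond-order assignment."""
    out = []
    for a in g.atoms:
        total = sum(orders[b] for b in g.bonds if a.index in b)
        out.append(max(VALENCE_TARGETS[a.element] - a.formal_charge - total, 0))
    return out


# ---------------------------------------------------------------------------
# RDKit bridges
# ---------------------------------------------------------------------------

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def to_rdkit(
    g: MolGraph,
    orders: Optional[Dict[Bond, int]] = None,
    map_numbers: Optional[Sequence[int]] = None,
) -> Chem.Mol:
    """Build an RDKit molecule with explicit hydrogens and no implicit-H inference."""
    orders = orders or {b: 1 for b in g.bonds}
    rw = Chem.RWMol()
    for a in g.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.formal_charge)
        atom.SetNoImplicit(True)
        if map_numbers is not None:
            atom.SetAtomMapNum(int(map_numbers[a.index]))
        rw.AddAtom(atom)
    for b in g.bonds:
        rw.AddBond(b[0], b[1], _BOND_TYPES.get(orders.get(b, 1), Chem.BondType.SINGLE))
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, catchErrors=True)
    return mol


def graph_from_rdkit(mol: Chem.Mol) -> MolGraph:
    """Connectivity graph (explicit hydrogens) from an RDKit molecule."""
    mol = Chem.AddHs(mol)
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    atoms = []
    for a in mol.GetAtoms():
        coords = None
        if conf is not None:
            p = conf.GetAtomPosition(a.GetIdx())
            coords = (p.x, p.y, p.z)
        atoms.append(Atom(a.GetIdx(), a.GetSymbol(), a.GetFormalCharge(), coords))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return MolGraph(atoms, bonds)


def graph_from_smiles(smiles: str) -> MolGraph:
    """Connectivity graph with explicit hydrogens from a SMILES string.

    If the SMILES is atom-mapped, atoms are ordered by their map numbers
    (map m becomes index m-1), so a graph rebuilt from a mapped SMILES
    recovers the original index space.
    """
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise PerceptionError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    maps = [a.GetAtomMapNum() for a in mol.GetAtoms()]
    if any(maps):
        if sorted(maps) != list(range(1, mol.GetNumAtoms() + 1)):
            raise PerceptionError("mapped SMILES must carry a complete 1..N map")
        order = [0] * mol.GetNumAtoms()
        for idx, m in enumerate(maps):
            order[m - 1] = idx
        mol = Chem.RenumberAtoms(mol, order)
    return graph_from_rdkit(mol)


# ---------------------------------------------------------------------------
# identity keys
# ---------------------------------------------------------------------------


@dataclass
class PerceivedMolecule:
    """A perceived minimum: connectivity graph, bond orders, identity key."""

    graph: MolGraph
    bond_orders: Dict[Bond, int]
    identity_key: str


def _fixed_h_inchi(g: MolGraph, orders: Dict[Bond, int]) -> Optional[str]:
    mol = to_rdkit(g, orders)
    for a, nrad in zip(mol.GetAtoms(), radical_electrons(g, orders)):
        a.SetNumRadicalElectrons(int(nrad))
    try:
        key = Chem.MolToInchi(mol, options="/FixedH")
    except Exception:
        return None
    return key or None


def _fallback_key(g: MolGraph) -> str:
    """Canonical connectivity serialization with fixed-hydrogen semantics.

    Hydrogens are real nodes, so tautomers (which differ in H placement)
    hash differently, while bond-order-ambiguous resonance forms with the
    same H skeleton hash identically.  Uses a Weisfeiler-Lehman graph hash
    over element/charge node labels plus the molecular formula.
    """
    h = nx.Graph()
    for a in g.atoms:
        h.add_node(a.index, label=f"{a.element}{a.formal_charge:+d}")
    h.add_edges_from(g.bonds)
    wl = nx.weisfeiler_lehman_graph_hash(h, node_attr="label", iterations=max(3, g.n_atoms))
    formula = "".join(
        f"{el}{sum(1 for a in g.atoms if a.element == el)}" for el in ("C", "H", "N", "O")
    )
    return f"XKEY/{formula}/{wl}"


def identity_key(
    g: MolGraph, orders: Optional[Dict[Bond, int]] = None, use_inchi: bool = True
) -> str:
    """Canonical identity string with fixed-hydrogen semantics.

    Relabeled copies of a molecule give equal keys; tautomers give
    different keys; resonance forms with identical fixed-H skeletons give
    equal keys.  Uses fixed-hydrogen InChI when the InChI backend is
    available (it is in standard RDKit builds), otherwise the documented
    fallback serialization.
    """
    orders = orders if orders is not None else assign_bond_orders(g)
    if use_inchi:
        key = _fixed_h_inchi(g, orders)
        if key is not None:
            return key
    return _fallback_key(g)


def perceive_molecule(
    elements: Sequence[str],
    geometry: np.ndarray,
    tol: float = DEFAULT_TOLERANCE,
    use_inchi: bool = True,
) -> PerceivedMolecule:
    """Full perception of a minimum geometry: connectivity, orders, identity."""
    g = perceive_connectivity(elements, geometry, tol)
    orders = assign_bond_orders(g)
    return PerceivedMolecule(g, orders, identity_key(g, orders, use_inchi))


def perceived_from_graph(g: MolGraph, use_inchi: bool = True) -> PerceivedMolecule:
    """Perceive orders/identity directly from a connectivity graph (no geometry)."""
    orders = assign_bond_orders(g)
    return PerceivedMolecule(g, orders, identity_key(g, orders, use_inchi))


# ---------------------------------------------------------------------------
# atom-mapped SMILES
# ---------------------------------------------------------------------------


def atom_mapped_smiles(
    p: PerceivedMolecule,
    original: MolGraph,
    parent_indices: Optional[Sequence[int]] = None,
) -> str:
    """Atom-mapped SMILES for a perceived molecule.

    Map numbers are reconstructed by connectivity-only graph isomorphism
    against ``original``, the index-carrying graph: the atom of ``p``
    matched to original atom i receives map number i+1 (SMILES map numbers
    are 1-based; internal indices are 0-based -- this writer owns the
    shift).  ``parent_indices`` translates the original's local indices to
    a larger shared index space (used for product fragments).
    """
    iso = connectivity_isomorphism(original, p.graph)
    if iso is None:
        raise MappingFailureError("no connectivity isomorphism with the original graph")
    maps = [0] * p.graph.n_atoms
    for i, img in enumerate(iso):
        orig = parent_indices[i] if parent_indices is not None else i
        maps[img] = orig + 1
    mol = to_rdkit(p.graph, p.bond_orders, map_numbers=maps)
    return Chem.MolToSmiles(mol)


def split_fragments(p: PerceivedMolecule) -> List[Tuple[PerceivedMolecule, Tuple[int, ...]]]:
    """Connected components of a perceived (possibly multi-molecular) system.

    Returns (fragment, parent_indices) pairs; each fragment keeps its bond
    orders and gets its own identity key.
    """
    out = []
    for comp in p.graph.connected_components():
        sub, parent = p.graph.subgraph(comp)
        local = {pi: k for k, pi in enumerate(parent)}
        orders = {
            (local[i], local[j]) if local[i] < local[j] else (local[j], local[i]): o
            for (i, j), o in p.bond_orders.items()
            if i in local and j in local
        }
        out.append(
            (PerceivedMolecule(sub, orders, identity_key(sub, orders)), parent)
        )
    return out


def reaction_smiles(
    reactant: PerceivedMolecule,
    products: List[Tuple[PerceivedMolecule, Tuple[int, ...]]],
    original: MolGraph,
) -> Tuple[str, str]:
    """Assemble (rsmi, psmi) for one reaction.

    ``original`` is the index-carrying reactant graph whose indices define
    the map numbers.  ``products`` are fragment/parent-index pairs over
    that index space (see :func:`split_fragments`); their parent indices
    must partition the reactant's atoms.  Each product fragment's map is
    reconstructed by isomorphism against its own index-carrying product
    connectivity (the atom order of the perceived product geometry), then
    lifted to the shared space through the parent indices.  The product
    side joins fragment SMILES with '.', and the union of product map
    numbers equals the reactant's.
    """
    covered = sorted(i for _, parent in products for i in parent)
    if covered != list(range(original.n_atoms)):
        raise MappingFailureError("product fragments do not partition the reactant atoms")
    rsmi = atom_mapped_smiles(reactant, original)
    frags = [
        atom_mapped_smiles(frag, frag.graph, parent_indices=parent)
        for frag, parent in products
    ]
    return rsmi, ".".join(frags)
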