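"""Diversity analyses over a curated reaction table.

Works on atom-mapped reaction SMILES pairs (the ``rsmi``/``psmi`` columns
of the dataset CSV): connectivity-change counting, bond-change-type
classification, reactive-center isolation, general reaction-template
extraction, template ranking, per-group activation-energy distributions,
and a bivariate Gaussian kernel density over (reaction enthalpy,
activation energy).

Two related but distinct definitions are used deliberately: the *number*
of bond changes counts connectivity changes only (irrespective of bond
order), while the bond-change *types* additionally include pure
bond-order changes between atoms that stay connected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from rxnforge.molgraph import Bond, MolGraphError

BOND_SYMBOL = {1: "-", 2: "=", 3: "#", 15: ":"}  # 15 = aromatic sentinel


class AnalysisInputError(MolGraphError):
    """Unmapped or inconsistent reaction SMILES."""


class NoReactionError(AnalysisInputError):
    """Identity reaction: empty reactive center."""


# ---------------------------------------------------------------------------
# mapped-SMILES plumbing
# ---------------------------------------------------------------------------


@dataclass
class _MappedSide:
    """One side of a mapped reaction keyed by map number."""

    elements: Dict[int, str]
    charges: Dict[int, int]
    aromatic: Dict[int, bool]
    bonds: Dict[Bond, int]  # (map_i, map_j) sorted -> order (15 = aromatic)


def _parse_side(smiles: str) -> _MappedSide:
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise AnalysisInputError(f"unparsable SMILES {smiles!r}")
    elements, charges, aromatic = {}, {}, {}
    for a in mol.GetAtoms():
        m = a.GetAtomMapNum()
        if m == 0:
            raise AnalysisInputError(f"unmapped atom in {smiles!r}")
        if a.GetTotalNumHs() > 0:  # implicit/bracket H would escape the map
            raise AnalysisInputError(f"hydrogens must be explicit mapped atoms in {smiles!r}")
        elements[m] = a.GetSymbol()
        charges[m] = a.GetFormalCharge()
        aromatic[m] = a.GetIsAromatic()
    bonds = {}
    for b in mol.GetBonds():
        mi = b.GetBeginAtom().GetAtomMapNum()
        mj = b.GetEndAtom().GetAtomMapNum()
        key = (min(mi, mj), max(mi, mj))
        if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.AROMATIC:
            bonds[key] = 15
        else:
            bonds[key] = int(round(b.GetBondTypeAsDouble()))
    return _MappedSide(elements, charges, aromatic, bonds)


def _parse_pair(rsmi: str, psmi: str) -> Tuple[_MappedSide, _MappedSide]:
    r, p = _parse_side(rsmi), _parse_side(psmi)
    if set(r.elements) != set(p.elements):
        raise AnalysisInputError("map-number sets differ between reactant and product")
    for m in r.elements:
        if r.elements[m] != p.elements[m]:
            raise AnalysisInputError(f"element changes at map {m}")
    return r, p


# ---------------------------------------------------------------------------
# bond-change statistics
# ---------------------------------------------------------------------------


def count_bond_changes(rsmi: str, psmi: str) -> int:
    """Number of connectivity changes (broken + formed), ignoring bond orders."""
    r, p = _parse_pair(rsmi, psmi)
    rb, pb = set(r.bonds), set(p.bonds)
    return len(rb - pb) + len(pb - rb)


def _pair_label(el_i: str, el_j: str) -> str:
    a, b = sorted((el_i, el_j))
    return f"{a}-{b}"


def bond_change_types(rsmi: str, psmi: str) -> Counter:
    """Multiset of unordered element-pair labels, one per change.

    Covers every connectivity change (a bond between C and N forming *or*
    breaking both count as "C-N") plus every bonded pair whose bond order
    differs between the two sides.
    """
    r, p = _parse_pair(rsmi, psmi)
    rb, pb = set(r.bonds), set(p.bonds)
    labels = Counter()
    for i, j in (rb - pb) | (pb - rb):
        labels[_pair_label(r.elements[i], r.elements[j])] += 1
    for i, j in rb & pb:
        if r.bonds[(i, j)] != p.bonds[(i, j)]:
            labels[_pair_label(r.elements[i], r.elements[j])] += 1
    return labels


def reactive_center(rsmi: str, psmi: str) -> Set[int]:
    """Map numbers of all atoms incident to a connectivity or bond-order change."""
    r, p = _parse_pair(rsmi, psmi)
    rb, pb = set(r.bonds), set(p.bonds)
    center: Set[int] = set()
    for i, j in (rb - pb) | (pb - rb):
        center.update((i, j))
    for i, j in rb & pb:
        if r.bonds[(i, j)] != p.bonds[(i, j)]:
            center.update((i, j))
    if not center:
        raise NoReactionError("identity reaction has no reactive center")
    return center


# ---------------------------------------------------------------------------
# reaction templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionTemplate:
    """A general template over the reactive center.

    The serialization considers exactly four per-atom/bond features:
    element identity, formal charge, aromaticity, and bond type; it is
    canonical (relabeling-invariant) and spectator-invariant by
    construction since only center atoms and their mutual bonds enter.
    """

    template: str

    def __str__(self) -> str:
        return self.template


def _canonical_fragment(
    atoms: List[Tuple[str, int, bool]], edges: Dict[Tuple[int, int], int]
) -> str:
    """Lexicographically minimal serialization of a small feature graph.

    Atoms are (element, charge, aromatic) triples and edges carry bond
    types.  The minimum is taken over all relabelings consistent with a
    Weisfeiler-Lehman pre-partition (centers are small, so this is cheap
    and exactly canonical).
    """
    n = len(atoms)

    def serialize(order: Sequence[int]) -> str:
        pos = {old: new for new, old in enumerate(order)}
        toks = []
        for old in order:
            el, q, ar = atoms[old]
            toks.append(f"[{el.lower() if ar else el}{q:+d}]")
        etoks = sorted(
            f"{min(pos[i], pos[j])}{BOND_SYMBOL.get(o, '~')}{max(pos[i], pos[j])}"
            for (i, j), o in edges.items()
        )
        return "".join(toks) + "(" + ",".join(etoks) + ")"

    # WL refinement to cut the permutation space
    colors = [repr(a) for a in atoms]
    for _ in range(n):
        new = []
        for i in range(n):
            nbr = sorted(
                (colors[j], BOND_SYMBOL.get(o, "~"))
                for (a, b), o in edges.items()
                for j in ((b,) if a == i else (a,) if b == i else ())
            )
            new.append(repr((colors[i], nbr)))
        if len(set(new)) == len(set(colors)):
            colors = new
            break
        colors = new
    groups: Dict[str, List[int]] = {}
    for i, c in enumerate(colors):
        groups.setdefault(c, []).append(i)
    blocks = [groups[c] for c in sorted(groups)]
    best: Optional[str] = None
    for parts in _block_permutations(blocks):
        s = serialize(parts)
        if best is None or s < best:
            best = s
    return best or "()"


def _block_permutations(blocks: List[List[int]]):
    """All orderings permuting atoms only within their WL color blocks."""

    def rec(k: int, prefix: List[int]):
        if k == len(blocks):
            yield prefix
            return
        for perm in permutations(blocks[k]):
            yield from rec(k + 1, prefix + list(perm))

    yield from rec(0, [])


def _side_template(side: _MappedSide, center: Set[int]) -> str:
    """Canonical serialization of the center-induced fragments of one side."""
    # split center into connected components within this side's bonds
    nodes = sorted(center)
    adj = {m: set() for m in nodes}
    for (i, j), _ in side.bonds.items():
        if i in center and j in center:
            adj[i].add(j)
            adj[j].add(i)
    seen: Set[int] = set()
    frags = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], []
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(adj[v] - seen)
        comp = sorted(comp)
        local = {m: k for k, m in enumerate(comp)}
        atoms = [(side.elements[m], side.charges[m], side.aromatic[m]) for m in comp]
        edges = {
            (local[i], local[j]): o
            for (i, j), o in side.bonds.items()
            if i in local and j in local
        }
        frags.append(_canonical_fragment(atoms, edges))
    return ".".join(sorted(frags))


def extract_template(rsmi: str, psmi: str) -> ReactionTemplate:
    """Reaction template over the reactive center, as reactants>>products.

    Only center atoms and the bonds among them enter; adding spectator
    atoms far from the center leaves the template unchanged, and two
    relabeled copies of the same reaction produce identical strings.
    """
    center = reactive_center(rsmi, psmi)
    r, p = _parse_pair(rsmi, psmi)
    return ReactionTemplate(_side_template(r, center) + ">>" + _side_template(p, center))


# ---------------------------------------------------------------------------
# table-level summaries
# ---------------------------------------------------------------------------


def template_ranking(table: pd.DataFrame) -> List[Tuple[str, int]]:
    """Templates with example counts, sorted by count desc then template asc."""
    counts = Counter(
        extract_template(row.rsmi, row.psmi).template for row in table.itertuples()
    )
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def bond_change_type_counts(table: pd.DataFrame) -> Counter:
    """Aggregate bond-change-type counts over a reaction table."""
    total = Counter()
    for row in table.itertuples():
        total.update(bond_change_types(row.rsmi, row.psmi))
    return total


def gaussian_kde_1d(
    values: np.ndarray, grid: Optional[np.ndarray] = None, bandwidth: Optional[float] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE on a grid wide enough to hold essentially all the mass.

    Bandwidth defaults to Scott's factor n**(-1/5) times the sample
    standard deviation (floored to keep degenerate samples finite); the
    returned density integrates to 1 on its grid to high accuracy.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise AnalysisInputError("empty sample")
    if bandwidth is None:
        sigma = float(np.std(values))
        bandwidth = max(sigma, 1e-3) * n ** (-1.0 / 5.0)
    if grid is None:
        lo = values.min() - 8 * bandwidth
        hi = values.max() + 8 * bandwidth
        grid = np.linspace(lo, hi, 512)
    z = (grid[:, None] - values[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (n * bandwidth * np.sqrt(2 * np.pi))
    return grid, dens


def ea_by_change_count(table: pd.DataFrame) -> Dict[int, Tuple[np.ndarray, np.ndarray]]:
    """Activation-energy density per number of bond changes, each of unit area."""
    out: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    counts = [count_bond_changes(row.rsmi, row.psmi) for row in table.itertuples()]
    ea = table["ea"].to_numpy(dtype=float)
    for c in sorted(set(counts)):
        sel = ea[[k for k, cc in enumerate(counts) if cc == c]]
        out[c] = gaussian_kde_1d(sel)
    return out


def kde2d(
    table: pd.DataFrame,
    gridsize: int = 128,
    bandwidth: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bivariate Gaussian kernel density of (dh, ea).

    Product Gaussian kernels with per-dimension Scott bandwidths
    (sigma * n**(-1/6)) unless explicit bandwidths are given.  Returns
    (dh_grid, ea_grid, density) with density integrating to 1 on the grid
    to within a fraction of a percent.
    """
    x = table["dh"].to_numpy(dtype=float)
    y = table["ea"].to_numpy(dtype=float)
    n = len(x)
    if n == 0:
        raise AnalysisInputError("empty table")
    if bandwidth is None:
        hx = max(float(np.std(x)), 1e-3) * n ** (-1.0 / 6.0)
        hy = max(float(np.std(y)), 1e-3) * n ** (-1.0 / 6.0)
    else:
        hx, hy = bandwidth
    gx = np.linspace(x.min() - 8 * hx, x.max() + 8 * hx, gridsize)
    gy = np.linspace(y.min() - 8 * hy, y.max() + 8 * hy, gridsize)
    zx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    zy = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    density = (zx[:, None, :] * zy[None, :, :]).mean(axis=2)
    return gx, gy, density


def load_reaction_table(csv_path) -> pd.DataFrame:
    """Read a dataset CSV (columns idx,rsmi,psmi,ea,dh)."""
    return pd.read_csv(csv_path)
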