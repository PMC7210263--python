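"""Connectivity-graph core: symmetry classes, change application, isomorphism."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxnforge import molgraph as mg
from rxnforge.perception import graph_from_smiles

from conftest import SMALL_MOLECULES, simple_graph


def brute_force_orbits(g):
    """Automorphism orbits by literal search over element-preserving permutations."""
    n = g.n_atoms
    autos = []
    for perm in permutations(range(n)):
        if all(g.atoms[i].element == g.atoms[perm[i]].element for i in range(n)) and all(
            (min(perm[i], perm[j]), max(perm[i], perm[j])) in g.bonds for i, j in g.bonds
        ):
            autos.append(perm)
    orbits = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        orbit = {a[i] for a in autos}
        seen |= orbit
        orbits.append(frozenset(orbit))
    return sorted(orbits, key=min)


def brute_force_isomorphism(g1, g2):
    """All element/adjacency-preserving bijections as image tuples."""
    n = g1.n_atoms
    if n != g2.n_atoms:
        return []
    out = []
    for perm in permutations(range(n)):
        if all(g1.atoms[i].element == g2.atoms[perm[i]].element for i in range(n)) and all(
            ((min(perm[i], perm[j]), max(perm[i], perm[j])) in g2.bonds) == ((i, j) in g1.bonds)
            for i in range(n)
            for j in range(i + 1, n)
        ):
            out.append(perm)
    return out


class TestSymmetryClasses:
    def test_methane_full_hydrogen_orbit(self, methane):
        assert mg.symmetry_classes(methane) == [frozenset({0}), frozenset({1, 2, 3, 4})]

    def test_methanol_distinguishes_oh_from_ch(self):
        g = graph_from_smiles("CO")  # C0 O1 H2 H3 H4 (on C) H5 (on O)
        classes = mg.symmetry_classes(g)
        ch = next(c for c in classes if 2 in c)
        oh = next(c for c in classes if 5 in c)
        assert ch == frozenset({2, 3, 4})
        assert oh == frozenset({5})

    @pytest.mark.parametrize("smiles", [s for s in SMALL_MOLECULES if len(graph_from_smiles(s).atoms) <= 8])
    def test_matches_bruteforce_automorphism_orbits(self, smiles):
        g = graph_from_smiles(smiles)
        assert mg.symmetry_classes(g) == brute_force_orbits(g)

    def test_no_class_mixes_elements(self):
        for smiles in SMALL_MOLECULES:
            g = graph_from_smiles(smiles)
            for cls in mg.symmetry_classes(g):
                assert len({g.atoms[i].element for i in cls}) == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_relabeling_permutes_classes(self, random):
        smiles = random.choice(SMALL_MOLECULES)
        g = graph_from_smiles(smiles)
        perm = list(range(g.n_atoms))
        random.shuffle(perm)
        relabeled = g.relabel(perm)
        expected = sorted(
            (frozenset(perm[i] for i in cls) for cls in mg.symmetry_classes(g)), key=min
        )
        assert mg.symmetry_classes(relabeled) == expected


class TestApplyChanges:
    def test_water_h_transfer(self, water):
        out = mg.apply_changes(water, breaks={(0, 1)}, forms={(1, 2)})
        assert out.bonds == frozenset({(0, 2), (1, 2)})
        assert water.bonds == frozenset({(0, 1), (0, 2)})  # input untouched

    def test_empty_changes_identity(self, methane):
        assert mg.apply_changes(methane, set(), set()) == methane

    def test_forming_existing_bond_rejected(self, water):
        with pytest.raises(mg.InvalidChangeError):
            mg.apply_changes(water, set(), forms={(0, 1)})

    def test_breaking_nonbond_rejected(self, water):
        with pytest.raises(mg.InvalidChangeError):
            mg.apply_changes(water, breaks={(1, 2)}, forms=set())

    def test_roundtrip_with_bond_changes(self, rng):
        for smiles in ("CCO", "CC=O", "CNC"):
            g = graph_from_smiles(smiles)
            bonds = sorted(g.bonds)
            nonbonds = [
                (i, j)
                for i in range(g.n_atoms)
                for j in range(i + 1, g.n_atoms)
                if (i, j) not in g.bonds
            ]
            for _ in range(20):
                breaks = {bonds[k] for k in rng.choice(len(bonds), 2, replace=False)}
                forms = {nonbonds[k] for k in rng.choice(len(nonbonds), 2, replace=False)}
                product = mg.apply_changes(g, breaks, forms)
                broken, formed = mg.bond_changes(g, product)
                assert broken == breaks and formed == forms


class TestValence:
    def test_underbonded_carbon_infeasible(self):
        g = simple_graph(["C", "H"], [(0, 1)])
        assert not mg.is_valence_feasible(g)

    def test_water_feasible(self, water):
        assert mg.is_valence_feasible(water)

    def test_overbonded_nitrogen_infeasible(self):
        g = simple_graph(["N", "H", "H", "H", "H"], [(0, 1), (0, 2), (0, 3), (0, 4)])
        assert not mg.is_valence_feasible(g)

    def test_unsupported_element_rejected(self):
        with pytest.raises(mg.UnsupportedElementError):
            mg.Atom(0, "S")


class TestIsomorphism:
    def test_identity(self, methane):
        assert mg.connectivity_isomorphism(methane, methane) == [0, 1, 2, 3, 4]

    def test_different_elements_none(self):
        assert (
            mg.connectivity_isomorphism(graph_from_smiles("CN"), graph_from_smiles("CO"))
            is None
        )

    @pytest.mark.parametrize(
        "smiles", [s for s in SMALL_MOLECULES if graph_from_smiles(s).n_atoms <= 8]
    )
    def test_permuted_copy_agrees_with_bruteforce(self, smiles, rng):
        g = graph_from_smiles(smiles)
        perm = rng.permutation(g.n_atoms).tolist()
        h = g.relabel(perm)
        iso = mg.connectivity_isomorphism(g, h)
        all_isos = brute_force_isomorphism(g, h)
        assert iso is not None and tuple(iso) in all_isos
        assert tuple(iso) == min(all_isos)  # lexicographically smallest image sequence

    def test_composed_map_is_automorphism(self, rng):
        g = graph_from_smiles("CCO")
        perm = rng.permutation(g.n_atoms).tolist()
        h = g.relabel(perm)
        iso = mg.connectivity_isomorphism(g, h)
        # inverse-permute the image: must be an automorphism of g
        composed = [perm.index(iso[i]) for i in range(g.n_atoms)]
        assert tuple(composed) in brute_force_isomorphism(g, g)


class TestBondChanges:
    def test_identical_graphs_empty_diff(self, water):
        assert mg.bond_changes(water, water) == (set(), set())

    def test_water_dissociation_diff(self, water):
        product = simple_graph(["O", "H", "H"], [(0, 2), (1, 2)])
        assert mg.bond_changes(water, product) == ({(0, 1)}, {(1, 2)})

    def test_atom_count_mismatch_rejected(self, water, methane):
        with pytest.raises(mg.MappingMismatchError):
            mg.bond_changes(water, methane)

    def test_element_mismatch_rejected(self):
        g1 = simple_graph(["O", "H"], [(0, 1)])
        g2 = simple_graph(["N", "H"], [(0, 1)])
        with pytest.raises(mg.MappingMismatchError):
            mg.bond_changes(g1, g2)
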