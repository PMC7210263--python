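"""Perception: connectivity from distances, bond orders, identity, atom maps."""

from itertools import product as iproduct

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, rdDistGeom

from rxnforge import perception as pc
from rxnforge.molgraph import bond_changes, connectivity_isomorphism

from conftest import SMALL_MOLECULES, simple_graph


def embedded_geometry(smiles, seed=7):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = rdDistGeom.ETKDGv3()
    params.randomSeed = seed
    assert rdDistGeom.EmbedMolecule(mol, params) == 0
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    return [a.GetSymbol() for a in mol.GetAtoms()], mol.GetConformer().GetPositions()


class TestConnectivity:
    def test_oh_within_cutoff(self):
        g = pc.perceive_connectivity(["O", "H"], [[0, 0, 0], [0.96, 0, 0]])
        assert g.bonds == frozenset({(0, 1)})  # 0.96 <= 1.2*(0.66+0.31)

    def test_distant_hydrogens_unbonded(self):
        g = pc.perceive_connectivity(["H", "H"], [[0, 0, 0], [2.0, 0, 0]])
        assert g.bonds == frozenset()  # 2.0 > 1.2*0.62

    def test_overlapping_atoms_rejected(self):
        with pytest.raises(pc.GeometryError):
            pc.perceive_connectivity(["H", "H"], [[0, 0, 0], [0.2, 0, 0]])

    @pytest.mark.parametrize("smiles", ["O", "CC", "C=O", "c1ccccc1", "C1CCO1"])
    def test_embedded_geometry_recovers_graph(self, smiles):
        elements, geometry = embedded_geometry(smiles)
        perceived = pc.perceive_connectivity(elements, geometry)
        assert perceived.bonds == pc.graph_from_smiles(smiles).bonds


def exhaustive_order_oracle(g):
    """Minimal-leftover-unsaturation order assignment by literal enumeration."""
    bonds = sorted(g.bonds)
    best, best_left = None, None
    for orders in iproduct((1, 2, 3), repeat=len(bonds)):
        totals = [0] * g.n_atoms
        for (i, j), o in zip(bonds, orders):
            totals[i] += o
            totals[j] += o
        leftovers = [
            pc.VALENCE_TARGETS[a.element] - totals[a.index] for a in g.atoms
        ]
        if any(x < 0 for x in leftovers):
            continue
        left = sum(leftovers)
        if best_left is None or left < best_left:
            best, best_left = dict(zip(bonds, orders)), left
    return best, best_left


class TestBondOrders:
    def test_saturated_molecule_all_single(self):
        orders = pc.assign_bond_orders(pc.graph_from_smiles("CC"))
        assert set(orders.values()) == {1}

    def test_ethene_gets_double_bond(self):
        g = pc.graph_from_smiles("C=C")
        orders = pc.assign_bond_orders(g)
        assert orders[(0, 1)] == 2

    def test_ethyl_radical_keeps_single_cc(self):
        g = simple_graph(
            ["C", "C", "H", "H", "H", "H", "H"],
            [(0, 1), (0, 2), (0, 3), (0, 4), (1, 5), (1, 6)],
        )
        orders = pc.assign_bond_orders(g)
        assert orders[(0, 1)] == 1
        assert sum(pc.radical_electrons(g, orders)) == 1

    @pytest.mark.parametrize("smiles", [s for s in SMALL_MOLECULES if pc.graph_from_smiles(s).n_atoms <= 9])
    def test_matches_exhaustive_saturation_oracle(self, smiles):
        g = pc.graph_from_smiles(smiles)
        orders = pc.assign_bond_orders(g)
        _, best_left = exhaustive_order_oracle(g)
        assert sum(pc.radical_electrons(g, orders)) == best_left


class TestIdentityKey:
    def test_relabeling_invariance(self, rng):
        for smiles in ("O", "CCO", "CC=O", "c1ccccc1"):
            g = pc.graph_from_smiles(smiles)
            base = pc.identity_key(g)
            for _ in range(30):
                perm = rng.permutation(g.n_atoms).tolist()
                assert pc.identity_key(g.relabel(perm)) == base

    def test_keto_enol_tautomers_distinct(self):
        assert pc.identity_key(pc.graph_from_smiles("CC=O")) != pc.identity_key(
            pc.graph_from_smiles("C=CO")
        )

    def test_constitutional_isomers_distinct(self):
        assert pc.identity_key(pc.graph_from_smiles("CCO")) != pc.identity_key(
            pc.graph_from_smiles("COC")
        )

    def test_fallback_backend_induces_same_partition(self, rng):
        corpus = ["O", "N", "CO", "CC=O", "C=CO", "CCO", "COC", "OCO", "CN"]
        graphs = [pc.graph_from_smiles(s) for s in corpus]
        relabeled = []
        for g in graphs:
            perm = rng.permutation(g.n_atoms).tolist()
            relabeled.append(g.relabel(perm))
        for backend in (True, False):
            keys = [pc.identity_key(g, use_inchi=backend) for g in graphs + relabeled]
            # each molecule equals its relabeled twin; all distinct otherwise
            n = len(graphs)
            for i in range(n):
                assert keys[i] == keys[n + i]
            assert len(set(keys[:n])) == n


class TestAtomMappedSmiles:
    def test_water_roundtrip(self):
        g = pc.graph_from_smiles("O")
        p = pc.perceived_from_graph(g)
        smi = pc.atom_mapped_smiles(p, g)
        back = pc.graph_from_smiles(smi)  # reorders by map number
        assert back.bonds == g.bonds and back.elements == g.elements

    def test_permuted_methane_maps_through_isomorphism(self, rng, methane):
        p_graph = methane.relabel(rng.permutation(5).tolist())
        p = pc.perceived_from_graph(p_graph)
        smi = pc.atom_mapped_smiles(p, methane)
        back = pc.graph_from_smiles(smi)
        assert back.bonds == methane.bonds and back.elements == methane.elements

    def test_element_mismatch_fails(self):
        p = pc.perceived_from_graph(pc.graph_from_smiles("O"))
        with pytest.raises(pc.MappingFailureError):
            pc.atom_mapped_smiles(p, pc.graph_from_smiles("N"))


class TestReactionSmiles:
    def test_fragment_conservation(self):
        reactant_g = pc.graph_from_smiles("C")  # CH4 -> CH2 + H2
        product_g = simple_graph(
            ["C", "H", "H", "H", "H"], [(0, 3), (0, 4), (1, 2)]
        )
        r = pc.perceived_from_graph(reactant_g)
        p = pc.perceived_from_graph(product_g)
        rsmi, psmi = pc.reaction_smiles(r, pc.split_fragments(p), reactant_g)
        assert psmi.count(".") == 1
        r_maps = sorted(a.GetAtomMapNum() for a in Chem.MolFromSmiles(rsmi, _params()).GetAtoms())
        p_maps = sorted(
            a.GetAtomMapNum()
            for frag in psmi.split(".")
            for a in Chem.MolFromSmiles(frag, _params()).GetAtoms()
        )
        assert r_maps == p_maps == [1, 2, 3, 4, 5]

    def test_unimolecular_single_fragment(self):
        g = pc.graph_from_smiles("CC=O")
        iso = simple_graph(
            ["C", "C", "O", "H", "H", "H", "H"],
            [(0, 1), (1, 2), (0, 3), (0, 4), (1, 5), (2, 6)],  # vinyl alcohol skeleton
        )
        r = pc.perceived_from_graph(g)
        p = pc.perceived_from_graph(iso)
        _, psmi = pc.reaction_smiles(r, pc.split_fragments(p), g)
        assert "." not in psmi

    def test_missing_atom_rejected(self):
        g = pc.graph_from_smiles("O")
        frag, _ = pc.graph_from_smiles("[H][H]"), None
        p = pc.perceived_from_graph(frag)
        with pytest.raises(pc.MappingFailureError):
            pc.reaction_smiles(pc.perceived_from_graph(g), [(p, (0, 1))], g)


def _params():
    params = Chem.SmilesParserParams()
    params.removeHs = False
    return params


def test_roundtrip_identity_through_geometry():
    """Embed a molecule, perceive it from raw coordinates, and recover its identity."""
    for smiles in ("O", "CCO", "CC=O", "C1CC1"):
        elements, geometry = embedded_geometry(smiles)
        perceived = pc.perceive_molecule(elements, geometry)
        assert perceived.identity_key == pc.identity_key(pc.graph_from_smiles(smiles))
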