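"""Shared fixtures: molecule corpora and small constructors."""

import numpy as np
import pytest

from rxnforge.molgraph import Atom, MolGraph

# closed-shell H/C/N/O molecules with at most 4 heavy atoms (driving-coordinate
# enumeration oracle corpus; the oracle iterates literally over all subsets,
# so these stay small)
SMALL_MOLECULES = [
    "[H][H]",
    "O",
    "N",
    "C",
    "CO",
    "CC",
    "CN",
    "C=O",
    "C#N",
    "OO",
    "NN",
    "NO",
    "C=C",
    "C#C",
    "C=N",
    "CCO",
    "CCC",
    "CCN",
    "COC",
    "CNC",
    "OCO",
    "NCO",
    "CC=O",
    "CC#N",
    "OC=O",
]

# wider perception corpus (up to 7 heavy atoms, rings and aromatics included)
PERCEPTION_MOLECULES = SMALL_MOLECULES + [
    "C=CC",
    "CC(C)C",
    "CCCC",
    "CCCO",
    "CC(=O)C",
    "CC(=O)O",
    "C1CC1",
    "C1CCC1",
    "C1CCO1",
    "C1CCNC1",
    "c1ccccc1",
    "c1ccncc1",
    "c1cc[nH]c1",
    "C=CC=C",
    "N#CC#N",
]


def graph(smiles):
    from rxnforge.perception import graph_from_smiles

    return graph_from_smiles(smiles)


def simple_graph(elements, bonds):
    """MolGraph from element list + bond pairs (no coordinates)."""
    return MolGraph([Atom(i, el) for i, el in enumerate(elements)], bonds)


@pytest.fixture
def water():
    return simple_graph(["O", "H", "H"], [(0, 1), (0, 2)])


@pytest.fixture
def methane():
    return simple_graph(["C", "H", "H", "H", "H"], [(0, 1), (0, 2), (0, 3), (0, 4)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
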