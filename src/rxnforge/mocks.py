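"""Deterministic mock external engine and verification fixtures.

The real workflow delegates three kinds of jobs to an electronic-
structure engine: geometry optimization + frequencies for minima,
string-path searches seeded by driving coordinates, and transition-state
optimization + frequencies.  The :class:`MockEngine` here implements the
same executor contract with physically *shaped* synthetic output --
energies from a deterministic per-graph energy model, geometries from
distance-geometry embedding of the product connectivity, string paths
with a planted barrier, and transition-state imaginary modes constructed
(by least squares) to displace exactly the changing bonds.  Everything is
a pure function of the campaign seed and the job text, so campaigns are
bit-reproducible and resumable with a fresh engine instance.

The module also provides the seeded defect-injection fixtures used to
exercise the verification filter stack: reactant/TS/product triples that
are clean, or planted with a second imaginary frequency, an imaginary
frequency below the 100 cm^-1 cutoff, an energy drift above 3 kcal/mol,
or a spectator-localized imaginary mode.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDistGeom

from rxnforge import perception, qcio
from rxnforge.driving import DrivingCoordinateSet, parse_isomers_file
from rxnforge.molgraph import Bond, MolGraph, apply_changes
from rxnforge.qcio import OptFreqResult, StringPath

HARTREE_PER_KCAL = 1.0 / 627.5095

# crude per-element electronic energies (hartree) for the mock energy model
_ELEMENT_ENERGY = {"H": -0.5004, "C": -37.8400, "N": -54.5800, "O": -75.0600}


def seeded_rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic RNG derived from a campaign seed and string tokens."""
    tag = "|".join(str(t) for t in tokens)
    sub = (zlib.crc32(tag.encode()) ^ (seed & 0x7FFFFFFF)) & 0x7FFFFFFF
    return np.random.default_rng(sub)


def mock_electronic_energy(graph: MolGraph, level_tag: str) -> float:
    """Deterministic 'electronic energy' (hartree) of a connectivity graph.

    Sum of per-element baselines, a stabilization per bond, and a
    reproducible hash perturbation of the molecular identity so that
    isomers differ.  Purely synthetic numbers with realistic magnitudes.
    """
    key = perception.identity_key(graph, use_inchi=False)
    u = zlib.crc32(f"{key}|{level_tag}".encode()) / 2**32
    base = sum(_ELEMENT_ENERGY[a.element] for a in graph.atoms)
    return base - 0.035 * len(graph.bonds) - 0.15 * u


# ---------------------------------------------------------------------------
# geometry synthesis
# ---------------------------------------------------------------------------


def embed_graph_geometry(g: MolGraph, seed: int) -> np.ndarray:
    """3D coordinates realizing a connectivity graph, fragment by fragment.

    Each connected component is embedded with ETKDG distance geometry
    (radical centers allowed); fragments are then spaced 8 A apart along x
    so that distance-based perception recovers exactly the input
    connectivity.  Raises :class:`perception.PerceptionError` when the
    embedding cannot realize the graph.
    """
    coords = np.zeros((g.n_atoms, 3))
    x_cursor = 0.0
    for comp in g.connected_components():
        sub, parent = g.subgraph(comp)
        mol = perception.to_rdkit(sub, perception.assign_bond_orders(sub))
        for atom, nrad in zip(
            mol.GetAtoms(), perception.radical_electrons(sub, perception.assign_bond_orders(sub))
        ):
            atom.SetNumRadicalElectrons(int(nrad))
        params = rdDistGeom.ETKDGv3()
        params.randomSeed = int(seeded_rng(seed, "embed", sorted(comp)).integers(1, 2**31 - 1))
        if rdDistGeom.EmbedMolecule(mol, params) != 0:
            raise perception.PerceptionError(f"embedding failed for fragment {comp}")
        pos = mol.GetConformer().GetPositions()
        pos = pos - pos.min(axis=0)
        pos[:, 0] += x_cursor
        x_cursor = pos[:, 0].max() + 8.0
        for k, p in enumerate(parent):
            coords[p] = pos[k]
    check = perception.perceive_connectivity([a.element for a in g.atoms], coords)
    if check.bonds != g.bonds:
        raise perception.PerceptionError("embedded geometry does not reproduce connectivity")
    return coords


def plant_mode(
    geometry: np.ndarray, targets: Dict[Bond, float]
) -> np.ndarray:
    """Cartesian displacement field with prescribed bond-projection scores.

    Solves, in the least-squares sense, (u_i - u_j) . e_ij = v for every
    (i,j) -> v in `targets`, where e_ij is the unit interatomic direction
    in `geometry`; returns the minimum-norm solution normalized to unit
    Euclidean length.  With targets of 1 on the changing bonds and 0 on
    every unchanged bond this manufactures an imaginary mode that the
    mode-match filter accepts (and the reverse assignment one it
    rejects).
    """
    geometry = np.asarray(geometry, dtype=float)
    n = geometry.shape[0]
    a = np.zeros((len(targets), 3 * n))
    b = np.zeros(len(targets))
    for row, ((i, j), v) in enumerate(sorted(targets.items())):
        axis = geometry[j] - geometry[i]
        axis = axis / np.linalg.norm(axis)
        a[row, 3 * i : 3 * i + 3] = axis
        a[row, 3 * j : 3 * j + 3] = -axis
        b[row] = v
    u, *_ = np.linalg.lstsq(a, b, rcond=None)
    u = u.reshape(n, 3)
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise ValueError("planted mode is identically zero")
    return u / nrm


def _random_modes(rng: np.random.Generator, nmodes: int, natoms: int) -> np.ndarray:
    modes = rng.normal(size=(max(nmodes, 1), natoms, 3))[:nmodes]
    if nmodes:
        modes /= np.linalg.norm(modes.reshape(nmodes, -1), axis=1)[:, None, None]
    return modes


def _positive_frequencies(rng: np.random.Generator, count: int) -> List[float]:
    return sorted(float(f) for f in rng.uniform(200.0, 3500.0, size=count))


def _n_vib(natoms: int, linear: bool = False) -> int:
    if natoms == 1:
        return 0
    return max(3 * natoms - (5 if natoms == 2 or linear else 6), 1)


# ---------------------------------------------------------------------------
# mock engine (Executor contract)
# ---------------------------------------------------------------------------

GSM_FAILURE_MARKER = "ENGINE-FAILURE"


def make_gsm_job(
    elements: Sequence[str], geometry: np.ndarray, dcs: DrivingCoordinateSet, job_id: str
) -> str:
    """String-path job input: header, coordinate specification, reactant XYZ."""
    from rxnforge.driving import format_isomers_file

    return (
        f"GSM-JOB 1\nid {job_id}\n"
        + format_isomers_file(dcs)
        + qcio.write_xyz(elements, geometry, comment=job_id)
    )


def _parse_gsm_job(text: str):
    lines = text.splitlines()
    job_id = lines[1].split()[1]
    iso_end = next(k for k, ln in enumerate(lines) if ln.split() and ln.split()[0].isdigit())
    dcs = parse_isomers_file("\n".join(lines[2:iso_end]))
    elements, geometry = qcio.read_xyz("\n".join(lines[iso_end:]))
    return job_id, dcs, elements, geometry


def _format_pairs(pairs) -> str:
    return ";".join(f"{i}-{j}" for i, j in sorted(pairs)) or "-"


def _parse_pairs(text: str):
    if text == "-":
        return []
    return [tuple(int(x) for x in p.split("-")) for p in text.split(";")]


@dataclass
class MockEngine:
    """Deterministic stand-in for the external engine (executor contract).

    ``fail_rates`` maps job kinds ("opt", "gsm", "prodopt", "tsopt") to
    the probability that a job of that kind is reported failed; failure
    is decided reproducibly from the seed and job id.
    """

    seed: int
    fail_rates: Optional[Dict[str, float]] = None

    def _fails(self, kind: str, job_id: str) -> bool:
        rate = (self.fail_rates or {}).get(kind, 0.0)
        return rate > 0 and seeded_rng(self.seed, "fail", kind, job_id).random() < rate

    def run(self, job_text: str) -> str:
        """Execute one job synchronously; returns the output file text."""
        if job_text.startswith("GSM-JOB"):
            return self._run_gsm(job_text)
        comment, elements, geometry, charge, mult, rem = qcio.parse_engine_input(job_text)
        tokens = comment.split()
        kind, job_id = tokens[0], tokens[1]
        if self._fails(kind, job_id):
            return f"{GSM_FAILURE_MARKER} {kind} {job_id}\n"
        if kind in ("opt", "prodopt"):
            return self._run_minimum(kind, job_id, elements, geometry, rem)
        if kind == "tsopt":
            return self._run_tsopt(job_id, tokens, elements, geometry, rem)
        raise qcio.QCIOError(f"unknown mock job kind {kind!r}")

    # -- minima ----------------------------------------------------------

    def _run_minimum(self, kind, job_id, elements, geometry, rem):
        level = f"{rem.get('method', '?')}/{rem.get('basis', '?')}"
        g = perception.perceive_connectivity(elements, geometry)
        rng = seeded_rng(self.seed, kind, job_id)
        energy = mock_electronic_energy(g, level) + 0.0005 * rng.random()
        nvib = _n_vib(len(elements))
        freqs = _positive_frequencies(rng, nvib)
        return qcio.make_mock_optfreq_log(
            elements, geometry, energy, freqs, _random_modes(rng, nvib, len(elements))
        )

    # -- string path -----------------------------------------------------

    def _run_gsm(self, job_text: str) -> str:
        job_id, dcs, elements, geometry = _parse_gsm_job(job_text)
        if self._fails("gsm", job_id):
            return f"{GSM_FAILURE_MARKER} gsm {job_id}\n"
        rng = seeded_rng(self.seed, "gsm", job_id)
        reactant = perception.perceive_connectivity(elements, geometry)
        product = apply_changes(reactant, dcs.breaks, dcs.forms)
        try:
            pgeom = embed_graph_geometry(product, int(rng.integers(1, 2**31 - 1)))
        except perception.PerceptionError:
            return f"{GSM_FAILURE_MARKER} gsm {job_id}\n"
        level = "string"
        e_r = mock_electronic_energy(reactant, level)
        e_p = mock_electronic_energy(product, level)
        barrier = max(0.0, e_p - e_r) + (5.0 + 75.0 * rng.random()) * HARTREE_PER_KCAL
        nodes = 9
        s = np.linspace(0.0, 1.0, nodes)
        energies = (1 - s) * e_r + s * e_p + barrier * np.sin(np.pi * s) ** 2
        ts_geom = pgeom + rng.normal(scale=0.04, size=pgeom.shape)
        return qcio.make_mock_string_output(elements, energies, pgeom, ts_geom)

    # -- transition states ----------------------------------------------

    def _run_tsopt(self, job_id, tokens, elements, geometry, rem):
        # comment grammar: tsopt <id> ref <E_string_max> changing <pairs> unchanged <pairs>
        meta = dict(zip(tokens[2::2], tokens[3::2]))
        ref = float(meta["ref"])
        changing = _parse_pairs(meta["changing"])
        unchanged = _parse_pairs(meta["unchanged"])
        rng = seeded_rng(self.seed, "tsopt", job_id)
        energy = ref + rng.uniform(0.0, 1.0) * HARTREE_PER_KCAL
        natoms = len(elements)
        targets = {tuple(b): 1.0 for b in changing}
        targets.update({tuple(b): 0.0 for b in unchanged})
        imag_mode = plant_mode(geometry, targets)
        nvib = _n_vib(natoms)
        freqs = [-float(rng.uniform(300.0, 1500.0))] + _positive_frequencies(rng, nvib - 1)
        modes = np.concatenate(
            [imag_mode[None], _random_modes(rng, nvib - 1, natoms)], axis=0
        )
        return qcio.make_mock_optfreq_log(elements, geometry, energy, freqs, modes)


def make_tsopt_comment(job_id: str, string_max: float, changing, unchanged) -> str:
    """Provenance comment for a TS-optimization job (consumed by the mock engine)."""
    return (
        f"tsopt {job_id} ref {string_max:.10f} "
        f"changing {_format_pairs(changing)} unchanged {_format_pairs(unchanged)}"
    )


# ---------------------------------------------------------------------------
# verification defect-injection fixtures
# ---------------------------------------------------------------------------

DEFECT_KINDS = ("two_imaginary", "low_imaginary", "energy_drift", "spectator_mode")


@dataclass
class VerificationCase:
    """One planted reactant/TS/product triple with its ground-truth label."""

    r: OptFreqResult
    ts: OptFreqResult
    p: OptFreqResult
    rg: MolGraph
    pg: MolGraph
    string: StringPath
    defect: Optional[str]  # None means clean

    @property
    def should_pass(self) -> bool:
        return self.defect is None


def _rigid_transform(rng: np.random.Generator, geometry: np.ndarray, mode=None):
    """Random proper rotation + translation (applied to the mode rotationally)."""
    q = rng.normal(size=(3, 3))
    rot, _ = np.linalg.qr(q)
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    shift = rng.uniform(-5, 5, size=3)
    geom2 = geometry @ rot.T + shift
    if mode is None:
        return geom2
    return geom2, mode @ rot.T


def make_verification_case(seed: int, index: int, defect: Optional[str] = None) -> VerificationCase:
    """A hydrogen-abstraction toy triple (CH4 + OH -> CH3 + H2O), optionally defective.

    Atom order: C0 H1 H2 H3 H4 O5 H6; the transferring hydrogen is H1.
    The TS geometry is a jittered, rigidly transformed collinear C...H1...O
    arrangement; the clean imaginary mode is planted to stretch exactly
    the changing bonds (C0-H1 broken, H1-O5 formed).
    """
    if defect is not None and defect not in DEFECT_KINDS:
        raise ValueError(f"unknown defect {defect!r}")
    rng = seeded_rng(seed, "vcase", index, defect or "clean")
    elements = ("C", "H", "H", "H", "H", "O", "H")
    rg_bonds = [(0, 1), (0, 2), (0, 3), (0, 4), (5, 6)]
    pg_bonds = [(0, 2), (0, 3), (0, 4), (1, 5), (5, 6)]
    from rxnforge.molgraph import Atom

    rg = MolGraph([Atom(i, el) for i, el in enumerate(elements)], rg_bonds)
    pg = MolGraph([Atom(i, el) for i, el in enumerate(elements)], pg_bonds)
    changing = [(0, 1), (1, 5)]
    unchanged = [(0, 2), (0, 3), (0, 4), (5, 6)]

    # TS skeleton: C at origin, methyl H's pyramidal, H1 between C and O
    ts_geom = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.30, 0.0, 0.0],
            [-0.36, 1.03, 0.0],
            [-0.36, -0.51, 0.89],
            [-0.36, -0.51, -0.89],
            [2.55, 0.0, 0.0],
            [2.90, 0.90, 0.0],
        ]
    )
    ts_geom = ts_geom + rng.normal(scale=0.02, size=ts_geom.shape)
    targets = {b: 1.0 for b in changing}
    targets.update({b: 0.0 for b in unchanged})
    if defect == "spectator_mode":
        targets = {b: 0.0 for b in changing}
        targets[(0, 2)] = 1.0  # localize on an unchanged methyl C-H
    imag_mode = plant_mode(ts_geom, targets)
    ts_geom, imag_mode = _rigid_transform(rng, ts_geom, imag_mode)

    natoms = len(elements)
    nvib = _n_vib(natoms)
    imag_freq = -float(rng.uniform(300.0, 1500.0))
    if defect == "low_imaginary":
        imag_freq = -float(rng.uniform(20.0, 95.0))
    freqs = [imag_freq] + _positive_frequencies(rng, nvib - 1)
    modes = np.concatenate([imag_mode[None], _random_modes(rng, nvib - 1, natoms)])
    if defect == "two_imaginary":
        freqs[1] = -float(rng.uniform(120.0, 400.0))
        freqs = [freqs[0], freqs[1]] + freqs[2:]

    e_r = -115.4 - 0.02 * rng.random()
    e_p = e_r + rng.uniform(-0.02, 0.02)
    barrier = (10.0 + 40.0 * rng.random()) * HARTREE_PER_KCAL
    s = np.linspace(0, 1, 9)
    node_e = (1 - s) * e_r + s * e_p + barrier * np.sin(np.pi * s) ** 2
    string_max = float(node_e.max())
    drift = rng.uniform(0.0, 1.5) * HARTREE_PER_KCAL
    if defect == "energy_drift":
        drift = rng.uniform(3.5, 10.0) * HARTREE_PER_KCAL
    ts_energy = string_max + drift

    r_geom = _rigid_transform(rng, ts_geom * 0.98)
    p_geom = _rigid_transform(rng, ts_geom * 1.02)
    r_rng = seeded_rng(seed, "vcase-r", index, defect or "clean")
    p_rng = seeded_rng(seed, "vcase-p", index, defect or "clean")
    r = OptFreqResult(
        elements, r_geom, e_r, tuple(_positive_frequencies(r_rng, nvib)),
        _random_modes(r_rng, nvib, natoms),
    )
    p = OptFreqResult(
        elements, p_geom, e_p, tuple(_positive_frequencies(p_rng, nvib)),
        _random_modes(p_rng, nvib, natoms),
    )
    ts = OptFreqResult(elements, ts_geom, ts_energy, tuple(freqs), modes)
    string = StringPath(tuple(node_e), p_geom, ts_geom, elements)
    return VerificationCase(r, ts, p, rg, pg, string, defect)


def make_verification_suite(seed: int, n_per_class: int = 10) -> List[VerificationCase]:
    """n_per_class clean triples plus n_per_class of each defect class."""
    cases = [make_verification_case(seed, k, None) for k in range(n_per_class)]
    for defect in DEFECT_KINDS:
        cases.extend(
            make_verification_case(seed, k, defect) for k in range(n_per_class)
        )
    return cases


def random_optfreq_spec(rng: np.random.Generator, natoms: int):
    """Random but internally consistent opt+freq spec for round-trip tests."""
    elements = [str(rng.choice(["H", "C", "N", "O"])) for _ in range(natoms)]
    geometry = rng.uniform(-4, 4, size=(natoms, 3))
    energy = float(rng.uniform(-200.0, -1.0))
    nvib = int(rng.integers(0, 3 * natoms))
    freqs = [float(f) for f in rng.uniform(-800.0, 3800.0, size=nvib)]
    modes = _random_modes(rng, nvib, natoms)
    return elements, geometry, energy, freqs, modes
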