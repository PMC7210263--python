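"""Readers and writers for the external-engine interface.

The pipeline consumes exactly five physical quantities from an
electronic-structure engine: a final electronic energy (hartree), a
converged geometry (angstrom), harmonic frequencies (cm^-1, imaginary
modes printed as negative numbers), per-mode Cartesian displacement
vectors, and -- from a string-path optimizer -- the node energies of a
reaction path together with the endpoint and highest-energy-node
geometries.  This module defines a minimal canonical text dialect carrying
those fields, parsers and writers for it, an engine-input writer, and a
best-effort reader for Q-Chem-style logs behind the same contract.

The canonical dialects are deliberately tiny and versioned:

``OPTFREQ-LOG 1`` ::

    OPTFREQ-LOG 1
    converged true
    charge 0
    multiplicity 1
    final_energy -100.5000000000
    natoms 3
    geometry
    O 0.00000000 0.00000000 0.00000000
    ...
    nmodes 3
    frequencies
    -612.3000 1200.0000 3600.0000
    mode 1
    0.00000000 0.00000000 0.70710678
    ...
    end

``STRING-PATH 1`` ::

    STRING-PATH 1
    natoms 3
    nodes 9
    energies
    -100.1000000000 ... (one float per node)
    endpoint_geometry
    O 0.0 0.0 0.0
    ...
    ts_geometry
    ...
    end

Energies are hartree everywhere in this module; unit conversion lives in
:mod:`rxnforge.energetics` only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


class QCIOError(ValueError):
    """Base error for engine-I/O problems."""


class ParseError(QCIOError):
    """Malformed text for one of the supported dialects."""


class IncompleteLogError(ParseError):
    """A log is missing a required physical quantity."""


class DegeneratePathError(ParseError):
    """A string path with fewer than two nodes."""


class SpecError(QCIOError):
    """An internally inconsistent mock-file specification."""


class ConfigError(QCIOError):
    """An invalid engine configuration."""


# ---------------------------------------------------------------------------
# data records
# ---------------------------------------------------------------------------


@dataclass
class OptFreqResult:
    """Parsed geometry-optimization + harmonic-frequency record."""

    elements: Tuple[str, ...]
    geometry: np.ndarray  # N x 3, angstrom
    energy: float  # hartree
    frequencies: Tuple[float, ...]  # cm^-1, imaginary negative
    modes: np.ndarray  # M x N x 3, unit-normalized Cartesian displacements
    converged: bool = True
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self) -> None:
        self.geometry = np.asarray(self.geometry, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float).reshape(
            len(self.frequencies), len(self.elements), 3
        )
        if self.geometry.shape != (len(self.elements), 3):
            raise QCIOError("geometry row count != number of elements")
        for k, m in enumerate(self.modes):
            nrm = float(np.linalg.norm(m))
            if abs(nrm - 1.0) > 1e-8:
                raise QCIOError(f"mode {k} not unit-normalized (norm {nrm})")

    @property
    def n_imaginary(self) -> int:
        return sum(1 for f in self.frequencies if f < 0)

    def imaginary_mode(self) -> Tuple[float, np.ndarray]:
        """(frequency, displacement) of the unique imaginary mode."""
        idx = [k for k, f in enumerate(self.frequencies) if f < 0]
        if len(idx) != 1:
            raise QCIOError(f"expected exactly one imaginary mode, found {len(idx)}")
        return self.frequencies[idx[0]], self.modes[idx[0]]


@dataclass
class StringPath:
    """Parsed reaction-path record from a string-method output file."""

    node_energies: Tuple[float, ...]  # hartree
    endpoint_geometry: np.ndarray  # N x 3
    ts_geometry: np.ndarray  # N x 3 (highest-energy node)
    elements: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.node_energies) < 2:
            raise DegeneratePathError("string path needs at least two nodes")
        self.endpoint_geometry = np.asarray(self.endpoint_geometry, dtype=float)
        self.ts_geometry = np.asarray(self.ts_geometry, dtype=float)

    @property
    def ts_node_index(self) -> int:
        """Index of the highest-energy node (first occurrence on ties)."""
        return int(np.argmax(self.node_energies))

    @property
    def max_energy(self) -> float:
        return float(self.node_energies[self.ts_node_index])


@dataclass(frozen=True)
class EngineConfig:
    """Level-of-theory and job-type strings passed through to the engine."""

    method: str = "B97-D3"
    basis: str = "def2-mSVP"
    job_type: str = "opt+freq"  # or "ts-opt+freq"
    extra: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.method or not self.basis:
            raise ConfigError("method and basis must be non-empty")

    @property
    def level_tag(self) -> str:
        return f"{self.method}/{self.basis}"


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def read_xyz(text: str) -> Tuple[List[str], np.ndarray]:
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ text")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError("XYZ count line is not an integer")
    rows = [ln for ln in lines[2 : 2 + n]]
    if len(rows) < n:
        raise ParseError(f"XYZ promises {n} atoms but has {len(rows)} rows")
    elements, coords = [], []
    for ln in rows:
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"bad XYZ row: {ln!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.array(coords, dtype=float)


def write_xyz(elements: Sequence[str], geometry: np.ndarray, comment: str = "") -> str:
    geometry = np.asarray(geometry, dtype=float)
    if geometry.shape != (len(elements), 3):
        raise QCIOError("geometry shape mismatch")
    lines = [str(len(elements)), comment.replace("\n", " ")]
    for el, row in zip(elements, geometry):
        lines.append(f"{el} {row[0]:.8f} {row[1]:.8f} {row[2]:.8f}")
    return "\n".join(lines) + "\n"


def _geometry_block(lines: List[str], k: int, natoms: int):
    elements, coords = [], []
    for r in range(natoms):
        parts = lines[k + r].split()
        if len(parts) < 4:
            raise ParseError(f"bad geometry row: {lines[k + r]!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.array(coords, dtype=float), k + natoms


# ---------------------------------------------------------------------------
# canonical opt+freq log dialect
# ---------------------------------------------------------------------------


def parse_optfreq_log(text: str) -> OptFreqResult:
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("OPTFREQ-LOG"):
        raise ParseError("missing OPTFREQ-LOG header")
    fields: Dict[str, str] = {}
    k = 1
    while k < len(lines) and lines[k].split()[0] in (
        "converged",
        "charge",
        "multiplicity",
        "final_energy",
        "natoms",
    ):
        key, val = lines[k].split(None, 1)
        fields[key] = val
        k += 1
    for req in ("final_energy", "natoms"):
        if req not in fields:
            raise IncompleteLogError(f"log missing {req}")
    natoms = int(fields["natoms"])
    if k >= len(lines) or lines[k] != "geometry":
        raise IncompleteLogError("log missing geometry block")
    elements, geometry, k = _geometry_block(lines, k + 1, natoms)
    if k >= len(lines) or not lines[k].startswith("nmodes"):
        raise IncompleteLogError("log missing frequency block")
    nmodes = int(lines[k].split()[1])
    k += 1
    if k >= len(lines) or lines[k] != "frequencies":
        raise IncompleteLogError("log missing frequency block")
    k += 1
    freqs: List[float] = []
    while len(freqs) < nmodes:
        if k >= len(lines):
            raise IncompleteLogError("frequency list truncated")
        freqs.extend(float(x) for x in lines[k].split())
        k += 1
    modes = np.zeros((nmodes, natoms, 3))
    for m in range(nmodes):
        if k >= len(lines) or not lines[k].startswith("mode"):
            raise IncompleteLogError(f"log missing normal mode {m + 1}")
        k += 1
        for r in range(natoms):
            if k >= len(lines):
                raise IncompleteLogError("normal-mode block truncated")
            modes[m, r] = [float(x) for x in lines[k].split()]
            k += 1
        nrm = np.linalg.norm(modes[m])
        if nrm == 0:
            raise ParseError(f"normal mode {m + 1} is all zero")
        modes[m] /= nrm
    return OptFreqResult(
        elements=tuple(elements),
        geometry=geometry,
        energy=float(fields["final_energy"]),
        frequencies=tuple(freqs),
        modes=modes,
        converged=fields.get("converged", "true").lower() == "true",
        charge=int(fields.get("charge", 0)),
        multiplicity=int(fields.get("multiplicity", 1)),
    )


def make_mock_optfreq_log(
    elements: Sequence[str],
    geometry: np.ndarray,
    energy: float,
    frequencies: Sequence[float],
    modes: Optional[np.ndarray] = None,
    converged: bool = True,
    charge: int = 0,
    multiplicity: int = 1,
) -> str:
    """Write a canonical opt+freq log; inverse of :func:`parse_optfreq_log`.

    `modes` may be omitted, in which case deterministic placeholder modes
    (unit vectors cycling over Cartesian components) are emitted.  An
    inconsistent spec (mode count != frequency count) raises
    :class:`SpecError`.
    """
    geometry = np.asarray(geometry, dtype=float)
    natoms = len(elements)
    if geometry.shape != (natoms, 3):
        raise SpecError("geometry shape inconsistent with elements")
    if not math.isfinite(energy):
        raise SpecError("energy must be finite")
    nmodes = len(frequencies)
    if modes is None:
        modes = np.zeros((nmodes, natoms, 3))
        for m in range(nmodes):
            modes[m, m % natoms, m % 3] = 1.0
    modes = np.asarray(modes, dtype=float)
    if modes.shape != (nmodes, natoms, 3):
        raise SpecError(
            f"modes shape {modes.shape} inconsistent with {nmodes} frequencies, {natoms} atoms"
        )
    lines = [
        "OPTFREQ-LOG 1",
        f"converged {'true' if converged else 'false'}",
        f"charge {charge}",
        f"multiplicity {multiplicity}",
        f"final_energy {energy:.10f}",
        f"natoms {natoms}",
        "geometry",
    ]
    for el, row in zip(elements, geometry):
        lines.append(f"{el} {row[0]:.8f} {row[1]:.8f} {row[2]:.8f}")
    lines.append(f"nmodes {nmodes}")
    lines.append("frequencies")
    if nmodes:
        lines.append(" ".join(f"{f:.4f}" for f in frequencies))
    for m in range(nmodes):
        nrm = np.linalg.norm(modes[m])
        if nrm == 0:
            raise SpecError(f"mode {m} is all zero")
        lines.append(f"mode {m + 1}")
        for row in modes[m] / nrm:
            lines.append(f"{row[0]:.10f} {row[1]:.10f} {row[2]:.10f}")
    lines.append("end")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# string-path dialect
# ---------------------------------------------------------------------------


def parse_string_output(text: str) -> StringPath:
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("STRING-PATH"):
        raise ParseError("missing STRING-PATH header")
    try:
        natoms = int(lines[1].split()[1])
        nnodes = int(lines[2].split()[1])
    except (IndexError, ValueError):
        raise ParseError("bad natoms/nodes lines")
    if nnodes < 2:
        raise DegeneratePathError(f"string path with {nnodes} node(s)")
    if lines[3] != "energies":
        raise ParseError("missing energies block")
    k = 4
    energies: List[float] = []
    while len(energies) < nnodes:
        if k >= len(lines):
            raise ParseError("energy list truncated")
        energies.extend(float(x) for x in lines[k].split())
        k += 1
    if k >= len(lines) or lines[k] != "endpoint_geometry":
        raise ParseError("missing endpoint_geometry block")
    elements, endpoint, k = _geometry_block(lines, k + 1, natoms)
    if k >= len(lines) or lines[k] != "ts_geometry":
        raise ParseError("missing ts_geometry block")
    elements2, tsgeom, k = _geometry_block(lines, k + 1, natoms)
    if elements != elements2:
        raise ParseError("endpoint and TS geometries disagree on elements")
    return StringPath(
        node_energies=tuple(energies),
        endpoint_geometry=endpoint,
        ts_geometry=tsgeom,
        elements=tuple(elements),
    )


def make_mock_string_output(
    elements: Sequence[str],
    node_energies: Sequence[float],
    endpoint_geometry: np.ndarray,
    ts_geometry: np.ndarray,
) -> str:
    """Write a canonical string-path file; inverse of :func:`parse_string_output`."""
    if len(node_energies) < 2:
        raise SpecError("string path needs at least two node energies")
    endpoint_geometry = np.asarray(endpoint_geometry, dtype=float)
    ts_geometry = np.asarray(ts_geometry, dtype=float)
    natoms = len(elements)
    if endpoint_geometry.shape != (natoms, 3) or ts_geometry.shape != (natoms, 3):
        raise SpecError("geometry shapes inconsistent with elements")
    lines = [
        "STRING-PATH 1",
        f"natoms {natoms}",
        f"nodes {len(node_energies)}",
        "energies",
        " ".join(f"{e:.10f}" for e in node_energies),
        "endpoint_geometry",
    ]
    for el, row in zip(elements, endpoint_geometry):
        lines.append(f"{el} {row[0]:.8f} {row[1]:.8f} {row[2]:.8f}")
    lines.append("ts_geometry")
    for el, row in zip(elements, ts_geometry):
        lines.append(f"{el} {row[0]:.8f} {row[1]:.8f} {row[2]:.8f}")
    lines.append("end")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# engine input
# ---------------------------------------------------------------------------


def write_engine_input(
    geometry: np.ndarray,
    elements: Sequence[str],
    cfg: EngineConfig,
    charge: int = 0,
    multiplicity: int = 1,
    comment: str = "",
) -> str:
    """Deterministic engine input text: comment, molecule block, job keywords.

    Identical inputs produce byte-identical text.  The comment block
    carries free-form provenance (job id, source path, reference data) and
    is ignored by real engines.
    """
    geometry = np.asarray(geometry, dtype=float)
    if geometry.shape != (len(elements), 3):
        raise QCIOError("geometry shape mismatch")
    lines = ["$comment", comment or "rxnforge job", "$end", "", "$molecule"]
    lines.append(f"{charge} {multiplicity}")
    for el, row in zip(elements, geometry):
        lines.append(f"{el} {row[0]:.8f} {row[1]:.8f} {row[2]:.8f}")
    lines += ["$end", "", "$rem"]
    lines.append(f"jobtype {cfg.job_type}")
    lines.append(f"method {cfg.method}")
    lines.append(f"basis {cfg.basis}")
    for key in sorted(cfg.extra):
        lines.append(f"{key} {cfg.extra[key]}")
    lines += ["$end", ""]
    return "\n".join(lines)


def parse_engine_input(text: str):
    """Read back an engine input: (comment, elements, geometry, charge, mult, rem dict)."""
    comment_lines: List[str] = []
    elements: List[str] = []
    coords: List[List[float]] = []
    charge, mult = 0, 1
    rem: Dict[str, str] = {}
    section = None
    first_mol_line = True
    for ln in text.splitlines():
        s = ln.strip()
        if s == "$end":
            section = None
            continue
        if s.startswith("$"):
            section = s[1:]
            first_mol_line = True
            continue
        if not s:
            continue
        if section == "comment":
            comment_lines.append(s)
        elif section == "molecule":
            if first_mol_line:
                charge, mult = (int(x) for x in s.split())
                first_mol_line = False
            else:
                parts = s.split()
                elements.append(parts[0])
                coords.append([float(x) for x in parts[1:4]])
        elif section == "rem":
            key, val = s.split(None, 1)
            rem[key] = val
    return (
        "\n".join(comment_lines),
        elements,
        np.array(coords, dtype=float).reshape(len(elements), 3),
        charge,
        mult,
        rem,
    )


# ---------------------------------------------------------------------------
# best-effort reader for Q-Chem-style logs
# ---------------------------------------------------------------------------


def parse_qchem_log(text: str) -> OptFreqResult:
    """Best-effort reader for Q-Chem-style opt+freq output.

    Extracts the last "Final energy is" value, the last "Standard
    Orientation" geometry, the "Frequency:" table and its mode
    displacement columns.  Only the five quantities the pipeline consumes
    are read; anything else in the log is ignored.
    """
    lines = text.splitlines()
    energy = None
    for ln in lines:
        if "Final energy is" in ln:
            energy = float(ln.split()[-1])
        elif "Total energy in the final basis set" in ln:
            energy = float(ln.split()[-1])
    if energy is None:
        raise IncompleteLogError("no final energy found")
    geom_start = None
    for k, ln in enumerate(lines):
        if "Standard Nuclear Orientation" in ln:
            geom_start = k + 3  # header + column labels + separator
    if geom_start is None:
        raise IncompleteLogError("no geometry block found")
    elements, coords = [], []
    for ln in lines[geom_start:]:
        parts = ln.split()
        if len(parts) < 5 or not parts[0].isdigit():
            break
        elements.append(parts[1])
        coords.append([float(x) for x in parts[2:5]])
    natoms = len(elements)
    freqs: List[float] = []
    mode_cols: List[np.ndarray] = []
    k = 0
    while k < len(lines):
        ln = lines[k]
        if ln.strip().startswith("Frequency:"):
            block = [float(x) for x in ln.split()[1:]]
            # displacement table: skip to "X Y Z" header
            j = k + 1
            while j < len(lines) and "X" not in lines[j].split():
                j += 1
            cols = [np.zeros((natoms, 3)) for _ in block]
            for r in range(natoms):
                parts = lines[j + 1 + r].split()[1:]
                for c in range(len(block)):
                    cols[c][r] = [float(x) for x in parts[3 * c : 3 * c + 3]]
            freqs.extend(block)
            mode_cols.extend(cols)
            k = j + 1 + natoms
        else:
            k += 1
    if not freqs:
        raise IncompleteLogError("no frequency block found")
    modes = np.stack(mode_cols)
    modes /= np.linalg.norm(modes.reshape(len(freqs), -1), axis=1)[:, None, None]
    return OptFreqResult(
        elements=tuple(elements),
        geometry=np.array(coords),
        energy=energy,
        frequencies=tuple(freqs),
        modes=modes,
        converged=True,
    )
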