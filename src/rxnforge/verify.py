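"""Transition-state verification: the filter stack for proposed reactions.

A proposed reactant/TS/product triple survives only if

1. the TS has exactly one imaginary frequency,
2. that imaginary frequency is at least 100 cm^-1 in magnitude (smaller
   values typically indicate conformational motion, not a reaction),
3. the TS energy moved by at most 3 kcal/mol relative to the highest
   energy on the string path that produced it,
4. the imaginary-mode displacements along the changing bonds are strictly
   larger than along every unchanged bond -- motion along the reaction
   coordinate must involve the atoms actually reacting, and
5. reactant and product are true minima (no imaginary frequencies).

Check 4 uses the relative-displacement projection |(u_i - u_j) . e_ij| of
the unit-normalized Cartesian imaginary mode onto the bond axis e_ij in
the TS geometry; no mass weighting is applied.  "Every unchanged bond"
means the bonded pairs of reactant or product that are not changing, not
all atom pairs.  Ties reject (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np

from rxnforge.energetics import HARTREE_TO_KCAL
from rxnforge.molgraph import Bond, MolGraph, MolGraphError, bond_changes
from rxnforge.qcio import OptFreqResult, StringPath

IMAG_FREQ_MIN_MAGNITUDE = 100.0  # cm^-1
ENERGY_DRIFT_TOL = 3.0  # kcal/mol


class VerificationInputError(MolGraphError):
    """Inconsistent inputs to the verifier (atom counts, index spaces)."""


class NoReactionError(VerificationInputError):
    """Reactant and product have identical connectivity."""


@dataclass
class VerificationReport:
    """Outcome of the five-filter stack; `passed` is their conjunction."""

    one_imaginary: bool
    imag_magnitude_ok: bool
    energy_drift_ok: bool
    mode_match_ok: bool
    endpoints_are_minima: bool
    details: Dict[str, object] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return (
            self.one_imaginary
            and self.imag_magnitude_ok
            and self.energy_drift_ok
            and self.mode_match_ok
            and self.endpoints_are_minima
        )


def check_ts_imaginary(
    frequencies: Sequence[float], min_magnitude: float = IMAG_FREQ_MIN_MAGNITUDE
) -> Tuple[bool, bool]:
    """(exactly one imaginary?, its magnitude >= min_magnitude?).

    The magnitude check is False whenever the count check fails.  The
    boundary keeps: a magnitude of exactly `min_magnitude` passes ("less
    than 100 cm^-1" is what gets removed).
    """
    if not frequencies:
        raise VerificationInputError("empty frequency list")
    negs = [f for f in frequencies if f < 0]
    one = len(negs) == 1
    return one, bool(one and abs(negs[0]) >= min_magnitude)


def check_energy_drift(
    ts_opt_energy: float, string_max_energy: float, tol: float = ENERGY_DRIFT_TOL
) -> bool:
    """True iff |E_TS(opt) - E_max(string)| <= tol, energies hartree, tol kcal/mol.

    The boundary keeps: a drift of exactly `tol` passes ("more than
    3 kcal/mol" is what gets removed).
    """
    if not (np.isfinite(ts_opt_energy) and np.isfinite(string_max_energy)):
        raise VerificationInputError("non-finite energies")
    return abs(ts_opt_energy - string_max_energy) * HARTREE_TO_KCAL <= tol


def mode_bond_scores(
    mode: np.ndarray, geometry: np.ndarray, pairs: Sequence[Bond]
) -> Dict[Bond, float]:
    """Relative-displacement projections |(u_i - u_j) . e_ij| for atom pairs.

    `mode` is the (unit-normalized) Cartesian displacement field; `e_ij`
    is the unit interatomic direction in `geometry`.  Both ingredients are
    internal/relative, so the score is invariant under rigid rotation and
    translation of geometry-plus-mode and under a global mode sign flip.
    """
    mode = np.asarray(mode, dtype=float)
    geometry = np.asarray(geometry, dtype=float)
    scores: Dict[Bond, float] = {}
    for i, j in pairs:
        axis = geometry[j] - geometry[i]
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            raise VerificationInputError(f"coincident atoms {i},{j} in TS geometry")
        scores[(i, j)] = float(abs(np.dot(mode[i] - mode[j], axis / nrm)))
    return scores


def check_mode_match(
    ts: OptFreqResult, reactant: MolGraph, product: MolGraph
) -> Tuple[bool, Dict[Bond, float]]:
    """Does the imaginary mode move the changing bonds more than every other bond?

    Changing pairs are the union of broken and formed bonds; unchanged
    pairs are all other bonds of reactant or product.  Returns
    (min-over-changing > max-over-unchanged, all per-bond scores).  An
    empty changing set raises :class:`NoReactionError`.
    """
    broken, formed = bond_changes(reactant, product)
    changing: Set[Bond] = broken | formed
    if not changing:
        raise NoReactionError("no connectivity change between reactant and product")
    unchanged = (set(reactant.bonds) | set(product.bonds)) - changing
    _, mode = ts.imaginary_mode()
    scores = mode_bond_scores(mode, ts.geometry, sorted(changing | unchanged))
    min_changing = min(scores[b] for b in changing)
    max_unchanged = max((scores[b] for b in unchanged), default=0.0)
    return min_changing > max_unchanged, scores


def check_minimum(r: OptFreqResult) -> bool:
    """True iff the structure has no imaginary frequencies (an atom has none)."""
    return all(f >= 0 for f in r.frequencies)


def verify_reaction(
    r: OptFreqResult,
    ts: OptFreqResult,
    p: OptFreqResult,
    rg: MolGraph,
    pg: MolGraph,
    string: StringPath,
    imag_min_magnitude: float = IMAG_FREQ_MIN_MAGNITUDE,
    drift_tol: float = ENERGY_DRIFT_TOL,
) -> VerificationReport:
    """Run the full filter stack and aggregate the evidence.

    Failing checks are data, not exceptions; only inconsistent inputs
    (mismatched atom counts or index spaces) raise.
    """
    n = rg.n_atoms
    for name, obj in (("ts", ts), ("product", p), ("reactant", r)):
        if len(obj.elements) != n:
            raise VerificationInputError(f"{name} log has {len(obj.elements)} atoms, expected {n}")
    if pg.n_atoms != n:
        raise VerificationInputError("product graph atom count mismatch")

    one_imag, mag_ok = check_ts_imaginary(ts.frequencies, imag_min_magnitude)
    drift = abs(ts.energy - string.max_energy) * HARTREE_TO_KCAL
    drift_ok = check_energy_drift(ts.energy, string.max_energy, drift_tol)
    minima = check_minimum(r) and check_minimum(p)
    scores: Dict[Bond, float] = {}
    if one_imag:
        mode_ok, scores = check_mode_match(ts, rg, pg)
    else:
        mode_ok = False
    return VerificationReport(
        one_imaginary=one_imag,
        imag_magnitude_ok=mag_ok,
        energy_drift_ok=drift_ok,
        mode_match_ok=mode_ok,
        endpoints_are_minima=minima,
        details={
            "ts_frequencies": tuple(ts.frequencies),
            "energy_drift_kcal": drift,
            "bond_scores": scores,
        },
    )
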