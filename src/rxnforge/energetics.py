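"""Zero-point energies and ZPE-corrected reaction energetics.

Electronic energies are hartree everywhere upstream; this module is the
single place where they are converted to kcal/mol.  All quantities are
0 K ZPE-corrected electronic energies -- no thermal or enthalpic 298 K
corrections, and harmonic frequencies are used unscaled.

Conversion constants (pinned, asserted against an independent constants
table in the test suite):

* 1 hartree = 627.5095 kcal/mol
* 1 cm^-1   = 0.0028591 kcal/mol (per mode, via E = h c nu)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

HARTREE_TO_KCAL = 627.5095
WAVENUMBER_TO_KCAL = 0.0028591


class EnergeticsError(ValueError):
    """Invalid input to an energetics computation."""


class LevelMismatchError(EnergeticsError):
    """Species computed at different levels of theory were combined."""


def zpe_from_frequencies(frequencies: Sequence[float]) -> float:
    """Harmonic zero-point energy in kcal/mol.

    Sums (1/2) h c nu over the strictly positive frequencies; imaginary
    (negative) and zero entries contribute nothing.  An atom (empty list)
    has zero ZPE.
    """
    return sum(0.5 * f * WAVENUMBER_TO_KCAL for f in frequencies if f > 0)


@dataclass(frozen=True)
class SpeciesEnergetics:
    """Electronic energy (hartree), ZPE (kcal/mol) and their 0 K sum (kcal/mol)."""

    e_elec: float
    zpe: float
    level_tag: str = ""

    def __post_init__(self) -> None:
        if self.zpe < 0:
            raise EnergeticsError("ZPE cannot be negative")

    @property
    def e0(self) -> float:
        """ZPE-corrected 0 K energy in kcal/mol."""
        return self.e_elec * HARTREE_TO_KCAL + self.zpe

    @classmethod
    def from_optfreq(cls, result, level_tag: str = "") -> "SpeciesEnergetics":
        """Build from a parsed opt+freq record."""
        return cls(result.energy, zpe_from_frequencies(result.frequencies), level_tag)


def _check_levels(*species: SpeciesEnergetics) -> None:
    tags = {s.level_tag for s in species}
    if len(tags) > 1:
        raise LevelMismatchError(f"mixed levels of theory: {sorted(tags)}")


def activation_energy(r: SpeciesEnergetics, ts: SpeciesEnergetics) -> float:
    """ZPE-corrected barrier E0(TS) - E0(reactant) in kcal/mol.

    May legitimately come out negative after ZPE correction for very low
    barriers; that is flagged with a warning but not rejected.
    """
    _check_levels(r, ts)
    ea = ts.e0 - r.e0
    if ea < 0:
        warnings.warn(f"negative activation energy ({ea:.3f} kcal/mol)", stacklevel=2)
    return ea


def reaction_enthalpy(r: SpeciesEnergetics, products: List[SpeciesEnergetics]) -> float:
    """0 K reaction enthalpy: sum of product E0 minus reactant E0, kcal/mol."""
    if not products:
        raise EnergeticsError("empty product list")
    _check_levels(r, *products)
    return sum(p.e0 for p in products) - r.e0
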