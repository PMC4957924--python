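"""Masses of modified phosphopeptides.

Monoisotopic and average masses of peptides carrying phosphotyrosine,
N-terminal acetylation and/or C-terminal amidation, and singly charged
proton / sodium adduct m/z values.  Peptides may be given in ``pY`` notation
("DPSDNpYAEPID").

Mass model: sum of residue masses + water, +42.010565 per acetyl (C2H2O),
-0.984016 for amidation (NH2 replaces OH), +79.966331 per phospho (HPO3).
Synthesis reports conventionally quote the calculated MW of such peptides as
the integer (floor) of the monoisotopic mass; :func:`calculated_mw` follows
that convention while the raw masses stay available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "ModifiedPeptide",
    "PeptideChemError",
    "monoisotopic_mass",
    "average_mass",
    "adduct_mz",
    "calculated_mw",
    "mass_report",
]


class PeptideChemError(ValueError):
    pass


# Monoisotopic residue masses (Da), IUPAC 2021 atomic masses.
MONO_RESIDUE = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
# Average residue masses (Da), IUPAC 2021 standard atomic weights.
AVG_RESIDUE = {
    "G": 57.0513, "A": 71.0779, "S": 87.0773, "P": 97.1152, "V": 99.1311,
    "T": 101.1039, "C": 103.1429, "L": 113.1576, "I": 113.1576,
    "N": 114.1026, "D": 115.0874, "Q": 128.1292, "K": 128.1723,
    "E": 129.1140, "M": 131.1961, "H": 137.1393, "F": 147.1739,
    "R": 156.1857, "Y": 163.1733, "W": 186.2099,
}

WATER_MONO = 18.010565
WATER_AVG = 18.0153
ACETYL_MONO = 42.010565          # +C2H2O
ACETYL_AVG = 42.0367
AMIDE_MONO = -0.984016           # -OH +NH2
AMIDE_AVG = -0.9847
PHOSPHO_MONO = 79.966331         # +HPO3
PHOSPHO_AVG = 79.9799
PROTON = 1.007276
SODIUM_CATION = 22.989218

ADDUCTS = {"H": PROTON, "Na": SODIUM_CATION}


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with phospho sites (1-based, Y only) and terminal modifications.

    ``n_terminal`` is ``"free"`` or ``"acetyl"``; ``c_terminal`` is ``"free"``
    (carboxylic acid) or ``"amide"``.
    """

    sequence: str
    phospho_positions: frozenset[int] = frozenset()
    n_terminal: str = "free"
    c_terminal: str = "free"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(MONO_RESIDUE)
        if not self.sequence or bad:
            raise PeptideChemError(
                f"invalid peptide sequence {self.sequence!r}"
                + (f": unknown residues {sorted(bad)}" if bad else "")
            )
        for pos in self.phospho_positions:
            if not 1 <= pos <= len(self.sequence):
                raise PeptideChemError(f"phospho position {pos} out of range")
            if self.sequence[pos - 1] != "Y":
                raise PeptideChemError(
                    f"phospho position {pos} is {self.sequence[pos - 1]}, not Y"
                )
        if self.n_terminal not in ("free", "acetyl"):
            raise PeptideChemError(f"unknown N-terminal state {self.n_terminal!r}")
        if self.c_terminal not in ("free", "amide"):
            raise PeptideChemError(f"unknown C-terminal state {self.c_terminal!r}")

    @classmethod
    def from_notation(
        cls, notation: str, n_terminal: str = "free", c_terminal: str = "free"
    ) -> "ModifiedPeptide":
        """Parse ``pY`` notation, e.g. ``"DPSDNpYAEPID"`` (one phospho at Y6)."""
        sequence, phospho = [], set()
        i = 0
        while i < len(notation):
            if notation[i] == "p":
                if i + 1 >= len(notation) or notation[i + 1] != "Y":
                    raise PeptideChemError(
                        f"{notation!r}: 'p' must be followed by 'Y' (position {i + 1})"
                    )
                sequence.append("Y")
                phospho.add(len(sequence))
                i += 2
            else:
                sequence.append(notation[i].upper())
                i += 1
        return cls("".join(sequence), frozenset(phospho), n_terminal, c_terminal)


def _mass(p: ModifiedPeptide, residue, water, acetyl, amide, phospho) -> float:
    m = sum(residue[a] for a in p.sequence) + water
    if p.n_terminal == "acetyl":
        m += acetyl
    if p.c_terminal == "amide":
        m += amide
    m += phospho * len(p.phospho_positions)
    return m


def monoisotopic_mass(p: ModifiedPeptide) -> float:
    """Monoisotopic mass in Da."""
    return _mass(p, MONO_RESIDUE, WATER_MONO, ACETYL_MONO, AMIDE_MONO, PHOSPHO_MONO)


def average_mass(p: ModifiedPeptide) -> float:
    """Average (chemical) mass in Da."""
    return _mass(p, AVG_RESIDUE, WATER_AVG, ACETYL_AVG, AMIDE_AVG, PHOSPHO_AVG)


def adduct_mz(mass: float, adduct: str = "H", charge: int = 1) -> float:
    """m/z of the singly charged [M+H]+ or [M+Na]+ ion."""
    if mass <= 0:
        raise PeptideChemError("mass must be positive")
    if adduct not in ADDUCTS:
        raise PeptideChemError(f"unknown adduct {adduct!r} (use 'H' or 'Na')")
    if charge != 1:
        raise PeptideChemError("only singly charged adducts are supported")
    return mass + ADDUCTS[adduct]


def calculated_mw(p: ModifiedPeptide) -> int:
    """Integer calculated MW as quoted in synthesis tables (floor of monoisotopic)."""
    return int(monoisotopic_mass(p))


def mass_report(peptides: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Mass table for ``(id, pY-notation)`` pairs of Ac-/-NH2 synthesis peptides."""
    rows = []
    for pid, notation in peptides:
        p = ModifiedPeptide.from_notation(notation, "acetyl", "amide")
        mono = monoisotopic_mass(p)
        rows.append(
            {
                "id": pid,
                "peptide": notation,
                "monoisotopic": round(mono, 5),
                "average": round(average_mass(p), 4),
                "calculated_mw": int(mono),
                "mz_H": round(adduct_mz(mono, "H"), 4),
                "mz_Na": round(adduct_mz(mono, "Na"), 4),
            }
        )
    return pd.DataFrame(rows)
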