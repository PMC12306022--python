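"""Reduced per-residue point representations.

Every residue is reduced to two point sets:

* a 3-atom **base triad** — three widely separated ring atoms spanning
  the base plane, used for match refinement and all reported RMSDs;
* a 5-atom **seed frame** — the triad plus the ribose C1' and the
  phosphate P (with an O5' fallback at 5' termini), used to initialise
  candidate superpositions from a single residue pair.

Atom choices: purines use (N9, C2, C6), pyrimidines (N1, C2, C4).  The
glycosidic nitrogen anchors the frame at the sugar; C2 and C6/C4 are far
ring atoms giving a well-conditioned triangle, and all five atoms are
present in virtually every modified nucleotide.  Triad slots are
homologous across residues of the same class and paired positionally
(slot k to slot k) across classes, which keeps the method fully
sequence-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import NucleicResidue, ResidueId, PURINES

__all__ = [
    "BaseTriad",
    "SeedFrame",
    "base_triad",
    "seed_frame",
    "base_matches_pattern",
    "IUPAC_EXPANSION",
    "PURINE_TRIAD",
    "PYRIMIDINE_TRIAD",
]

PURINE_TRIAD = ("N9", "C2", "C6")
PYRIMIDINE_TRIAD = ("N1", "C2", "C4")
RIBOSE_ATOM = "C1'"
PHOSPHATE_ATOM = "P"
PHOSPHATE_FALLBACK = "O5'"

# triangle area below this is treated as corrupt coordinates
_COLLINEARITY_AREA = 1e-6


@dataclass(frozen=True)
class BaseTriad:
    residue: ResidueId
    points: np.ndarray  # (3, 3)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class SeedFrame:
    residue: ResidueId
    points: np.ndarray  # (5, 3): triad, C1', P-or-O5'


def _residue_is_purine(r: NucleicResidue) -> bool:
    if r.base_code is not None:
        return r.base_code in PURINES
    # unmapped modified residue: an N9 glycosidic nitrogen marks the
    # fused five-membered ring of a purine
    return r.has_atom("N9")


def triad_atom_names(r: NucleicResidue) -> tuple[str, str, str]:
    return PURINE_TRIAD if _residue_is_purine(r) else PYRIMIDINE_TRIAD


def base_triad(r: NucleicResidue) -> BaseTriad | None:
    """3-point base representation, or None when a designated atom is absent
    or the three atoms are (numerically) collinear."""
    names = triad_atom_names(r)
    pts = []
    for name in names:
        a = r.atom(name)
        if a is None:
            return None
        pts.append(a.coords)
    points = np.array(pts, dtype=float)
    area = 0.5 * np.linalg.norm(np.cross(points[1] - points[0], points[2] - points[0]))
    if area <= _COLLINEARITY_AREA:
        return None
    return BaseTriad(residue=r.id, points=points)


def seed_frame(r: NucleicResidue) -> SeedFrame | None:
    """5-point seed representation: base triad + C1' + P (O5' at 5' termini)."""
    triad = base_triad(r)
    if triad is None:
        return None
    ribose = r.atom(RIBOSE_ATOM)
    if ribose is None:
        return None
    phosphate = r.atom(PHOSPHATE_ATOM) or r.atom(PHOSPHATE_FALLBACK)
    if phosphate is None:
        return None
    points = np.vstack([triad.points, ribose.coords, phosphate.coords])
    return SeedFrame(residue=r.id, points=points)


IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "T": frozenset("U"),  # T and U are the same base letter for matching
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}


def base_matches_pattern(code: str | None, pattern: str) -> bool:
    """True iff a one-letter base code satisfies an IUPAC ambiguity code.

    T is treated as U on both sides.  A residue with unknown base code
    (unmapped modified nucleotide) matches only the fully ambiguous
    pattern N.
    """
    pattern = pattern.upper()
    if pattern not in IUPAC_EXPANSION:
        raise ValueError(f"unknown IUPAC pattern letter {pattern!r}")
    if code is None:
        return pattern == "N"
    code = code.upper().replace("T", "U")
    return code in IUPAC_EXPANSION[pattern]
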