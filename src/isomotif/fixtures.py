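"""Synthetic nucleic-acid structure generator.

Builds idealized toy structures carrying exactly the atoms the search
algorithm touches (base triad atoms, C1', P, O5', O3'): helical
duplexes, noisy rigid-motion copies, chain-break cases, and a
two-stem "kink" module with positive and decoy query structures.  The
geometry is parametrically helical, not physically minimised — residues
are rigidly congruent by construction, consecutive O3'-P links fall in
the covalent range, and Watson-Crick partners are approximated by a
flipped second strand.  That is sufficient for exercising every code
path of the search; it does not emulate sugar puckers, base-pair
hydrogen bonding or crystallographic disorder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomRecord, NucleicResidue, NucleicStructure, ResidueId
from .superposition import RigidTransform

__all__ = [
    "HelixSpec",
    "build_duplex",
    "perturb",
    "break_chain",
    "build_kink_toy",
    "KinkToy",
    "transform_structure",
]

_COMPLEMENT = {"A": "U", "U": "A", "T": "A", "C": "G", "G": "C"}
_PURINES = "AG"

# helical parameters per form: (rise A/step, twist degrees/step)
_FORMS = {"A": (2.81, 32.7), "B": (3.38, 36.0)}

# per-atom cylindrical offsets (radius, d_angle rad, d_z) of the residue
# template; every residue is this template rotated/translated along the
# helix, so all residues are rigidly congruent
_TEMPLATE = {
    "P": (8.8, -0.30, -2.0),
    "O5'": (8.3, -0.20, -1.3),
    "C1'": (9.2, 0.00, 0.0),
    "_glyN": (6.9, 0.02, 0.1),
    "_C2": (5.0, 0.20, 0.35),
    "_third": (5.5, -0.18, 0.6),
}
_O3_ANCHOR = (8.6, 0.25, 1.2)
_LINK_LENGTH = 1.6  # O3'(i)-P(i+1), mid-covalent-range


@dataclass(frozen=True)
class HelixSpec:
    sequence: str
    form: str = "A"
    rise: float | None = None
    twist: float | None = None
    chain_ids: tuple[str, str] = ("A", "B")
    start_number: int = 1

    def geometry(self) -> tuple[float, float]:
        if self.form not in _FORMS:
            raise ValueError(f"unknown helix form {self.form!r}")
        rise, twist = _FORMS[self.form]
        return (self.rise if self.rise is not None else rise,
                self.twist if self.twist is not None else twist)


def _cyl(radius: float, angle: float, z: float) -> np.ndarray:
    return np.array([radius * math.cos(angle), radius * math.sin(angle), z])


def _atom_names(base: str) -> dict[str, str]:
    if base in _PURINES:
        return {"_glyN": "N9", "_C2": "C2", "_third": "C6"}
    return {"_glyN": "N1", "_C2": "C2", "_third": "C4"}


def _make_strand(
    sequence: str, chain: str, start_number: int, rise: float, twist_deg: float
) -> list[NucleicResidue]:
    twist = math.radians(twist_deg)
    residues: list[NucleicResidue] = []
    raw_atoms: list[dict[str, np.ndarray]] = []
    for i, base in enumerate(sequence.upper()):
        if base not in _COMPLEMENT:
            raise ValueError(f"unknown base letter {base!r}")
        theta, z = i * twist, i * rise
        coords = {
            key: _cyl(r, theta + dang, z + dz) for key, (r, dang, dz) in _TEMPLATE.items()
        }
        raw_atoms.append(coords)
    # O3' of residue i sits exactly _LINK_LENGTH from P of residue i+1,
    # on the segment towards the residue's own anchor point
    for i in range(len(sequence)):
        theta, z = i * twist, i * rise
        anchor = _cyl(_O3_ANCHOR[0], theta + _O3_ANCHOR[1], z + _O3_ANCHOR[2])
        if i + 1 < len(sequence):
            next_p = raw_atoms[i + 1]["P"]
        else:
            next_p = _cyl(_TEMPLATE["P"][0], (i + 1) * twist + _TEMPLATE["P"][1],
                          (i + 1) * rise + _TEMPLATE["P"][2])
        direction = anchor - next_p
        direction /= np.linalg.norm(direction)
        raw_atoms[i]["O3'"] = next_p + _LINK_LENGTH * direction

    for i, base in enumerate(sequence.upper()):
        names = _atom_names(base)
        atoms = []
        for key, xyz in raw_atoms[i].items():
            name = names.get(key, key)
            atoms.append(AtomRecord(name=name, element=name[0], coords=xyz))
        rid = ResidueId(model=1, chain=chain, number=start_number + i, insertion="", comp=base)
        residues.append(NucleicResidue(id=rid, atoms=atoms, base_code=base, polymer_index=i))
    return residues


def transform_structure(s: NucleicStructure, t: RigidTransform) -> NucleicStructure:
    """Rigidly transformed deep copy of a structure."""
    residues = []
    for r in s.residues:
        atoms = [
            AtomRecord(a.name, a.element, t.apply(a.coords)[0], a.altloc, a.occupancy)
            for a in r.atoms
        ]
        residues.append(NucleicResidue(r.id, atoms, r.base_code, r.polymer_index))
    return NucleicStructure(s.entry_id, residues, s.source_path, s.format)


def _rotation(axis: str, degrees: float) -> RigidTransform:
    a = math.radians(degrees)
    c, s = math.cos(a), math.sin(a)
    mats = {
        "x": [[1, 0, 0], [0, c, -s], [0, s, c]],
        "y": [[c, 0, s], [0, 1, 0], [-s, 0, c]],
        "z": [[c, -s, 0], [s, c, 0], [0, 0, 1]],
    }
    return RigidTransform(np.array(mats[axis], dtype=float), np.zeros(3))


def build_duplex(spec: HelixSpec) -> NucleicStructure:
    """Idealized duplex: two antiparallel strands on a common axis.

    Strand 2 carries the reverse complement and is a proper rigid copy
    (flipped 180 degrees about x, never mirrored), so residues of the
    same base are congruent across strands.  Consecutive O3'-P link
    distances are in the covalent range by construction.
    """
    rise, twist = spec.geometry()
    n = len(spec.sequence)
    strand1 = _make_strand(spec.sequence, spec.chain_ids[0], spec.start_number, rise, twist)

    comp = "".join(_COMPLEMENT[b] for b in spec.sequence.upper()[::-1])
    strand2 = _make_strand(comp, spec.chain_ids[1], spec.start_number, rise, twist)
    flip = _rotation("x", 180.0)
    place = RigidTransform(np.eye(3), np.array([0.0, 0.0, (n - 1) * rise]))
    spin = _rotation("z", 150.0)
    move = place.compose(spin.compose(flip))
    strand2_res = []
    for r in strand2:
        atoms = [AtomRecord(a.name, a.element, move.apply(a.coords)[0]) for a in r.atoms]
        strand2_res.append(NucleicResidue(r.id, atoms, r.base_code, r.polymer_index))

    return NucleicStructure(
        entry_id=f"duplex-{spec.form}{n}", residues=strand1 + strand2_res, format="PDB"
    )


def perturb(s: NucleicStructure, noise_sd: float, rng_seed: int) -> NucleicStructure:
    """Isotropic Gaussian displacement of every atom; seeded, reproducible."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(rng_seed)
    residues = []
    for r in s.residues:
        atoms = [
            AtomRecord(a.name, a.element, a.coords + rng.normal(0.0, noise_sd, 3),
                       a.altloc, a.occupancy)
            for a in r.atoms
        ]
        residues.append(NucleicResidue(r.id, atoms, r.base_code, r.polymer_index))
    return NucleicStructure(s.entry_id, residues, s.source_path, s.format)


def break_chain(s: NucleicStructure, after: ResidueId | tuple, gap: float) -> NucleicStructure:
    """Translate the tail of a chain so one O3'-P link has length ``gap``.

    The residue ``after`` must exist and have a successor in its chain;
    the successor and all following residues of that chain are shifted
    along the existing link direction.
    """
    key = after.key() if isinstance(after, ResidueId) else tuple(after)
    target = None
    for idx, r in enumerate(s.residues):
        if r.id.key() == key:
            target = (idx, r)
            break
    if target is None:
        raise ValueError(f"residue {after} not found")
    idx, res = target
    successor = None
    for r in s.residues:
        if r.id.chain == res.id.chain and r.polymer_index == res.polymer_index + 1:
            successor = r
            break
    if successor is None:
        raise ValueError(f"residue {after} has no successor in its chain")
    o3 = res.atom("O3'")
    p = successor.atom("P")
    if o3 is None or p is None:
        raise ValueError("link atoms missing")
    direction = p.coords - o3.coords
    length = float(np.linalg.norm(direction))
    shift = (gap - length) / length * direction

    residues = []
    for r in s.residues:
        if r.id.chain == res.id.chain and r.polymer_index > res.polymer_index:
            atoms = [AtomRecord(a.name, a.element, a.coords + shift, a.altloc, a.occupancy)
                     for a in r.atoms]
            residues.append(NucleicResidue(r.id, atoms, r.base_code, r.polymer_index))
        else:
            residues.append(r)
    return NucleicStructure(s.entry_id, residues, s.source_path, s.format)


def _rechain(
    residues: list[NucleicResidue], chain: str, start_number: int, start_index: int
) -> list[NucleicResidue]:
    out = []
    for k, r in enumerate(residues):
        rid = ResidueId(model=1, chain=chain, number=start_number + k, insertion="",
                        comp=r.id.comp)
        out.append(NucleicResidue(rid, r.atoms, r.base_code, start_index + k))
    return out


@dataclass
class KinkToy:
    """A desk-scale kinked two-stem module with query structures.

    ``reference`` is a 14-residue module of two helical stems meeting at
    a sharp ~110-degree bend, with residues labelled by kink-turn-style
    position names (``labels``).  ``positive`` embeds a rigid copy of
    the module (renamed chains) in a 60-residue context; ``decoy`` is a
    straight duplex of the same size class containing no kinked module.
    """

    reference: NucleicStructure
    positive: NucleicStructure
    decoy: NucleicStructure
    labels: dict = field(default_factory=dict)


def build_kink_toy() -> KinkToy:
    stem_a = build_duplex(HelixSpec("GGCA", chain_ids=("a", "b")))
    stem_b = build_duplex(HelixSpec("GCU", chain_ids=("c", "d")))

    # place stem B after stem A with a sharp bend
    bend = _rotation("y", 110.0)
    offset = RigidTransform(np.eye(3), np.array([6.0, 2.0, 4 * 2.81 + 3.0]))
    stem_b = transform_structure(stem_b, offset.compose(bend))

    a_res = {r.id.chain: [] for r in stem_a.residues}
    for r in stem_a.residues:
        a_res[r.id.chain].append(r)
    b_res = {r.id.chain: [] for r in stem_b.residues}
    for r in stem_b.residues:
        b_res[r.id.chain].append(r)

    chain_k = _rechain(a_res["a"], "K", 1, 0) + _rechain(b_res["c"], "K", 5, 4)
    chain_l = _rechain(b_res["d"], "L", 1, 0) + _rechain(a_res["b"], "L", 4, 3)
    reference = NucleicStructure("kink-toy-ref", chain_k + chain_l, format="PDB")

    label_names_k = ["-2b", "-1b", "1b", "2b", "L1", "3b", "4b"]
    label_names_l = ["4n", "3n", "L1p", "2n", "1n", "-1n", "-2n"]
    labels = {}
    for r, name in zip(chain_k, label_names_k):
        labels[r.id] = name
    for r, name in zip(chain_l, label_names_l):
        labels[r.id] = name

    # positive query: context duplex (46 nt) + displaced rigid copy (14 nt)
    context = build_duplex(HelixSpec("GAUCGGAUCCGAUAGCUAGGCAU", chain_ids=("X", "Y")))
    motion = RigidTransform(
        _rotation("z", 63.0).compose(_rotation("x", 41.0)).rotation,
        np.array([52.0, -18.0, 9.0]),
    )
    copy = transform_structure(reference, motion)
    copy_res = []
    rename = {"K": "M", "L": "N"}
    for r in copy.residues:
        rid = ResidueId(1, rename[r.id.chain], r.id.number, "", r.id.comp)
        copy_res.append(NucleicResidue(rid, r.atoms, r.base_code, r.polymer_index))
    positive = NucleicStructure("kink-toy-positive", context.residues + copy_res, format="PDB")

    decoy = build_duplex(HelixSpec("GGAUCCGAUAGCUAG", chain_ids=("E", "F")))
    decoy = NucleicStructure("kink-toy-decoy", decoy.residues, format="PDB")

    return KinkToy(reference=reference, positive=positive, decoy=decoy, labels=labels)
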