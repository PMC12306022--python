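"""Reading, writing and selecting nucleic-acid 3D structures.

Parsing and serialisation of PDB and mmCIF go through gemmi; this module
reduces a coordinate file to the flat, ordered residue list the search
algorithm operates on.  Only nucleotide residues are kept (amino acids,
waters, ions and base-less ligands are skipped but counted in a parse
report).  Author numbering (chain id, residue number, insertion code) is
preserved throughout, since that is how structural biologists cite
residues.

Conventions:

* the first model is read by default; another model may be requested;
* for alternate locations the highest-occupancy atom wins (ties broken
  alphabetically by altloc code), yielding single-conformer geometry;
* modified residues are mapped to a parent base through a shipped
  component table; unmapped components that still carry a glycosidic
  nitrogen are kept with an unknown base code, because the search itself
  is sequence-agnostic.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

from .superposition import RigidTransform

__all__ = [
    "AtomRecord",
    "ResidueId",
    "NucleicResidue",
    "NucleicStructure",
    "ResidueSelector",
    "ParseReport",
    "read_structure",
    "select_residues",
    "write_structure",
    "parent_base",
    "SelectorSyntaxError",
]


def _load_component_table() -> dict[str, str]:
    with resources.files("isomotif.data").joinpath("base_components.json").open() as fh:
        return json.load(fh)["components"]


_COMPONENT_TABLE: dict[str, str] = _load_component_table()

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CUT")


def parent_base(comp: str) -> str | None:
    """One-letter parent base for a component name, or None if unmapped."""
    return _COMPONENT_TABLE.get(comp.strip().upper())


@dataclass(frozen=True)
class ResidueId:
    """Author-style residue identifier: model, chain, number, insertion code."""

    model: int
    chain: str
    number: int
    insertion: str = ""
    comp: str = ""

    def key(self) -> tuple[int, str, int, str]:
        """Position key; comp is descriptive and excluded from identity lookups."""
        return (self.model, self.chain, self.number, self.insertion)

    def __str__(self) -> str:
        return f"{self.chain}.{self.number}{self.insertion}"


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class NucleicResidue:
    id: ResidueId
    atoms: list[AtomRecord]
    base_code: str | None
    polymer_index: int

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atom(self, name: str) -> bool:
        return self.atom(name) is not None


@dataclass
class ParseReport:
    nucleotides: int = 0
    skipped_waters: int = 0
    skipped_amino_acids: int = 0
    skipped_other: int = 0


@dataclass
class NucleicStructure:
    """An ordered list of nucleotide residues from one model of one file."""

    entry_id: str
    residues: list[NucleicResidue]
    source_path: str = ""
    format: str = "PDB"
    report: ParseReport = field(default_factory=ParseReport)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_empty(self) -> bool:
        return not self.residues

    def by_id(self) -> dict[tuple, NucleicResidue]:
        return {r.id.key(): r for r in self.residues}

    def find(self, chain: str, number: int, insertion: str = "") -> NucleicResidue | None:
        for r in self.residues:
            if r.id.chain == chain and r.id.number == number and r.id.insertion == insertion:
                return r
        return None


class SelectorSyntaxError(ValueError):
    """Malformed residue-selector expression."""


_ITEM_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")
_RANGE_RE = re.compile(r"^(-?\d+)([A-Za-z]?)-(-?\d+)([A-Za-z]?)$")


@dataclass(frozen=True)
class ResidueSelector:
    """Residue selection by chain, residue numbers/ranges and model.

    Grammar (units separated by ``;`` or whitespace)::

        unit  ::=  [ '#' model '/' ] chain [ '/' item { ',' item } ]
        item  ::=  number [icode]  |  number[icode] '-' number[icode]

    Examples: ``A`` (all of chain A), ``A/10-12,25`` (three-residue range
    plus residue 25), ``#2/B/5`` (model 2, chain B, residue 5),
    ``0/94A`` is chain "0" residue 94 insertion code A.
    """

    expression: str

    def _units(self) -> list[tuple[int | None, str, list[tuple] | None]]:
        units = []
        for raw in re.split(r"[;\s]+", self.expression.strip()):
            if not raw:
                continue
            model: int | None = None
            rest = raw
            if rest.startswith("#"):
                m = re.match(r"^#(\d+)/(.+)$", rest)
                if not m:
                    raise SelectorSyntaxError(f"bad model prefix in {raw!r}")
                model = int(m.group(1))
                rest = m.group(2)
            if "/" in rest:
                chain, _, items_text = rest.partition("/")
                if not chain:
                    raise SelectorSyntaxError(f"missing chain in {raw!r}")
                items: list[tuple] | None = []
                for it in items_text.split(","):
                    it = it.strip()
                    if not it:
                        raise SelectorSyntaxError(f"empty item in {raw!r}")
                    m = _ITEM_RE.match(it)
                    if m:
                        items.append((int(m.group(1)), m.group(2), int(m.group(1)), m.group(2)))
                        continue
                    m = _RANGE_RE.match(it)
                    if m:
                        lo, lo_ic, hi, hi_ic = int(m.group(1)), m.group(2), int(m.group(3)), m.group(4)
                        if (lo, lo_ic) > (hi, hi_ic):
                            raise SelectorSyntaxError(f"descending range in {raw!r}: {it!r}")
                        items.append((lo, lo_ic, hi, hi_ic))
                        continue
                    raise SelectorSyntaxError(f"cannot parse item {it!r} in {raw!r}")
            else:
                chain, items = rest, None
            units.append((model, chain, items))
        if not units:
            raise SelectorSyntaxError(f"empty selector expression {self.expression!r}")
        return units

    def models(self) -> set[int]:
        return {m for m, _, _ in self._units() if m is not None}

    def matches(self, rid: ResidueId) -> bool:
        for model, chain, items in self._units():
            if model is not None and rid.model != model:
                continue
            if rid.chain != chain:
                continue
            if items is None:
                return True
            for lo, lo_ic, hi, hi_ic in items:
                if (lo, lo_ic) <= (rid.number, rid.insertion.strip()) <= (hi, hi_ic):
                    return True
        return False


def _is_nucleotide(res: gemmi.Residue) -> tuple[bool, str | None]:
    """Classify a residue; return (is_nucleotide, base_code or None).

    Components in the shipped table are nucleotides with a known parent
    base.  Otherwise a residue with a ribose C1' and a glycosidic
    nitrogen is treated as an unmapped (modified) nucleotide.
    """
    code = parent_base(res.name)
    if code is not None:
        return True, code
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_water():
        return False, None
    if info is not None and info.is_amino_acid():
        return False, None
    names = {a.name for a in res}
    if "C1'" in names and ("N9" in names or "N1" in names) and "C2" in names:
        return True, None
    return False, None


def _collapse_altlocs(res: gemmi.Residue) -> list[AtomRecord]:
    """One atom per name: highest occupancy wins, ties to lowest altloc code."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        key_new = (-atom.occ, atom.altloc or "~")
        key_old = (-prev.occ, prev.altloc or "~")
        if key_new < key_old:
            best[atom.name] = atom
    records = []
    seen = set()
    for atom in res:
        if atom.name in seen or best[atom.name] is not atom:
            continue
        seen.add(atom.name)
        records.append(
            AtomRecord(
                name=atom.name,
                element=atom.element.name,
                coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                altloc=atom.altloc or "",
                occupancy=atom.occ,
            )
        )
    return records


def _guess_format(path: str | Path, hint: str | None) -> str:
    if hint:
        return hint.upper().replace("MMCIF", "mmCIF").replace("CIF", "mmCIF") if "CIF" in hint.upper() else "PDB"
    suffix = "".join(Path(path).suffixes).lower()
    return "mmCIF" if ".cif" in suffix else "PDB"


def read_structure(
    path: str | Path,
    format_hint: str | None = None,
    model: int | None = None,
) -> NucleicStructure:
    """Read all nucleotide residues of one model of a PDB/mmCIF file.

    ``model`` selects a model by its serial number; by default the first
    model is used.  Non-nucleotide residues are skipped and tallied in
    the returned structure's ``report``.  A file with zero nucleotide
    residues yields an empty structure (``is_empty``), not an error.
    """
    path = Path(path)
    fmt = _guess_format(path, format_hint)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"cannot parse {path}: no coordinate models found")

    if model is None:
        gm = st[0]
    else:
        gm = None
        for candidate in st:
            if candidate.num == model:
                gm = candidate
                break
        if gm is None:
            raise ValueError(f"model {model} not present in {path}")

    report = ParseReport()
    residues: list[NucleicResidue] = []
    for chain in gm:
        polymer_index = 0
        for res in chain:
            ok, base_code = _is_nucleotide(res)
            if not ok:
                info = gemmi.find_tabulated_residue(res.name)
                if info is not None and info.is_water():
                    report.skipped_waters += 1
                elif info is not None and info.is_amino_acid():
                    report.skipped_amino_acids += 1
                else:
                    report.skipped_other += 1
                continue
            rid = ResidueId(
                model=gm.num,
                chain=chain.name,
                number=res.seqid.num,
                insertion=(res.seqid.icode or "").strip(),
                comp=res.name,
            )
            residues.append(
                NucleicResidue(
                    id=rid,
                    atoms=_collapse_altlocs(res),
                    base_code=base_code,
                    polymer_index=polymer_index,
                )
            )
            polymer_index += 1
    report.nucleotides = len(residues)
    return NucleicStructure(
        entry_id=st.name or path.stem,
        residues=residues,
        source_path=str(path),
        format=fmt,
        report=report,
    )


def select_residues(s: NucleicStructure, sel: ResidueSelector | str) -> NucleicStructure:
    """Sub-structure with exactly the residues matching the selector, in order.

    polymer_index values are preserved from the parent structure so that
    sequence-distance measures still refer to the full chain.
    """
    if isinstance(sel, str):
        sel = ResidueSelector(sel)
    sel._units()  # validate eagerly
    chosen = [r for r in s.residues if sel.matches(r.id)]
    return NucleicStructure(
        entry_id=s.entry_id,
        residues=chosen,
        source_path=s.source_path,
        format=s.format,
        report=s.report,
    )


def write_structure(
    s: NucleicStructure,
    path: str | Path,
    transform: RigidTransform | None = None,
    format: str | None = None,
) -> None:
    """Write the structure, optionally rigidly transformed, as PDB or mmCIF.

    Round-tripping through either format preserves residue identifiers
    exactly and coordinates to the format's printed precision (1e-3 A).
    """
    if s.is_empty:
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    fmt = _guess_format(path, format)

    st = gemmi.Structure()
    st.name = s.entry_id
    models: dict[int, gemmi.Model] = {}
    chains: dict[tuple[int, str], gemmi.Chain] = {}
    for r in s.residues:
        if r.id.model not in models:
            gm = gemmi.Model(r.id.model)
            models[r.id.model] = gm
        gm = models[r.id.model]
        ckey = (r.id.model, r.id.chain)
        if ckey not in chains:
            chains[ckey] = gemmi.Chain(r.id.chain)
        gres = gemmi.Residue()
        gres.name = r.id.comp or (r.base_code or "N")
        gres.seqid = gemmi.SeqId(r.id.number, r.id.insertion or " ")
        for a in r.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element or a.name[0])
            xyz = a.coords if transform is None else transform.apply(a.coords)[0]
            atom.pos = gemmi.Position(*np.asarray(xyz, dtype=float).reshape(3))
            atom.occ = a.occupancy
            atom.altloc = "\0" if not a.altloc else a.altloc
            gres.add_atom(atom)
        chains[ckey].add_residue(gres)
    for (mnum, _), chain in chains.items():
        models[mnum].add_chain(chain)
    for gm in models.values():
        st.add_model(gm)
    st.setup_entities()

    if fmt == "mmCIF":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def expand_inputs(spec: str | Path, recursive: bool = False) -> list[Path]:
    """Resolve a file path, folder, or glob mask into a sorted file list."""
    spec = str(spec)
    p = Path(spec)
    if p.is_file():
        return [p]
    if p.is_dir():
        pattern = "**/*" if recursive else "*"
        return sorted(q for q in p.glob(pattern) if q.is_file())
    # glob mask
    import glob as _glob

    return sorted(Path(q) for q in _glob.glob(spec, recursive=True) if Path(q).is_file())
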