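"""User-defined restraints on candidate hits.

Four restraint types can be imposed on a match, mirroring what a
curator knows about a motif beyond pure geometry:

* **required** — the match must include counterparts of the listed
  reference residues (a hit missing any of them is discarded);
* **base patterns** — the query partner of a listed reference residue
  must carry a base satisfying an IUPAC ambiguity code;
* **subset RMSD** — the listed reference residues, under the hit's own
  transform (no refitting), must superimpose on their partners within a
  given RMSD;
* **strand continuity** — the query partners of a listed residue group
  must form one covalently continuous strand, where continuity between
  neighbouring residues means an O3'(i)–P(i+1) distance strictly under
  2.0 A.

Restraint files are plain text, one restraint per line::

    REQ  <resid> [<resid> ...]
    BASE <resid>=<IUPAC letter>
    RMSD <angstroms> <resid> [<resid> ...]
    CHAIN <resid> <resid> [<resid> ...]

where ``<resid>`` is ``chain/number[icode]`` (e.g. ``0/94`` or
``A/72B``).  Blank lines and ``#`` comments are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import representations as reprs
from .matching import Hit, SearchParams
from .structure_io import NucleicResidue, NucleicStructure, ResidueId
from .superposition import rmsd as plain_rmsd

__all__ = [
    "RestraintSet",
    "RestraintError",
    "parse_restraints",
    "check_required",
    "check_base_patterns",
    "check_subset_rmsd",
    "check_strand_continuity",
    "apply_all",
]

CONTINUITY_CUTOFF = 2.0  # A, strict: a link of exactly 2.0 is a break


class RestraintError(ValueError):
    """Malformed or unresolvable restraint specification."""


# residue references are stored as position keys (model, chain, number, icode)
Key = tuple


@dataclass
class RestraintSet:
    required: frozenset = frozenset()
    base_patterns: dict = field(default_factory=dict)  # Key -> IUPAC letter
    subset_rmsd: list = field(default_factory=list)  # [(frozenset[Key], max A)]
    continuous_groups: list = field(default_factory=list)  # [[Key, ...]]

    def is_empty(self) -> bool:
        return not (self.required or self.base_patterns or self.subset_rmsd or self.continuous_groups)

    def validate_against(self, ref: NucleicStructure) -> None:
        """Fail fast if any referenced residue is absent from the module."""
        known = set(ref.by_id())
        mentioned = set(self.required) | set(self.base_patterns)
        for keys, _ in self.subset_rmsd:
            mentioned |= set(keys)
        for group in self.continuous_groups:
            mentioned |= set(group)
        missing = sorted(mentioned - known)
        if missing:
            raise RestraintError(f"restraint residues not in reference module: {missing}")
        for key, letter in self.base_patterns.items():
            if letter.upper() not in reprs.IUPAC_EXPANSION:
                raise RestraintError(f"invalid IUPAC letter {letter!r} for {key}")

    def accepts(self, hit: Hit, ref: NucleicStructure, qry: NucleicStructure, params: SearchParams) -> bool:
        return apply_all(hit, self, ref, qry, params)


def _resid_token(token: str, model: int) -> Key:
    import re

    m = re.match(r"^(?:#(\d+)/)?([^/]+)/(-?\d+)([A-Za-z]?)$", token)
    if not m:
        raise RestraintError(f"cannot parse residue reference {token!r} (expected chain/number)")
    mdl = int(m.group(1)) if m.group(1) else model
    return (mdl, m.group(2), int(m.group(3)), m.group(4))


def parse_restraints(text: str, ref: NucleicStructure) -> RestraintSet:
    """Parse a restraint file body and resolve it against the reference."""
    model = ref.residues[0].id.model if ref.residues else 1
    required: set = set()
    base_patterns: dict = {}
    subset_rmsd: list = []
    groups: list = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        kind = fields[0].upper()
        try:
            if kind == "REQ":
                required.update(_resid_token(t, model) for t in fields[1:])
            elif kind == "BASE":
                for t in fields[1:]:
                    resid, _, letter = t.partition("=")
                    if not letter:
                        raise RestraintError("BASE needs chain/number=LETTER")
                    base_patterns[_resid_token(resid, model)] = letter.upper()
            elif kind == "RMSD":
                bound = float(fields[1])
                subset_rmsd.append((frozenset(_resid_token(t, model) for t in fields[2:]), bound))
            elif kind == "CHAIN":
                groups.append([_resid_token(t, model) for t in fields[1:]])
            else:
                raise RestraintError(f"unknown restraint type {kind!r}")
        except (IndexError, ValueError) as exc:
            raise RestraintError(f"line {lineno}: {exc}") from exc
    rs = RestraintSet(
        required=frozenset(required),
        base_patterns=base_patterns,
        subset_rmsd=subset_rmsd,
        continuous_groups=groups,
    )
    rs.validate_against(ref)
    return rs


def _partner_map(hit: Hit) -> dict:
    return {a.key(): b for a, b in hit.pairs}


def check_required(hit: Hit, rs: RestraintSet) -> bool:
    """Every required reference residue has a counterpart in the hit."""
    matched = {a.key() for a, _ in hit.pairs}
    return rs.required <= matched


def check_base_patterns(hit: Hit, rs: RestraintSet, qry: NucleicStructure) -> bool:
    """Matched constrained residues pair with bases satisfying their IUPAC code.

    Constrained residues that are simply unmatched are not judged here —
    their presence is the business of the required-residue restraint.
    """
    if not rs.base_patterns:
        return True
    partners = _partner_map(hit)
    qmap = qry.by_id()
    for key, pattern in rs.base_patterns.items():
        partner = partners.get(key)
        if partner is None:
            continue
        qres = qmap.get(partner.key())
        code = qres.base_code if qres is not None else None
        if not reprs.base_matches_pattern(code, pattern):
            return False
    return True


def check_subset_rmsd(hit: Hit, rs: RestraintSet, ref: NucleicStructure, qry: NucleicStructure) -> bool:
    """Listed residues superimpose within the bound under the hit's transform.

    The hit's transform is used as-is (no refitting on the subset): the
    restraint asks how well the subset sits in the actual superposition,
    not how well it could fit in isolation.  A subset residue without a
    counterpart fails the restraint.
    """
    if not rs.subset_rmsd:
        return True
    partners = _partner_map(hit)
    rmap = ref.by_id()
    qmap = qry.by_id()
    for keys, bound in rs.subset_rmsd:
        P, Q = [], []
        for key in sorted(keys):
            partner = partners.get(key)
            if partner is None:
                return False
            rt = reprs.base_triad(rmap[key])
            qt = reprs.base_triad(qmap[partner.key()])
            if rt is None or qt is None:
                return False
            P.append(rt.points)
            Q.append(qt.points)
        moved = hit.transform.apply(np.vstack(P))
        if plain_rmsd(moved, np.vstack(Q)) > bound:
            return False
    return True


def check_strand_continuity(hit: Hit, rs: RestraintSet, qry: NucleicStructure) -> bool:
    """Query counterparts of each group form one covalently continuous strand.

    The partners, taken in group order, must be consecutive residues of
    a single query chain, and every adjacent pair must have an
    O3'(i)-P(i+1) distance strictly under 2.0 A.  Missing partners or
    missing backbone atoms fail the restraint (they make continuity
    unverifiable).
    """
    if not rs.continuous_groups:
        return True
    partners = _partner_map(hit)
    qmap = qry.by_id()
    for group in rs.continuous_groups:
        chain_res: list[NucleicResidue] = []
        for key in group:
            partner = partners.get(key)
            if partner is None:
                return False
            qres = qmap.get(partner.key())
            if qres is None:
                return False
            chain_res.append(qres)
        for a, b in zip(chain_res, chain_res[1:]):
            if a.id.chain != b.id.chain or b.polymer_index != a.polymer_index + 1:
                return False
            o3 = a.atom("O3'")
            p = b.atom("P")
            if o3 is None or p is None:
                return False
            if np.linalg.norm(o3.coords - p.coords) >= CONTINUITY_CUTOFF:
                return False
    return True


def apply_all(
    hit: Hit,
    rs: RestraintSet | None,
    ref: NucleicStructure,
    qry: NucleicStructure,
    params: SearchParams,
) -> bool:
    """Conjunction of size/RMSD thresholds and all four restraint checks.

    Evaluation short-circuits in order: size, required residues, base
    patterns, subset RMSD, strand continuity, global RMSD.  Evaluation
    never mutates the hit.
    """
    if hit.size < params.sizemin:
        return False
    if params.sizemax is not None and hit.size > params.sizemax:
        return False
    if rs is not None:
        if not check_required(hit, rs):
            return False
        if not check_base_patterns(hit, rs, qry):
            return False
        if not check_subset_rmsd(hit, rs, ref, qry):
            return False
        if not check_strand_continuity(hit, rs, qry):
            return False
    if params.rmsdmax is not None and hit.rmsd > params.rmsdmax:
        return False
    return True
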