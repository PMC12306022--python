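"""Hit-set reduction, annotation and benchmark scoring.

Covers the steps between raw per-seed hits and a motif census:
sub-match removal, merging of hits found from several reference
modules into unique matches, the sequence-distance kink heuristic, and
precision/recall/F-score evaluation against a ground-truth module list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matching import Hit
from .structure_io import NucleicStructure, ResidueId

__all__ = [
    "remove_submatches",
    "UniqueMatch",
    "deduplicate_across_references",
    "assign_kink_label",
    "BenchmarkResult",
    "OverlapJudgment",
    "score_against_truth",
    "KINK_SEQUENCE_CUTOFF",
]

# a 2b-to-L1 sequence separation of 10 or more residues cannot form the
# local kink; the label boundary is strict (distance 10 is "no-kink")
KINK_SEQUENCE_CUTOFF = 10


def remove_submatches(hits: list[Hit]) -> list[Hit]:
    """Drop hits whose residue pairing is a strict subset of another hit's.

    Among hits with identical pairings the lowest-RMSD one is kept.
    Idempotent: applying the filter twice changes nothing.
    """
    by_key: dict[frozenset, Hit] = {}
    for h in hits:
        key = h.pair_key()
        old = by_key.get(key)
        if old is None or h.rmsd < old.rmsd:
            by_key[key] = h
    # larger pairings can never be subsets of smaller ones, so one pass
    # over keys sorted by size descending suffices (subset is transitive)
    keys = sorted(by_key, key=len, reverse=True)
    kept: list[frozenset] = []
    for key in keys:
        if not any(key < other for other in kept):
            kept.append(key)
    kept_set = set(kept)
    return [h for h in hits if h.pair_key() in kept_set and by_key[h.pair_key()] is h]


@dataclass
class UniqueMatch:
    """A set of query residues matched by one or more reference modules."""

    query_path: str
    query_keys: frozenset
    hits: list[Hit] = field(default_factory=list)

    @property
    def provenance(self) -> list[tuple[str, int, float]]:
        return [(h.reference_path, h.size, h.rmsd) for h in self.hits]

    @property
    def best(self) -> Hit:
        return min(self.hits, key=lambda h: (-h.size, h.rmsd))


def deduplicate_across_references(hit_lists: list[list[Hit]]) -> list[UniqueMatch]:
    """Merge hits with identical query residue sets into unique matches.

    Hits from different reference modules that cover exactly the same
    query residues become one record carrying per-reference provenance.
    """
    merged: dict[tuple[str, frozenset], UniqueMatch] = {}
    for hits in hit_lists:
        for h in hits:
            key = (h.query_path, h.query_residue_keys())
            if key not in merged:
                merged[key] = UniqueMatch(query_path=h.query_path, query_keys=key[1])
            merged[key].hits.append(h)
    return sorted(
        merged.values(),
        key=lambda u: (u.query_path, -len(u.query_keys), sorted(u.query_keys)),
    )


def assign_kink_label(
    hit: Hit,
    ref_labels: dict[ResidueId, str] | dict[tuple, str],
    qry: NucleicStructure,
) -> str:
    """Kink / no-kink heuristic from the 2b-L1 sequence separation.

    ``ref_labels`` maps reference residues to their position names and
    must label both "2b" and "L1".  The query partners of those two
    positions are located; if both exist and share a chain, the match is
    labelled "kink" when they are fewer than 10 residues apart along the
    chain (distance measured in residues actually present in the
    coordinate file), otherwise "no-kink".  Partners on different chains
    cannot form the local kink and are labelled "no-kink"; a missing
    partner yields "undetermined".
    """
    normalized = {
        (k.key() if isinstance(k, ResidueId) else tuple(k)): v for k, v in ref_labels.items()
    }
    wanted = {}
    for key, name in normalized.items():
        if name in ("2b", "L1"):
            wanted[name] = key
    if "2b" not in wanted or "L1" not in wanted:
        raise ValueError('reference labelling must include positions "2b" and "L1"')

    partners = {a.key(): b for a, b in hit.pairs}
    qmap = qry.by_id()
    try:
        q2b = qmap[partners[wanted["2b"]].key()]
        ql1 = qmap[partners[wanted["L1"]].key()]
    except KeyError:
        return "undetermined"
    if q2b.id.chain != ql1.id.chain:
        return "no-kink"
    distance = abs(q2b.polymer_index - ql1.polymer_index)
    return "kink" if distance < KINK_SEQUENCE_CUTOFF else "no-kink"


@dataclass
class OverlapJudgment:
    query_keys: frozenset
    overlap_fraction: float
    verdict: str  # "TP" | "FP"
    truth_index: int | None


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    judgments: list[OverlapJudgment]


def _merge_fp_groups(residue_sets: list[frozenset]) -> list[frozenset]:
    """Union-find merge of query sets that mutually overlap by >= 50%."""
    parent = list(range(len(residue_sets)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(residue_sets)):
        for j in range(i + 1, len(residue_sets)):
            a, b = residue_sets[i], residue_sets[j]
            inter = len(a & b)
            if a and b and inter / len(a) >= 0.5 and inter / len(b) >= 0.5:
                parent[find(j)] = find(i)
    groups: dict[int, frozenset] = {}
    for i, s in enumerate(residue_sets):
        root = find(i)
        groups[root] = groups.get(root, frozenset()) | s
    return list(groups.values())


def score_against_truth(
    matches: list[UniqueMatch] | list[frozenset],
    truth_modules: list[frozenset] | list[set],
) -> BenchmarkResult:
    """Precision / recall / F-score of a hit set against known motif instances.

    A match is a true positive when at least 50% of its query residues
    lie inside some truth module; matches hitting the same module are
    merged and count a single TP.  Matches overlapping no module are
    false positives, merged when their residue sets mutually overlap by
    at least 50%.  Every truth module with no TP is a false negative.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    F = 2*TP/(2*TP+FP+FN).
    """
    truth = [frozenset(t) for t in truth_modules]
    residue_sets = [
        m.query_keys if isinstance(m, UniqueMatch) else frozenset(m) for m in matches
    ]

    judgments: list[OverlapJudgment] = []
    tp_modules: set[int] = set()
    fp_sets: list[frozenset] = []
    for keys in residue_sets:
        best_frac, best_idx = 0.0, None
        for t_idx, module in enumerate(truth):
            frac = len(keys & module) / len(keys) if keys else 0.0
            if frac > best_frac:
                best_frac, best_idx = frac, t_idx
        if best_frac >= 0.5:
            judgments.append(OverlapJudgment(keys, best_frac, "TP", best_idx))
            tp_modules.add(best_idx)
        else:
            judgments.append(OverlapJudgment(keys, best_frac, "FP", None))
            fp_sets.append(keys)

    tp = len(tp_modules)
    fp = len(_merge_fp_groups(fp_sets))
    fn = len(truth) - tp

    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f_score = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return BenchmarkResult(tp, fp, fn, precision, recall, f_score, judgments)
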