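"""The motif search proper.

Given a reference module of N residues and a query structure of M
residues, every ordered residue pair (one reference residue, one query
residue) defines a candidate **seed superposition**: the reference is
rigidly placed onto the query by fitting the two 5-atom seed frames.
Under each such placement, residues are paired by **mutual-closest
matching** of base-triad centroids within a distance cutoff, giving a
partial bijection between the two residue sets.  The pairing is then
refined ICP-style — refit the transform on all matched base triads,
re-derive the mutual-closest pairing, repeat to a fixed point — and
reported as a hit if it meets the size and RMSD thresholds.  The N*M
seed enumeration makes the otherwise NP-hard set-matching problem
polynomial, exploiting the planar, locally rigid geometry of nucleic
acids.

All reported RMSDs are computed on the concatenated 3-atom base triads
of the matched residues.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import representations as reprs
from .structure_io import NucleicResidue, NucleicStructure, ResidueId
from .superposition import RigidTransform, fit

__all__ = [
    "SearchParams",
    "Hit",
    "enumerate_seeds",
    "mutual_closest_pairs",
    "refine_match",
    "search",
]


@dataclass(frozen=True)
class SearchParams:
    """Thresholds and knobs of one search run.

    sizemin/sizemax bound the number of matched residues; rmsdmax bounds
    the base-triad RMSD (None = unlimited); matchrange is the
    mutual-closest distance cutoff on triad centroids, in Angstroms;
    max_refine_iters caps the fit/re-match iteration (1 reproduces a
    strict single-pass matching).
    """

    sizemin: int = 3
    sizemax: int | None = None
    rmsdmax: float | None = None
    matchrange: float = 3.0
    max_refine_iters: int = 10
    threads: int = 1

    def __post_init__(self) -> None:
        if self.sizemin < 3:
            raise ValueError("sizemin must be >= 3 (a rigid fit needs 3 points)")
        if self.sizemax is not None and self.sizemax < self.sizemin:
            raise ValueError("sizemax < sizemin")
        if self.matchrange <= 0:
            raise ValueError("matchrange must be positive")


@dataclass
class Hit:
    """One accepted match between a reference module and a query structure."""

    reference_path: str
    query_path: str
    pairs: list[tuple[ResidueId, ResidueId]]
    rmsd: float
    transform: RigidTransform
    seed: tuple[ResidueId, ResidueId]

    @property
    def size(self) -> int:
        return len(self.pairs)

    def pair_key(self) -> frozenset:
        return frozenset((a.key(), b.key()) for a, b in self.pairs)

    def query_residue_keys(self) -> frozenset:
        return frozenset(b.key() for _, b in self.pairs)


class _Indexed:
    """Precomputed triads/frames of a structure, in residue order."""

    def __init__(self, s: NucleicStructure):
        self.structure = s
        self.residues: list[NucleicResidue] = []
        triads = []
        self.frames: list[np.ndarray | None] = []
        for r in s.residues:
            triad = reprs.base_triad(r)
            if triad is None:
                continue  # residue cannot be matched at all
            self.residues.append(r)
            triads.append(triad.points)
            frame = reprs.seed_frame(r)
            self.frames.append(None if frame is None else frame.points)
        self.triads = np.array(triads, dtype=float).reshape(-1, 3, 3)
        self.centroids = self.triads.mean(axis=1) if len(self.residues) else np.empty((0, 3))
        self.seed_indices = [i for i, f in enumerate(self.frames) if f is not None]


def enumerate_seeds(
    ref: NucleicStructure, qry: NucleicStructure
) -> Iterator[tuple[NucleicResidue, NucleicResidue]]:
    """Yield every ordered pair of seed-eligible residues exactly once.

    Order is deterministic: reference residue order major, query order
    minor.
    """
    ref_ok = [r for r in ref.residues if reprs.seed_frame(r) is not None]
    qry_ok = [r for r in qry.residues if reprs.seed_frame(r) is not None]
    for r in ref_ok:
        for q in qry_ok:
            yield r, q


def _nearest(points: np.ndarray, tree: cKDTree, query_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour index and distance with deterministic tie-breaks.

    Ties (equal distances within 1e-9) resolve to the lowest index,
    i.e. the earliest residue in (chain, polymer_index) order.
    """
    dists, idx = tree.query(query_points)
    # refine ties: ask for all neighbours within dist + epsilon and take
    # the smallest index among those at (numerically) minimal distance
    for k in range(len(query_points)):
        near = tree.query_ball_point(query_points[k], dists[k] + 1e-9)
        if len(near) > 1:
            best = min(
                i for i in near
                if np.linalg.norm(points[i] - query_points[k]) <= dists[k] + 1e-9
            )
            idx[k] = best
    return dists, idx


def mutual_closest_pairs(
    ref_centroids: np.ndarray,
    qry_centroids: np.ndarray,
    matchrange: float,
    qry_tree: cKDTree | None = None,
) -> list[tuple[int, int]]:
    """Partial bijection of mutually closest points within ``matchrange``.

    Pair (i, j) is included iff j is the nearest query point to
    reference point i, i is the nearest reference point to j, and their
    distance does not exceed ``matchrange``.
    """
    ref_centroids = np.asarray(ref_centroids, dtype=float).reshape(-1, 3)
    qry_centroids = np.asarray(qry_centroids, dtype=float).reshape(-1, 3)
    if not len(ref_centroids) or not len(qry_centroids):
        return []
    if qry_tree is None:
        qry_tree = cKDTree(qry_centroids)
    dists, nearest_q = _nearest(qry_centroids, qry_tree, ref_centroids)

    pairs: list[tuple[int, int]] = []
    for i in np.argsort(nearest_q, kind="stable"):
        if dists[i] > matchrange:
            continue
        j = int(nearest_q[i])
        back = np.linalg.norm(ref_centroids - qry_centroids[j], axis=1)
        i_back = int(np.argmin(back))  # argmin takes the first minimum: lowest index
        if i_back == i:
            pairs.append((int(i), j))
    pairs.sort()
    return pairs


def _fit_pairs(
    ref_idx: _Indexed, qry_idx: _Indexed, pairs: Sequence[tuple[int, int]]
) -> tuple[RigidTransform, float]:
    P = ref_idx.triads[[i for i, _ in pairs]].reshape(-1, 3)
    Q = qry_idx.triads[[j for _, j in pairs]].reshape(-1, 3)
    return fit(P, Q)


def refine_match(
    ref_idx: _Indexed,
    qry_idx: _Indexed,
    initial_pairs: Sequence[tuple[int, int]],
    params: SearchParams,
    qry_tree: cKDTree | None = None,
) -> tuple[list[tuple[int, int]], float, RigidTransform] | None:
    """Iterate fit-on-matched / re-match to a fixed point.

    Each iteration fits the transform on all matched base triads (three
    points per pair) and re-derives the mutual-closest pairing under the
    new placement.  Stops when the pair set repeats or the iteration cap
    is reached; returns the best state seen (largest size, ties broken
    by lowest RMSD), or None if the pairing collapses below 3 residues.
    """
    if len(initial_pairs) < 3:
        return None
    pairs = sorted(initial_pairs)
    best: tuple[list[tuple[int, int]], float, RigidTransform] | None = None
    seen: set[frozenset] = set()
    for _ in range(max(1, params.max_refine_iters)):
        transform, value = _fit_pairs(ref_idx, qry_idx, pairs)
        if best is None or (len(pairs), -value) > (len(best[0]), -best[1]):
            best = (list(pairs), value, transform)
        seen.add(frozenset(pairs))
        moved = transform.apply(ref_idx.centroids)
        new_pairs = mutual_closest_pairs(moved, qry_idx.centroids, params.matchrange, qry_tree)
        if len(new_pairs) < 3 or frozenset(new_pairs) in seen:
            break
        pairs = new_pairs
    return best


def _accepts(size: int, value: float, params: SearchParams) -> bool:
    if size < params.sizemin:
        return False
    if params.sizemax is not None and size > params.sizemax:
        return False
    if params.rmsdmax is not None and value > params.rmsdmax:
        return False
    return True


def search(
    ref: NucleicStructure,
    qry: NucleicStructure,
    params: SearchParams | None = None,
    restraints=None,
) -> list[Hit]:
    """Full seed-enumeration search of a reference module in a query.

    Returns accepted hits, deduplicated (identical residue pairings
    found from different seeds are reported once) and sorted by size
    descending, then RMSD ascending.  Deterministic for any thread
    count.
    """
    params = params or SearchParams()
    ref_idx = _Indexed(ref)
    qry_idx = _Indexed(qry)
    n, m = len(ref_idx.residues), len(qry_idx.residues)
    if min(n, m) < params.sizemin or not ref_idx.seed_indices or not qry_idx.seed_indices:
        return []
    qry_tree = cKDTree(qry_idx.centroids)

    def process(seed_batch: list[tuple[int, int]]) -> list[Hit]:
        out: list[Hit] = []
        for si, sj in seed_batch:
            try:
                transform, _ = fit(ref_idx.frames[si], qry_idx.frames[sj])
            except np.linalg.LinAlgError:  # pragma: no cover - corrupt input
                continue
            moved = transform.apply(ref_idx.centroids)
            pairs = mutual_closest_pairs(moved, qry_idx.centroids, params.matchrange, qry_tree)
            refined = refine_match(ref_idx, qry_idx, pairs, params, qry_tree)
            if refined is None:
                continue
            best_pairs, value, best_t = refined
            if not _accepts(len(best_pairs), value, params):
                continue
            hit = Hit(
                reference_path=ref.source_path,
                query_path=qry.source_path,
                pairs=[
                    (ref_idx.residues[i].id, qry_idx.residues[j].id)
                    for i, j in best_pairs
                ],
                rmsd=value,
                transform=best_t,
                seed=(ref_idx.residues[si].id, qry_idx.residues[sj].id),
            )
            if restraints is not None and not restraints.accepts(hit, ref, qry, params):
                continue
            out.append(hit)
        return out

    seeds = [(i, j) for i in ref_idx.seed_indices for j in qry_idx.seed_indices]
    if params.threads > 1 and len(seeds) > 1:
        chunks = np.array_split(np.arange(len(seeds)), params.threads)
        with ThreadPoolExecutor(max_workers=params.threads) as pool:
            results = pool.map(process, [[seeds[k] for k in chunk] for chunk in chunks])
        hits = [h for batch in results for h in batch]
    else:
        hits = process(seeds)

    # dedup identical pairings reached from different seeds
    unique: dict[frozenset, Hit] = {}
    for h in hits:
        key = h.pair_key()
        old = unique.get(key)
        if old is None or h.rmsd < old.rmsd - 1e-12:
            unique[key] = h
    ordered = sorted(
        unique.values(),
        key=lambda h: (-h.size, h.rmsd, sorted(h.pair_key())),
    )
    return ordered
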