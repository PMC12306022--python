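# Methods

## The problem

Recurrent RNA/DNA tertiary modules — kink-turns, G-tetrads, GNRA
receptors and the like — are conventionally found by matching sequence
patterns, base-pair annotations or secondary-structure topology. All
three descriptions are more variable than the 3D arrangement itself:
the same spatial module recurs with different sequences, different
annotated pairs and differently threaded backbones. `isomotif`
therefore searches purely in coordinate space: a hit is any set of
query residues whose bases occupy (nearly) the same relative positions
as the reference module's, regardless of sequence, annotation or chain
connectivity (isostericity in the operational sense of
superimposability).

## The algorithm

Given a reference module of N residues and a query of M residues:

1. **Representations.** Each residue is reduced to a 3-atom *base
   triad* — purines (N9, C2, C6), pyrimidines (N1, C2, C4) — and a
   5-atom *seed frame* (triad + C1' + P, with O5' substituting for P at
   5' termini). The triad atoms are widely separated ring atoms present
   in nearly all modified nucleotides; the glycosidic nitrogen anchors
   the frame at the sugar. Residues missing triad atoms, or whose triad
   is numerically collinear (area ≤ 1e-6 Å²), are excluded and logged.
2. **Seed enumeration.** Every ordered residue pair (one reference, one
   query) is a seed: the reference is placed onto the query by a
   least-squares fit of the two 5-point frames, slot k to slot k
   irrespective of base class.
3. **Mutual-closest matching.** Under the placement, residues i and j
   are paired iff each one's triad centroid is the other's nearest
   neighbour and their distance is ≤ `matchrange`. The result is a
   partial bijection; nearest-neighbour ties resolve to the earliest
   residue in file order for determinism.
4. **Refinement.** The transform is refitted on all matched triads
   (Kabsch on 3 points per pair), the pairing re-derived, and the cycle
   iterated until the pair set repeats or `max_refine_iters` (default
   10) is reached; the best state seen (largest size, then lowest RMSD)
   is kept. `--refine 1` reproduces a strict single-pass matching.
5. **Filtering.** A candidate becomes a hit if it satisfies `sizemin`,
   `rmsdmax` and every active restraint. Hits with identical pairings
   reached from different seeds are reported once; output is sorted by
   size descending then RMSD ascending and is byte-deterministic for
   any thread count (threads only partition the seed loop; results are
   merged, deduplicated and sorted identically).

The N×M seed enumeration solves the otherwise NP-hard residue-set
matching problem in polynomial time; it works because nucleic-acid
modules are locally rigid and their planar bases give every residue a
well-defined frame.

All reported RMSDs are computed on the concatenated base triads of the
matched residues. The superposition kernel is Kabsch via SVD with a
determinant sign correction: reflections are never returned, because
the mirror image of a nucleic-acid fragment is a different molecule.

## Restraints

Four restraint types narrow a search to curated knowledge of a motif:
required positions, IUPAC base-type patterns on partners (an unmapped
modified base satisfies only `N`), subset RMSD, and strand continuity.
Two deliberate readings:

* **Subset RMSD is evaluated under the hit's own transform, without
  refitting.** A refit could pass a subset that is well-shaped but
  misplaced in the actual superposition; the no-refit reading is
  stricter and self-consistent.
* **Continuity is strict**: the query partners of the group, in order,
  must be consecutive residues of one chain with every O3'(i)–P(i+1)
  distance strictly under 2.0 Å. A link of exactly 2.0 Å is a break.

## Post-processing

* `remove_submatches` (the `nosub` option) drops hits whose pairing is
  a strict subset of a retained hit's pairing; among identical pairings
  the lowest-RMSD one is kept. The filter is idempotent.
* `deduplicate_across_references` merges hits with identical query
  residue sets found from different reference modules, keeping
  per-reference provenance.
* The kink/no-kink heuristic labels a hit *kink* when the query
  partners of positions 2b and L1 share a chain and are fewer than 10
  residues apart in sequence; exactly 10, or partners on different
  chains, is *no-kink*; a missing partner is *undetermined*. Sequence
  distance is measured in `polymer_index` units — residues actually
  present in the coordinate file — rather than author-numbering gaps,
  which is robust to numbering jumps and is all a structure-only tool
  can know.
* `score_against_truth` judges a merged hit a true positive when ≥ 50%
  of its query residues lie in some ground-truth module; hits on the
  same module merge into one TP, unrecovered modules count one FN each,
  and precision = TP/(TP+FP), recall = TP/(TP+FN),
  F = 2·TP/(2·TP+FP+FN). Matches overlapping no truth module are
  merged into one FP when their residue sets mutually overlap by ≥ 50%
  — the merging rule for false positives is a documented choice of this
  package and is the main place where benchmark FP counts could differ
  between implementations.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sizemin` | 3 | minimum matched residues (3 = everything a rigid fit can use) |
| `sizemax` | unlimited | maximum matched residues |
| `rmsdmax` | unlimited | maximum base-triad RMSD, Å |
| `matchrange` | 3.0 Å | mutual-closest centroid cutoff |
| `max_refine_iters` | 10 | fit/re-match iteration cap |
| `threads` | 1 | seed-loop parallelism (results identical for any value) |

`matchrange` = 3.0 Å sits between the displacement of a genuinely
corresponding residue in a distorted module instance (≲ 2 Å) and the
distance to stacked/paired neighbours at typical helical rise and twist
(≳ 4 Å); it is exposed because the exact value interacts with how
aggressively refinement can grow a match. Published kink-turn searches
use `sizemin 12`, `rmsdmax 2.0` and a required-position restraint on
the seven core positions (see `examples/kink_turn/`).

## Structure parsing policy

The first model is read by default (crystallographic and cryo-EM
entries put the meaningful coordinates there); a selector can name
another model. For alternate locations the highest-occupancy conformer
wins, ties broken alphabetically — superposition needs one conformer
per atom. Modified residues map to a parent base through a shipped,
user-extensible component table; unmapped components with a ribose C1'
and a glycosidic nitrogen are kept with unknown base code (the search
is sequence-agnostic; base codes matter only to IUPAC restraints).
Author chain ids and numbering, including insertion codes, identify
residues everywhere.

## The synthetic generator, and what passing tests show

`isomotif.fixtures` builds parametrically helical toy structures
carrying only the atoms the algorithm touches: A/B-form duplexes
(rise 2.81/3.38 Å, twist 32.7°/36° per step), seeded Gaussian coordinate
noise, controlled O3'–P chain breaks, and a 14-residue two-stem module
with a sharp ~110° bend plus a 60-residue positive query embedding a
rigid copy and a straight-duplex decoy. Residues are rigidly congruent
by construction and consecutive links fall in the covalent range, so
the fixtures satisfy every invariant the parser and representations
assert. They are *not* physically realistic: no full sugar ring, no
hydrogen-bonded base pairing, no disorder. Passing tests therefore
demonstrate the correctness of the geometry, matching, restraint and
scoring machinery — not recall on experimental structures, which
depends on how far real motif instances deviate from a reference
(addressed operationally by `rmsdmax` and the published threshold
calibration protocol in `examples/kink_turn/`).

The exact atom names behind the original 5-atom/3-atom residue
representations used by prior tools are not standardised; this
package's choice (N9/N1, C2, C6/C4, C1', P) is documented prominently
because match RMSDs are only comparable across tools at the level of
reproduced hit sizes and thresholds, not digit-for-digit.

## Numerical choices and degenerate inputs

* Fits with fewer than 3 points raise; collinear point sets are fitted
  with a warning-free arbitrary in-axis rotation (the minimum exists).
* RMSDs are computed from actual transformed distances, not the trace
  identity, to avoid cancellation near zero.
* Nearest-neighbour ties break to the earliest residue; hit ordering
  and TSV output are fully deterministic.
* Per-seed numerical failures are skipped and logged, never fatal.

## Problem sizes

The test suite and `scripts/acceptance.py` run on the toy scale the
generator targets — modules of 14 residues against queries of 30–60
residues, a few hundred to a thousand seeds per search — which
exercises every code path in seconds. Database-scale surveys are the
same code driven over folders of mmCIF files with `--threads`.

## Known limitations

* No secondary-structure or base-pair annotation of hits (loop-type
  labels require an external annotator; the TSV reserves a free-text
  column).
* No assembly/symmetry expansion; no NMR-ensemble-aware matching
  (single model per search).
* Sub-match removal and cross-reference dedup operate on exact residue
  sets; near-duplicate hits differing by one residue are distinct by
  design.
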