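"""Sub-match removal, cross-reference dedup, kink labels and scoring."""

import itertools

import pytest

from isomotif.matching import Hit
from isomotif.postprocess import (
    assign_kink_label,
    deduplicate_across_references,
    remove_submatches,
    score_against_truth,
)
from isomotif.structure_io import ResidueId
from isomotif.superposition import RigidTransform


def rid(chain, num, model=1):
    return ResidueId(model, chain, num, "", "N")


def make_hit(pair_nums, rmsd=1.0, ref="ref.pdb", qry="qry.pdb", qry_chain="Q"):
    pairs = [(rid("R", a), rid(qry_chain, b)) for a, b in pair_nums]
    return Hit(ref, qry, pairs, rmsd, RigidTransform.identity(), pairs[0])


class TestRemoveSubmatches:
    def test_strict_subset_removed(self):
        big = make_hit([(1, 1), (2, 2), (3, 3), (4, 4)])
        sub = make_hit([(1, 1), (2, 2), (3, 3)])
        assert remove_submatches([sub, big]) == [big]

    def test_disjoint_hits_both_kept(self):
        a = make_hit([(1, 1), (2, 2), (3, 3)])
        b = make_hit([(4, 4), (5, 5), (6, 6)])
        assert set(map(id, remove_submatches([a, b]))) == {id(a), id(b)}

    def test_chain_of_subsets_keeps_only_largest(self):
        a = make_hit([(1, 1), (2, 2), (3, 3)])
        b = make_hit([(1, 1), (2, 2), (3, 3), (4, 4)])
        c = make_hit([(1, 1), (2, 2), (3, 3), (4, 4), (5, 5)])
        # verify transitivity against a pairwise-subset oracle
        keys = [h.pair_key() for h in (a, b, c)]
        expected = [
            h for h, k in zip((a, b, c), keys)
            if not any(k < other for other in keys)
        ]
        assert remove_submatches([a, b, c]) == expected == [c]

    def test_identical_pairings_keep_lowest_rmsd(self):
        worse = make_hit([(1, 1), (2, 2), (3, 3)], rmsd=1.5)
        better = make_hit([(1, 1), (2, 2), (3, 3)], rmsd=0.5)
        assert remove_submatches([worse, better]) == [better]

    def test_idempotent(self):
        hits = [
            make_hit([(1, 1), (2, 2), (3, 3)]),
            make_hit([(1, 1), (2, 2), (3, 3), (4, 4)]),
            make_hit([(7, 7), (8, 8), (9, 9)]),
        ]
        once = remove_submatches(hits)
        assert remove_submatches(once) == once

    def test_partial_overlap_is_not_a_subset(self):
        a = make_hit([(1, 1), (2, 2), (3, 3)])
        b = make_hit([(2, 2), (3, 3), (4, 4)])
        assert len(remove_submatches([a, b])) == 2


class TestDeduplicateAcrossReferences:
    def test_same_query_set_merges_with_provenance(self):
        h1 = make_hit([(1, 1), (2, 2), (3, 3)], ref="kink.pdb", rmsd=1.0)
        h2 = make_hit([(4, 1), (5, 2), (6, 3)], ref="kjunction.pdb", rmsd=1.4)
        merged = deduplicate_across_references([[h1], [h2]])
        assert len(merged) == 1
        assert len(merged[0].provenance) == 2
        assert merged[0].best is h1

    def test_query_sets_differing_by_one_residue_stay_separate(self):
        h1 = make_hit([(1, 1), (2, 2), (3, 3)])
        h2 = make_hit([(1, 1), (2, 2), (3, 4)])
        assert len(deduplicate_across_references([[h1], [h2]])) == 2

    def test_empty_input(self):
        assert deduplicate_across_references([]) == []

    def test_every_input_hit_mapped_exactly_once(self):
        hits = [make_hit([(1, i), (2, i + 1), (3, i + 2)]) for i in range(4)]
        merged = deduplicate_across_references([hits])
        assert sum(len(m.hits) for m in merged) == len(hits)
        assert len(merged) <= len(hits)


class TestKinkLabel:
    def _toy_setup(self, l1_num, b2_num, l1_chain="Q", b2_chain="Q"):
        from isomotif.structure_io import AtomRecord, NucleicResidue, NucleicStructure

        labels = {rid("R", 1): "L1", rid("R", 2): "2b"}
        hit = make_hit([(1, 0), (2, 0), (3, 0)])
        hit.pairs = [
            (rid("R", 1), rid(l1_chain, l1_num)),
            (rid("R", 2), rid(b2_chain, b2_num)),
            (rid("R", 3), rid("Q", 90)),
        ]
        residues = []
        for chain in ("Q", "Z"):
            for k, num in enumerate(range(0, 100)):
                residues.append(NucleicResidue(
                    rid(chain, num),
                    [AtomRecord("C1'", "C", (float(num), 0.0, 0.0))], "G", k))
        qry = NucleicStructure("toy", residues)
        return hit, labels, qry

    @pytest.mark.parametrize("distance,expected", [
        (5, "kink"), (9, "kink"), (10, "no-kink"), (30, "no-kink"),
    ])
    def test_sequence_distance_threshold_is_strict(self, distance, expected):
        hit, labels, qry = self._toy_setup(l1_num=20, b2_num=20 + distance)
        assert assign_kink_label(hit, labels, qry) == expected

    def test_partners_on_different_chains_no_kink(self):
        hit, labels, qry = self._toy_setup(l1_num=20, b2_num=21, b2_chain="Z")
        assert assign_kink_label(hit, labels, qry) == "no-kink"

    def test_missing_partner_undetermined(self):
        hit, labels, qry = self._toy_setup(l1_num=20, b2_num=21)
        hit.pairs = [p for p in hit.pairs if p[0].number != 2]
        assert assign_kink_label(hit, labels, qry) == "undetermined"

    def test_labelling_without_2b_is_an_error(self):
        hit, labels, qry = self._toy_setup(l1_num=20, b2_num=21)
        with pytest.raises(ValueError):
            assign_kink_label(hit, {rid("R", 1): "L1"}, qry)

    def test_real_toy_module_is_kinked(self, kink_toy):
        from isomotif.matching import SearchParams, search

        hit = search(kink_toy.reference, kink_toy.positive,
                     SearchParams(sizemin=12, rmsdmax=2.0))[0]
        assert assign_kink_label(hit, kink_toy.labels, kink_toy.positive) == "kink"


def res_set(*nums, chain="Q"):
    return frozenset((1, chain, n, "") for n in nums)


class TestScoring:
    def test_single_perfect_hit(self):
        result = score_against_truth([res_set(1, 2, 3)], [res_set(1, 2, 3)])
        assert (result.precision, result.recall, result.f_score) == (1.0, 1.0, 1.0)

    def test_one_tp_one_fp(self):
        result = score_against_truth(
            [res_set(1, 2, 3), res_set(50, 51, 52)], [res_set(1, 2, 3)]
        )
        assert result.precision == pytest.approx(0.5)
        assert result.recall == pytest.approx(1.0)
        assert result.f_score == pytest.approx(2 / 3)

    def test_partial_recall_full_precision(self):
        truth = [res_set(10 * k, 10 * k + 1, 10 * k + 2) for k in range(1, 8)]
        hits = [res_set(10 * k, 10 * k + 1, 10 * k + 2) for k in range(1, 5)]
        result = score_against_truth(hits, truth)
        assert result.recall == pytest.approx(4 / 7)
        assert result.precision == pytest.approx(1.0)

    def test_half_overlap_counts_as_tp(self):
        # exactly 50% of the hit's residues inside the module
        result = score_against_truth([res_set(1, 2, 3, 4)], [res_set(1, 2, 30, 40)])
        assert result.tp == 1 and result.fp == 0

    def test_below_half_overlap_is_fp(self):
        result = score_against_truth([res_set(1, 2, 3, 4)], [res_set(1, 30, 40, 50)])
        assert result.tp == 0 and result.fp == 1 and result.fn == 1

    def test_multiple_hits_on_same_module_merge_to_one_tp(self):
        result = score_against_truth(
            [res_set(1, 2, 3), res_set(2, 3, 4)], [res_set(1, 2, 3, 4)]
        )
        assert result.tp == 1 and result.fp == 0

    def test_exhaustive_small_cases_match_hand_oracle(self):
        """Every configuration of <=3 hits x <=2 truth modules agrees with a
        direct recount of the TP/FP/FN definitions."""
        pool = [res_set(1, 2, 3), res_set(3, 4, 5), res_set(40, 41, 42)]
        truths = [res_set(1, 2, 3), res_set(40, 41, 42, 43)]
        for k in range(4):
            for hits in itertools.combinations(pool, k):
                for tk in range(1, 3):
                    for truth in itertools.combinations(truths, tk):
                        result = score_against_truth(list(hits), list(truth))
                        # oracle: recount from the definitions
                        tp_modules = set()
                        fp_sets = []
                        for h in hits:
                            fracs = [len(h & t) / len(h) for t in truth]
                            if fracs and max(fracs) >= 0.5:
                                tp_modules.add(max(range(len(truth)), key=lambda i: fracs[i]))
                            else:
                                fp_sets.append(h)
                        tp, fn = len(tp_modules), len(truth) - len(tp_modules)
                        # pool FPs never mutually overlap >= 50% here
                        fp = len(fp_sets)
                        assert (result.tp, result.fp, result.fn) == (tp, fp, fn)
                        if tp + fp:
                            assert result.precision == pytest.approx(tp / (tp + fp))
                        if tp + fn:
                            assert result.recall == pytest.approx(tp / (tp + fn))
                        if 2 * tp + fp + fn:
                            assert result.f_score == pytest.approx(
                                2 * tp / (2 * tp + fp + fn))

    def test_fp_merging_by_mutual_overlap(self):
        a = res_set(1, 2, 3, 4)
        b = res_set(3, 4, 5, 6)  # 50% mutual overlap with a -> merged
        c = res_set(50, 51, 52)
        result = score_against_truth([a, b, c], [res_set(90, 91, 92)])
        assert result.fp == 2
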