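"""Indel canonicalization, microhomology calculus, flank matching,
classification and directionality."""

import pytest
from hypothesis import given, settings, strategies as st

from cas9repair import (
    FlankMatch,
    Indel,
    OutcomeCategory,
    apply_indel,
    canonicalize,
    classify,
    directionality,
    insertion_flank_match,
    mh_length,
    templated_insertion,
)
from cas9repair.outcomes import CoordinateError

from conftest import make_site, site_with_flanks

dna = st.text(alphabet="ACGT", min_size=0)


class TestCanonicalize:
    def test_deletion_left_shifts_through_microhomology(self):
        # brute-force equivalence class of [3,7) on AATCGATCGTT is
        # {[1,5),[2,6),[3,7),[4,8),[5,9)}: the canonical form is [1,5)
        t = make_site("AATCGATCGTT")
        can = canonicalize(t, Indel(3, 7))
        assert (can.start, can.end) == (1, 5)
        assert apply_indel(t.sequence, can) == apply_indel(t.sequence, Indel(3, 7))

    def test_idempotent(self):
        t = make_site("AATCGATCGTT")
        can = canonicalize(t, Indel(3, 7))
        assert canonicalize(t, can) == can

    def test_insertion_shifts_to_run_start(self):
        # inserting T at the 3' end of the TTT run is the same molecule as
        # inserting T at its 5' end
        t = make_site("ACGTTTACG")
        can = canonicalize(t, Indel(6, 6, "T"))
        assert can == Indel(3, 3, "T")
        assert apply_indel(t.sequence, can) == apply_indel(t.sequence, Indel(6, 6, "T"))

    def test_compound_reduces_to_pure_deletion(self):
        # deleting CGC and re-inserting C is just a CG deletion
        t = make_site("ACGCAT")
        can = canonicalize(t, Indel(1, 4, "C"))
        assert not can.is_compound
        assert apply_indel(t.sequence, can) == apply_indel(t.sequence, Indel(1, 4, "C"))

    def test_out_of_bounds_rejected(self):
        t = make_site("ACGTACGT")
        with pytest.raises(CoordinateError):
            canonicalize(t, Indel(2, 99))

    def test_identity_edit_rejected(self):
        t = make_site("ACGTACGT")
        with pytest.raises(ValueError):
            canonicalize(t, Indel(2, 4, t.sequence[2:4]))

    @settings(max_examples=300, derandomize=True)
    @given(st.data())
    def test_preserves_mutated_sequence_and_is_class_consistent(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=8, max_size=20))
        t = make_site(seq)
        n = len(t.sequence)
        a = data.draw(st.integers(0, n - 1))
        b = data.draw(st.integers(a, min(n, a + 6)))
        ins = data.draw(st.text(alphabet="ACGT", min_size=0, max_size=4))
        if a == b and not ins:
            return
        raw = Indel(a, b, ins)
        mutated = apply_indel(t.sequence, raw)
        if mutated == t.sequence:
            return
        can = canonicalize(t, raw)
        assert apply_indel(t.sequence, can) == mutated
        assert canonicalize(t, can) == can
        # every equivalent same-size deletion window canonicalizes identically
        if can.is_deletion:
            L = can.deletion_size
            for x in range(0, n - L + 1):
                if t.sequence[:x] + t.sequence[x + L :] == mutated:
                    assert canonicalize(t, Indel(x, x + L)) == can


class TestMicrohomology:
    @pytest.mark.parametrize(
        "seq,a,b,expected",
        [
            ("AATCGATCGTT", 2, 6, 4),  # class {[1,5)..[5,9)}: 5 windows
            ("ACGT", 1, 2, 0),
            ("AAAA", 0, 2, 2),
        ],
    )
    def test_examples(self, seq, a, b, expected):
        assert mh_length(make_site(seq), Indel(a, b)) == expected

    def test_rejects_insertions(self):
        with pytest.raises(ValueError):
            mh_length(make_site("ACGTACGT"), Indel(1, 2, "G"))

    @settings(max_examples=150, derandomize=True)
    @given(st.data())
    def test_equals_window_class_size_minus_one(self, data):
        """mh_length + 1 == number of same-size deletion windows producing
        the identical mutated sequence (brute-force oracle)."""
        seq = data.draw(st.text(alphabet="ACGT", min_size=10, max_size=24))
        t = make_site(seq)
        n = len(t.sequence)
        L = data.draw(st.integers(1, 5))
        a = data.draw(st.integers(0, n - L))
        mutated = t.sequence[:a] + t.sequence[a + L :]
        n_windows = sum(
            1
            for x in range(0, n - L + 1)
            if t.sequence[:x] + t.sequence[x + L :] == mutated
        )
        assert mh_length(t, Indel(a, a + L)) + 1 == n_windows


class TestFlankMatch:
    def test_distal_and_proximal(self, gattaca):
        # flanks: distal T, proximal C
        assert insertion_flank_match(gattaca, Indel(17, 17, "T")) is FlankMatch.DISTAL_ONLY
        assert insertion_flank_match(gattaca, Indel(17, 17, "C")) is FlankMatch.PROXIMAL_ONLY
        assert insertion_flank_match(gattaca, Indel(17, 17, "G")) is FlankMatch.NEITHER

    def test_both_when_flanks_equal(self):
        t = site_with_flanks("T", "T")
        assert insertion_flank_match(t, Indel(17, 17, "T")) is FlankMatch.BOTH

    def test_two_bp_insertion_compared_to_two_bp_flanks(self, gattaca):
        # distal 2-mer is sequence[15:17] == "GT"
        assert gattaca.sequence[15:17] == "GT"
        assert insertion_flank_match(gattaca, Indel(17, 17, "GT")) is FlankMatch.DISTAL_ONLY

    def test_off_cut_and_long_insertions_are_na(self, gattaca):
        assert insertion_flank_match(gattaca, Indel(3, 3, "T")) is FlankMatch.NA
        assert insertion_flank_match(gattaca, Indel(17, 17, "TTT")) is FlankMatch.NA


class TestTemplatedInsertion:
    def test_substring_of_flank_is_templated(self):
        t = make_site("AAGGCATTTTTT")
        # insert CAT right after ...GGCAT (left 10bp window contains CAT)
        assert templated_insertion(t, Indel(7, 7, "CAT"))

    def test_absent_motif_is_not_templated(self):
        t = make_site("ACACACACACAC")
        assert not templated_insertion(t, Indel(6, 6, "GGG"))

    def test_single_base_never_templated(self):
        t = make_site("AAAAAAAAAA")
        assert not templated_insertion(t, Indel(4, 4, "A"))


class TestClassify:
    def test_medium_deletion_with_mh(self):
        t = make_site("AATCGATCGTT")
        co = classify(t, Indel(2, 6))
        assert co.category is OutcomeCategory.D3_9_MH
        assert co.mh_len == 4
        assert not co.in_frame  # net -4

    def test_1bp_deletion_is_D1_regardless_of_mh(self):
        t = make_site("AAAAACGT")
        co = classify(t, Indel(2, 3))
        assert co.category is OutcomeCategory.D1

    def test_compound_untemplated_is_other_i(self, gattaca):
        co = classify(gattaca, Indel(16, 18, "GGG"))
        assert co.category is OutcomeCategory.OTHER_I
        assert co.indel.is_compound
        assert not co.in_frame  # net +1

    def test_insertion_categories(self, gattaca):
        assert classify(gattaca, Indel(17, 17, "T")).category is OutcomeCategory.I12_DIST
        assert classify(gattaca, Indel(17, 17, "C")).category is OutcomeCategory.I12_PROX
        both = classify(site_with_flanks("T", "T"), Indel(17, 17, "T"))
        assert both.category is OutcomeCategory.I12_DIST
        assert both.flank_match is FlankMatch.BOTH

    def test_in_frame_matches_net_change(self, gattaca):
        assert classify(gattaca, Indel(14, 17)).in_frame  # net -3
        assert not classify(gattaca, Indel(16, 17)).in_frame  # net -1
        assert classify(gattaca, Indel(16, 18, "GA")).in_frame  # net 0

    def test_total_and_unique_over_candidate_space(self):
        from cas9repair import GenerativeParams, enumerate_candidates, generate_targets

        params = GenerativeParams(n_targets=1)
        target = next(iter(generate_targets(params, seed=13).values()))
        cands = enumerate_candidates(target)
        cats = [classify(target, c).category for c in cands.candidates]
        assert len(cats) == len(cands.candidates)
        assert all(isinstance(c, OutcomeCategory) for c in cats)


class TestDirectionality:
    def test_one_bp_deletions_are_fully_directional(self, atgc_site):
        c = atgc_site.cut_index
        assert directionality(atgc_site, Indel(c - 1, c)) == 1.0
        assert directionality(atgc_site, Indel(c, c + 1)) == 1.0

    def test_symmetric_deletion(self, atgc_site):
        c = atgc_site.cut_index
        assert directionality(atgc_site, Indel(c - 3, c + 3)) == 0.5

    def test_asymmetric_deletion(self, atgc_site):
        c = atgc_site.cut_index
        assert directionality(atgc_site, Indel(c - 4, c + 1)) == pytest.approx(0.8)

    def test_one_sided_deletion(self, atgc_site):
        c = atgc_site.cut_index
        assert directionality(atgc_site, Indel(c - 6, c - 2)) == 1.0

    def test_rejects_insertions(self, atgc_site):
        with pytest.raises(ValueError):
            directionality(atgc_site, Indel(4, 4, "G"))

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_bounded_in_unit_interval(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=12, max_size=20))
        t = make_site(seq)
        n = len(t.sequence)
        a = data.draw(st.integers(0, n - 2))
        b = data.draw(st.integers(a + 1, min(n, a + 8)))
        v = directionality(t, Indel(a, b))
        assert 0.5 <= v <= 1.0
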