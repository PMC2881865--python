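"""Folding and six-criteria filter tests, anchored by an exhaustive
enumeration oracle over all nested structures for short sequences."""

import random

import pytest

from mirrace.hairpin import (
    MIN_LOOP,
    FoldError,
    HairpinConfig,
    NoStarError,
    Span,
    duplex_mismatch_count,
    evaluate_criteria,
    fold_hairpin,
    infer_star,
    mature_arm,
)
from mirrace.seqcore import NucSequence
from mirrace.simulate import draw_feasible_precursor, make_precursor, random_mature

PAIR_SCORE = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def best_score_by_enumeration(seq: str) -> int:
    """Maximum pair-score over *all* nested structures, by brute-force
    recursion over every pairing choice (independent of the DP)."""

    def rec(i: int, j: int) -> int:
        if j - i <= MIN_LOOP:
            return 0
        best = rec(i, j - 1)  # j unpaired
        for k in range(i, j - MIN_LOOP):
            w = PAIR_SCORE.get((seq[k], seq[j]))
            if w:
                best = max(best, rec(i, k - 1) + rec(k + 1, j - 1) + w)
        return best

    return rec(0, len(seq) - 1)


class TestFoldHairpin:
    def test_simple_stem_loop(self):
        h = fold_hairpin(NucSequence("x", "GGGGAAAACCCC", "RNA"))
        assert h.pair_table == (12, 11, 10, 9, 0, 0, 0, 0, 4, 3, 2, 1)
        assert h.fold_score == -12.0
        assert h.dot_bracket() == "((((....))))"

    def test_homopolymer_has_no_pairs(self):
        h = fold_hairpin(NucSequence("x", "A" * 40, "RNA"))
        assert h.n_pairs() == 0
        assert h.fold_score == 0.0

    def test_min_length_enforced(self):
        with pytest.raises(FoldError):
            fold_hairpin(NucSequence("x", "ACGUACGU", "RNA"), min_len=40)

    def test_accepts_dna_input(self):
        h = fold_hairpin(NucSequence("x", "GGGGAAAACCCC", "DNA"))
        assert h.n_pairs() == 4

    def test_matches_enumeration_oracle_short(self):
        rng = random.Random(11)
        for _ in range(80):
            n = rng.randint(5, 14)
            s = "".join(rng.choice("ACGU") for _ in range(n))
            h = fold_hairpin(NucSequence("x", s, "RNA"))
            assert -h.fold_score == best_score_by_enumeration(s), s

    def test_pair_table_valid_on_random_sequences(self):
        rng = random.Random(5)
        for _ in range(25):
            n = rng.randint(30, 70)
            s = "".join(rng.choice("ACGU") for _ in range(n))
            h = fold_hairpin(NucSequence("x", s, "RNA"))
            pt = h.pair_table
            stack = []
            for i, j in enumerate(pt, start=1):
                if j == 0:
                    continue
                assert pt[j - 1] == i  # symmetric
                if j > i:
                    assert j - i > MIN_LOOP
                    assert (s[i - 1], s[j - 1]) in PAIR_SCORE
                    stack.append(j)
                else:
                    assert stack.pop() == i  # properly nested

    def test_deterministic(self):
        s = NucSequence("x", "GCAUGGCUAGCUAGGCAUGCUUAGCGCUAAGCUAGCAUGC", "RNA")
        assert fold_hairpin(s).pair_table == fold_hairpin(s).pair_table


class TestInferStar:
    def test_perfect_stem_opposing_span_with_overhang(self):
        mat = random_mature(20, seed=3)
        prec, truth = make_precursor(mat, 0, seed=3)
        span = Span(*truth.params["mature_span"])
        h = fold_hairpin(prec, span)
        star = infer_star(h, span, overhang=2)
        true_star = truth.params["star_span"]
        assert (star.start, star.end) == (true_star[0] + 2, true_star[1] + 2)
        assert mature_arm(h, span) == "5p"

    def test_zero_overhang_is_exact_opposite(self):
        mat = random_mature(20, seed=3)
        prec, truth = make_precursor(mat, 0, seed=3)
        span = Span(*truth.params["mature_span"])
        h = fold_hairpin(prec, span)
        star = infer_star(h, span, overhang=0)
        assert (star.start, star.end) == tuple(truth.params["star_span"])

    def test_loop_overlap_raises(self):
        mat = random_mature(20, seed=3)
        prec, truth = make_precursor(mat, 0, seed=3)
        s, e = truth.params["mature_span"]
        h = fold_hairpin(prec)
        # span straddling the terminal loop pairs on both sides
        with pytest.raises(NoStarError):
            infer_star(h, Span(e - 4, e + 10))

    def test_unpaired_mature_raises(self):
        h = fold_hairpin(NucSequence("x", "A" * 40, "RNA"))
        with pytest.raises(NoStarError):
            infer_star(h, Span(5, 24))


class TestCriteria:
    def test_perfect_precursor_passes_all_six(self):
        mat = random_mature(21, seed=8)
        prec, truth = make_precursor(mat, 0, seed=8)
        span = Span(*truth.params["mature_span"])
        rep = evaluate_criteria(fold_hairpin(prec, span), span, mat)
        assert rep.passed and all(rep.criteria.values())
        assert rep.duplex_mismatches == 0

    def test_seven_duplex_mismatches_fail_criterion_six(self):
        mat, prec, truth = draw_feasible_precursor(7, length=24, seed=101)
        span = Span(*truth.params["mature_span"])
        rep = evaluate_criteria(fold_hairpin(prec, span), span, mat)
        assert rep.duplex_mismatches == 7
        assert rep.criteria[6] is False and not rep.passed

    def test_five_substitutions_fail_criterion_two(self):
        mat = random_mature(21, seed=8)
        prec, truth = make_precursor(mat, 0, seed=8)
        span = Span(*truth.params["mature_span"])
        other = list(mat.residues)
        for i in (0, 9, 11, 13, 19):
            other[i] = {"A": "C", "C": "A", "G": "U", "U": "G"}[other[i]]
        known = NucSequence("k", "".join(other), "RNA")
        rep = evaluate_criteria(fold_hairpin(prec, span), span, known)
        assert rep.substitutions == 5
        assert rep.criteria[2] is False and not rep.passed

    def test_four_substitutions_pass_criterion_two(self):
        mat = random_mature(21, seed=8)
        prec, truth = make_precursor(mat, 0, seed=8)
        span = Span(*truth.params["mature_span"])
        other = list(mat.residues)
        for i in (0, 9, 11, 13):
            other[i] = {"A": "C", "C": "A", "G": "U", "U": "G"}[other[i]]
        rep = evaluate_criteria(
            fold_hairpin(prec, span), span, NucSequence("k", "".join(other), "RNA")
        )
        assert rep.substitutions == 4 and rep.criteria[2] is True

    def test_fold_score_threshold_configurable(self):
        mat = random_mature(21, seed=8)
        prec, truth = make_precursor(mat, 0, seed=8)
        span = Span(*truth.params["mature_span"])
        h = fold_hairpin(prec, span)
        strict = evaluate_criteria(h, span, config=HairpinConfig(max_fold_score=-1000))
        assert strict.criteria[1] is False

    def test_duplex_mismatches_monotone_in_engineered_k(self):
        # adding engineered mismatches never flips criterion 6 fail -> pass
        prev_fail = False
        for k in range(0, 9):
            mat, prec, truth = draw_feasible_precursor(k, length=24, seed=55)
            span = Span(*truth.params["mature_span"])
            rep = evaluate_criteria(fold_hairpin(prec, span), span, mat)
            assert rep.duplex_mismatches == k
            if prev_fail:
                assert rep.criteria[6] is False
            prev_fail = prev_fail or not rep.criteria[6]

    def test_report_always_produced(self):
        h = fold_hairpin(NucSequence("x", "A" * 50, "RNA"))
        rep = evaluate_criteria(h, Span(10, 30))
        assert not rep.passed and rep.arm == "unpaired"


def test_duplex_mismatch_count_equals_unpaired_mature_positions():
    mat = random_mature(22, seed=77)
    prec, truth = make_precursor(mat, 3, seed=77)
    span = Span(*truth.params["mature_span"])
    h = fold_hairpin(prec, span)
    unpaired = sum(
        1 for p in range(span.start, span.end + 1) if h.pair_table[p - 1] == 0
    )
    assert duplex_mismatch_count(h, span) == unpaired == 3
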