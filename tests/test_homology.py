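"""Seed-anchored scanning tests, checked against a brute-force
all-substring oracle and generator ground truth."""

import random

import pytest

from mirrace.homology import (
    MatureMiRNA,
    PredictConfig,
    extract_precursor_windows,
    pattern_filter,
    predict_mirnas,
    seed_scan,
)
from mirrace.seqcore import NucSequence, reverse_complement, rna
from mirrace.simulate import make_est, make_precursor, mutate_nonseed, random_mature


def brute_force_hits(known: MatureMiRNA, est: NucSequence):
    """Independent oracle: check every substring on both strands directly."""
    L = len(known)
    kres = known.sequence.residues
    found = []
    for strand in "+-":
        s = rna(est if strand == "+" else reverse_complement(est)).residues
        for off in range(len(s) - L + 1):
            win = s[off : off + L]
            if win[1:8] == kres[1:8]:
                start = off + 1 if strand == "+" else len(s) - off - L + 1
                mm = sum(
                    1 for i in range(L) if i not in range(1, 8) and win[i] != kres[i]
                )
                found.append((strand, start, mm))
    return sorted(found)


def _embed(insert_dna: str, est_len: int, at: int, seed: int) -> NucSequence:
    rng = random.Random(seed)
    bg = "".join(rng.choice("ACGT") for _ in range(est_len - len(insert_dna)))
    return NucSequence("est", bg[: at - 1] + insert_dna + bg[at - 1 :], "DNA")


@pytest.fixture
def known():
    return MatureMiRNA("k", random_mature(21, seed=17))


class TestSeedScan:
    def test_exact_copy_plus_strand(self, known):
        ins = known.sequence.residues.replace("U", "T")
        est = _embed(ins, 200, at=50, seed=1)
        hits = [h for h in seed_scan(known, est) if h.nonseed_mismatches == 0]
        assert any(h.strand == "+" and h.start == 50 for h in hits)

    def test_reverse_complement_minus_strand(self, known):
        ins = reverse_complement(
            NucSequence("m", known.sequence.residues.replace("U", "T"), "DNA")
        ).residues
        est = _embed(ins, 200, at=50, seed=2)
        hits = [h for h in seed_scan(known, est) if h.nonseed_mismatches == 0]
        assert any(h.strand == "-" for h in hits)

    def test_mutated_seed_never_hits(self, known):
        res = list(known.sequence.residues.replace("U", "T"))
        res[4] = {"A": "C", "C": "A", "G": "T", "T": "G"}[res[4]]  # seed position 5
        est = _embed("".join(res), 200, at=50, seed=3)
        assert all(h.start != 50 or h.strand != "+" for h in seed_scan(known, est))

    def test_seed_always_exact_in_hits(self, known):
        rng = random.Random(4)
        for trial in range(5):
            est = NucSequence(
                "e", "".join(rng.choice("ACGT") for _ in range(500)), "DNA"
            )
            for h in seed_scan(known, est):
                assert h.extracted.residues[1:8] == known.seed

    def test_matches_brute_force_oracle(self, known):
        rng = random.Random(6)
        for trial in range(8):
            est_res = "".join(rng.choice("ACGT") for _ in range(300))
            # implant a partially mutated copy to guarantee some hits
            mut = mutate_nonseed(known.sequence, 2, seed=trial).residues
            pos = rng.randrange(0, 300 - 21)
            est = NucSequence(
                f"e{trial}", est_res[:pos] + mut.replace("U", "T") + est_res[pos + 21 :], "DNA"
            )
            got = sorted(
                (h.strand, h.start, h.nonseed_mismatches) for h in seed_scan(known, est)
            )
            assert got == brute_force_hits(known, est)

    def test_short_est_returns_empty(self, known):
        assert seed_scan(known, NucSequence("e", "ACGT", "DNA")) == []


class TestPatternFilter:
    def _hit_with_mm(self, known, n_mm, seed):
        mut = mutate_nonseed(known.sequence, n_mm, seed=seed)
        est = _embed(mut.residues.replace("U", "T"), 150, at=40, seed=seed)
        return [h for h in seed_scan(known, est) if h.start == 40 and h.strand == "+"]

    def test_three_mismatches_retained(self, known):
        hits = self._hit_with_mm(known, 3, seed=9)
        kept = pattern_filter(hits, known)
        assert any(h.nonseed_mismatches == 3 for h in kept)

    def test_four_mismatches_removed(self, known):
        hits = self._hit_with_mm(known, 4, seed=10)
        assert all(
            h.nonseed_mismatches != 4 for h in pattern_filter(hits, known)
        )

    def test_empty_input(self, known):
        assert pattern_filter([], known) == []

    def test_length_mismatch_rejected(self, known):
        other = MatureMiRNA("o", random_mature(24, seed=1))
        est = _embed(other.sequence.residues.replace("U", "T"), 150, at=30, seed=2)
        hits = seed_scan(other, est)
        if hits:
            with pytest.raises(ValueError):
                pattern_filter(hits, known)


class TestPrecursorWindows:
    def test_window_arithmetic(self, known):
        ins = known.sequence.residues.replace("U", "T")
        est = _embed(ins, 400, at=100, seed=11)
        hit = next(
            h for h in seed_scan(known, est) if h.start == 100 and h.strand == "+"
        )
        cfg = PredictConfig(window_extents=(60,))
        (win,) = extract_precursor_windows(est, hit, cfg)
        assert len(win.precursor) == 60 + 21 + 60
        assert not win.truncated
        assert (win.mature.start, win.mature.end) == (61, 81)
        assert win.precursor.residues[60:81] == known.sequence.residues

    def test_truncation_flagged_near_est_edge(self, known):
        ins = known.sequence.residues.replace("U", "T")
        est = _embed(ins, 200, at=10, seed=12)
        hit = next(
            h for h in seed_scan(known, est) if h.start == 10 and h.strand == "+"
        )
        cfg = PredictConfig(window_extents=(60,))
        (win,) = extract_precursor_windows(est, hit, cfg)
        assert win.truncated
        assert win.mature.start == 10

    def test_window_contains_implanted_precursor(self, known):
        prec, truth = make_precursor(known.sequence, 0, seed=13)
        ests, etruth = make_est([prec], est_len=300, seed=13)
        hits = pattern_filter(seed_scan(known, ests[0]), known)
        assert hits
        cfg = PredictConfig(window_extents=(100,))
        # the implant may sit on either strand; a star-arm hit's window
        # contains the reverse complement of the precursor instead
        variants = {prec.residues, rna(reverse_complement(prec)).residues}
        found = False
        for hit in hits:
            for w in extract_precursor_windows(ests[0], hit, cfg):
                if any(v in rna(w.precursor).residues for v in variants):
                    found = True
        assert found


class TestPredictPipeline:
    def test_implants_recovered_decoys_rejected(self):
        knowns, precs = [], []
        for i in range(3):
            m = random_mature(21, seed=40 + i)
            knowns.append(MatureMiRNA(f"k{i}", m))
            precs.append(make_precursor(m, 0, seed=40 + i)[0])
        ests, truth = make_est(precs, n_decoys=5, est_len=300, seed=41)
        cands = predict_mirnas(knowns, ests)
        recovered = {c.mature for c in cands}
        assert {k.sequence.residues for k in knowns} <= recovered
        assert all(not c.est_id.startswith("est_decoy") for c in cands)

    def test_no_seed_match_empty(self):
        known = MatureMiRNA("k", random_mature(21, seed=50))
        est = NucSequence("e", "ACGT" * 30, "DNA")
        assert predict_mirnas([known], [est]) == []

    def test_table1_mir156_region_recovered_with_ath_ortholog(
        self, table1_mirnas, table1_ath, table1_precursors
    ):
        # synthetic hairpin whose 5' arm carries the published precursor
        # region verbatim; scanning with the Arabidopsis ortholog must
        # recover the trifoliate-orange mature exactly
        region = next(s for s in table1_precursors if s.id == "ptrmir156")
        star = reverse_complement(region).residues
        hairpin = "AAC" + region.residues + "CAAC" + star + "GUU"
        est = NucSequence("est156", hairpin.replace("U", "T"), "DNA")
        ath = MatureMiRNA("ath-miR156", next(s for s in table1_ath if s.id == "ptrmir156"))
        cands = predict_mirnas([ath], [est])
        pt_mature = next(s for s in table1_mirnas if s.id == "ptrmir156")
        assert any(
            c.mature == pt_mature.residues == "UGACAGAAGAGAGUGAGCAC"
            and c.substitutions == 0
            for c in cands
        )

    def test_candidates_respect_filter_bounds(self):
        known = MatureMiRNA("k", random_mature(21, seed=60))
        prec, _ = make_precursor(mutate_nonseed(known.sequence, 3, seed=60), 0, seed=60)
        ests, _ = make_est([prec], n_decoys=2, est_len=300, seed=61)
        for c in predict_mirnas([known], ests):
            assert c.substitutions <= 3
            assert rna(NucSequence("x", c.mature, "RNA")).residues[1:8] == known.seed
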