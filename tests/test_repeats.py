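"""Repeat-scanner unit and property tests.

The inverted-repeat scanner is checked against an independent exhaustive
oracle that enumerates every (start, arm, spacer) triple and applies the
maximality rules by direct string comparison.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_seq
from okamut._seq import pairs, revcomp
from okamut.events import Event
from okamut.repeats import (
    decompose_direct_repeat,
    find_inverted_repeats,
    find_quasi_palindromes,
    find_tandem_repeats,
)


def ir_oracle(seq: str, min_arm: int, max_spacer: int) -> set:
    """Brute force over all (left_start, arm, spacer) triples; keeps the
    perfect IRs that can be extended neither outward nor inward."""
    n = len(seq)
    res = set()
    for ls in range(n):
        for arm in range(min_arm, n - ls + 1):
            le = ls + arm - 1
            for sp in range(0, max_spacer + 1):
                rs, re = le + sp + 1, le + sp + arm
                if re >= n:
                    break
                left, right = seq[ls : le + 1], seq[rs : re + 1]
                if "N" in left or "N" in right or left != revcomp(right):
                    continue
                if ls > 0 and re + 1 < n and pairs(seq[ls - 1], seq[re + 1]):
                    continue
                if sp >= 2 and pairs(seq[le + 1], seq[rs - 1]):
                    continue
                res.add((ls + 1, le + 1, rs + 1, re + 1, arm, sp))
    return res


def as_tuples(irs):
    return {
        (r.left_start, r.left_end, r.right_start, r.right_end, r.arm_len, r.spacer_len)
        for r in irs
    }


class TestInvertedRepeats:
    def test_restriction_site_palindrome(self):
        (ir,) = find_inverted_repeats("GAATTC", min_arm=3, max_spacer=0)
        assert (ir.arm_len, ir.spacer_len, ir.arm_edits) == (3, 0, 0)
        assert ir.left_arm == (1, 3) and ir.right_arm == (4, 6)

    def test_homopolymer_has_no_inverted_repeat(self):
        assert find_inverted_repeats("AAAAAAAA", min_arm=3, max_spacer=5) == []

    def test_perfect_form_of_worked_quasi_palindrome(self):
        # spacer bases instantiated as GGGG
        (ir,) = find_inverted_repeats("AGAACAGGGGTGTTCT", min_arm=5, max_spacer=10)
        assert ir.arm_len == 6 and ir.spacer_len == 4
        assert "AGAACAGGGGTGTTCT"[ir.left_start - 1 : ir.left_end] == "AGAACA"

    def test_empty_sequence(self):
        assert find_inverted_repeats("", min_arm=5, max_spacer=10) == []

    @pytest.mark.parametrize("seed,max_spacer", [(0, 5), (1, 10), (2, 20), (3, 70)])
    def test_matches_exhaustive_oracle_random(self, seed, max_spacer):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            s = random_seq(rng, int(rng.integers(8, 120)))
            assert as_tuples(find_inverted_repeats(s, 3, max_spacer)) == ir_oracle(
                s, 3, max_spacer
            )

    @pytest.mark.parametrize(
        "seq",
        [
            "ATATATATATAT",          # palindrome-dense
            "GCGCGCGCGC",
            "GAATTCNNNGAATTC",       # N breaks arms
            "ACGT" * 10,
            "TTTTAAAA",              # long complementary run
        ],
    )
    def test_matches_exhaustive_oracle_adversarial(self, seq):
        assert as_tuples(find_inverted_repeats(seq, 2, 8)) == ir_oracle(seq, 2, 8)

    def test_arms_never_contain_n(self):
        rng = np.random.default_rng(5)
        s = list(random_seq(rng, 100))
        for i in rng.integers(0, 100, 12):
            s[i] = "N"
        s = "".join(s)
        for r in find_inverted_repeats(s, 3, 10):
            assert "N" not in s[r.left_start - 1 : r.left_end]
            assert "N" not in s[r.right_start - 1 : r.right_end]

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_revcomp_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        s = random_seq(rng, int(rng.integers(10, 80)))
        n = len(s)
        fwd = as_tuples(find_inverted_repeats(s, 3, 10))
        rev = find_inverted_repeats(revcomp(s), 3, 10)
        mirrored = {
            (n - r.right_end + 1, n - r.right_start + 1,
             n - r.left_end + 1, n - r.left_start + 1, r.arm_len, r.spacer_len)
            for r in rev
        }
        assert fwd == mirrored

    def test_sorted_by_start_then_arm_desc(self):
        rng = np.random.default_rng(9)
        s = random_seq(rng, 300)
        irs = find_inverted_repeats(s, 3, 20)
        key = [(r.left_start, -r.arm_len) for r in irs]
        assert key == sorted(key)


class TestQuasiPalindromes:
    def test_worked_single_mismatch(self):
        (q,) = find_quasi_palindromes(
            "AGAACAGGGGTCTTCT", min_arm=5, max_spacer=10, max_arm_edits=1
        )
        assert (q.arm_len, q.spacer_len, q.arm_edits) == (6, 4, 1)

    def test_perfect_palindrome_excluded(self):
        # a bare perfect palindrome yields no quasi report at all
        assert find_quasi_palindromes("GAATTC", 3, 5, max_arm_edits=3) == []
        # the canonical perfect IR is never re-reported with zero edits
        for q in find_quasi_palindromes("AGAACAGGGGTGTTCT", 5, 10, max_arm_edits=3):
            assert q.arm_edits >= 1
            assert (q.left_arm, q.right_arm) != ((1, 6), (11, 16))

    def test_mismatch_plus_two_base_deletion_counts_three_edits(self):
        # left arm 12 nt; right arm carries one mismatch and lacks two bases
        left = "AGGATCCATGCA"
        right = list(revcomp(left))
        right[3] = "A" if right[3] != "A" else "C"  # one mismatch
        del right[6:8]                              # two-base deletion
        seq = left + "GGGG" + "".join(right)
        qs = find_quasi_palindromes(seq, min_arm=5, max_spacer=10, max_arm_edits=3)
        assert any(q.arm_edits == 3 and q.arm_len == 12 for q in qs)

    def test_requires_positive_edit_budget(self):
        with pytest.raises(ValueError):
            find_quasi_palindromes("ACGT", 3, 5, max_arm_edits=0)


class TestTandemRepeats:
    def test_homopolymer(self):
        (t,) = find_tandem_repeats("A" * 12)
        assert (t.period, t.copy_number, t.purity) == (1, 12.0, 1.0)

    def test_dinucleotide(self):
        (t,) = find_tandem_repeats("ACACACAC")
        assert (t.period, t.copy_number) == (2, 4.0)

    def test_impure_trinucleotide_detected_at_relaxed_purity(self):
        hits = find_tandem_repeats("ACGACGACTACG", min_purity=0.8)
        t = next(h for h in hits if h.period == 3)
        assert t.purity < 1.0
        # exhaustive check of the reported purity at the reported span
        s = "ACGACGACTACG"[t.start - 1 : t.end]
        matches = sum(1 for i in range(len(s) - 3) if s[i] == s[i + 3])
        assert t.purity == pytest.approx(matches / (len(s) - 3))

    def test_planted_arrays_recovered(self):
        rng = np.random.default_rng(3)
        for period in (1, 2, 3, 4, 6):
            unit = random_seq(rng, period)
            while any(unit == unit[p:] + unit[:p] for p in range(1, period)):
                unit = random_seq(rng, period)
            copies = int(rng.integers(4, 9))
            left, right = random_seq(rng, 20), random_seq(rng, 20)
            while left[-1] == unit[-1]:
                left = random_seq(rng, 20)
            while right[0] == unit[0]:
                right = random_seq(rng, 20)
            hits = find_tandem_repeats(left + unit * copies + right,
                                       max_period=6, min_purity=0.95)
            spans = [(t.period, round(t.copy_number)) for t in hits
                     if t.start == 21 and t.end == 20 + period * copies]
            assert (period, copies) in spans


class TestDirectRepeatDecomposition:
    @staticmethod
    def make_insertion(left, unit, right, pos=1000):
        return Event("chr", pos, "", unit, frozenset({"s"}), "insertion",
                     flank_left=left, flank_right=right)

    def test_eight_plus_eight_duplication_geometry(self):
        # ABA -> ABABA with len_A = len_B = 8; verified against brute
        # force over all (A, B) splits below
        A, B = "ACGTAGCA", "TTGGCCAA"
        rng = np.random.default_rng(4)
        ev = self.make_insertion(random_seq(rng, 40) + A + B + A, B + A,
                                 random_seq(rng, 40))
        dec = decompose_direct_repeat(ev)
        assert dec is not None
        assert (dec.len_A, dec.len_B, dec.similarity) == (8, 8, 1.0)
        # brute force: the best split must reconstruct ABABA exactly
        ctx = ev.flank_left
        best = []
        for a in range(1, 16):
            for phase in ("suffix", "prefix"):
                U = ev.alt_allele
                As = U[-a:] if phase == "suffix" else U[:a]
                if phase == "suffix" and ctx.endswith(U) and ctx[: -len(U)].endswith(As):
                    best.append(a)
        assert dec.len_A == max(best)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            la, lb = int(rng.integers(2, 12)), int(rng.integers(2, 20))
            A, B = random_seq(rng, la), random_seq(rng, lb)
            left = random_seq(rng, 50) + A + B + A
            ev = self.make_insertion(left, B + A, random_seq(rng, 50))
            dec = decompose_direct_repeat(ev)
            if dec is None:
                continue  # ambiguous context; similarity guard rejected
            assert dec.len_A + dec.len_B == len(ev.alt_allele)
            # splicing one more (A,B) unit into ABA yields the ABABA form
            aba = dec.A + dec.B + dec.A
            ababa = dec.A + dec.B + dec.A + dec.B + dec.A
            assert left.endswith(aba) or dec.similarity < 1.0
            if dec.similarity == 1.0:
                assert (left + ev.alt_allele).endswith(ababa)

    def test_two_base_insertion_with_empty_b_is_rejected(self):
        ev = self.make_insertion("CCTTGGTTAG", "AG", "CTCTCCGGTT")
        assert decompose_direct_repeat(ev) is None

    def test_random_insertion_has_no_decomposition(self):
        rng = np.random.default_rng(12)
        ev = self.make_insertion(random_seq(rng, 60), random_seq(rng, 20),
                                 random_seq(rng, 60))
        assert decompose_direct_repeat(ev) is None

    def test_paper_scale_lengths_are_representable(self):
        # B up to 91 nt and A up to 21 nt must decompose cleanly
        rng = np.random.default_rng(21)
        A, B = random_seq(rng, 21), random_seq(rng, 91)
        left, right = random_seq(rng, 30), random_seq(rng, 30)
        while left[-1] == B[-1]:  # forbid chance rotation of the A boundary
            left = random_seq(rng, 30)
        while right[0] == B[0]:
            right = random_seq(rng, 30)
        ev = self.make_insertion(left + A + B + A, B + A, right)
        dec = decompose_direct_repeat(ev)
        assert dec is not None and (dec.len_A, dec.len_B) == (21, 91)

    def test_deletion_direction(self):
        rng = np.random.default_rng(5)
        A, B = "GATTACAT", "CCGGAATT"
        left = random_seq(rng, 40) + A
        ev = Event("chr", 1000, B + A, "", frozenset({"s"}), "deletion",
                   flank_left=left, flank_right=B + A + random_seq(rng, 40))
        dec = decompose_direct_repeat(ev)
        assert dec is not None and dec.similarity == 1.0
        assert dec.len_A + dec.len_B == len(B + A)

    def test_non_indel_raises(self):
        ev = Event("chr", 10, "A", "G", frozenset({"s"}), "snp",
                   flank_left="ACGT", flank_right="ACGT")
        with pytest.raises(ValueError):
            decompose_direct_repeat(ev)
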