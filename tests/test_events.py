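"""Event extraction, filtering, grouping and rate tests."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import random_seq
from okamut.errors import ConfigurationError, MalformedAlignmentError
from okamut.events import (
    Event,
    StrainSet,
    apply_event,
    apply_events,
    events_to_dataframe,
    extract_events_from_msa,
    filter_events,
    group_recurrent_loci,
    ingest_event_table,
    left_align_indel,
    mutation_rate,
)

FOCAL = StrainSet("L1", 25, ("s1", "s2", "s3"))
CTRL = StrainSet("L1", 5, ("c1",))


def msa_of(**rows):
    return dict(rows)


class TestExtraction:
    def test_three_column_gap_is_one_deletion(self):
        msa = msa_of(
            reference="ACGTACGTTTGGAACC",
            s1="ACGTA---TTGGAACC",
            s2="ACGTACGTTTGGAACC",
            s3="ACGTACGTTTGGAACC",
        )
        evs = extract_events_from_msa(msa, "reference", FOCAL, chrom="chrI")
        assert len(evs) == 1
        ev = evs[0]
        assert ev.event_type == "deletion"
        assert len(ev.ref_allele) == 3 and ev.alt_allele == ""
        assert ev.strains_with_alt == {"s1"}
        # applying the deletion reproduces the strain sequence
        assert apply_event(msa["reference"], ev) == msa["s1"].replace("-", "")

    def test_change_shared_by_all_focal_strains_is_dropped(self):
        msa = msa_of(
            reference="ACGTACGTACGT",
            s1="ACGTACATACGT",
            s2="ACGTACATACGT",
            s3="ACGTACATACGT",
        )
        assert extract_events_from_msa(msa, "reference", FOCAL) == []

    def test_two_substitutions_within_window_merge_to_cluster(self):
        ref = "ACGTACGTACGTACGTACGT"
        alt = "ACCTACGTACGAACGTACGT"  # positions 3 and 12
        msa = msa_of(reference=ref, s1=alt, s2=ref, s3=ref)
        evs = extract_events_from_msa(msa, "reference", FOCAL, cluster_window=25)
        assert len(evs) == 1 and evs[0].event_type == "snp_cluster"
        assert evs[0].pos == 3 and len(evs[0].ref_allele) == 10

    def test_distant_substitutions_stay_separate_snps(self):
        ref = "A" * 3 + "C" + "G" * 40 + "T" + "A" * 3
        alt = "A" * 3 + "T" + "G" * 40 + "G" + "A" * 3
        msa = msa_of(reference=ref, s1=alt, s2=ref, s3=ref)
        evs = extract_events_from_msa(msa, "reference", FOCAL, cluster_window=25)
        assert [e.event_type for e in evs] == ["snp", "snp"]

    def test_event_shared_with_control_is_dropped(self):
        ref = "ACGTACGTACGT"
        alt = "ACGTAGGTACGT"
        msa = msa_of(reference=ref, s1=alt, s2=ref, s3=ref, c1=alt)
        assert extract_events_from_msa(msa, "reference", FOCAL, CTRL) == []
        # without the control row the event is reported
        msa2 = msa_of(reference=ref, s1=alt, s2=ref, s3=ref, c1=ref)
        assert len(extract_events_from_msa(msa2, "reference", FOCAL, CTRL)) == 1

    def test_insertion_is_left_aligned(self):
        # an extra T inside a T run must shift to the run start
        aref = "ACGTTTT-GCA"
        s1 = "ACGTTTTTGCA"
        msa = msa_of(reference=aref, s1=s1, s2=aref, s3=aref)
        (ev,) = extract_events_from_msa(msa, "reference", FOCAL)
        assert ev.event_type == "insertion" and ev.pos == 4 and ev.alt_allele == "T"

    def test_unequal_rows_raise(self):
        with pytest.raises(MalformedAlignmentError):
            extract_events_from_msa(
                msa_of(reference="ACGT", s1="ACG", s2="ACGT", s3="ACGT"),
                "reference", FOCAL)

    def test_missing_reference_raises(self):
        with pytest.raises(ConfigurationError):
            extract_events_from_msa(msa_of(s1="ACGT", s2="ACGT", s3="ACGT"),
                                    "reference", FOCAL)

    def test_round_trip_apply_and_reextract(self):
        """Applying extracted alts to the reference and re-aligning
        recovers an equivalent left-aligned event set."""
        rng = np.random.default_rng(42)
        ref = random_seq(rng, 400)
        # plant one deletion, one insertion, one SNP in s1
        s1 = ref[:50] + ref[55:]                      # 5 bp deletion at 51
        s1 = s1[:150] + "ACGTA" + s1[150:]            # 5 bp insertion
        s1 = s1[:300] + ("A" if s1[300] != "A" else "C") + s1[301:]
        # the pairwise alignment implied by the edits: gap columns at the
        # insertion (ref side) and at the deletion (strain side)
        aref = ref[:155] + "-----" + ref[155:]
        as1 = s1[:50] + "-----" + s1[50:]
        msa = msa_of(reference=aref, s1=as1, s2=aref.replace("-", "") + "-" * 5,
                     s3=aref.replace("-", "") + "-" * 5)
        evs = extract_events_from_msa(msa, "reference", FOCAL)
        assert apply_events(ref, evs) == s1
        assert {e.event_type for e in evs} == {"deletion", "insertion", "snp"}


class TestLeftAlign:
    def test_shift_through_repeat_unit(self):
        ref = "GGCACACACATT"
        # deleting the last CA is equivalent to deleting the first
        pos, ra, aa = left_align_indel(ref, 9, "CA", "")
        assert (pos, ra, aa) == (3, "CA", "")

    def test_non_indel_untouched(self):
        assert left_align_indel("ACGT", 2, "C", "G") == (2, "C", "G")


class TestFiltering:
    @staticmethod
    def ev(chrom="chr1", pos=100_000, ra="A", aa="T", support=None):
        return Event(chrom, pos, ra, aa, frozenset({"s1"}), "snp",
                     support=support)

    def test_telomeric_event_removed(self):
        ref = {"chr1": "A" * 500_000}
        assert filter_events([self.ev(pos=1_000)], ref=ref) == []
        assert len(filter_events([self.ev(pos=250_000)], ref=ref)) == 1
        assert filter_events([self.ev(pos=499_000)], ref=ref) == []

    def test_event_over_n_removed(self):
        seq = "A" * 50_000 + "N" + "A" * 50_000
        ref = {"chr1": seq}
        assert filter_events([self.ev(pos=50_001)], ref=ref,
                             exclude_telomeric_bp=1000) == []

    def test_mask_interval_bed_semantics(self):
        masks = [("chr1", 99_999, 100_001)]  # 0-based half-open covers pos 100000
        kept = filter_events([self.ev()], mask_intervals=masks)
        assert kept == []
        masks2 = [("chr1", 100_000, 100_002)]  # starts after the event base
        assert len(filter_events([self.ev()], mask_intervals=masks2)) == 1

    def test_support_threshold(self):
        assert len(filter_events([self.ev(support={"s1": 0.95})])) == 1
        assert filter_events([self.ev(support={"s1": 0.85})]) == []
        # no support attached -> filter not enforced
        assert len(filter_events([self.ev()])) == 1

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(0)
        ref = {"chr1": random_seq(rng, 300_000)}
        events = [self.ev(pos=int(p)) for p in
                  rng.integers(1, 300_000, size=60)]
        once = filter_events(events, ref=ref)
        twice = filter_events(once, ref=ref)
        assert once == twice
        positions = [e.pos for e in once]
        assert positions == [e.pos for e in events if e in once]


class TestGrouping:
    @staticmethod
    def ev(pos, aa="T", strains=("s1",), ra="A", etype="snp", chrom="chr1"):
        return Event(chrom, pos, ra, aa, frozenset(strains), etype)

    def test_same_locus_two_strains_recurrent(self):
        g, = group_recurrent_loci([self.ev(500, strains=("s1", "s2"))])
        assert g.recurrent

    def test_insertion_and_deletion_at_one_locus_recurrent(self):
        ins = Event("chr1", 500, "", "ACGTACGTACGTACGT", frozenset({"s1"}), "insertion")
        dele = Event("chr1", 500, "ACGTACGTACGTACGT", "", frozenset({"s2"}), "deletion")
        (g,) = group_recurrent_loci([ins, dele])
        assert g.recurrent and len(g.events) == 2

    def test_distant_loci_not_recurrent(self):
        groups = group_recurrent_loci([self.ev(1_000), self.ev(11_000)])
        assert len(groups) == 2 and not any(g.recurrent for g in groups)

    def test_partition(self):
        rng = np.random.default_rng(7)
        events = [self.ev(int(p), chrom=f"chr{int(c)}")
                  for p, c in zip(rng.integers(1, 50_000, 80), rng.integers(1, 4, 80))]
        groups = group_recurrent_loci(events)
        members = [id(e) for g in groups for e in g.events]
        assert sorted(members) == sorted(id(e) for e in events)
        assert len(members) == len(events)


class TestRates:
    def test_zero_events(self):
        assert mutation_rate(0, 10, 25, 1_000_000).rate == 0.0

    def test_cohort_arithmetic(self):
        # 455 events over 10 colonies x 25 generations x genome size
        r = mutation_rate(455, 10, 25, 12_071_326)
        assert r.rate == pytest.approx(455 / (10 * 25 * 12_071_326))
        assert r.rate == pytest.approx(1.5075e-07, rel=1e-3)

    def test_linearity(self):
        a = mutation_rate(40, 10, 25, 10_000).rate
        b = mutation_rate(80, 10, 25, 10_000).rate
        assert b == pytest.approx(2 * a)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            mutation_rate(5, 0, 25, 1_000)

    def test_additive_over_disjoint_classes(self):
        total = mutation_rate(30, 10, 25, 1_000).rate
        parts = (mutation_rate(10, 10, 25, 1_000).rate
                 + mutation_rate(20, 10, 25, 1_000).rate)
        assert total == pytest.approx(parts)


class TestIngest:
    def test_supplementary_style_table_tallies(self, tmp_path):
        # synthetic export shaped like a supplementary event list
        df = events_to_dataframe([
            Event("chrI", 100, "", "AT", frozenset({"a", "b"}), "insertion"),
            Event("chrI", 100, "AT", "", frozenset({"c"}), "deletion"),
            Event("chrII", 900, "G", "T", frozenset({"a"}), "snp"),
        ])
        df["class"] = ["ssr", "ssr", "other"]
        path = tmp_path / "events.tsv"
        df.to_csv(path, sep="\t", index=False)
        _, tallies = ingest_event_table(path, column_map={"mech_class": "class"})
        assert tallies["n_loci"] == 2          # two distinct (chrom, pos) loci
        assert tallies["n_occurrences"] == 4   # strain-by-locus occurrences
        assert tallies["per_class"] == {"ssr": 2, "other": 1}
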