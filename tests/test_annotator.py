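"""Nearest-downstream-gene and TSS queries, component classification,
and the profiling summaries."""

import pytest

from conftest import random_transcripts
from oracles import brute_ndg, brute_tss

from peaktools.core import GenomicInterval, PeaktoolsError, Transcript
from peaktools.annotator import (
    ComponentClass,
    classify_overlap,
    nearest_downstream_genes,
    nearest_tss,
    profile_components,
    profile_distances,
    component_category,
)
from peaktools.nclist import ContainmentIndex


def tx(tid, chrom, strand, start, end, exons=None, cds=None, gid=None):
    exons = exons or ((start, end),)
    cds_start, cds_end = cds if cds else (None, None)
    return Transcript(gid or tid, tid, chrom, strand, start, end,
                      tuple(exons), cds_start, cds_end)


def peak(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end, name="pk")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassifyOverlap:
    # + transcript: exons [0,100) and [200,300), CDS [50,250)
    T_PLUS = tx("t+", "chr1", "+", 0, 300, exons=((0, 100), (200, 300)), cds=(50, 250))
    T_MINUS = tx("t-", "chr1", "-", 0, 300, exons=((0, 100), (200, 300)), cds=(50, 250))

    def test_five_prime_utr_forward(self):
        # center of [10, 31) is 20, in exon 1 before the CDS
        assert classify_overlap(peak(10, 31), self.T_PLUS).kind == "five_prime_utr"

    def test_first_intron(self):
        c = classify_overlap(peak(140, 161), self.T_PLUS)  # center 150
        assert (c.kind, c.intron_rank) == ("intron", 1)

    def test_utr_polarity_flips_with_strand(self):
        # center 270 is in exon 2 after the CDS: 3' UTR on +, 5' UTR on -
        assert classify_overlap(peak(260, 281), self.T_PLUS).kind == "three_prime_utr"
        assert classify_overlap(peak(260, 281), self.T_MINUS).kind == "five_prime_utr"

    def test_intron_rank_counts_in_transcription_order(self):
        t_minus = tx("t", "chr1", "-", 0, 500,
                     exons=((0, 100), (200, 300), (400, 500)))
        # genomic intron 1 ([100,200)) is the LAST intron in transcription
        # order on the minus strand
        c = classify_overlap(peak(140, 161), t_minus)
        assert (c.intron_rank, c.n_introns) == (2, 2)
        c = classify_overlap(peak(340, 361), t_minus)
        assert c.intron_rank == 1

    def test_cds_exon(self):
        assert classify_overlap(peak(60, 81), self.T_PLUS).kind == "exon_cds"

    def test_no_cds_means_exon(self):
        t = tx("t", "chr1", "+", 0, 300, exons=((0, 100), (200, 300)))
        assert classify_overlap(peak(10, 31), t).kind == "exon_cds"

    def test_upstream_downstream_relative_to_strand(self):
        t = tx("t", "chr1", "+", 100, 200)
        assert classify_overlap(peak(0, 21), t).kind == "upstream"
        assert classify_overlap(peak(250, 271), t).kind == "downstream"
        t_rev = tx("t", "chr1", "-", 100, 200)
        assert classify_overlap(peak(0, 21), t_rev).kind == "downstream"
        assert classify_overlap(peak(250, 271), t_rev).kind == "upstream"

    def test_chromosome_mismatch_is_usage_error(self):
        with pytest.raises(PeaktoolsError):
            classify_overlap(peak(0, 10, chrom="chr2"), self.T_PLUS)

    def test_total_over_all_centers(self):
        """Every center position gets exactly one class per transcript."""
        t = self.T_PLUS
        for pos in range(0, 400):
            c = classify_overlap(GenomicInterval("chr1", pos, pos + 1), t)
            assert isinstance(c, ComponentClass)


# ---------------------------------------------------------------------------
# NDG
# ---------------------------------------------------------------------------

class TestNearestDownstreamGenes:
    def test_both_strands_with_distances(self):
        transcripts = [
            tx("fwd", "chr1", "+", 300, 400),
            tx("rev", "chr1", "-", 10, 60),
        ]
        index = ContainmentIndex.build(transcripts)
        r = nearest_downstream_genes(peak(100, 200), index)
        assert r.nearest_forward[0].transcript_id == "fwd"
        assert r.nearest_forward[1] == 100
        assert r.nearest_reverse[0].transcript_id == "rev"
        assert r.nearest_reverse[1] == 40

    def test_overlapping_transcript_excluded_from_nearest_slots(self):
        transcripts = [tx("host", "chr1", "+", 50, 250)]
        index = ContainmentIndex.build(transcripts)
        r = nearest_downstream_genes(peak(100, 200), index)
        assert [t.transcript_id for t, _ in r.overlapping] == ["host"]
        assert r.nearest_forward is None and r.nearest_reverse is None

    def test_reverse_candidate_found_via_containment_chain(self):
        # a - transcript [0,500) containing a + transcript [100,150);
        # peak at [600,700): the - gene is the reverse downstream candidate
        transcripts = [
            tx("outer-", "chr1", "-", 0, 500),
            tx("inner+", "chr1", "+", 100, 150),
        ]
        index = ContainmentIndex.build(transcripts)
        r = nearest_downstream_genes(peak(600, 700), index)
        assert r.nearest_reverse[0].transcript_id == "outer-"
        assert r.nearest_reverse[1] == 100

    def test_forward_candidate_nested_in_overlapping_container(self):
        # + gene nested inside a - gene that spans the peak: the nested
        # gene is the true nearest forward gene
        transcripts = [
            tx("span-", "chr1", "-", 0, 1000),
            tx("nested+", "chr1", "+", 300, 400),
            tx("far+", "chr1", "+", 2000, 2100),
        ]
        index = ContainmentIndex.build(transcripts)
        r = nearest_downstream_genes(peak(100, 200), index)
        assert r.nearest_forward[0].transcript_id == "nested+"
        assert r.nearest_forward[1] == 100

    def test_empty_chromosome_gives_none_slots(self):
        index = ContainmentIndex.build([])
        r = nearest_downstream_genes(peak(0, 10), index)
        assert r.nearest_forward is None and r.nearest_reverse is None
        assert r.overlapping == ()

    def test_bidirectional_promoter_flag(self):
        transcripts = [
            tx("fwd", "chr1", "+", 250, 400),
            tx("rev", "chr1", "-", 10, 60),
        ]
        index = ContainmentIndex.build(transcripts)
        near = nearest_downstream_genes(peak(100, 200), index, bidir_window=1000)
        assert near.bidirectional_promoter
        tight = nearest_downstream_genes(peak(100, 200), index, bidir_window=30)
        assert not tight.bidirectional_promoter

    def test_strand_reflection_swaps_forward_and_reverse(self, rng):
        """Mirroring coordinates and flipping strands swaps the two slots."""
        L = 300_000
        transcripts = random_transcripts(rng, 80, chroms=("chr1",), span=L - 50_000)
        mirrored = [
            Transcript(t.gene_id, t.transcript_id, t.chrom,
                       "-" if t.strand == "+" else "+",
                       L - t.tx_end, L - t.tx_start,
                       tuple(sorted((L - e, L - s) for s, e in t.exons)))
            for t in transcripts
        ]
        index = ContainmentIndex.build(transcripts)
        index_m = ContainmentIndex.build(mirrored)
        for _ in range(50):
            s = int(rng.integers(0, L - 600))
            p = GenomicInterval("chr1", s, s + int(rng.integers(1, 500)))
            p_m = GenomicInterval("chr1", L - p.end, L - p.start)
            r = nearest_downstream_genes(p, index)
            r_m = nearest_downstream_genes(p_m, index_m)
            fwd = (r.nearest_forward[0].transcript_id, r.nearest_forward[1]) \
                if r.nearest_forward else None
            rev_m = (r_m.nearest_reverse[0].transcript_id, r_m.nearest_reverse[1]) \
                if r_m.nearest_reverse else None
            assert fwd == rev_m

    def test_matches_linear_scan_oracle(self, rng):
        for trial in range(30):
            transcripts = random_transcripts(
                rng, int(rng.integers(1, 120)), chroms=("chr1", "chr2")
            )
            index = ContainmentIndex.build(transcripts)
            for _ in range(20):
                chrom = ("chr1", "chr2")[int(rng.integers(0, 2))]
                s = int(rng.integers(0, 220_000))
                p = GenomicInterval(chrom, s, s + int(rng.integers(1, 2000)))
                r = nearest_downstream_genes(p, index)
                exp_fwd, exp_rev, exp_over = brute_ndg(p, transcripts)
                got_fwd = (r.nearest_forward[0].transcript_id, r.nearest_forward[1]) \
                    if r.nearest_forward else None
                got_rev = (r.nearest_reverse[0].transcript_id, r.nearest_reverse[1]) \
                    if r.nearest_reverse else None
                assert got_fwd == (
                    (exp_fwd[0].transcript_id, exp_fwd[1]) if exp_fwd else None
                )
                assert got_rev == (
                    (exp_rev[0].transcript_id, exp_rev[1]) if exp_rev else None
                )
                assert {t.transcript_id for t, _ in r.overlapping} == {
                    t.transcript_id for t in exp_over
                }


# ---------------------------------------------------------------------------
# TSS
# ---------------------------------------------------------------------------

class TestNearestTss:
    def test_center_tss_coincidence(self):
        index = ContainmentIndex.build([tx("t", "chr1", "+", 99, 200)])
        r = nearest_tss(peak(90, 110), index)  # center 99
        assert r.signed_distance == 0 and r.within_gene

    def test_two_candidate_signed_distance(self):
        transcripts = [
            tx("near", "chr1", "+", 0, 1000),
            tx("far", "chr1", "+", 500, 1500),
        ]
        index = ContainmentIndex.build(transcripts)
        r = nearest_tss(peak(195, 206), index)  # center 200
        assert r.transcript.transcript_id == "near"
        assert r.signed_distance == 200  # downstream of the TSS

    def test_upstream_is_negative(self):
        index = ContainmentIndex.build([tx("t", "chr1", "+", 500, 1000)])
        r = nearest_tss(peak(195, 206), index)
        assert r.signed_distance == -300

    def test_reverse_strand_sign(self):
        # - transcript [0,100): TSS at 99; center 199 is upstream (gene
        # transcribes leftward)
        index = ContainmentIndex.build([tx("t", "chr1", "-", 0, 100)])
        r = nearest_tss(peak(195, 204), index)
        assert r.signed_distance == -100

    def test_no_transcripts_gives_none(self):
        index = ContainmentIndex.build([tx("t", "chr2", "+", 0, 10)])
        r = nearest_tss(peak(0, 10), index)
        assert r.transcript is None and r.signed_distance is None

    def test_tie_broken_by_transcript_id_and_reported(self):
        transcripts = [
            tx("b", "chr1", "+", 300, 400),
            tx("a", "chr1", "-", 0, 101),  # TSS 100; center 200: both dist 100
        ]
        index = ContainmentIndex.build(transcripts)
        r = nearest_tss(peak(195, 206), index)
        assert r.transcript.transcript_id == "a"
        assert r.ties == ("a", "b")

    def test_matches_exhaustive_scan_oracle(self, rng):
        for trial in range(20):
            transcripts = random_transcripts(
                rng, int(rng.integers(1, 150)), chroms=("chr1", "chr2")
            )
            index = ContainmentIndex.build(transcripts)
            for _ in range(25):
                chrom = ("chr1", "chr2")[int(rng.integers(0, 2))]
                s = int(rng.integers(0, 220_000))
                p = GenomicInterval(chrom, s, s + int(rng.integers(1, 2000)))
                r = nearest_tss(p, index)
                exp_t, exp_signed, exp_ties = brute_tss(p, transcripts)
                if exp_t is None:
                    assert r.transcript is None
                else:
                    assert r.transcript.transcript_id == exp_t.transcript_id
                    assert r.signed_distance == exp_signed
                    assert r.ties == exp_ties


# ---------------------------------------------------------------------------
# profiling
# ---------------------------------------------------------------------------

class TestProfileDistances:
    def test_empty_input_all_zero(self):
        table = profile_distances([])
        assert table["count"].sum() == 0
        assert (table["percentage"] == 0).all()

    def test_all_zero_distances_in_innermost_bin(self):
        table = profile_distances([0] * 10)
        row = table.set_index("bin").loc["downstream 0-1 kb"]
        assert row["count"] == 10 and row["percentage"] == 100.0

    def test_unsorted_edges_rejected(self):
        with pytest.raises(PeaktoolsError):
            profile_distances([0], edges=(0, 5000, 1000))

    def test_uniform_distances_match_analytic_proportions(self, rng):
        # uniform on [-20k, 20k]: mass 1/40 per kb
        d = rng.integers(-20_000, 20_001, size=40_000)
        table = profile_distances(list(d)).set_index("bin")
        expected = {
            "downstream 0-1 kb": 1 / 40,
            "downstream 1-10 kb": 9 / 40,
            "downstream >10 kb": 10 / 40,
            "upstream 0-1 kb": 1 / 40,
            "upstream 1-10 kb": 9 / 40,
            "upstream >10 kb": 10 / 40,
        }
        for bin_label, frac in expected.items():
            got = table.loc[bin_label, "percentage"] / 100
            assert abs(got - frac) < 0.01  # ~multinomial error at n=40k

    def test_percentages_sum_to_100(self, rng):
        d = rng.integers(-30_000, 30_000, size=500)
        table = profile_distances(list(d))
        assert table["percentage"].sum() == pytest.approx(100.0)


class TestProfileComponents:
    def test_empty(self):
        table = profile_components([])
        assert table["count"].sum() == 0

    def test_all_first_intron(self):
        classes = [ComponentClass("intron", 1, 3)] * 10
        table = profile_components(classes).set_index("component")
        assert table.loc["first intron", "percentage"] == 100.0

    def test_crafted_mixture_exact_percentages(self):
        classes = (
            [ComponentClass("five_prime_utr")] * 2
            + [ComponentClass("exon_cds")] * 3
            + [ComponentClass("intron", 1, 4)] * 2
            + [ComponentClass("intron", 2, 4)] * 1
            + [ComponentClass("intron", 4, 4)] * 1
            + [ComponentClass("three_prime_utr")] * 1
        )
        table = profile_components(classes).set_index("component")
        assert table["count"].sum() == 10
        assert table.loc["5' UTR", "percentage"] == 20.0
        assert table.loc["exon (CDS)", "percentage"] == 30.0
        assert table.loc["first intron", "count"] == 2
        assert table.loc["higher rank-order introns", "count"] == 1
        assert table.loc["last intron", "count"] == 1

    def test_single_intron_counts_as_first(self):
        assert component_category(ComponentClass("intron", 1, 1)) == "first intron"
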