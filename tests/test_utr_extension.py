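"""Coverage pooling, junction filters, extension and classification."""

import pytest

from mirpollen.annotation_io import AlignedRead, GenomicInterval, SpliceJunction
from mirpollen.utr_extension import (
    CoverageTrack,
    classify_extension,
    extend_transcripts,
    pool_coverage,
    reconstruct_fragments,
    select_junctions,
)


def read(chrom, strand, *blocks, rid="r", seq=None):
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks)
    n = sum(e - s for s, e in blocks)
    return AlignedRead(rid, seq or "A" * n, chrom, strand, ivs)


class TestPoolCoverage:
    def test_depth_counts_overlapping_blocks(self):
        track, junctions = pool_coverage(
            [read("chr1", "+", (10, 20)), read("chr1", "+", (10, 20))]
        )
        assert all(track.depth("chr1", "+", p) == 2 for p in range(10, 20))
        assert track.depth("chr1", "+", 20) == 0
        assert junctions == []

    def test_spliced_read_yields_junction(self):
        track, junctions = pool_coverage([read("chr1", "+", (10, 20), (120, 130))])
        assert len(junctions) == 1
        j = junctions[0]
        assert (j.intron.start, j.intron.end, j.coverage) == (20, 120, 1)

    def test_junction_coverage_counts_supporting_reads(self):
        reads = [read("chr1", "+", (10, 20), (120, 130), rid=f"r{i}") for i in range(3)]
        _, junctions = pool_coverage(reads)
        assert junctions[0].coverage == 3

    def test_strand_separation(self):
        track, _ = pool_coverage(
            [read("chr1", "+", (10, 20)), read("chr1", "-", (10, 20))]
        )
        assert track.depth("chr1", "+", 15) == 1
        assert track.depth("chr1", "-", 15) == 1

    def test_empty_input_is_not_an_error(self):
        track, junctions = pool_coverage([])
        assert list(track.keys()) == [] and junctions == []


def junction(s, e, cov, chrom="chr1", strand="+"):
    return SpliceJunction(chrom, GenomicInterval(chrom, s, e, strand), strand, cov)


class TestJunctionFilters:
    def test_overlapping_junctions_keep_highest_coverage(self):
        track = CoverageTrack()
        kept, removed_ov, _ = select_junctions(
            [junction(100, 200, 7), junction(120, 220, 3)], track
        )
        assert [(j.intron.start, j.coverage) for j in kept] == [(100, 7)]
        assert [(j.intron.start, j.coverage) for j in removed_ov] == [(120, 3)]

    def test_junction_below_skipped_mean_removed(self):
        track = CoverageTrack()
        for _ in range(10):
            track.add_block("chr1", "+", 100, 200)
        kept, _, removed_cov = select_junctions([junction(100, 200, 5)], track)
        assert kept == []
        assert [j.coverage for j in removed_cov] == [5]

    def test_junction_at_or_above_skipped_mean_kept(self):
        track = CoverageTrack()
        for _ in range(5):
            track.add_block("chr1", "+", 100, 200)
        kept, _, _ = select_junctions([junction(100, 200, 5)], track)
        assert len(kept) == 1

    def test_filter_order_overlap_then_coverage(self):
        # the cov-7 winner of the overlap is itself under-covered and must
        # then be removed by the second filter; the cov-3 junction stays
        # removed even though it would have survived the coverage filter
        track = CoverageTrack()
        for _ in range(10):
            track.add_block("chr1", "+", 100, 200)
        kept, removed_ov, removed_cov = select_junctions(
            [junction(100, 200, 7), junction(250, 300, 3)], track
        )
        assert [(j.intron.start, j.coverage) for j in kept] == [(250, 3)]
        assert [j.coverage for j in removed_cov] == [7]


class TestReconstruct:
    def test_coverage_runs_become_fragments(self):
        track = CoverageTrack()
        track.add_block("chr1", "+", 0, 10)
        track.add_block("chr1", "+", 12, 20)
        frags = reconstruct_fragments(track, [])
        spans = [[(b.start, b.end) for b in f.blocks] for f in frags]
        assert spans == [[(0, 10)], [(12, 20)]]

    def test_accepted_junction_joins_blocks(self):
        track = CoverageTrack()
        for _ in range(3):
            track.add_block("chr1", "+", 0, 20)
            track.add_block("chr1", "+", 120, 140)
        frags = reconstruct_fragments(track, [junction(20, 120, 5)])
        assert len(frags) == 1
        assert [(b.start, b.end) for b in frags[0].blocks] == [(0, 20), (120, 140)]

    def test_min_depth_threshold(self):
        track = CoverageTrack()
        track.add_block("chr1", "+", 0, 10)
        for _ in range(3):
            track.add_block("chr1", "+", 20, 30)
        frags = reconstruct_fragments(track, [], min_depth=2)
        assert [[(b.start, b.end) for b in f.blocks] for f in frags] == [[(20, 30)]]

    def test_monotonicity_adding_reads_never_shortens_fragments(self):
        reads1 = [read("chr1", "+", (0, 50), rid="a")]
        reads2 = reads1 + [read("chr1", "+", (40, 90), rid="b")]
        t1, j1 = pool_coverage(reads1)
        t2, j2 = pool_coverage(reads2)
        f1 = reconstruct_fragments(t1, j1)
        f2 = reconstruct_fragments(t2, j2)
        assert f2[0].end - f2[0].start >= f1[0].end - f1[0].start


class TestExtendTranscripts:
    def make_models(self, factory):
        return [
            factory(tid="t1", gene="g1", exons=((900, 1000),),
                    cds=((900, 970),), utr3=((970, 1000),)),
        ]

    def test_overlapping_fragment_extends_to_fragment_end(self, transcript_factory):
        models = self.make_models(transcript_factory)
        from mirpollen.utr_extension import ReconstructedFragment

        frag = ReconstructedFragment(
            "chr1", "+", (GenomicInterval("chr1", 950, 1160, "+"),)
        )
        results = extend_transcripts([frag], models)
        r = results["t1"]
        assert r.new_end == 1160
        assert sum(len(b) for b in r.added_blocks) == 160

    def test_fragment_upstream_of_end_gives_none(self, transcript_factory):
        models = self.make_models(transcript_factory)
        from mirpollen.utr_extension import ReconstructedFragment

        frag = ReconstructedFragment(
            "chr1", "+", (GenomicInterval("chr1", 900, 990, "+"),)
        )
        r = extend_transcripts([frag], models)["t1"]
        assert r.category == "none" and r.added_blocks == ()

    def test_extension_truncated_at_downstream_gene_exon(self, transcript_factory):
        models = self.make_models(transcript_factory) + [
            transcript_factory(tid="t2", gene="g2", exons=((1120, 1300),)),
            transcript_factory(tid="t3", gene="g3", exons=((1400, 1500),)),
        ]
        from mirpollen.utr_extension import ReconstructedFragment

        frag = ReconstructedFragment(
            "chr1", "+", (GenomicInterval("chr1", 950, 1160, "+"),)
        )
        r = extend_transcripts([frag], models)["t1"]
        assert r.new_end == 1120  # clipped at g2's exon start
        assert all(b.end <= 1120 for b in r.added_blocks)

    def test_minus_strand_extension(self, transcript_factory):
        models = [
            transcript_factory(tid="t1", gene="g1", strand="-",
                               exons=((900, 1000),), cds=((930, 1000),),
                               utr3=((900, 930),)),
        ]
        from mirpollen.utr_extension import ReconstructedFragment

        frag = ReconstructedFragment(
            "chr1", "-", (GenomicInterval("chr1", 750, 950, "-"),)
        )
        r = extend_transcripts([frag], models)["t1"]
        assert r.new_end == 750
        assert [(b.start, b.end) for b in r.added_blocks] == [(750, 900)]

    def test_strand_mismatch_ignored(self, transcript_factory):
        models = self.make_models(transcript_factory)
        from mirpollen.utr_extension import ReconstructedFragment

        frag = ReconstructedFragment(
            "chr1", "-", (GenomicInterval("chr1", 950, 1160, "-"),)
        )
        assert extend_transcripts([frag], models)["t1"].category == "none"


def run_classification(factory, cds_seq, ext_seq, utr3=()):
    """Build a one-exon gene whose CDS reads cds_seq, with ext_seq planted
    immediately downstream, and classify an extension over ext_seq."""
    from mirpollen.utr_extension import ExtensionResult

    genome = {"chr1": "T" * 10 + cds_seq + ext_seq + "T" * 10}
    cds_lo, cds_hi = 10, 10 + len(cds_seq)
    model = factory(
        exons=((cds_lo, cds_hi),), cds=((cds_lo, cds_hi),), utr3=utr3
    )
    result = ExtensionResult(
        "t1", cds_hi, cds_hi + len(ext_seq),
        (GenomicInterval("chr1", cds_hi, cds_hi + len(ext_seq), "+"),),
        utr3_length_before=sum(e - s for s, e in utr3),
    )
    return classify_extension(result, model, genome)


class TestClassification:
    def test_stop_present_whole_extension_is_utr3(self, transcript_factory):
        r = run_classification(transcript_factory, "ATGGCCTAA", "GGGTTTCCC")
        assert r.category == "3UTR"
        assert r.utr3_length_after - r.utr3_length_before == 9

    def test_stop_inside_extension_splits_cds_and_utr3(self, transcript_factory):
        r = run_classification(transcript_factory, "ATGGCC", "GGTTAAACCC")
        assert r.category == "CDS+3UTR"
        assert r.cds_added == 6  # "GGTTAA" including the stop
        assert r.utr3_length_after - r.utr3_length_before == 4  # "ACCC"

    def test_no_stop_anywhere_extension_is_cds(self, transcript_factory):
        r = run_classification(transcript_factory, "ATGGCC", "GGTGCTGCC")
        assert r.category == "CDS"
        assert r.cds_added == 9
        assert r.utr3_length_after == r.utr3_length_before

    def test_frame_violation_flagged(self, transcript_factory):
        r = run_classification(transcript_factory, "ATGGC", "GGGTTT")
        assert r.frame_flagged

    def test_utr3_conservation_invariant(self, transcript_factory):
        # added 3UTR length equals the change in annotated 3'UTR length
        for cds, ext in [("ATGTAA", "GCGCGC"), ("ATGGCC", "GGTTAAACCC")]:
            r = run_classification(transcript_factory, cds, ext)
            added_utr3 = sum(len(b) for b in r.added_blocks) - r.cds_added
            assert r.utr3_length_after - r.utr3_length_before == added_utr3
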