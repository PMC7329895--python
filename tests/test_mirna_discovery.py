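"""Discovery cascade filters, window excision, five-criteria evaluation."""

import random

import pytest

from mirpollen import mirna_discovery as md
from mirpollen.annotation_io import GenomicInterval, revcomp


class TestPreprocess:
    def test_length_filter(self):
        libs = {"A": ["A" * 17, "C" * 18, "G" * 24, "T" * 25]}
        kept = md.preprocess_reads(libs, min_abundance=1)
        assert sorted(r.length for r in kept) == [18, 24]

    def test_singletons_removed(self):
        libs = {"A": ["ACGTACGTACGTACGTACGTA"], "B": []}
        assert md.preprocess_reads(libs) == []

    def test_collapse_counts_per_library(self):
        seq = "ACGTACGTACGTACGTACGTA"
        libs = {"A": [seq] * 3, "B": [seq] * 2}
        (r,) = md.preprocess_reads(libs)
        assert r.abundance == {"A": 3, "B": 2}
        assert r.total == 5

    def test_u_normalized_to_t(self):
        seq = "ACGUACGUACGUACGUACGUA"
        libs = {"A": [seq] * 2}
        (r,) = md.preprocess_reads(libs)
        assert "U" not in r.sequence


class TestContaminantScreen:
    RRNA = "GGGCCCGGGAAATTTCCCGGGTTTAAACCCGGG"

    def reads(self, *seqs):
        return [md.CollapsedRead(s, {"A": 2}) for s in seqs]

    def test_rrna_substring_dropped(self):
        (kept,) = [
            r.sequence
            for r in md.screen_contaminants(
                self.reads(self.RRNA[2:25], "ACGTACGTACGTACGTACGTA"),
                [(self.RRNA, "rRNA")],
            )
        ] or [None]
        assert kept == "ACGTACGTACGTACGTACGTA"

    def test_mirna_typed_match_kept(self):
        seq = self.RRNA[2:25]
        kept = md.screen_contaminants(
            self.reads(seq), [(self.RRNA, "rRNA"), (self.RRNA, "miRNA")]
        )
        assert [r.sequence for r in kept] == [seq]

    def test_no_match_kept(self):
        kept = md.screen_contaminants(
            self.reads("ACGTACGTACGTACGTACGTA"), [(self.RRNA, "rRNA")]
        )
        assert len(kept) == 1


class TestAligner:
    def test_unique_plant_found_with_strand(self):
        mer = "ACGTTGCAACGGTTCCAAGGT"
        genome = {"chr1": "T" * 50 + mer + "G" * 50}
        loci = md.align_small_reads([md.CollapsedRead(mer, {"A": 2})], genome)
        assert [(iv.start, iv.end, iv.strand) for iv in loci[mer]] == [(50, 71, "+")]

    def test_minus_strand_occurrence(self):
        mer = "ACGTTGCAACGGTTCCAAGGT"
        genome = {"chr1": "T" * 50 + revcomp(mer) + "G" * 50}
        loci = md.align_small_reads([md.CollapsedRead(mer, {"A": 2})], genome)
        assert [(iv.start, iv.end, iv.strand) for iv in loci[mer]] == [(50, 71, "-")]

    def test_max_loci_cap(self):
        mer = "ACGTTGCAACGGTTCCAAGGT"
        genome = {"chr1": ("TTTT" + mer) * 25}
        loci = md.align_small_reads([md.CollapsedRead(mer, {"A": 2})], genome, max_loci=20)
        assert len(loci[mer]) == 20

    def test_absent_read_has_no_loci(self):
        loci = md.align_small_reads(
            [md.CollapsedRead("ACGTTGCAACGGTTCCAAGGT", {"A": 2})], {"chr1": "T" * 200}
        )
        assert loci["ACGTTGCAACGGTTCCAAGGT"] == []


class TestExonFilter:
    def test_overlap_by_one_nt_removed(self, transcript_factory):
        models = [transcript_factory(exons=((100, 200),))]
        loci = {
            "x": [
                GenomicInterval("chr1", 180, 201, "+"),   # 20 nt inside
                GenomicInterval("chr1", 199, 220, "+"),   # 1 nt overlap
                GenomicInterval("chr1", 200, 221, "+"),   # abuts, no overlap
            ]
        }
        out = md.filter_exonic(loci, models)
        assert [(iv.start, iv.end) for iv in out["x"]] == [(200, 221)]

    def test_strand_agnostic(self, transcript_factory):
        models = [transcript_factory(exons=((100, 200),))]
        loci = {"x": [GenomicInterval("chr1", 150, 171, "-")]}
        assert md.filter_exonic(loci, models)["x"] == []


class TestExciseWindows:
    GENOME = {"chr1": "ACGT" * 600}

    def test_plus_strand_window_arithmetic(self):
        locus = GenomicInterval("chr1", 1000, 1021, "+")
        w3, w5 = md.excise_windows("A" * 21, locus, self.GENOME)
        assert (w3.interval.start, w3.interval.end) == (930, 1041)
        assert len(w3.window_sequence) == 111
        assert w3.read_offset == 70
        assert (w5.interval.start, w5.interval.end) == (980, 1091)
        assert w5.read_offset == 20

    def test_minus_strand_window_revcomp(self):
        locus = GenomicInterval("chr1", 1000, 1021, "-")
        w3, w5 = md.excise_windows("A" * 21, locus, self.GENOME)
        assert (w3.interval.start, w3.interval.end) == (980, 1091)
        assert w3.read_offset == 70
        assert w3.window_sequence == revcomp(self.GENOME["chr1"][980:1091])

    def test_truncation_at_chromosome_start(self):
        locus = GenomicInterval("chr1", 30, 51, "+")
        w3, _ = md.excise_windows("A" * 21, locus, self.GENOME)
        assert w3.interval.start == 0
        assert w3.read_offset == 30


def window_from(structure, read_offset, read_len, mfe):
    return md.HairpinWindow(
        read_sequence="A" * read_len,
        interval=GenomicInterval("chr1", 0, len(structure), "+"),
        arm="3p",
        window_sequence="A" * len(structure),
        read_offset=read_offset,
        structure=structure,
        mfe=mfe,
    )


class TestEvaluateHairpin:
    def test_reference_passing_fixture(self):
        w = window_from("((((....))))", 1, 8, -40.0)
        ev = md.evaluate_hairpin(w)
        assert ev.flags() == (True, True, True, True, True) and ev.passed

    def test_loop_of_three_fails_c4(self):
        w = window_from("((((...))))".ljust(11, "."), 1, 6, -40.0)
        ev = md.evaluate_hairpin(w)
        assert not ev.c4_loop_ge_4 and not ev.passed

    def test_read_inside_loop_fails_c3(self):
        w = window_from("((((......))))", 5, 4, -40.0)
        ev = md.evaluate_hairpin(w)
        assert not ev.c3_read_not_in_loop and not ev.passed

    def test_mfe_boundary_is_strict(self):
        w = window_from("((((....))))", 1, 8, -34.5)
        assert not md.evaluate_hairpin(w).c5_mfe_below_threshold
        w = window_from("((((....))))", 1, 8, -35.0)
        assert not md.evaluate_hairpin(w).c5_mfe_below_threshold
        w = window_from("((((....))))", 1, 8, -35.5)
        assert md.evaluate_hairpin(w).c5_mfe_below_threshold

    def test_extent_below_75_percent_fails_c2(self):
        # 12-nt stem-loop inside a 16-nt window: extent 75% exactly passes;
        # one extra window base drops it to 70.6% and fails
        w = window_from("((((....))))....", 1, 8, -40.0)
        assert md.evaluate_hairpin(w).c2_hairpin_covers_75
        w = window_from("((((....))))" + "." * 5, 1, 8, -40.0)
        assert not md.evaluate_hairpin(w).c2_hairpin_covers_75

    def test_read_outside_stem_loop_fails_c1(self):
        w = window_from("((((....))))......", 13, 5, -40.0)
        ev = md.evaluate_hairpin(w)
        assert not ev.c1_read_in_hairpin and not ev.passed

    def test_branched_structure_is_not_one_stem_loop(self):
        # two hairpins side by side: the read spans both, so it is inside
        # no single branch-free element
        s = "((((....))))((((....))))"
        w = window_from(s, 2, 20, -40.0)
        assert not md.evaluate_hairpin(w).c1_read_in_hairpin


def _independent_stem_loops(structure):
    """Straightforward re-implementation used as the property oracle."""
    match = {}
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            match[stack[-1]] = i
            match[i] = stack.pop()
    opens = sorted(i for i in match if structure[i] == "(")
    elements = []
    for i in opens:
        j = match[i]
        inner = [k for k in opens if i < k < j]
        if any(match[k] < j for k in inner):  # has nested pair => not innermost
            continue
        lo, hi = i, j
        while True:
            parent = None
            for k in opens:
                if k < lo and match[k] > hi:
                    if parent is None or k > parent:
                        parent = k
            if parent is None:
                break
            enclosed = [k for k in opens if parent < k < match[parent] and k != parent]
            top = [k for k in enclosed if not any(q < k and match[q] > match[k] for q in enclosed)]
            if len(top) == 1:
                lo, hi = parent, match[parent]
            else:
                break
        elements.append((lo, hi, i + 1, j))
    return elements


class TestStemLoopProperty:
    def test_matches_independent_reimplementation(self):
        rnd = random.Random(7)

        def random_structure(n):
            s = ["."] * n
            for _ in range(rnd.randint(0, n // 3)):
                i = rnd.randrange(n)
                j = rnd.randrange(n)
                i, j = min(i, j), max(i, j)
                if j - i > 4 and all(c == "." for c in s[i : j + 1]):
                    s[i], s[j] = "(", ")"
                    # sometimes stack inward
                    k = 1
                    while rnd.random() < 0.6 and j - i - 2 * k > 4:
                        s[i + k], s[j - k] = "(", ")"
                        k += 1
            return "".join(s)

        for _ in range(200):
            structure = random_structure(rnd.randint(15, 60))
            got = sorted(md._stem_loops(structure))
            want = sorted(_independent_stem_loops(structure))
            assert got == want, structure


class TestCallMirnas:
    DESIGN = {
        f"{s}_{r}": (s, "CO", str(r))
        for s in ("tet", "pm") for r in (1, 2, 3)
    }

    def passing(self, seq):
        return {seq: [window_from("((((....))))", 1, 8, -40.0)]}

    def test_read_missing_one_replicate_everywhere_removed(self):
        seq = "ACGTACGTACGTACGTACGTA"
        r = md.CollapsedRead(seq, {"tet_1": 3, "tet_2": 2, "pm_1": 1, "pm_2": 1})
        assert md.call_mirnas([r], self.passing(seq), self.DESIGN) == []

    def test_full_group_presence_retained(self):
        seq = "ACGTACGTACGTACGTACGTA"
        r = md.CollapsedRead(seq, {"tet_1": 3, "tet_2": 2, "tet_3": 1})
        (rec,) = md.call_mirnas([r], self.passing(seq), self.DESIGN)
        assert rec.name == "solyc-miR001"

    def test_lexicographic_naming(self):
        seqs = ["AAG" + "T" * 18, "AAC" + "T" * 18]
        reads = [
            md.CollapsedRead(s, {"tet_1": 1, "tet_2": 1, "tet_3": 1}) for s in seqs
        ]
        passing = {}
        for s in seqs:
            passing.update(self.passing(s))
        recs = md.call_mirnas(reads, passing, self.DESIGN)
        assert [r.name for r in recs] == ["solyc-miR001", "solyc-miR002"]
        assert recs[0].sequence.startswith("AAC")

    def test_name_width_grows_with_total(self):
        import string

        seqs = sorted(
            "".join(c) + "A" * 18
            for c in __import__("itertools").product("ACGT", repeat=3)
        )[:1000]
        reads = [
            md.CollapsedRead(s, {"tet_1": 1, "tet_2": 1, "tet_3": 1}) for s in seqs
        ]
        passing = {}
        for s in seqs:
            passing.update(self.passing(s))
        recs = md.call_mirnas(reads, passing, self.DESIGN)
        assert recs[0].name == "solyc-miR001"  # 64 records: width stays 3

    def test_missing_library_in_design_fatal(self):
        seq = "ACGTACGTACGTACGTACGTA"
        r = md.CollapsedRead(seq, {"unknown_lib": 3})
        with pytest.raises(ValueError, match="unknown_lib"):
            md.call_mirnas([r], self.passing(seq), self.DESIGN)

    def test_no_passing_window_removed(self):
        seq = "ACGTACGTACGTACGTACGTA"
        r = md.CollapsedRead(seq, {"tet_1": 1, "tet_2": 1, "tet_3": 1})
        assert md.call_mirnas([r], {}, self.DESIGN) == []


class TestCascadeMonotonicity:
    def test_each_stage_output_subset_of_input(self):
        rnd = random.Random(3)
        genome = {"chr1": "".join(rnd.choice("ACGT") for _ in range(4000))}
        libs = {
            "tet_1": [genome["chr1"][i : i + 21] for i in range(0, 400, 10)] * 2,
            "tet_2": [genome["chr1"][i : i + 21] for i in range(0, 400, 20)] * 2,
            "tet_3": [genome["chr1"][i : i + 21] for i in range(0, 400, 40)] * 2,
        }
        design = {f"tet_{r}": ("tet", "CO", str(r)) for r in (1, 2, 3)}
        _, report = md.discover_mirnas(libs, genome, [], design)
        counts = [c for _s, c in report.stage_counts[1:]]  # after raw total
        assert counts == sorted(counts, reverse=True)
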