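"""Duplex scoring, exhaustive-search equivalence, filters, regions."""

import numpy as np
import pytest

from mirpollen import target_prediction as tp
from mirpollen.annotation_io import revcomp

MIR = "TGAAGCTGCCAGCATGATCTA"  # 21-mer


def mutate(seq, pos, base):
    s = list(seq)
    s[pos] = base
    return "".join(s)


class TestScoreDuplex:
    def test_perfect_complement(self):
        e, mode = tp.score_duplex(MIR, revcomp(MIR), (MIR, MIR))
        assert (e, mode) == (0.0, "cleavage")

    def test_wobble_in_doubled_window(self):
        # G:U at miRNA position 5 (inside 2-13): 0.5 x 2 = 1.0
        assert MIR[4] == "G"
        ar = mutate(MIR, 4, "A")  # rc-space A means target U -> G:U
        e, mode = tp.score_duplex(MIR, revcomp(ar), (MIR, ar))
        assert (e, mode) == (1.0, "cleavage")

    def test_central_mismatch_means_translation(self):
        ar = mutate(MIR, 9, {"A": "C", "C": "A", "G": "T", "T": "G"}[MIR[9]])
        e, mode = tp.score_duplex(MIR, revcomp(ar), (MIR, ar))
        assert (e, mode) == (2.0, "translation")

    def test_mismatch_outside_doubled_window(self):
        ar = mutate(MIR, 15, {"A": "C", "C": "A", "G": "T", "T": "G"}[MIR[15]])
        e, mode = tp.score_duplex(MIR, revcomp(ar), (MIR, ar))
        assert (e, mode) == (1.0, "cleavage")

    def test_gap_column_penalty(self):
        # unpaired miRNA base at position 15 (outside doubling): 2.0
        am = MIR
        ar = MIR[:14] + "-" + MIR[15:]
        site = revcomp(MIR[:14] + MIR[15:])
        e, _mode = tp.score_duplex(MIR, site, (am, ar))
        assert e == 2.0

    def test_inconsistent_alignment_rejected(self):
        with pytest.raises(ValueError):
            tp.score_duplex(MIR, revcomp(MIR), (MIR[::-1], MIR))


# --- brute-force oracle: enumerate every <=2-gap alignment ----------------

_PEN = {"match": 0, "wobble": 1, "mismatch": 2}
_GAP = 4


def _colpen(m_base, rc_base):
    if m_base == rc_base:
        return 0
    if (m_base, rc_base) in (("G", "A"), ("T", "C")):
        return 1
    return 2


def _mult(i):
    return 2 if 1 <= i <= 12 else 1


def oracle_min_half_penalty(mirna, cdna, max_gaps=2):
    """Exhaustive minimum penalty (half units) over all canonical
    alignments: gap events are (type, miRNA position); 'B' inserts an
    unpaired target base before the position, 'U' leaves the miRNA base
    unpaired; alignments start and end with a pair column."""
    m = mirna
    r = revcomp(cdna)
    L, n = len(m), len(r)
    # per-register column penalties with inf padding, prefix sums
    pad = L + 3
    big = 10**6
    P = {}
    C = {}
    for d in range(-max_gaps, max_gaps + 1):
        col = np.full((L, n + 2 * pad), big, dtype=np.int64)
        for i in range(L):
            for o in range(n):
                x = o + i + d
                if 0 <= x < n:
                    col[i, o + pad] = _colpen(m[i], r[x]) * _mult(i)
        C[d] = np.vstack([np.zeros((1, n + 2 * pad), np.int64), np.cumsum(col, 0)])
    offsets = np.arange(n) + pad

    def segsum(d, a, b):
        return C[d][b][offsets] - C[d][a][offsets]

    events = [("B", i) for i in range(1, L)] + [("U", i) for i in range(1, L - 1)]
    configs = [[]]
    configs += [[e] for e in events]
    for e1 in events:
        for e2 in events:
            if e1[1] < e2[1]:
                configs.append([e1, e2])
            elif e1[1] == e2[1] and e1[0] == "B" and (e2[0] == "U" or e2 is e1):
                # at equal positions only a bulge can come first; two
                # bulges at the same slot insert two target bases
                configs.append([e1, e2])

    best = np.full(n, big, dtype=np.int64)
    for config in configs:
        pen = np.zeros(n, dtype=np.int64)
        d = 0
        seg = 0
        ok = True
        for typ, i in config:
            if i < seg:
                ok = False
                break
            pen = pen + segsum(d, seg, i)
            pen = pen + _GAP * _mult(i)
            if typ == "B":
                d += 1
                seg = i
            else:
                d -= 1
                seg = i + 1
        if not ok:
            continue
        pen = pen + segsum(d, seg, L)
        best = np.minimum(best, pen)
    return int(best.min())


class TestSearchOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_min_penalty_matches_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        bases = np.array(list("ACGT"))
        mir = "".join(bases[rng.integers(0, 4, 21)])
        cdna = "".join(bases[rng.integers(0, 4, 120)])
        # plant an imperfect site to make low penalties reachable
        site = revcomp(mutate(mir, 6, "A"))
        cdna = cdna[:50] + site + cdna[50:]
        want = oracle_min_half_penalty(mir, cdna)
        sites = tp.predict_targets(
            {"m": mir}, {"t": cdna}, max_expectation=want / 2.0,
            allow_translation=True,
        )
        assert sites, "search missed the brute-force optimum"
        assert min(s.expectation for s in sites) == pytest.approx(want / 2.0)

    def test_no_survivor_violates_filters(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        mir = "".join(bases[rng.integers(0, 4, 21)])
        cdna = (
            "".join(bases[rng.integers(0, 4, 150)]) + revcomp(mir)
            + "".join(bases[rng.integers(0, 4, 30)])
        )
        sites = tp.predict_targets({"m": mir}, {"t": cdna})
        assert sites
        for s in sites:
            assert s.expectation <= 3.0
            assert s.mode == "cleavage"


class TestPredictTargets:
    def test_planted_perfect_site_found(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        cdna = "".join(bases[rng.integers(0, 4, 200)])
        cdna = cdna[:100] + revcomp(MIR) + cdna[100:]
        sites = tp.predict_targets({"m": MIR}, {"t": cdna})
        hit = [s for s in sites if s.start == 100]
        assert hit and hit[0].expectation == 0.0
        assert hit[0].end == 121

    def test_expectation_above_three_removed(self):
        # four mismatches outside the doubled window = 4.0 > 3
        site = MIR
        for pos in (14, 15, 16, 17):
            site = mutate(site, pos, {"A": "C", "C": "A", "G": "T", "T": "G"}[site[pos]])
        cdna = "T" * 50 + revcomp(site) + "T" * 50
        sites = tp.predict_targets({"m": MIR}, {"t": cdna})
        assert all(not (45 <= s.start <= 55) for s in sites)

    def test_translation_mode_removed_by_default(self):
        site = mutate(MIR, 9, {"A": "C", "C": "A", "G": "T", "T": "G"}[MIR[9]])
        cdna = "T" * 50 + revcomp(site) + "T" * 50
        assert tp.predict_targets({"m": MIR}, {"t": cdna}) == []
        kept = tp.predict_targets({"m": MIR}, {"t": cdna}, allow_translation=True)
        assert any(s.mode == "translation" for s in kept)

    def test_max_targets_keeps_lowest_expectation(self):
        cdna = ("TTTT" + revcomp(MIR)) * 5
        sites = tp.predict_targets({"m": MIR}, {"t": cdna}, max_targets=3)
        assert len(sites) == 3
        assert all(s.expectation == 0.0 for s in sites)

    def test_empty_cdna_set(self):
        assert tp.predict_targets({"m": MIR}, {}) == []


class TestImportTable:
    def test_filters_applied_on_import(self, tmp_path):
        rows = ["miRNA\tTarget\tTarget_start\tTarget_end\tExpectation\tInhibition"]
        for i in range(5):
            rows.append(f"m{i}\tt{i}\t10\t30\t1.5\tCleavage")
        for i in range(3):
            rows.append(f"x{i}\tt{i}\t10\t30\t3.5\tCleavage")
        for i in range(2):
            rows.append(f"y{i}\tt{i}\t10\t30\t1.0\tTranslation")
        p = tmp_path / "pred.tsv"
        p.write_text("\n".join(rows) + "\n")
        sites = tp.import_prediction_table(str(p))
        assert len(sites) == 5
        assert {s.mirna for s in sites} == {f"m{i}" for i in range(5)}

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "pred.tsv"
        p.write_text("miRNA\tTarget\tTarget_start\tTarget_end\tExpectation\tInhibition\n")
        assert tp.import_prediction_table(str(p)) == []

    def test_missing_column_is_fatal_with_name(self, tmp_path):
        p = tmp_path / "pred.tsv"
        p.write_text("miRNA\tTarget\tTarget_start\tTarget_end\tExpectation\n" )
        with pytest.raises(ValueError, match="Inhibition"):
            tp.import_prediction_table(str(p))

    def test_coordinates_round_trip(self, tmp_path):
        p = tmp_path / "pred.tsv"
        p.write_text(
            "miRNA\tTarget\tTarget_start\tTarget_end\tExpectation\tInhibition\n"
            "m1\tt1\t101\t121\t0.5\tCleavage\n"
        )
        (s,) = tp.import_prediction_table(str(p))
        assert (s.start, s.end) == (100, 121)
        out = tmp_path / "out.tsv"
        tp.export_prediction_table([s], str(out))
        (s2,) = tp.import_prediction_table(str(out))
        assert (s2.start, s2.end) == (s.start, s.end)


class TestRegionAnnotation:
    def make_model(self, factory):
        # cDNA: 5UTR 0-50, CDS 50-150, 3UTR 150-200
        return factory(
            exons=((0, 200),), cds=((50, 150),), utr5=((0, 50),), utr3=((150, 200),)
        )

    def site(self, start, end):
        return tp.TargetSite("m", "t1", start, end, 0.0, "cleavage")

    def test_wholly_in_utr3(self, transcript_factory):
        m = self.make_model(transcript_factory)
        assert tp.annotate_site_region(self.site(160, 181), m) == "3UTR"

    def test_majority_rule(self, transcript_factory):
        m = self.make_model(transcript_factory)
        # 12 nt in CDS, 9 in 3UTR
        assert tp.annotate_site_region(self.site(138, 159), m) == "CDS"

    def test_exact_tie_goes_three_prime(self, transcript_factory):
        m = self.make_model(transcript_factory)
        assert tp.annotate_site_region(self.site(140, 160), m) == "3UTR"

    def test_site_beyond_cdna_is_error(self, transcript_factory):
        m = self.make_model(transcript_factory)
        with pytest.raises(ValueError):
            tp.annotate_site_region(self.site(190, 211), m)

    def test_region_count_conservation(self, transcript_factory):
        m = self.make_model(transcript_factory)
        sites = [self.site(s, s + 21) for s in range(0, 179, 7)]
        for s in sites:
            tp.annotate_site_region(s, m)
        counts = {}
        for s in sites:
            counts[s.region] = counts.get(s.region, 0) + 1
        assert sum(counts.values()) == len(sites)
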