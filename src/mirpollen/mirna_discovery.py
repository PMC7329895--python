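"""Candidate miRNA identification from small-RNA sequencing reads.

The discovery cascade: length filter (18-24 nt) -> collapse identical
reads with per-library abundances -> singleton removal -> contaminant
screen (Rfam-style typed records; matches to miRNA-typed records are
kept) -> genomic alignment -> removal of exon-overlapping alignments ->
dual hairpin-window excision (70/20 and 20/70 nt flanks) -> folding ->
five structural criteria -> replicate-reproducibility filter -> naming by
lexicographic sequence order.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from . import folding
from .annotation_io import AlignedRead, GenomicInterval, TranscriptModel, revcomp

log = logging.getLogger(__name__)

MIN_LEN = 18
MAX_LEN = 24
UPSTREAM_LONG = 70
DOWNSTREAM_SHORT = 20
DEFAULT_MFE_THRESHOLD = -35.0
DEFAULT_HAIRPIN_COVERAGE = 0.75
DEFAULT_MIN_LOOP = 4
DEFAULT_MAX_LOCI = 20


@dataclass
class CollapsedRead:
    """A unique small-RNA sequence with per-library counts."""

    sequence: str
    abundance: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.abundance.values())


@dataclass
class HairpinWindow:
    """An excised genomic window under one arm hypothesis."""

    read_sequence: str
    interval: GenomicInterval
    arm: str  # 5p | 3p
    window_sequence: str
    read_offset: int  # start of the read within the window sequence
    structure: str | None = None
    mfe: float | None = None


@dataclass
class HairpinEvaluation:
    c1_read_in_hairpin: bool
    c2_hairpin_covers_75: bool
    c3_read_not_in_loop: bool
    c4_loop_ge_4: bool
    c5_mfe_below_threshold: bool
    hairpin_extent: tuple[int, int] | None = None  # inclusive window coords
    loop: tuple[int, int] | None = None  # half-open window coords

    @property
    def passed(self) -> bool:
        return (
            self.c1_read_in_hairpin
            and self.c2_hairpin_covers_75
            and self.c3_read_not_in_loop
            and self.c4_loop_ge_4
            and self.c5_mfe_below_threshold
        )

    def flags(self) -> tuple[bool, bool, bool, bool, bool]:
        return (
            self.c1_read_in_hairpin,
            self.c2_hairpin_covers_75,
            self.c3_read_not_in_loop,
            self.c4_loop_ge_4,
            self.c5_mfe_below_threshold,
        )


@dataclass
class MiRNARecord:
    name: str
    sequence: str
    loci: list[GenomicInterval]
    abundance: dict[str, int]
    passing_windows: list[HairpinWindow] = field(default_factory=list)


def preprocess_reads(
    libraries: dict[str, list[str]],
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    min_abundance: int = 2,
) -> list[CollapsedRead]:
    """Length-filter, collapse and singleton-remove raw reads.

    ``libraries`` maps library id -> raw read sequences.  Reads outside
    [min_len, max_len] are discarded; identical sequences collapse into
    one record with per-library counts; records with total abundance
    below ``min_abundance`` are removed.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    for lib, reads in libraries.items():
        if not reads:
            log.warning("library %s is empty", lib)
        for seq in reads:
            seq = seq.upper().replace("U", "T")
            if min_len <= len(seq) <= max_len:
                counts[seq][lib] += 1
    collapsed = [
        CollapsedRead(seq, dict(c)) for seq, c in sorted(counts.items())
    ]
    return [r for r in collapsed if r.total >= min_abundance]


def screen_contaminants(
    reads: list[CollapsedRead],
    contaminants: list[tuple[str, str]],
) -> list[CollapsedRead]:
    """Drop reads matching non-miRNA contaminant records.

    ``contaminants`` holds (sequence, rna_type) records.  A read is
    dropped iff it is an exact substring of a record whose type is not
    ``miRNA``; a match to a miRNA-typed record retains the read even if
    it also fails to match anything else.
    """
    bad = [
        (seq.upper().replace("U", "T"), t) for seq, t in contaminants if t != "miRNA"
    ]
    good = [
        seq.upper().replace("U", "T") for seq, t in contaminants if t == "miRNA"
    ]
    kept = []
    for r in reads:
        if any(r.sequence in seq for seq in good):
            kept.append(r)
        elif any(r.sequence in seq for seq, _ in bad):
            continue
        else:
            kept.append(r)
    return kept


def align_small_reads(
    reads: list[CollapsedRead],
    genome: dict[str, str],
    max_loci: int = DEFAULT_MAX_LOCI,
) -> dict[str, list[GenomicInterval]]:
    """Exact-match alignment of collapsed reads to both genome strands.

    Returns sequence -> loci (at most ``max_loci`` per read, genomic
    order, plus strand before minus at equal coordinates).
    """
    out: dict[str, list[GenomicInterval]] = {}
    rc_genome = {c: revcomp(s) for c, s in genome.items()}
    for r in reads:
        loci: list[GenomicInterval] = []
        for chrom in sorted(genome):
            fwd, rc = genome[chrom], rc_genome[chrom]
            n = len(fwd)
            for strand, hay in (("+", fwd), ("-", rc)):
                start = hay.find(r.sequence)
                while start != -1:
                    if strand == "+":
                        loci.append(GenomicInterval(chrom, start, start + r.length, "+"))
                    else:
                        g_end = n - start
                        loci.append(GenomicInterval(chrom, g_end - r.length, g_end, "-"))
                    start = hay.find(r.sequence, start + 1)
        loci.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
        out[r.sequence] = loci[:max_loci]
    return out


def filter_exonic(
    loci_by_read: dict[str, list[GenomicInterval]],
    models: list[TranscriptModel],
) -> dict[str, list[GenomicInterval]]:
    """Remove alignments overlapping any annotated exon by >= 1 nt.

    The overlap test is strand-agnostic: a degradation fragment may be
    represented on either strand of an exonic locus.
    """
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for m in models:
        for ex in m.exons:
            exons[m.chrom].append((ex.start, ex.end))
    for chrom in exons:
        exons[chrom].sort()
    out: dict[str, list[GenomicInterval]] = {}
    for seq, loci in loci_by_read.items():
        kept = [
            iv
            for iv in loci
            if not any(s < iv.end and iv.start < e for s, e in exons.get(iv.chrom, []))
        ]
        out[seq] = kept
    return out


def excise_windows(
    read_sequence: str,
    locus: GenomicInterval,
    genome: dict[str, str],
    upstream_long: int = UPSTREAM_LONG,
    downstream_short: int = DOWNSTREAM_SHORT,
) -> tuple[HairpinWindow, HairpinWindow]:
    """Excise the two hairpin-hypothesis windows around an aligned read.

    Window A places the read in the 3' arm (70 nt upstream, 20 nt
    downstream in transcription orientation); window B places it in the
    5' arm (20 nt upstream, 70 nt downstream).  Minus-strand windows are
    reverse-complemented; windows are truncated at chromosome bounds.
    """
    chrom_seq = genome[locus.chrom]
    n = len(chrom_seq)

    def make(arm: str, up: int, down: int) -> HairpinWindow:
        if locus.strand == "+":
            w_start = max(0, locus.start - up)
            w_end = min(n, locus.end + down)
            seq = chrom_seq[w_start:w_end]
            offset = locus.start - w_start
        else:
            w_start = max(0, locus.start - down)
            w_end = min(n, locus.end + up)
            seq = revcomp(chrom_seq[w_start:w_end])
            offset = w_end - locus.end
        return HairpinWindow(
            read_sequence=read_sequence,
            interval=GenomicInterval(locus.chrom, w_start, w_end, locus.strand),
            arm=arm,
            window_sequence=seq,
            read_offset=offset,
        )

    window_3p = make("3p", upstream_long, downstream_short)
    window_5p = make("5p", downstream_short, upstream_long)
    return window_3p, window_5p


def _stem_loops(structure: str) -> list[tuple[int, int, int, int]]:
    """Branch-free stem-loop elements of a dot-bracket structure.

    Each element is (extent_start, extent_end, loop_inner_start,
    loop_inner_end): the extent is the inclusive span of the outermost
    pair of a maximal chain of singly-nested pairs; the terminal loop is
    the half-open unpaired region enclosed by the innermost pair.
    """
    pairs = folding.dotbracket_to_pairs(structure)
    pair_set = set(pairs)
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    ordered = sorted(pairs)
    for p in ordered:
        # direct parent: tightest enclosing pair
        best = None
        for q in ordered:
            if q[0] < p[0] and p[1] < q[1]:
                if best is None or q[0] > best[0]:
                    best = q
        if best is not None:
            children[best].append(p)
    stem_loops = []
    for p in ordered:
        if children[p]:
            continue  # not innermost
        inner = p
        outer = p
        # walk outward while the parent has exactly this single child chain
        while True:
            parent = None
            for q in ordered:
                if q[0] < outer[0] and outer[1] < q[1]:
                    if parent is None or q[0] > parent[0]:
                        parent = q
            if parent is not None and len(children[parent]) == 1:
                outer = parent
            else:
                break
        stem_loops.append((outer[0], outer[1], inner[0] + 1, inner[1]))
    return stem_loops


def evaluate_hairpin(
    window: HairpinWindow,
    mfe_threshold: float = DEFAULT_MFE_THRESHOLD,
    min_coverage: float = DEFAULT_HAIRPIN_COVERAGE,
    min_loop: int = DEFAULT_MIN_LOOP,
    strict_loop: bool = False,
) -> HairpinEvaluation:
    """Evaluate the five structural criteria on a folded window.

    (i) the read lies within the extent of a branch-free stem-loop;
    (ii) that extent covers >= ``min_coverage`` of the window;
    (iii) the read is not located in the terminal loop (default: not
    fully contained; ``strict_loop`` forbids any overlap);
    (iv) the terminal loop is >= ``min_loop`` nt;
    (v) the MFE is strictly below ``mfe_threshold`` kcal/mol.
    """
    if window.structure is None or window.mfe is None:
        raise ValueError("window must be folded before evaluation")
    wlen = len(window.window_sequence)
    r0 = window.read_offset
    r1 = r0 + len(window.read_sequence)  # half-open
    elements = _stem_loops(window.structure)

    containing = [
        el for el in elements if el[0] <= r0 and r1 - 1 <= el[1]
    ]
    if containing:
        # prefer the largest-extent element containing the read
        el = max(containing, key=lambda e: e[1] - e[0])
        c1 = True
    elif elements:
        el = max(elements, key=lambda e: e[1] - e[0])
        c1 = False
    else:
        return HairpinEvaluation(False, False, False, False, window.mfe < mfe_threshold)

    ext_len = el[1] - el[0] + 1
    loop_start, loop_end = el[2], el[3]
    c2 = ext_len >= min_coverage * wlen
    if strict_loop:
        c3 = not (r0 < loop_end and loop_start < r1)
    else:
        c3 = not (loop_start <= r0 and r1 <= loop_end)
    c4 = (loop_end - loop_start) >= min_loop
    c5 = window.mfe < mfe_threshold
    return HairpinEvaluation(
        c1, c2, c3, c4, c5,
        hairpin_extent=(el[0], el[1]),
        loop=(loop_start, loop_end),
    )


def fold_and_evaluate(
    window: HairpinWindow,
    mfe_threshold: float = DEFAULT_MFE_THRESHOLD,
    backend: str = "builtin",
    **kwargs,
) -> HairpinEvaluation:
    if window.structure is None:
        window.structure, window.mfe = folding.fold(window.window_sequence, backend)
    return evaluate_hairpin(window, mfe_threshold, **kwargs)


def call_mirnas(
    reads: list[CollapsedRead],
    passing: dict[str, list[HairpinWindow]],
    design: dict[str, tuple[str, str, str]],
    loci_by_read: dict[str, list[GenomicInterval]] | None = None,
    name_prefix: str = "solyc-miR",
) -> list[MiRNARecord]:
    """Apply the replicate-reproducibility filter and name survivors.

    ``design`` maps library -> (stage, condition, replicate).  A read is
    retained iff it has abundance >= 1 in all replicates of at least one
    (stage, condition) group and has >= 1 passing hairpin window.  Names
    are assigned in ascending order of the lexicographically sorted
    sequences, zero-padded to max(3, digits of total).
    """
    groups: dict[tuple[str, str], set[str]] = defaultdict(set)
    for lib, (stage, condition, _rep) in design.items():
        groups[(stage, condition)].add(lib)
    missing = {
        lib for r in reads for lib in r.abundance if lib not in design
    }
    if missing:
        raise ValueError(f"design table missing libraries: {sorted(missing)}")

    survivors = []
    for r in reads:
        if not passing.get(r.sequence):
            continue
        reproducible = any(
            all(r.abundance.get(lib, 0) >= 1 for lib in libs)
            for libs in groups.values()
        )
        if reproducible:
            survivors.append(r)

    survivors.sort(key=lambda r: r.sequence)
    width = max(3, len(str(len(survivors))))
    records = []
    for idx, r in enumerate(survivors, 1):
        records.append(
            MiRNARecord(
                name=f"{name_prefix}{idx:0{width}d}",
                sequence=r.sequence,
                loci=(loci_by_read or {}).get(r.sequence, []),
                abundance=dict(r.abundance),
                passing_windows=passing[r.sequence],
            )
        )
    return records


@dataclass
class DiscoveryReport:
    """Telescoping per-stage read counts of the discovery cascade."""

    stage_counts: list[tuple[str, int]] = field(default_factory=list)

    def add(self, stage: str, count: int) -> None:
        self.stage_counts.append((stage, count))

    def as_dict(self) -> dict[str, int]:
        return dict(self.stage_counts)


def discover_mirnas(
    libraries: dict[str, list[str]],
    genome: dict[str, str],
    models: list[TranscriptModel],
    design: dict[str, tuple[str, str, str]],
    contaminants: list[tuple[str, str]] | None = None,
    mfe_threshold: float = DEFAULT_MFE_THRESHOLD,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    min_abundance: int = 2,
    max_loci: int = DEFAULT_MAX_LOCI,
    min_coverage: float = DEFAULT_HAIRPIN_COVERAGE,
    min_loop: int = DEFAULT_MIN_LOOP,
    strict_loop: bool = False,
    backend: str = "builtin",
    name_prefix: str = "solyc-miR",
) -> tuple[list[MiRNARecord], DiscoveryReport]:
    """Run the full discovery cascade and return named miRNA records plus
    a telescoping per-stage report."""
    report = DiscoveryReport()
    raw_total = sum(len(v) for v in libraries.values())
    report.add("raw_reads", raw_total)

    collapsed = preprocess_reads(libraries, min_len, max_len, min_abundance)
    report.add("after_length_collapse_singleton", len(collapsed))

    if contaminants:
        collapsed = screen_contaminants(collapsed, contaminants)
    report.add("after_contaminant_screen", len(collapsed))

    loci = align_small_reads(collapsed, genome, max_loci)
    aligned = [r for r in collapsed if loci[r.sequence]]
    report.add("aligned_reads", len(aligned))

    loci = filter_exonic(loci, models)
    nonexonic = [r for r in aligned if loci[r.sequence]]
    report.add("after_exon_filter", len(nonexonic))

    passing: dict[str, list[HairpinWindow]] = defaultdict(list)
    for r in nonexonic:
        for locus in loci[r.sequence]:
            for window in excise_windows(r.sequence, locus, genome):
                ev = fold_and_evaluate(
                    window, mfe_threshold, backend,
                    min_coverage=min_coverage, min_loop=min_loop,
                    strict_loop=strict_loop,
                )
                if ev.passed:
                    passing[r.sequence].append(window)
    with_hairpin = [r for r in nonexonic if passing.get(r.sequence)]
    report.add("after_hairpin_criteria", len(with_hairpin))

    records = call_mirnas(nonexonic, passing, design, loci, name_prefix)
    report.add("after_replicate_filter", len(records))
    return records, report


__all__ = [
    "CollapsedRead",
    "HairpinWindow",
    "HairpinEvaluation",
    "MiRNARecord",
    "DiscoveryReport",
    "preprocess_reads",
    "screen_contaminants",
    "align_small_reads",
    "filter_exonic",
    "excise_windows",
    "evaluate_hairpin",
    "fold_and_evaluate",
    "call_mirnas",
    "discover_mirnas",
]
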