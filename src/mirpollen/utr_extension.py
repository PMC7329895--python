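"""De novo reconstruction of mRNA 3' ends from pooled 3'-end-sequencing
coverage, and extension of an existing annotation.

The workflow pools per-library alignments into a stranded coverage track,
merges continuously covered nucleotides into exon blocks, introduces
splice junctions (overlap resolution by coverage, then removal of
junctions weaker than the mean depth of the nucleotides they would skip),
superimposes the reconstructed fragments on annotated mRNAs, and
classifies each extension as CDS, CDS+3UTR or 3UTR by continuing
translation in frame until the first stop codon.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .annotation_io import (
    AlignedRead,
    GenomicInterval,
    SpliceJunction,
    TranscriptModel,
    revcomp,
)

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


class CoverageTrack:
    """Sparse per-(chrom, strand) depth map; absent positions have depth 0."""

    def __init__(self) -> None:
        self._depth: dict[tuple[str, str], Counter] = defaultdict(Counter)

    def add_block(self, chrom: str, strand: str, start: int, end: int) -> None:
        c = self._depth[(chrom, strand)]
        for p in range(start, end):
            c[p] += 1

    def depth(self, chrom: str, strand: str, pos: int) -> int:
        return self._depth.get((chrom, strand), Counter()).get(pos, 0)

    def mean_depth(self, chrom: str, strand: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        c = self._depth.get((chrom, strand), Counter())
        return sum(c.get(p, 0) for p in range(start, end)) / (end - start)

    def keys(self):
        return self._depth.keys()

    def covered_runs(self, chrom: str, strand: str, min_depth: int = 1) -> list[tuple[int, int]]:
        """Maximal runs of positions with depth >= min_depth, half-open."""
        c = self._depth.get((chrom, strand))
        if not c:
            return []
        positions = sorted(p for p, d in c.items() if d >= min_depth)
        runs = []
        if not positions:
            return runs
        start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                runs.append((start, prev + 1))
                start = p
            prev = p
        runs.append((start, prev + 1))
        return runs


@dataclass(frozen=True)
class ReconstructedFragment:
    """Exonic pieces joined by accepted splice junctions."""

    chrom: str
    strand: str
    blocks: tuple[GenomicInterval, ...]

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end


@dataclass
class ExtensionResult:
    transcript_id: str
    old_end: int
    new_end: int
    added_blocks: tuple[GenomicInterval, ...]
    category: str = "none"  # CDS | CDS+3UTR | 3UTR | none
    utr3_length_before: int = 0
    utr3_length_after: int = 0
    cds_added: int = 0
    frame_flagged: bool = False

    @property
    def extended(self) -> bool:
        return self.category != "none" and bool(self.added_blocks)

    @property
    def added_length(self) -> int:
        return sum(len(b) for b in self.added_blocks)


def pool_coverage(
    alignments: list[AlignedRead],
) -> tuple[CoverageTrack, list[SpliceJunction]]:
    """Pool alignments into a stranded coverage track and junction calls.

    Depth at p counts read blocks covering p on that strand; junction
    coverage counts spliced reads containing that exact intron span.
    """
    track = CoverageTrack()
    jc: Counter = Counter()
    for read in alignments:
        for b in read.blocks:
            track.add_block(read.chrom, read.strand, b.start, b.end)
        for intron in read.introns():
            jc[(read.chrom, read.strand, intron.start, intron.end)] += 1
    junctions = [
        SpliceJunction(chrom, GenomicInterval(chrom, s, e, strand), strand, cov)
        for (chrom, strand, s, e), cov in sorted(jc.items())
    ]
    return track, junctions


def select_junctions(
    junctions: list[SpliceJunction], track: CoverageTrack
) -> tuple[list[SpliceJunction], list[SpliceJunction], list[SpliceJunction]]:
    """Apply the two junction filters, in order.

    1. Among junctions with overlapping intron spans (same chrom/strand)
       only the one with the highest coverage is kept.
    2. Junctions whose coverage is lower than the average coverage of the
       nucleotides they would skip are removed.

    Returns (kept, removed_by_overlap, removed_by_skipped_coverage).
    """
    kept: list[SpliceJunction] = []
    removed_overlap: list[SpliceJunction] = []
    by_group: dict[tuple[str, str], list[SpliceJunction]] = defaultdict(list)
    for j in junctions:
        by_group[(j.chrom, j.strand)].append(j)
    for group in by_group.values():
        # highest coverage wins; ties resolved by leftmost, then shortest
        chosen: list[SpliceJunction] = []
        for j in sorted(group, key=lambda j: (-j.coverage, j.intron.start, j.intron.end)):
            if any(j.intron.overlaps(c.intron) for c in chosen):
                removed_overlap.append(j)
            else:
                chosen.append(j)
        kept.extend(chosen)

    survivors: list[SpliceJunction] = []
    removed_cov: list[SpliceJunction] = []
    for j in kept:
        skipped_mean = track.mean_depth(j.chrom, j.strand, j.intron.start, j.intron.end)
        if j.coverage < skipped_mean:
            removed_cov.append(j)
        else:
            survivors.append(j)
    survivors.sort(key=lambda j: (j.chrom, j.strand, j.intron.start))
    return survivors, removed_overlap, removed_cov


def reconstruct_fragments(
    track: CoverageTrack,
    junctions: list[SpliceJunction],
    min_depth: int = 1,
) -> list[ReconstructedFragment]:
    """Merge covered runs into exon blocks and join them across accepted
    junctions whose flanks touch block boundaries."""
    accepted, _, _ = select_junctions(junctions, track)
    fragments: list[ReconstructedFragment] = []
    for chrom, strand in sorted(track.keys()):
        runs = track.covered_runs(chrom, strand, min_depth)
        if not runs:
            continue
        end_index = {e: i for i, (s, e) in enumerate(runs)}
        start_index = {s: i for i, (s, e) in enumerate(runs)}
        parent = list(range(len(runs)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        links: set[tuple[int, int]] = set()
        for j in accepted:
            if j.chrom != chrom or j.strand != strand:
                continue
            i_left = end_index.get(j.intron.start)
            i_right = start_index.get(j.intron.end)
            if i_left is not None and i_right is not None and i_left != i_right:
                parent[find(i_right)] = find(i_left)
                links.add((i_left, i_right))
        groups: dict[int, list[int]] = defaultdict(list)
        for i in range(len(runs)):
            groups[find(i)].append(i)
        for members in groups.values():
            blocks = tuple(
                GenomicInterval(chrom, runs[i][0], runs[i][1], strand)
                for i in sorted(members)
            )
            fragments.append(ReconstructedFragment(chrom, strand, blocks))
    fragments.sort(key=lambda f: (f.chrom, f.strand, f.start))
    return fragments


def _extension_blocks(
    fragment: ReconstructedFragment, old_end: int, strand: str, limit: int | None
) -> tuple[GenomicInterval, ...]:
    """Fragment pieces beyond the annotated 3' terminus, clipped at the
    downstream-gene boundary ``limit`` (genomic position) when given."""
    out = []
    if strand == "+":
        hi = limit if limit is not None else None
        for b in fragment.blocks:
            s = max(b.start, old_end)
            e = b.end if hi is None else min(b.end, hi)
            if e > s:
                out.append(GenomicInterval(fragment.chrom, s, e, strand))
    else:
        lo = limit if limit is not None else None
        for b in fragment.blocks:
            s = b.start if lo is None else max(b.start, lo)
            e = min(b.end, old_end)
            if e > s:
                out.append(GenomicInterval(fragment.chrom, s, e, strand))
    return tuple(out)


def extend_transcripts(
    fragments: list[ReconstructedFragment],
    models: list[TranscriptModel],
    track: CoverageTrack | None = None,
    adjacency_gap: int = 0,
) -> dict[str, ExtensionResult]:
    """Superimpose reconstructed fragments on annotated mRNAs.

    A model is extended iff a same-strand fragment overlaps or abuts
    (within ``adjacency_gap`` nt) its 3'-terminal exon and reaches beyond
    the annotated 3' terminus.  The single eligible fragment with the
    longest extension is adopted (ties: higher mean depth, then leftmost);
    extensions are truncated at the nearest downstream exon of another
    same-strand gene.
    """
    by_loc: dict[tuple[str, str], list[ReconstructedFragment]] = defaultdict(list)
    for f in fragments:
        by_loc[(f.chrom, f.strand)].append(f)

    # downstream-gene exon boundaries per chrom/strand
    exon_bounds: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
    for m in models:
        for ex in m.exons:
            exon_bounds[(m.chrom, m.strand)].append((ex.start, ex.end, m.gene_id))

    results: dict[str, ExtensionResult] = {}
    for m in models:
        old_end = m.three_prime_end
        terminal_exon = m.exons[-1] if m.strand == "+" else m.exons[0]
        if m.strand == "+":
            others = [
                s for s, e, g in exon_bounds[(m.chrom, m.strand)]
                if g != m.gene_id and s >= old_end
            ]
            limit = min(others) if others else None
        else:
            others = [
                e for s, e, g in exon_bounds[(m.chrom, m.strand)]
                if g != m.gene_id and e <= old_end
            ]
            limit = max(others) if others else None

        best: tuple | None = None
        for f in by_loc.get((m.chrom, m.strand), []):
            touches = any(
                b.start <= terminal_exon.end + adjacency_gap
                and b.end >= terminal_exon.start - adjacency_gap
                for b in f.blocks
            )
            if not touches:
                continue
            reaches = f.end > old_end if m.strand == "+" else f.start < old_end
            if not reaches:
                continue
            added = _extension_blocks(f, old_end, m.strand, limit)
            if not added:
                continue
            length = sum(len(b) for b in added)
            depth = (
                sum(
                    track.mean_depth(m.chrom, m.strand, b.start, b.end) * len(b)
                    for b in added
                ) / length
                if track is not None
                else 0.0
            )
            key = (length, depth, -f.start)
            if best is None or key > best[0]:
                best = (key, added)

        if best is None:
            results[m.transcript_id] = ExtensionResult(
                m.transcript_id, old_end, old_end, (), "none",
                m.utr3_length, m.utr3_length,
            )
        else:
            added = best[1]
            new_end = added[-1].end if m.strand == "+" else added[0].start
            results[m.transcript_id] = ExtensionResult(
                m.transcript_id, old_end, new_end, added,
                utr3_length_before=m.utr3_length,
            )
    return results


def _cds_sequence(model: TranscriptModel, genome: dict[str, str]) -> str:
    seq = "".join(genome[model.chrom][c.start : c.end] for c in model.cds)
    return revcomp(seq) if model.strand == "-" else seq


def _spliced_sequence(
    blocks: tuple[GenomicInterval, ...], strand: str, genome: dict[str, str]
) -> str:
    seq = "".join(genome[b.chrom][b.start : b.end] for b in blocks)
    return revcomp(seq) if strand == "-" else seq


def classify_extension(
    result: ExtensionResult, model: TranscriptModel, genome: dict[str, str]
) -> ExtensionResult:
    """Assign the CDS / CDS+3UTR / 3UTR category to an extension.

    If the annotated CDS already ends with a stop codon the whole
    extension is 3'UTR.  Otherwise translation continues in frame through
    the extension: bases up to and including the first stop codon extend
    the CDS, the remainder is 3'UTR; with no stop, the whole extension is
    CDS.  A CDS length not divisible by 3 is flagged and treated as
    stop-less, with translation resuming at the dangling frame offset.
    """
    if not result.added_blocks:
        result.category = "none"
        result.utr3_length_after = result.utr3_length_before
        return result
    cds_seq = _cds_sequence(model, genome) if model.cds else ""
    ext_seq = _spliced_sequence(result.added_blocks, model.strand, genome)
    n_ext = len(ext_seq)
    if len(cds_seq) % 3 != 0:
        result.frame_flagged = True
    has_stop = (
        len(cds_seq) >= 3
        and len(cds_seq) % 3 == 0
        and cds_seq[-3:] in STOP_CODONS
    )
    if has_stop or not cds_seq:
        result.category = "3UTR"
        result.cds_added = 0
    else:
        leftover = len(cds_seq) % 3
        carry = cds_seq[len(cds_seq) - leftover :] if leftover else ""
        stream = carry + ext_seq
        cds_added = 0
        for pos in range(0, len(stream) - 2, 3):
            codon = stream[pos : pos + 3]
            if codon in STOP_CODONS:
                cds_added = pos + 3 - len(carry)
                break
        if cds_added > 0:
            result.cds_added = cds_added
            result.category = "CDS+3UTR" if cds_added < n_ext else "CDS"
        else:
            result.cds_added = n_ext
            result.category = "CDS"
    result.utr3_length_after = result.utr3_length_before + (n_ext - result.cds_added)
    return result


def apply_extension(
    model: TranscriptModel, result: ExtensionResult
) -> TranscriptModel:
    """Return a new transcript model incorporating a classified extension."""
    if not result.extended:
        return model
    added = list(result.added_blocks)
    chrom, strand = model.chrom, model.strand
    # merge added blocks into the exon chain
    exons = [(e.start, e.end) for e in model.exons]
    for b in added:
        merged = False
        for i, (s, e) in enumerate(exons):
            if b.start <= e and b.end >= s:
                exons[i] = (min(s, b.start), max(e, b.end))
                merged = True
                break
        if not merged:
            exons.append((b.start, b.end))
    exons.sort()
    # split the added run into CDS-extension and new-3UTR parts, in
    # transcription order
    ordered = added if strand == "+" else added[::-1]
    cds_new: list[tuple[int, int]] = [(c.start, c.end) for c in model.cds]
    utr3_new: list[tuple[int, int]] = (
        [(u.start, u.end) for u in model.utr3] if result.cds_added == 0 else []
    )
    remaining_cds = result.cds_added
    for b in ordered:
        blen = len(b)
        take = min(remaining_cds, blen)
        if strand == "+":
            if take:
                cds_new.append((b.start, b.start + take))
            if take < blen:
                utr3_new.append((b.start + take, b.end))
        else:
            if take:
                cds_new.append((b.end - take, b.end))
            if take < blen:
                utr3_new.append((b.start, b.end - take))
        remaining_cds -= take

    def norm(ivs: list[tuple[int, int]]) -> tuple[GenomicInterval, ...]:
        ivs = sorted(ivs)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return tuple(GenomicInterval(chrom, s, e, strand) for s, e in merged)

    return TranscriptModel(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        strand=strand,
        exons=norm(exons),
        cds=norm(cds_new),
        utr5=model.utr5,
        utr3=norm(utr3_new),
    )


def extend_annotation(
    alignments: list[AlignedRead],
    models: list[TranscriptModel],
    genome: dict[str, str],
    min_depth: int = 1,
    adjacency_gap: int = 0,
) -> tuple[dict[str, ExtensionResult], list[TranscriptModel]]:
    """Full 3'-end extension workflow: pool, reconstruct, extend, classify.

    Returns per-transcript results and the extended annotation.
    """
    track, junctions = pool_coverage(alignments)
    fragments = reconstruct_fragments(track, junctions, min_depth=min_depth)
    results = extend_transcripts(fragments, models, track, adjacency_gap)
    extended = []
    for m in models:
        res = results[m.transcript_id]
        if res.added_blocks:
            classify_extension(res, m, genome)
            extended.append(apply_extension(m, res))
        else:
            res.category = "none"
            res.utr3_length_after = res.utr3_length_before
            extended.append(m)
    n_ext = sum(1 for r in results.values() if r.extended)
    log.info("extended %d of %d transcripts", n_ext, len(models))
    return results, extended


__all__ = [
    "CoverageTrack",
    "ReconstructedFragment",
    "ExtensionResult",
    "pool_coverage",
    "select_junctions",
    "reconstruct_fragments",
    "extend_transcripts",
    "classify_extension",
    "apply_extension",
    "extend_annotation",
]
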