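"""Genomic coordinate types and annotation/alignment I/O.

All in-memory coordinates are 0-based half-open on the forward genomic
strand; the GFF3 boundary converts to/from the format's 1-based inclusive
convention.  These types are shared by every downstream stage (3'-end
extension, miRNA discovery, counting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pysam

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

#: STAR-style spliced-alignment interpretation defaults.
DEFAULT_MIN_INTRON = 35
DEFAULT_MAX_INTRON = 6000
DEFAULT_MAX_MISMATCH = 2


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed annotation input (names the offending record)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class SpliceJunction:
    """An intron call supported by spliced reads; ``intron`` is the skipped span."""

    chrom: str
    intron: GenomicInterval
    strand: str
    coverage: int = 1

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise ValueError("junction coverage must be >= 1")


@dataclass(frozen=True)
class AlignedRead:
    """One genomic alignment; >= 2 blocks means the read is spliced."""

    read_id: str
    sequence: str
    chrom: str
    strand: str
    blocks: tuple[GenomicInterval, ...]
    mismatch_count: int = 0

    def __post_init__(self) -> None:
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"read {self.read_id}: blocks unsorted/overlapping")

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    @property
    def spliced(self) -> bool:
        return len(self.blocks) > 1

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.blocks, self.blocks[1:])
        ]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS/UTR structure of one mRNA on the genome.

    ``exons``/``cds``/``utr5``/``utr3`` are sorted in genomic order
    regardless of strand; transcription order is derived from ``strand``.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: exons unsorted/overlapping")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def three_prime_end(self) -> int:
        """Genomic position of the 3' terminus (half-open end on +, start on -)."""
        return self.end if self.strand == "+" else self.start

    @property
    def utr3_length(self) -> int:
        return sum(len(iv) for iv in self.utr3)

    def cdna_length(self) -> int:
        return sum(len(iv) for iv in self.exons)

    def genomic_to_cdna(self, pos: int) -> int:
        """Map a genomic position inside an exon to 0-based cDNA coordinate."""
        offset = 0
        for ex in self.exons:
            if ex.start <= pos < ex.end:
                cpos = offset + (pos - ex.start)
                if self.strand == "-":
                    cpos = self.cdna_length() - 1 - cpos
                return cpos
            offset += len(ex)
        raise ValueError(f"{self.transcript_id}: position {pos} not exonic")

    def region_spans_cdna(self) -> dict[str, tuple[int, int]]:
        """cDNA-space half-open spans of 5UTR/CDS/3UTR (empty spans omitted)."""
        l5 = sum(len(iv) for iv in self.utr5)
        lc = sum(len(iv) for iv in self.cds)
        l3 = sum(len(iv) for iv in self.utr3)
        spans: dict[str, tuple[int, int]] = {}
        if l5:
            spans["5UTR"] = (0, l5)
        if lc:
            spans["CDS"] = (l5, l5 + lc)
        if l3:
            spans["3UTR"] = (l5 + lc, l5 + lc + l3)
        return spans


def _subtract(intervals: list[tuple[int, int]], sub: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference of sorted non-overlapping half-open interval lists."""
    out = []
    for s, e in intervals:
        cur = s
        for ss, se in sub:
            if se <= cur or ss >= e:
                continue
            if ss > cur:
                out.append((cur, ss))
            cur = max(cur, se)
        if cur < e:
            out.append((cur, e))
    return out


def derive_utrs(
    strand: str,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split (exons minus CDS) into 5' and 3' UTR by transcription direction."""
    if not cds:
        return [], []
    non_cds = _subtract(exons, cds)
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    left = [(s, e) for s, e in non_cds if e <= cds_lo]
    right = [(s, e) for s, e in non_cds if s >= cds_hi]
    if strand == "+":
        return left, right
    return right, left


def load_annotation(path: str) -> list[TranscriptModel]:
    """Read a GFF3 annotation into :class:`TranscriptModel` records.

    One model per mRNA feature.  UTRs are taken from explicit
    five_prime_UTR/three_prime_UTR rows when present, otherwise derived
    from the exon minus CDS set difference.  Coordinates convert from the
    file's 1-based inclusive convention to 0-based half-open.
    """
    mrnas: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in ("mRNA", "transcript"):
                tid = attrd.get("ID")
                if tid is None:
                    raise AnnotationError(f"{path}:{lineno}: mRNA without ID")
                mrnas[tid] = {
                    "gene": attrd.get("Parent", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "exon": [],
                    "CDS": [],
                    "five_prime_UTR": [],
                    "three_prime_UTR": [],
                }
                order.append(tid)
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = attrd.get("Parent")
                if parent is None or parent not in mrnas:
                    raise AnnotationError(
                        f"{path}:{lineno}: {ftype} without known mRNA parent"
                    )
                mrnas[parent][ftype].append((int(start) - 1, int(end)))

    models = []
    for tid in order:
        rec = mrnas[tid]
        chrom, strand = rec["chrom"], rec["strand"]
        exons = sorted(rec["exon"])
        if not exons:
            raise AnnotationError(f"{path}: mRNA {tid} has no exons")
        cds = sorted(rec["CDS"])
        utr5 = sorted(rec["five_prime_UTR"])
        utr3 = sorted(rec["three_prime_UTR"])
        if not utr5 and not utr3:
            utr5, utr3 = derive_utrs(strand, exons, cds)
        mk = lambda ivs: tuple(GenomicInterval(chrom, s, e, strand) for s, e in ivs)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene"],
                strand=strand,
                exons=mk(exons),
                cds=mk(cds),
                utr5=mk(utr5),
                utr3=mk(utr3),
            )
        )
    return models


def write_annotation(models: list[TranscriptModel], path: str) -> None:
    """Write models as GFF3; round-trip stable with :func:`load_annotation`."""
    ftype_map = [("exons", "exon"), ("cds", "CDS"),
                 ("utr5", "five_prime_UTR"), ("utr3", "three_prime_UTR")]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        genes: dict[str, list[TranscriptModel]] = {}
        for m in models:
            genes.setdefault(m.gene_id, []).append(m)
        for gene_id, ms in genes.items():
            chrom = ms[0].chrom
            strand = ms[0].strand
            gstart = min(m.start for m in ms)
            gend = max(m.end for m in ms)
            fh.write(
                f"{chrom}\tmirpollen\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for m in ms:
                fh.write(
                    f"{chrom}\tmirpollen\tmRNA\t{m.start + 1}\t{m.end}\t.\t"
                    f"{m.strand}\t.\tID={m.transcript_id};Parent={m.gene_id}\n"
                )
                for attr, ftype in ftype_map:
                    for iv in getattr(m, attr):
                        fh.write(
                            f"{chrom}\tmirpollen\t{ftype}\t{iv.start + 1}\t{iv.end}"
                            f"\t.\t{m.strand}\t.\tParent={m.transcript_id}\n"
                        )


def load_alignments(
    path: str,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_intron: int = DEFAULT_MAX_INTRON,
) -> list[AlignedRead]:
    """Read a SAM file into :class:`AlignedRead` records.

    N-cigar operations become inter-block gaps; records whose N spans
    fall outside [min_intron, max_intron] are skipped and counted, as
    are unmapped records; records whose NM tag exceeds ``max_mismatch``
    are excluded (a missing NM tag counts as 0 mismatches, with a
    warning).  Records whose cigar length disagrees with the stored
    sequence are skipped and tallied.
    """
    reads: list[AlignedRead] = []
    skipped_bad = 0
    skipped_intron = 0
    missing_nm = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        iterator = iter(sam)
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except OSError as exc:
                # htslib aborts the stream on cigar/sequence disagreement;
                # keep the records parsed so far and count the failure
                skipped_bad += 1
                log.warning("record-level parse failure in %s: %s", path, exc)
                break
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            if rec.has_tag("NM"):
                nm = rec.get_tag("NM")
            else:
                nm = 0
                missing_nm += 1
            if nm > max_mismatch:
                continue
            seq = rec.query_sequence or ""
            qlen_cigar = sum(ln for op, ln in rec.cigartuples if op in (0, 1, 4, 7, 8))
            if seq and qlen_cigar != len(seq):
                skipped_bad += 1
                log.warning("record %s: cigar/sequence length mismatch, skipped", rec.query_name)
                continue
            strand = "-" if rec.is_reverse else "+"
            chrom = rec.reference_name
            blocks: list[GenomicInterval] = []
            pos = rec.reference_start
            blk_start = pos
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8, 2):  # M/=/X/D consume reference
                    pos += ln
                elif op == 3:  # N: splice gap
                    if pos > blk_start:
                        blocks.append(GenomicInterval(chrom, blk_start, pos, strand))
                    pos += ln
                    blk_start = pos
            if pos > blk_start:
                blocks.append(GenomicInterval(chrom, blk_start, pos, strand))
            gaps = [b.start - a.end for a, b in zip(blocks, blocks[1:])]
            if any(g < min_intron or g > max_intron for g in gaps):
                skipped_intron += 1
                continue
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    sequence=seq,
                    chrom=chrom,
                    strand=strand,
                    blocks=tuple(blocks),
                    mismatch_count=int(nm),
                )
            )
    if missing_nm:
        log.warning("%d records lacked NM tag; mismatch count assumed 0", missing_nm)
    if skipped_bad:
        log.warning("%d records skipped for cigar/sequence disagreement", skipped_bad)
    if skipped_intron:
        log.warning(
            "%d records skipped for intron spans outside [%d, %d]",
            skipped_intron, min_intron, max_intron,
        )
    return reads


def load_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence map."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_transcript_sequence(model: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced cDNA sequence of a transcript, 5'->3' in transcription order."""
    try:
        chrom_seq = genome[model.chrom]
    except KeyError:
        raise AnnotationError(f"{model.transcript_id}: chromosome {model.chrom} absent")
    parts = []
    for ex in model.exons:
        if ex.end > len(chrom_seq):
            raise AnnotationError(
                f"{model.transcript_id}: exon [{ex.start},{ex.end}) beyond "
                f"chromosome end {len(chrom_seq)}"
            )
        parts.append(chrom_seq[ex.start : ex.end])
    seq = "".join(parts)
    return revcomp(seq) if model.strand == "-" else seq


__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AlignedRead",
    "SpliceJunction",
    "AnnotationError",
    "load_annotation",
    "write_annotation",
    "load_alignments",
    "load_fasta",
    "write_fasta",
    "extract_transcript_sequence",
    "derive_utrs",
    "revcomp",
]
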