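"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the shape of a 3-stage x 2-condition x 3-replicate
pollen study: a small genome with single-transcript genes whose 3'UTRs
are truncated in the emitted "current" annotation (geometric-tailed
truncations, median 160 nt), 3'-biased stranded read libraries over the
true transcript ends (with spliced reads over final introns), intergenic
pre-miRNA hairpins constructed to satisfy the five structural criteria
with mature-arm reads across replicates, background small-RNA classes
that each exercise one discovery filter, negative-binomial count
matrices with planted inverse miRNA/mRNA fold changes, and degradome
cleavage records at planted target sites.

Everything derives from a single seed; identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from . import mirna_discovery
from .annotation_io import (
    GenomicInterval,
    TranscriptModel,
    extract_transcript_sequence,
    revcomp,
)
from .expression_integration import CountMatrix
from .degradome_validation import CleavageRecord
from .target_prediction import TargetSite

log = logging.getLogger(__name__)

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 60_000
    n_genes: int = 30
    fraction_truncated_utr: float = 0.6
    utr_truncation_median: int = 160
    fraction_stopless: float = 0.2  # of truncated genes: CDS-involving truncations
    n_hairpins: int = 10
    n_decoys: int = 5
    stages: tuple[str, ...] = ("tetrads", "postmeiotic", "mature")
    conditions: tuple[str, ...] = ("CO", "HS")
    replicates: int = 3
    mace_depth: float = 12.0  # mean reads per gene per library
    mace_read_length: int = 40
    mace_noise_fraction: float = 0.02
    smallrna_depth: float = 30.0  # mean mature abundance per library
    nb_dispersion: float = 0.1
    planted_lfc: float = 2.0
    n_inverse_pairs: int = 6
    n_target_genes: int = 8
    degradome_fraction: float = 0.75
    hairpin_zone: int = 6_000  # reserved intergenic tail per chromosome

    @property
    def libraries(self) -> dict[str, tuple[str, str, str]]:
        design = {}
        for stage in self.stages:
            for cond in self.conditions:
                for rep in range(1, self.replicates + 1):
                    design[f"{stage}_{cond}_R{rep}"] = (stage, cond, str(rep))
        return design


def preset_config(name: str, seed: int = 1) -> SimulationConfig:
    """Named study-shape presets: tiny (fast smoke/benchmark, 3 libraries),
    default (full 18-library shape), stress (larger genome)."""
    if name == "tiny":
        return SimulationConfig(
            seed=seed, n_chromosomes=2, chrom_length=280_000, n_genes=200,
            stages=("tetrads",), conditions=("CO",), replicates=3,
            mace_depth=35.0, n_hairpins=8, n_decoys=4,
        )
    if name == "default":
        return SimulationConfig(seed=seed)
    if name == "stress":
        return SimulationConfig(
            seed=seed, n_chromosomes=4, chrom_length=120_000, n_genes=120,
            n_hairpins=30, n_decoys=10,
        )
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class PlantedHairpin:
    hairpin_id: str
    chrom: str
    start: int  # insert span on the chromosome
    end: int
    arm: str  # 5p | 3p
    mature_sequence: str
    mature_interval: GenomicInterval


@dataclass
class TruthTable:
    true_ends: dict[str, int] = field(default_factory=dict)  # tid -> 3' terminus
    truncated: dict[str, int] = field(default_factory=dict)  # tid -> removed nt
    categories: dict[str, str] = field(default_factory=dict)  # tid -> expected class
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    target_sites: list[TargetSite] = field(default_factory=list)
    de_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    inverse_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    verifiable_sites: list[tuple[str, str, int]] = field(default_factory=list)
    size_factors: dict[str, float] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.42) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _tx_to_genomic(
    model: TranscriptModel, tx_start: int, tx_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-space interval to genomic blocks (genomic order)."""
    exons = list(model.exons) if model.strand == "+" else list(model.exons)[::-1]
    blocks = []
    offset = 0
    for ex in exons:
        elen = len(ex)
        lo = max(tx_start, offset)
        hi = min(tx_end, offset + elen)
        if lo < hi:
            if model.strand == "+":
                blocks.append((ex.start + (lo - offset), ex.start + (hi - offset)))
            else:
                blocks.append((ex.end - (hi - offset), ex.end - (lo - offset)))
        offset += elen
    return sorted(blocks)


def _patch_tx(
    chrom_seq: bytearray, model: TranscriptModel, tx_start: int, seq: str
) -> None:
    """Overwrite genome bases so the transcript reads ``seq`` starting at
    transcript coordinate ``tx_start``."""
    blocks = _tx_to_genomic(model, tx_start, tx_start + len(seq))
    payload = seq if model.strand == "+" else revcomp(seq)
    # genomic-order concatenation of the payload across the blocks
    pos = 0
    for s, e in blocks:
        chrom_seq[s:e] = payload[pos : pos + (e - s)].encode()
        pos += e - s


def _build_gene(
    rng: np.random.Generator,
    chrom: str,
    cursor: int,
    idx: int,
    strand: str,
) -> tuple[TranscriptModel, int]:
    """One single-transcript gene laid out from ``cursor``; returns the
    model and the genomic end of the gene."""
    utr5 = int(rng.integers(40, 120))
    cds = 3 * int(rng.integers(100, 220))
    utr3 = int(rng.integers(280, 450))
    tx_len = utr5 + cds + utr3
    n_exons = int(rng.integers(1, 5))
    # split points away from the CDS end so the stop codon stays intact
    candidates = [
        p for p in range(60, tx_len - 60)
        if not (utr5 + cds - 15 <= p <= utr5 + cds + 15)
    ]
    splits = sorted(rng.choice(candidates, size=n_exons - 1, replace=False)) if n_exons > 1 else []
    introns = [int(rng.integers(60, 200)) for _ in splits]

    bounds = [0] + [int(s) for s in splits] + [tx_len]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
    if strand == "-":
        exon_lens = exon_lens[::-1]
        introns = introns[::-1]
    g = cursor
    exons = []
    for i, elen in enumerate(exon_lens):
        exons.append((g, g + elen))
        g += elen
        if i < len(introns):
            g += introns[i]
    exons_iv = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    tid = f"gene{idx:04d}.1"
    shell = TranscriptModel(tid, f"gene{idx:04d}", strand, exons_iv)
    cds_blocks = _tx_to_genomic(shell, utr5, utr5 + cds)
    utr5_blocks = _tx_to_genomic(shell, 0, utr5)
    utr3_blocks = _tx_to_genomic(shell, utr5 + cds, tx_len)
    mk = lambda bl: tuple(GenomicInterval(chrom, s, e, strand) for s, e in bl)
    model = TranscriptModel(
        tid, f"gene{idx:04d}", strand, exons_iv,
        cds=mk(cds_blocks), utr5=mk(utr5_blocks), utr3=mk(utr3_blocks),
    )
    return model, g


def _truncate_model(model: TranscriptModel, delta: int) -> TranscriptModel:
    """Remove ``delta`` nt from the transcript 3' end (transcript space)."""
    tx_len = model.cdna_length()
    keep = tx_len - delta
    exon_blocks = _tx_to_genomic(model, 0, keep)
    chrom, strand = model.chrom, model.strand
    mk = lambda bl: tuple(GenomicInterval(chrom, s, e, strand) for s, e in bl)

    def clip(blocks: tuple[GenomicInterval, ...]) -> tuple[GenomicInterval, ...]:
        out = []
        for b in blocks:
            for s, e in exon_blocks:
                lo, hi = max(b.start, s), min(b.end, e)
                if lo < hi:
                    out.append((lo, hi))
        return mk(sorted(out))

    return TranscriptModel(
        model.transcript_id, model.gene_id, strand,
        mk(exon_blocks), cds=clip(model.cds), utr5=clip(model.utr5),
        utr3=clip(model.utr3),
    )


def simulate_genome_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptModel], list[TranscriptModel], TruthTable]:
    """Genome, true annotation, and truncated ("current") annotation.

    Genes carry in-frame CDSs ending in a stop codon; a configured
    fraction of the truncated genes instead exercises CDS-involving
    extension classes (stop-less annotated CDS).  The truncated
    annotation shortens 3' ends by geometric-tailed deltas with the
    configured median.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    genome_arrays: dict[str, bytearray] = {}
    true_models: list[TranscriptModel] = []
    per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    gap = (120, 700)
    idx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        genome_arrays[chrom] = bytearray(
            _random_seq(rng, config.chrom_length).encode()
        )
        cursor = 300
        zone_end = config.chrom_length - config.hairpin_zone
        for _ in range(per_chrom):
            if idx >= config.n_genes:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            model, gene_end = _build_gene(rng, chrom, cursor, idx, strand)
            if gene_end + 800 > zone_end:
                break
            true_models.append(model)
            cursor = gene_end + int(rng.integers(*gap)) + 600
            idx += 1
    if idx < config.n_genes:
        raise ValueError(
            f"could not pack {config.n_genes} genes into "
            f"{config.n_chromosomes} x {config.chrom_length} nt"
        )

    # deterministic choice of truncated genes and their classes
    n_trunc = int(round(config.fraction_truncated_utr * len(true_models)))
    order = rng.permutation(len(true_models))
    trunc_idx = sorted(order[:n_trunc])
    n_stopless = int(round(config.fraction_stopless * n_trunc))
    stopless = set(trunc_idx[:n_stopless])
    p_geom = 1 - 2 ** (-1 / config.utr_truncation_median)

    truncated_models: list[TranscriptModel] = []
    for i, model in enumerate(true_models):
        arr = genome_arrays[model.chrom]
        utr5_len = sum(len(b) for b in model.utr5)
        cds_len = sum(len(b) for b in model.cds)
        utr3_len = sum(len(b) for b in model.utr3)
        tx_len = model.cdna_length()
        truth.true_ends[model.transcript_id] = model.three_prime_end
        if i not in trunc_idx:
            _patch_tx(arr, model, utr5_len + cds_len - 3, "TAA")
            truncated_models.append(model)
            truth.truncated[model.transcript_id] = 0
            truth.categories[model.transcript_id] = "none"
            continue
        if i in stopless:
            cds_cut = 3 * int(rng.integers(4, 16))
            if (i % 3) == 0:
                # pure-CDS class: the true transcript ends at the CDS end
                # and its tail is stop-free, so translation runs through
                # the whole extension without terminating
                model = _truncate_model(model, utr3_len)
                true_models[i] = model
                truth.true_ends[model.transcript_id] = model.three_prime_end
                new_len = model.cdna_length()
                _patch_tx(arr, model, new_len - cds_cut, "GCT" * (cds_cut // 3))
                _patch_tx(arr, model, new_len - cds_cut - 3, "GCA")
                delta = cds_cut
                expected = "CDS"
            else:
                # CDS+3UTR class: short true 3'UTR, truncation removes it
                # plus an in-frame CDS tail; the true stop codon sits
                # inside the extension
                short_utr = int(rng.integers(50, 90))
                model = _truncate_model(model, utr3_len - short_utr)
                true_models[i] = model
                truth.true_ends[model.transcript_id] = model.three_prime_end
                _patch_tx(arr, model, utr5_len + cds_len - 3, "TAA")
                _patch_tx(arr, model, utr5_len + cds_len - cds_cut - 3, "GCA")
                delta = short_utr + cds_cut
                expected = "CDS+3UTR"
        else:
            _patch_tx(arr, model, utr5_len + cds_len - 3, "TAA")
            cap = min(utr3_len - 30, 280)
            delta = int(min(max(rng.geometric(p_geom), 10), cap))
            expected = "3UTR"
        truncated_models.append(_truncate_model(model, delta))
        truth.truncated[model.transcript_id] = delta
        truth.categories[model.transcript_id] = expected

    genome = {c: arr.decode() for c, arr in genome_arrays.items()}
    return genome, true_models, truncated_models, truth


# ---------------------------------------------------------------------------
# 3'-end (MACE-style) libraries
# ---------------------------------------------------------------------------

def simulate_mace_reads(
    genome: dict[str, str],
    true_models: list[TranscriptModel],
    config: SimulationConfig,
) -> dict[str, list]:
    """Per-library synthetic 3'-biased alignments.

    Reads cluster in the final ~300 nt of each true transcript, half of
    them ending exactly at the 3' terminus (the 3'-tag property); reads
    crossing final introns come out spliced.  A small intergenic noise
    fraction is added.  Returns library -> list of pysam-style records
    as (read_id, chrom, strand, blocks, sequence).
    """
    rng = np.random.default_rng(config.seed + 1)
    libraries: dict[str, list] = {}
    window = 300
    rl = config.mace_read_length
    for lib in config.libraries:
        records = []
        rid = 0
        for model in true_models:
            tx_len = model.cdna_length()
            lam = config.mace_depth * float(rng.lognormal(0.0, 0.35))
            depth = int(rng.poisson(lam))
            for _ in range(depth):
                if rng.random() < 0.5:
                    end = tx_len
                else:
                    end = tx_len - int(rng.integers(0, window - rl))
                start = max(0, min(end - rl, tx_len - rl))
                end = start + rl
                blocks = _tx_to_genomic(model, start, end)
                seq = "".join(
                    genome[model.chrom][s:e] for s, e in blocks
                )
                records.append(
                    (f"{lib}.r{rid}", model.chrom, model.strand,
                     tuple(blocks), seq if model.strand == "+" else seq)
                )
                rid += 1
        n_noise = int(config.mace_noise_fraction * len(records))
        chroms = sorted(genome)
        for _ in range(n_noise):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(0, len(genome[chrom]) - rl))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                (f"{lib}.r{rid}", chrom, strand,
                 ((pos, pos + rl),), genome[chrom][pos : pos + rl])
            )
            rid += 1
        libraries[lib] = records
    return libraries


def write_sam(
    records: list,
    genome: dict[str, str],
    path: str,
) -> None:
    """Write (read_id, chrom, strand, blocks, sequence) records as SAM."""
    chroms = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read_id, chrom, strand, blocks, seq in records:
            a = pysam.AlignedSegment()
            a.query_name = read_id
            a.reference_id = tid[chrom]
            a.reference_start = blocks[0][0]
            a.flag = 16 if strand == "-" else 0
            cig = []
            prev_end = None
            for s, e in blocks:
                if prev_end is not None:
                    cig.append((3, s - prev_end))
                cig.append((0, e - s))
                prev_end = e
            a.cigartuples = cig
            a.query_sequence = seq
            a.mapping_quality = 255
            a.set_tag("NM", 0)
            out.write(a)


# ---------------------------------------------------------------------------
# planted hairpins + small-RNA libraries
# ---------------------------------------------------------------------------

_ARM_LEN = 40
_LOOP = "CAACA"  # 5 nt, cannot pair with itself
# mature offset within the insert, per arm hypothesis (see design note in
# docs: read at window position 70 (3p) or 20 (5p) keeps the whole stem
# inside the excised window with extent >= 75% of 111 nt)
_MATURE_OFFSET = {"3p": 60, "5p": 4}
_MATURE_LEN = 21


def _design_hairpin(
    rng: np.random.Generator, arm: str, max_tries: int = 40
) -> tuple[str, str]:
    """A stem-loop insert whose mature read passes all five criteria
    under the built-in folder (checked by construction + evaluation)."""
    for _ in range(max_tries):
        arm5 = _random_seq(rng, _ARM_LEN, gc=0.62)
        insert = arm5 + _LOOP + revcomp(arm5)
        off = _MATURE_OFFSET[arm]
        mature = insert[off : off + _MATURE_LEN]
        # emulate the genomic excision: flanks around the insert
        left = _random_seq(rng, 30, gc=0.35)
        right = _random_seq(rng, 30, gc=0.35)
        ctx = left + insert + right
        m0 = 30 + off
        if arm == "3p":
            w = ctx[m0 - 70 : m0 + _MATURE_LEN + 20]
            offset = 70
        else:
            w = ctx[m0 - 20 : m0 + _MATURE_LEN + 70]
            offset = 20
        window = mirna_discovery.HairpinWindow(
            read_sequence=mature,
            interval=GenomicInterval("x", 0, len(w), "+"),
            arm=arm, window_sequence=w, read_offset=offset,
        )
        ev = mirna_discovery.fold_and_evaluate(window)
        if ev.passed:
            return insert, mature
    raise RuntimeError("hairpin design failed after bounded retries")


def simulate_hairpins_smallrna(
    genome: dict[str, str],
    config: SimulationConfig,
    exonic_pool: list[str] | None = None,
) -> tuple[dict[str, str], dict[str, list[str]], list[tuple[str, str]], TruthTable]:
    """Embed designed hairpins and decoys intergenically and synthesize
    small-RNA libraries with planted matures plus background classes.

    Background read classes each exercise one discovery filter: 17/25-nt
    length rejects, total-abundance-1 singletons, rRNA contaminant
    fragments, exonic degradation fragments (``exonic_pool`` sequences),
    and shuffled decoy inserts whose reads reach the folding stage but
    fail the five criteria.
    """
    rng = np.random.default_rng(config.seed + 2)
    truth = TruthTable()
    arrays = {c: bytearray(s.encode()) for c, s in genome.items()}
    chroms = sorted(genome)
    zone_starts = {c: len(genome[c]) - config.hairpin_zone + 200 for c in chroms}
    spacing = 300

    def next_slot(i: int) -> tuple[str, int]:
        chrom = chroms[i % len(chroms)]
        slot = zone_starts[chrom] + (i // len(chroms)) * spacing
        if slot + spacing > len(genome[chrom]):
            raise ValueError("hairpin zone exhausted; enlarge chrom_length")
        return chrom, slot

    matures: list[str] = []
    slot_i = 0
    for h in range(config.n_hairpins):
        arm = "3p" if h % 2 == 0 else "5p"
        insert, mature = _design_hairpin(rng, arm)
        chrom, pos = next_slot(slot_i)
        slot_i += 1
        arrays[chrom][pos : pos + len(insert)] = insert.encode()
        off = _MATURE_OFFSET[arm]
        truth.hairpins.append(
            PlantedHairpin(
                hairpin_id=f"hp{h + 1:03d}", chrom=chrom, start=pos,
                end=pos + len(insert), arm=arm, mature_sequence=mature,
                mature_interval=GenomicInterval(
                    chrom, pos + off, pos + off + _MATURE_LEN, "+"
                ),
            )
        )
        matures.append(mature)

    decoy_reads: list[str] = []
    for d in range(config.n_decoys):
        base = _random_seq(rng, 2 * _ARM_LEN + len(_LOOP), gc=0.45)
        shuffled = "".join(rng.permutation(list(base)))
        chrom, pos = next_slot(slot_i)
        slot_i += 1
        arrays[chrom][pos : pos + len(shuffled)] = shuffled.encode()
        off = _MATURE_OFFSET["3p"]
        read = shuffled[off : off + _MATURE_LEN]
        # a decoy read must fail the five criteria at its planted locus;
        # the generator re-labels any accidental passer as planted truth
        left = bytes(arrays[chrom][pos - 70 + off : pos + off]).decode()
        w = left + shuffled[off : off + _MATURE_LEN + 20]
        window = mirna_discovery.HairpinWindow(
            read_sequence=read,
            interval=GenomicInterval(chrom, 0, len(w), "+"),
            arm="3p", window_sequence=w, read_offset=70,
        )
        if mirna_discovery.fold_and_evaluate(window).passed:
            truth.hairpins.append(
                PlantedHairpin(
                    hairpin_id=f"decoy{d + 1:03d}", chrom=chrom, start=pos,
                    end=pos + len(shuffled), arm="3p", mature_sequence=read,
                    mature_interval=GenomicInterval(
                        chrom, pos + off, pos + off + _MATURE_LEN, "+"
                    ),
                )
            )
            matures.append(read)
        else:
            decoy_reads.append(read)

    genome_out = {c: arr.decode() for c, arr in arrays.items()}

    # contaminant reference: one rRNA record plus one miRNA-typed record
    rrna = _random_seq(rng, 300, gc=0.5)
    contaminants = [(rrna, "rRNA")]
    if matures:
        contaminants.append((matures[0], "miRNA"))

    design = config.libraries
    libs = sorted(design)
    groups: dict[tuple[str, str], list[str]] = {}
    for lib, (s, c, _r) in design.items():
        groups.setdefault((s, c), []).append(lib)
    anchor_group = sorted(groups)[0]

    n = 1.0 / config.nb_dispersion

    def nb_draw(mean: float) -> int:
        return int(rng.negative_binomial(n, n / (n + mean)))

    libraries: dict[str, list[str]] = {lib: [] for lib in libs}

    def add(seq: str, lib: str, count: int) -> None:
        libraries[lib].extend([seq] * count)

    for mature in matures:
        for lib in libs:
            cnt = nb_draw(config.smallrna_depth)
            if lib in groups[anchor_group]:
                cnt = max(cnt, 1)
            add(mature, lib, cnt)
    for read in decoy_reads:
        for lib in libs:
            cnt = max(nb_draw(config.smallrna_depth / 2), 1 if lib in groups[anchor_group] else 0)
            add(read, lib, cnt)

    # background classes
    intergenic = genome_out[chroms[0]][50:1000]
    for i, ln in enumerate((17, 25)):  # length rejects
        s = intergenic[40 * i : 40 * i + ln]
        for lib in libs:
            add(s, lib, 2)
    for i in range(3):  # singletons: total abundance 1
        s = intergenic[200 + 30 * i : 200 + 30 * i + 21]
        add(s, libs[0], 1)
    for i in range(3):  # rRNA contaminant fragments
        s = rrna[10 + 25 * i : 10 + 25 * i + 21]
        for lib in libs:
            add(s, lib, 2)
    for i, s in enumerate(exonic_pool or []):  # exonic degradation fragments
        for lib in libs:
            add(s, lib, 2)

    for lib in libs:
        rng.shuffle(libraries[lib])
    return genome_out, libraries, contaminants, truth


def write_fastq(reads: list[str], path: str, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{quality * len(seq)}\n")


# ---------------------------------------------------------------------------
# planted target sites
# ---------------------------------------------------------------------------

def plant_target_sites(
    genome: dict[str, str],
    true_models: list[TranscriptModel],
    truncated_tids: set[str],
    matures: list[str],
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TargetSite]]:
    """Patch perfect complementary sites of planted matures into gene
    3'UTRs (preferring untruncated genes so target discovery does not
    depend on successful 3'-end extension).  Returns the modified genome
    and the truth sites in cDNA coordinates of the true annotation."""
    rng = np.random.default_rng(config.seed + 3)
    arrays = {c: bytearray(s.encode()) for c, s in genome.items()}
    candidates = [
        m for m in true_models
        if m.transcript_id not in truncated_tids and sum(len(b) for b in m.utr3) > 120
    ]
    if len(candidates) < config.n_target_genes:
        candidates = [m for m in true_models if sum(len(b) for b in m.utr3) > 120]
    pick = rng.permutation(len(candidates))[: config.n_target_genes]
    sites: list[TargetSite] = []
    for j, ci in enumerate(sorted(pick)):
        model = candidates[ci]
        mature = matures[j % len(matures)]
        utr5 = sum(len(b) for b in model.utr5)
        cds = sum(len(b) for b in model.cds)
        site_seq = revcomp(mature)
        tx_pos = utr5 + cds + 40 + 5 * (j % 4)
        _patch_tx(arrays[model.chrom], model, tx_pos, site_seq)
        sites.append(
            TargetSite(
                mirna=mature, transcript_id=model.transcript_id,
                start=tx_pos, end=tx_pos + len(site_seq),
                expectation=0.0, mode="cleavage", region="3UTR",
            )
        )
    return {c: a.decode() for c, a in arrays.items()}, sites


# ---------------------------------------------------------------------------
# count matrices with planted inverse regulation
# ---------------------------------------------------------------------------

def simulate_counts(
    mrna_features: list[str],
    mirna_features: list[str],
    candidate_pairs: list[tuple[str, str]],
    config: SimulationConfig,
    contrast: tuple[tuple[str, str], tuple[str, str]] | None = None,
    contrast_name: str | None = None,
) -> tuple[CountMatrix, CountMatrix, TruthTable]:
    """Negative-binomial count matrices with planted opposite-sign fold
    changes for selected miRNA-target pairs in one contrast.

    The planted truth lists *every* candidate pair whose two members end
    up with opposite-sign planted effects (cross pairs between planted
    features included), so exact-recovery comparisons are well defined.
    """
    rng = np.random.default_rng(config.seed + 4)
    design = config.libraries
    if contrast is None:
        contrast = (
            (config.stages[min(1, len(config.stages) - 1)], config.conditions[0]),
            (config.stages[0], config.conditions[0]),
        )
    (sa, ca), (sb, cb) = contrast
    name = contrast_name or f"{sa}_vs_{sb}" + ("" if ca == cb else f"_{ca}_vs_{cb}")
    libs_a = [l for l, (s, c, _r) in design.items() if (s, c) == (sa, ca)]
    libs_b = [l for l, (s, c, _r) in design.items() if (s, c) == (sb, cb)]

    truth = TruthTable()
    chosen: list[tuple[str, str]] = []
    used_m: set[str] = set()
    used_t: set[str] = set()
    for mir, tid in candidate_pairs:
        if mir in used_m or tid in used_t:
            continue
        chosen.append((mir, tid))
        used_m.add(mir)
        used_t.add(tid)
        if len(chosen) >= config.n_inverse_pairs:
            break
    effects: dict[str, float] = {}
    for k, (mir, tid) in enumerate(chosen):
        sign = 1.0 if k % 2 == 0 else -1.0
        effects[mir] = sign * config.planted_lfc
        effects[tid] = -sign * config.planted_lfc
    for feat, lfc in effects.items():
        truth.de_effects[(feat, name)] = lfc
    for mir, tid in candidate_pairs:
        em, et = effects.get(mir, 0.0), effects.get(tid, 0.0)
        if em * et < 0:
            truth.inverse_pairs.append(
                (mir, tid, "miR_up_mRNA_down" if em > 0 else "miR_down_mRNA_up")
            )

    sf = {lib: float(rng.uniform(0.7, 1.4)) for lib in design}
    truth.size_factors = sf
    n = 1.0 / config.nb_dispersion

    def matrix(features: list[str], kind: str) -> CountMatrix:
        base = rng.lognormal(math.log(80), 0.6, size=len(features))
        planted = np.array([effects.get(f, 0.0) for f in features])
        base = np.where(planted != 0.0, np.maximum(base, 60.0), base)
        data = {}
        for lib in sorted(design):
            mult = np.ones(len(features))
            if lib in libs_a:
                mult = 2.0 ** (planted / 2.0)
            elif lib in libs_b:
                mult = 2.0 ** (-planted / 2.0)
            mean = base * mult * sf[lib]
            data[lib] = rng.negative_binomial(n, n / (n + mean))
        df = pd.DataFrame(data, index=features)
        return CountMatrix(df, kind, design)

    return matrix(mrna_features, "mRNA"), matrix(mirna_features, "miRNA"), truth


# ---------------------------------------------------------------------------
# degradome records
# ---------------------------------------------------------------------------

def simulate_degradome(
    sites: list[TargetSite],
    cdnas: dict[str, str],
    config: SimulationConfig,
) -> tuple[list[CleavageRecord], TruthTable]:
    """Cleavage records for a configured fraction of true target sites
    (position opposite miRNA bases 10-11, flanked region sequence
    attached), plus off-site decoy records."""
    rng = np.random.default_rng(config.seed + 5)
    truth = TruthTable()
    records: list[CleavageRecord] = []
    n_true = int(round(config.degradome_fraction * len(sites)))
    order = rng.permutation(len(sites))
    for idx in sorted(order[:n_true]):
        s = sites[idx]
        cdna = cdnas[s.transcript_id]
        cleave0 = s.end - 10  # base paired to miRNA position 10
        region = cdna[max(0, s.start - 4) : s.end + 4]
        records.append(
            CleavageRecord(
                transcript_id=s.transcript_id,
                position=cleave0 + 1,
                tag_counts={"tags": int(rng.integers(5, 300))},
                region_sequence=region,
                cdna_sequence=cdna,
            )
        )
        truth.verifiable_sites.append((s.mirna, s.transcript_id, s.start))
    tids = sorted(cdnas)
    for d in range(3):  # decoys far from any planted site
        tid = tids[int(rng.integers(len(tids)))]
        records.append(
            CleavageRecord(
                transcript_id=tid,
                position=20 + d,
                tag_counts={"tags": int(rng.integers(1, 20))},
                region_sequence=_random_seq(rng, 29),
            )
        )
    return records, truth


__all__ = [
    "SimulationConfig",
    "TruthTable",
    "PlantedHairpin",
    "preset_config",
    "simulate_genome_annotation",
    "simulate_mace_reads",
    "simulate_hairpins_smallrna",
    "plant_target_sites",
    "simulate_counts",
    "simulate_degradome",
    "write_sam",
    "write_fastq",
]
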