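"""Read counting, differential abundance, and inverse miRNA-mRNA pairs.

mRNA counts come from a union-mode counter over 3'-end read alignments
(a read counts for a gene iff it overlaps exons of that gene and of no
other).  Differential abundance uses either imported external result
tables (the fidelity path) or the built-in surrogate test: median-of-
ratios size factors, Welch's t on log2(normalized + 1), and Benjamini-
Hochberg adjustment.  Inversely regulated miRNA-mRNA pairs are target
pairs where both members are significant in the same contrast with
opposite-sign fold changes.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import AlignedRead, TranscriptModel
from .target_prediction import TargetSite

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class CountMatrix:
    """Features x libraries integer counts with a replicate design."""

    counts: pd.DataFrame  # index: feature ids, columns: library ids
    kind: str  # mRNA | miRNA
    design: dict[str, tuple[str, str, str]]  # library -> (stage, condition, replicate)

    def __post_init__(self) -> None:
        missing = [c for c in self.counts.columns if c not in self.design]
        if missing:
            raise ValueError(f"design does not cover libraries: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def group_libraries(self, stage: str, condition: str) -> list[str]:
        return [
            lib
            for lib, (s, c, _r) in self.design.items()
            if s == stage and c == condition and lib in self.counts.columns
        ]


@dataclass
class DEResult:
    feature: str
    log2fc: float
    pvalue: float
    padj: float
    contrast: str
    source: str = "builtin"  # builtin | imported


@dataclass(frozen=True)
class InversePair:
    mirna: str
    transcript: str
    contrast: str
    direction: str  # miR_up_mRNA_down | miR_down_mRNA_up
    regions: tuple[str, ...] = ()


@dataclass
class CountingReport:
    """Per-library accounting: assigned + ambiguous + unassigned = aligned."""

    per_library: dict[str, dict[str, int]] = field(default_factory=dict)


def count_mrna_reads(
    alignments_by_library: dict[str, list[AlignedRead]],
    models: list[TranscriptModel],
    design: dict[str, tuple[str, str, str]],
    stranded: bool = True,
) -> tuple[CountMatrix, CountingReport]:
    """Union-mode counting of reads onto genes.

    A read counts for gene G iff its blocks overlap exons of G and of no
    other gene; ambiguous and zero-overlap reads are discarded and
    tallied in the report.
    """
    for lib in alignments_by_library:
        if lib not in design:
            raise ValueError(f"library {lib!r} absent from design")
    exon_index: dict[str, list[tuple[int, int, str, str]]] = defaultdict(list)
    gene_ids: list[str] = []
    seen = set()
    for m in models:
        if m.gene_id not in seen:
            seen.add(m.gene_id)
            gene_ids.append(m.gene_id)
        for ex in m.exons:
            exon_index[m.chrom].append((ex.start, ex.end, m.strand, m.gene_id))

    report = CountingReport()
    columns = {}
    for lib, reads in alignments_by_library.items():
        counts = dict.fromkeys(gene_ids, 0)
        assigned = ambiguous = unassigned = 0
        for read in reads:
            genes = set()
            for s, e, strand, gid in exon_index.get(read.chrom, []):
                if stranded and strand != read.strand:
                    continue
                if any(b.start < e and s < b.end for b in read.blocks):
                    genes.add(gid)
            if len(genes) == 1:
                counts[genes.pop()] += 1
                assigned += 1
            elif genes:
                ambiguous += 1
            else:
                unassigned += 1
        columns[lib] = counts
        report.per_library[lib] = {
            "aligned": len(reads),
            "assigned": assigned,
            "ambiguous": ambiguous,
            "unassigned": unassigned,
        }
    df = pd.DataFrame(columns, dtype=int).reindex(gene_ids).fillna(0).astype(int)
    return CountMatrix(df, "mRNA", design), report


def mirna_count_matrix(
    records,
    design: dict[str, tuple[str, str, str]],
) -> CountMatrix:
    """Count matrix from collapsed miRNA records (counts collected at the
    read-collapsing step)."""
    data = {
        r.name: {lib: r.abundance.get(lib, 0) for lib in design} for r in records
    }
    df = pd.DataFrame(data).T.reindex(columns=sorted(design)).fillna(0).astype(int)
    return CountMatrix(df, "miRNA", design)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over features of count_ij / geometric-mean_i,
    restricted to features with no zero count.  If no such feature
    exists, falls back to total-count ratios with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need >= 2 libraries")
    arr = counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if nonzero.sum() == 0:
        log.warning("no feature without zeros; using total-count size factors")
        totals = arr.sum(axis=0)
        f = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(f, index=counts.columns)
    sub = arr[nonzero]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations)."""
    from scipy.special import polygamma

    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tg = float(polygamma(1, x))
        dtg = float(polygamma(2, x))
        step = tg * (1 - tg / y) / dtg
        x += step
        if abs(step) < 1e-8 * x:
            break
    return max(x, 1e-8)


def _moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-feature variances toward a common
    prior (scaled inverse chi-square), returning posterior variances and
    the prior degrees of freedom."""
    from scipy.special import polygamma, psi

    ok = s2 > 0
    if ok.sum() < 3:
        return s2, 0.0
    z = np.log(s2[ok])
    var_z = float(np.var(z, ddof=1))
    resid = var_z - float(polygamma(1, df / 2))
    if resid <= 0:
        d0 = np.inf
        s0 = math.exp(float(np.mean(z)) - float(psi(df / 2)) + math.log(df / 2))
        post = np.full_like(s2, s0)
        return post, d0
    d0 = 2 * _trigamma_inverse(resid)
    log_s0 = (
        float(np.mean(z))
        - float(psi(df / 2)) + math.log(df / 2)
        + float(psi(d0 / 2)) - math.log(d0 / 2)
    )
    s0 = math.exp(log_s0)
    post = (d0 * s0 + df * s2) / (d0 + df)
    return post, d0


def differential_test(
    matrix: CountMatrix,
    contrast: tuple[tuple[str, str], tuple[str, str]],
    contrast_name: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    method: str = "moderated",
) -> list[DEResult]:
    """Surrogate differential-abundance test for one contrast.

    ``contrast`` is ((stageA, conditionA), (stageB, conditionB)); log2
    fold change is A minus B, so a positive value means higher in the
    first-named group.  Counts are normalized by median-of-ratios size
    factors and log2(normalized + 1)-transformed.  The default
    ``moderated`` method uses a pooled-variance t-statistic with
    empirical-Bayes variance shrinkage across features (the information
    sharing that makes small-replicate designs workable, in the spirit of
    the count-model tools this test stands in for); ``welch`` runs a
    plain per-feature Welch t-test.  BH adjustment runs across tested
    features; all-zero features are excluded.
    """
    (sa, ca), (sb, cb) = contrast
    libs_a = matrix.group_libraries(sa, ca)
    libs_b = matrix.group_libraries(sb, cb)
    if len(libs_a) < 2 or len(libs_b) < 2:
        raise ValueError("builtin test needs >= 2 replicates per group")
    name = contrast_name or f"{sa}_{ca}_vs_{sb}_{cb}"
    f = size_factors(matrix.counts[libs_a + libs_b])
    norm = matrix.counts[libs_a + libs_b] / f
    logn = np.log2(norm + 1.0)
    keep = matrix.counts[libs_a + libs_b].sum(axis=1) > 0
    logn = logn[keep]
    a = logn[libs_a].to_numpy()
    b = logn[libs_b].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    if method == "welch":
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
    elif method == "moderated":
        df = na + nb - 2
        s2 = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / df
        s2_post, d0 = _moderate_variances(s2, df)
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / se
        df_total = df + (d0 if np.isfinite(d0) else 10**6)
        p = 2 * stats.t.sf(np.abs(t), df_total)
        p = np.where(np.isnan(p), 1.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return [
        DEResult(feat, float(l), float(pv), float(pa), name, "builtin")
        for feat, l, pv, pa in zip(logn.index, lfc, p, padj)
    ]


def import_de_table(path: str, source: str = "imported") -> list[DEResult]:
    """Read an external differential-expression table with columns
    feature, log2fc, pvalue, padj, contrast."""
    df = pd.read_csv(path, sep="\t")
    required = ["feature", "log2fc", "pvalue", "padj", "contrast"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    return [
        DEResult(
            str(r.feature), float(r.log2fc), float(r.pvalue), float(r.padj),
            str(r.contrast), source,
        )
        for r in df.itertuples()
    ]


def find_inverse_pairs(
    de_mirna: list[DEResult],
    de_mrna: list[DEResult],
    sites: list[TargetSite],
    alpha: float = DEFAULT_ALPHA,
    min_lfc: float = 0.0,
) -> list[InversePair]:
    """Inversely regulated miRNA-mRNA pairs in one contrast.

    A pair is reported iff it appears in the target-site table, both
    members have padj < alpha (and |log2fc| >= min_lfc), and the fold
    changes have opposite signs.
    """
    contrasts = {d.contrast for d in de_mirna} | {d.contrast for d in de_mrna}
    if len(contrasts) > 1:
        raise ValueError(f"mixed contrasts in DE input: {sorted(contrasts)}")
    contrast = contrasts.pop() if contrasts else ""
    sig_mir = {
        d.feature: d
        for d in de_mirna
        if d.padj < alpha and abs(d.log2fc) >= min_lfc and d.log2fc != 0
    }
    sig_mrna = {
        d.feature: d
        for d in de_mrna
        if d.padj < alpha and abs(d.log2fc) >= min_lfc and d.log2fc != 0
    }
    pair_regions: dict[tuple[str, str], set[str]] = defaultdict(set)
    for s in sites:
        if s.region:
            pair_regions[(s.mirna, s.transcript_id)].add(s.region)
        else:
            pair_regions.setdefault((s.mirna, s.transcript_id), set())
    out = []
    for (mir, tid), regions in sorted(pair_regions.items()):
        dm = sig_mir.get(mir)
        dt = sig_mrna.get(tid)
        if dm is None or dt is None:
            continue
        if dm.log2fc * dt.log2fc >= 0:
            continue
        direction = "miR_up_mRNA_down" if dm.log2fc > 0 else "miR_down_mRNA_up"
        out.append(InversePair(mir, tid, contrast, direction, tuple(sorted(regions))))
    return out


def summarize_functional(
    pairs: list[InversePair],
    term_map: dict[str, list[str]],
    min_genes: int = 5,
) -> pd.DataFrame:
    """Per-term counts of distinct target mRNAs among inverse pairs,
    split by regulation direction.

    ``term_map`` maps feature id -> ontology terms (multi-assignment
    allowed; each term counts the mRNA once).  Unmapped features count
    under ``unassigned``.  The ``headline`` column marks terms with at
    least ``min_genes`` distinct mRNAs; the full table is retained.
    """
    term_dir_genes: dict[tuple[str, str], set[str]] = defaultdict(set)
    for p in pairs:
        terms = term_map.get(p.transcript, ["unassigned"])
        for term in terms:
            term_dir_genes[(term, p.direction)].add(p.transcript)
    term_genes: dict[str, set[str]] = defaultdict(set)
    for (term, _d), genes in term_dir_genes.items():
        term_genes[term] |= genes
    rows = [
        {
            "term": term,
            "direction": direction,
            "n_mrnas": len(genes),
            "headline": len(term_genes[term]) >= min_genes,
        }
        for (term, direction), genes in sorted(term_dir_genes.items())
    ]
    return pd.DataFrame(rows, columns=["term", "direction", "n_mrnas", "headline"])


def write_network(pairs: list[InversePair], path: str) -> None:
    """Edge list (graph exchange, GML) of miRNA -> mRNA regulation."""
    import networkx as nx

    g = nx.DiGraph()
    for p in pairs:
        g.add_node(p.mirna, kind="miRNA")
        g.add_node(p.transcript, kind="mRNA")
        g.add_edge(
            p.mirna, p.transcript,
            direction=p.direction, contrast=p.contrast,
        )
    nx.write_gml(g, path)


__all__ = [
    "CountMatrix",
    "DEResult",
    "InversePair",
    "CountingReport",
    "count_mrna_reads",
    "mirna_count_matrix",
    "size_factors",
    "differential_test",
    "import_de_table",
    "find_inverse_pairs",
    "summarize_functional",
    "write_network",
]
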