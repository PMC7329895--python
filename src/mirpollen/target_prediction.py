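"""miRNA target-site prediction with the classic plant penalty score.

The expectation of a miRNA:mRNA duplex is a penalty sum over alignment
columns — mismatch 1.0, G:U wobble 0.5, gap 2.0 — with penalties at
miRNA positions 2-13 (1-based from the 5' end) doubled.  Central
complementarity decides the inhibition mode: any mismatch or gap at
miRNA positions 9-11 implies translational inhibition, otherwise
cleavage.  Sites with expectation > 3 or translational mode are removed,
and at most 500 lowest-expectation sites are kept per miRNA.

The search enumerates every alignment with up to two gaps at every cDNA
offset (exhaustive-equivalent; alignments are canonical in that they
never start or end with a gap column, which could only add penalty).
Penalties
are handled as integer half-units internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import TranscriptModel, revcomp

log = logging.getLogger(__name__)

# integer penalties in half-units (mismatch 1.0 -> 2, G:U 0.5 -> 1, gap 2.0 -> 4)
PEN_MISMATCH = 2
PEN_WOBBLE = 1
PEN_GAP = 4
DOUBLE_LO, DOUBLE_HI = 1, 12  # 0-based miRNA positions with doubled penalty (2..13)
CENTRAL = (8, 9, 10)  # 0-based positions 9-11: cleavage requires perfect pairing
DEFAULT_MAX_EXPECTATION = 3.0
DEFAULT_MAX_TARGETS = 500
MAX_GAPS = 2

_INT = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_BIG = 10**6


@dataclass
class TargetSite:
    """One predicted miRNA-mRNA interaction on cDNA coordinates."""

    mirna: str
    transcript_id: str
    start: int  # 0-based half-open on the cDNA
    end: int
    expectation: float
    mode: str  # cleavage | translation
    region: str | None = None  # 5UTR | CDS | 3UTR, set by annotation
    alignment: tuple[str, str] | None = None  # (miRNA 5'->3', site revcomp)


def _mult(i: int) -> int:
    return 2 if DOUBLE_LO <= i <= DOUBLE_HI else 1


def _column_penalty(m_base: str, rc_base: str) -> int:
    """Penalty of pairing a miRNA base with a site base, both given in
    reverse-complement space (equal characters = Watson-Crick pair)."""
    if m_base == rc_base:
        return 0
    if (m_base, rc_base) in (("G", "A"), ("T", "C")):
        return PEN_WOBBLE
    return PEN_MISMATCH


def score_duplex(
    mirna: str, site: str, alignment: tuple[str, str]
) -> tuple[float, str]:
    """Score an explicit duplex alignment.

    ``alignment`` is a pair of equal-length gapped strings: the miRNA
    5'->3' and the reverse complement of the site, '-' marking gaps.  A
    gap column takes the doubling factor of the next miRNA position.
    Returns (expectation, mode).
    """
    am, ar = alignment
    if len(am) != len(ar):
        raise ValueError("alignment rows differ in length")
    if am.replace("-", "") != mirna.upper().replace("U", "T"):
        raise ValueError("alignment inconsistent with miRNA sequence")
    if ar.replace("-", "") != revcomp(site.upper().replace("U", "T")):
        raise ValueError("alignment inconsistent with site sequence")
    total = 0
    mpos = 0  # next miRNA index to consume
    translation = False
    for cm, cr in zip(am, ar):
        if cm == "-" and cr == "-":
            raise ValueError("empty alignment column")
        if cm == "-":  # unpaired target base (gap in miRNA strand)
            total += PEN_GAP * _mult(mpos)
            if mpos in CENTRAL:
                translation = True
        elif cr == "-":  # unpaired miRNA base
            total += PEN_GAP * _mult(mpos)
            if mpos in CENTRAL:
                translation = True
            mpos += 1
        else:
            pen = _column_penalty(cm, cr)
            total += pen * _mult(mpos)
            if pen >= PEN_MISMATCH and mpos in CENTRAL:
                translation = True
            mpos += 1
    return total / 2.0, ("translation" if translation else "cleavage")


def _search_offsets(m_enc: np.ndarray, r_enc: np.ndarray, max_half: int) -> list[tuple[int, int]]:
    """Vectorized min-penalty search over all cDNA offsets.

    Dynamic program over miRNA positions with state (net shift -2..+2,
    gaps used 0..2), carried in parallel across every offset of the
    reverse-complemented cDNA.  Returns (offset, best_half_penalty) for
    offsets whose best alignment is within ``max_half``.
    """
    L, n = m_enc.shape[0], r_enc.shape[0]
    if n < L:
        return []
    # P[i, x]: penalty of pairing miRNA i with rc position x (doubled window applied)
    wob = np.zeros((4, 4), dtype=np.int64)
    pen_tab = np.full((4, 4), PEN_MISMATCH, dtype=np.int64)
    np.fill_diagonal(pen_tab, 0)
    pen_tab[_INT["G"], _INT["A"]] = PEN_WOBBLE
    pen_tab[_INT["T"], _INT["C"]] = PEN_WOBBLE
    P = pen_tab[m_enc[:, None], r_enc[None, :]]
    mult = np.array([_mult(i) for i in range(L)], dtype=np.int64)
    P = P * mult[:, None]

    n_off = n - L + 1 + MAX_GAPS  # offsets where some shift keeps us in range
    n_off = min(n_off, n)
    offs = np.arange(n_off)
    D = 2 * MAX_GAPS + 1  # shift axis: d = -2..2 stored at d+2
    cur = np.full((MAX_GAPS + 1, D, n_off), _BIG, dtype=np.int64)
    cur[0, MAX_GAPS, :] = 0

    def col(i: int, d: int) -> np.ndarray:
        # P[i, o + i + d] for all offsets, out of range -> BIG
        x = offs + i + d
        ok = (x >= 0) & (x < n)
        out = np.full(n_off, _BIG, dtype=np.int64)
        out[ok] = P[i, x[ok]]
        return out

    for i in range(L):
        gap_here = PEN_GAP * mult[i]
        # target bulges precede the pair of m[i] and do not consume a
        # miRNA base: relax within the current step (g ascending so two
        # chained bulges are reachable).  No bulge before position 0 —
        # that is just a different offset.
        if i > 0:
            for g in range(MAX_GAPS):
                for dd in range(D - 1):
                    b = cur[g, dd] + gap_here
                    np.minimum(cur[g + 1, dd + 1], b, out=cur[g + 1, dd + 1])
        nxt = np.full_like(cur, _BIG)
        for g in range(MAX_GAPS + 1):
            for dd in range(D):
                d = dd - MAX_GAPS
                v = cur[g, dd]
                if not (v < _BIG).any():
                    continue
                # pair m[i] with r[o+i+d]
                p = v + col(i, d)
                np.minimum(nxt[g, dd], p, out=nxt[g, dd])
                # m[i] unpaired (gap in the target strand): d-1, g+1.
                # Alignments are canonical: they never start or end with
                # a gap column, so terminal miRNA bases must pair.
                if 0 < i < L - 1 and g < MAX_GAPS and dd - 1 >= 0:
                    u = v + gap_here
                    np.minimum(nxt[g + 1, dd - 1], u, out=nxt[g + 1, dd - 1])
        cur = nxt
    best = cur.min(axis=(0, 1))
    return [(int(o), int(b)) for o, b in zip(offs, best) if b <= max_half]


def _align_one(
    m: str, r: str, offset: int, max_gaps: int = MAX_GAPS
) -> tuple[int, int, tuple[str, str], bool] | None:
    """Exact min-penalty alignment at one offset (small DP with traceback).

    Returns (half_penalty, net_shift, (aligned_mirna, aligned_rc),
    central_hit) or None when no alignment fits in the sequence.
    """
    L, n = len(m), len(r)
    # state: (i consumed, d shift, g gaps) -> (cost, backpointer)
    start = (0, 0, 0)
    table: dict[tuple[int, int, int], tuple[int, tuple | None, str]] = {
        start: (0, None, "")
    }
    frontier = [start]
    for _step in range(3 * L + 6):
        if not frontier:
            break
        new_frontier = []
        for state in frontier:
            i, d, g = state
            cost = table[state][0]
            if i == L:
                continue
            x = offset + i + d
            moves = []
            if 0 <= x < n:
                moves.append(((i + 1, d, g), _column_penalty(m[i], r[x]) * _mult(i), "P"))
            if g < max_gaps:
                if 0 < i < L - 1:  # canonical: no terminal gap columns
                    moves.append(((i + 1, d - 1, g + 1), PEN_GAP * _mult(i), "U"))
                if i > 0:
                    moves.append(((i, d + 1, g + 1), PEN_GAP * _mult(i), "B"))
            for nstate, pen, op in moves:
                ncost = cost + pen
                old = table.get(nstate)
                if old is None or ncost < old[0]:
                    table[nstate] = (ncost, state, op)
                    new_frontier.append(nstate)
        frontier = new_frontier
    finals = [(c[0], s) for s, c in table.items() if s[0] == L]
    if not finals:
        return None
    best_cost, best_state = min(finals, key=lambda t: (t[0], t[1][1]))
    # traceback
    ops = []
    s = best_state
    while table[s][1] is not None:
        _, prev, op = table[s]
        ops.append(op)
        s = prev
    ops.reverse()
    am, ar = [], []
    i, d = 0, 0
    central_hit = False
    for op in ops:
        if op == "P":
            x = offset + i + d
            am.append(m[i])
            ar.append(r[x])
            if _column_penalty(m[i], r[x]) >= PEN_MISMATCH and i in CENTRAL:
                central_hit = True
            i += 1
        elif op == "U":
            am.append(m[i])
            ar.append("-")
            if i in CENTRAL:
                central_hit = True
            i += 1
            d -= 1
        else:  # B
            x = offset + i + d
            am.append("-")
            ar.append(r[x])
            if i in CENTRAL:
                central_hit = True
            d += 1
    return best_cost, best_state[1], ("".join(am), "".join(ar)), central_hit


def predict_targets(
    mirnas: dict[str, str],
    cdnas: dict[str, str],
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
    max_targets: int = DEFAULT_MAX_TARGETS,
    allow_translation: bool = False,
) -> list[TargetSite]:
    """Predict and filter target sites of each miRNA on a cDNA set.

    Sites with expectation > ``max_expectation`` are removed, as are
    translational-inhibition sites unless ``allow_translation``.  If a
    miRNA exceeds ``max_targets`` surviving sites, the lowest-expectation
    ones are kept (ties broken by transcript id, then lower coordinate).
    """
    max_half = int(round(max_expectation * 2))
    sites: list[TargetSite] = []
    for name in sorted(mirnas):
        m = mirnas[name].upper().replace("U", "T")
        m_enc = np.array([_INT[c] for c in m], dtype=np.int64)
        found: list[TargetSite] = []
        for tid in sorted(cdnas):
            c = cdnas[tid].upper().replace("U", "T")
            if len(c) < len(m):
                continue
            r = revcomp(c)
            r_enc = np.array([_INT[b] for b in r], dtype=np.int64)
            for offset, _half in _search_offsets(m_enc, r_enc, max_half):
                res = _align_one(m, r, offset)
                if res is None:
                    continue
                half, shift, aln, central_hit = res
                if half > max_half:
                    continue
                mode = "translation" if central_hit else "cleavage"
                if mode == "translation" and not allow_translation:
                    continue
                site_len = len(m) + shift
                n = len(c)
                start = n - (offset + site_len)
                end = n - offset
                if start < 0:
                    continue
                found.append(
                    TargetSite(
                        mirna=name,
                        transcript_id=tid,
                        start=start,
                        end=end,
                        expectation=half / 2.0,
                        mode=mode,
                        alignment=aln,
                    )
                )
        found.sort(key=lambda s: (s.expectation, s.transcript_id, s.start))
        sites.extend(found[:max_targets])
    return sites


REQUIRED_COLUMNS = {
    "miRNA": ("mirna", "mirna_acc.", "mirna_acc"),
    "Target": ("target", "target_acc.", "target_acc", "transcript"),
    "Target_start": ("target_start", "start"),
    "Target_end": ("target_end", "end"),
    "Expectation": ("expectation",),
    "Inhibition": ("inhibition",),
}


def import_prediction_table(
    path: str,
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
    allow_translation: bool = False,
) -> list[TargetSite]:
    """Import an external target-prediction table (psRNATarget-style TSV)
    and apply the same expectation/mode filters as :func:`predict_targets`.

    Input coordinates are 1-based inclusive; they convert to 0-based
    half-open internally.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for canonical, aliases in REQUIRED_COLUMNS.items():
        for a in aliases:
            if a in lower:
                colmap[canonical] = lower[a]
                break
        else:
            raise ValueError(f"prediction table is missing column {canonical!r}")
    sites = []
    for _, row in df.iterrows():
        exp = float(row[colmap["Expectation"]])
        mode_raw = str(row[colmap["Inhibition"]]).strip().lower()
        mode = "cleavage" if "cleav" in mode_raw else "translation"
        if exp > max_expectation:
            continue
        if mode == "translation" and not allow_translation:
            continue
        sites.append(
            TargetSite(
                mirna=str(row[colmap["miRNA"]]),
                transcript_id=str(row[colmap["Target"]]),
                start=int(row[colmap["Target_start"]]) - 1,
                end=int(row[colmap["Target_end"]]),
                expectation=exp,
                mode=mode,
            )
        )
    return sites


def export_prediction_table(sites: list[TargetSite], path: str) -> None:
    """Write sites in the tabular dialect read by
    :func:`import_prediction_table` (1-based inclusive coordinates)."""
    rows = [
        {
            "miRNA": s.mirna,
            "Target": s.transcript_id,
            "Target_start": s.start + 1,
            "Target_end": s.end,
            "Expectation": s.expectation,
            "Inhibition": s.mode.capitalize(),
            "Region": s.region or "",
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_REGION_ORDER = {"5UTR": 0, "CDS": 1, "3UTR": 2}


def annotate_site_region(site: TargetSite, model: TranscriptModel) -> str:
    """Label the transcript region containing the majority of the site's
    bases; an exact tie goes to the more 3' region."""
    spans = model.region_spans_cdna()
    total = model.cdna_length()
    if site.end > total:
        raise ValueError(
            f"site {site.mirna}->{site.transcript_id} [{site.start},{site.end}) "
            f"beyond cDNA length {total}"
        )
    best_region = None
    best_key = None
    for region, (s, e) in spans.items():
        ov = min(site.end, e) - max(site.start, s)
        if ov <= 0:
            continue
        key = (ov, _REGION_ORDER[region])
        if best_key is None or key > best_key:
            best_key = key
            best_region = region
    if best_region is None:
        raise ValueError(
            f"site {site.mirna}->{site.transcript_id} overlaps no annotated region"
        )
    site.region = best_region
    return best_region


def annotate_regions(
    sites: list[TargetSite], models: list[TranscriptModel]
) -> list[TargetSite]:
    by_id = {m.transcript_id: m for m in models}
    for s in sites:
        annotate_site_region(s, by_id[s.transcript_id])
    return sites


__all__ = [
    "TargetSite",
    "score_duplex",
    "predict_targets",
    "import_prediction_table",
    "export_prediction_table",
    "annotate_site_region",
    "annotate_regions",
]
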