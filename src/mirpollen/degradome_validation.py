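"""Verification of predicted target sites against degradome cleavage data.

A predicted site is verified when the site sequence plus 4 nt of flank on
each side (28-30 nt for a 20-22-nt site) matches the cleavage-region
sequence at 100% identity.  Two modes cover the two ways cleavage
evidence is published: ``sequence_pair`` compares the context directly
against a recorded cleavage-region sequence; ``search_in_cdna`` looks
for the context inside the degradome study's cDNA and requires the
recorded cleavage position to fall inside a matched span — tolerant of
coordinate drift between annotation versions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .target_prediction import TargetSite

log = logging.getLogger(__name__)

DEFAULT_FLANK = 4


@dataclass
class CleavageRecord:
    transcript_id: str
    position: int  # 1-based cleavage position on the record's cDNA
    tag_counts: dict[str, int] = field(default_factory=dict)
    region_sequence: str | None = None  # cleavage site + flanks
    cdna_sequence: str | None = None


@dataclass
class VerificationResult:
    site: TargetSite
    matched_span: tuple[int, int] | None
    identity: float
    verified: bool
    mode: str  # sequence_pair | search_in_cdna
    clamped: bool = False


def extract_site_context(
    cdna: str, site: TargetSite, flank: int = DEFAULT_FLANK
) -> tuple[str, bool]:
    """Site sequence with up to ``flank`` nt on each side.

    Returns (context, clamped); ``clamped`` is True when the site sits
    close enough to a cDNA end that a flank was shortened.
    """
    if site.start < 0 or site.end > len(cdna):
        raise ValueError(
            f"site [{site.start},{site.end}) outside cDNA of length {len(cdna)}"
        )
    lo = max(0, site.start - flank)
    hi = min(len(cdna), site.end + flank)
    clamped = lo != site.start - flank or hi != site.end + flank
    return cdna[lo:hi].upper(), clamped


def _identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def verify_site(
    context: str,
    record: CleavageRecord,
    site: TargetSite | None = None,
    flank: int = DEFAULT_FLANK,
    clamped: bool = False,
) -> VerificationResult:
    """Verify one site context against one cleavage record.

    ``sequence_pair`` mode (record carries a cleavage-region sequence):
    verified iff context and region sequence are identical.  ``search_in_
    cdna`` mode (record carries a full cDNA): verified iff the context
    occurs in the cDNA with the recorded cleavage position inside a
    matched span.  Any N makes a comparison fail (strict identity).
    """
    context = context.upper()
    if "N" in context:
        log.info("context contains N; not verifiable")
    if record.region_sequence is not None:
        other = record.region_sequence.upper()
        ident = _identity(context, other)
        verified = ident == 1.0 and "N" not in context
        return VerificationResult(
            site=site, matched_span=None, identity=ident,
            verified=verified, mode="sequence_pair", clamped=clamped,
        )
    if record.cdna_sequence is not None:
        cdna = record.cdna_sequence.upper()
        cleave0 = record.position - 1  # 0-based
        start = cdna.find(context)
        while start != -1:
            span = (start, start + len(context))
            if span[0] <= cleave0 < span[1] and "N" not in context:
                return VerificationResult(
                    site=site, matched_span=span, identity=1.0,
                    verified=True, mode="search_in_cdna", clamped=clamped,
                )
            start = cdna.find(context, start + 1)
        return VerificationResult(
            site=site, matched_span=None, identity=0.0,
            verified=False, mode="search_in_cdna", clamped=clamped,
        )
    raise ValueError(
        f"cleavage record for {record.transcript_id} carries neither a region "
        "sequence nor a cDNA sequence"
    )


def verify_sites(
    sites: list[TargetSite],
    cdnas: dict[str, str],
    records: list[CleavageRecord],
    flank: int = DEFAULT_FLANK,
) -> list[VerificationResult]:
    """Verify each site against every cleavage record of its transcript."""
    by_tid: dict[str, list[CleavageRecord]] = {}
    for r in records:
        by_tid.setdefault(r.transcript_id, []).append(r)
    out = []
    for s in sites:
        if s.transcript_id not in cdnas or s.transcript_id not in by_tid:
            continue
        context, clamped = extract_site_context(cdnas[s.transcript_id], s, flank)
        for rec in by_tid[s.transcript_id]:
            out.append(verify_site(context, rec, site=s, flank=flank, clamped=clamped))
    return out


def load_cleavage_table(path: str) -> list[CleavageRecord]:
    """Read a cleavage TSV: transcript, position, tags, optional
    region_sequence / cdna_sequence columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript", "position"):
        if col not in df.columns:
            raise ValueError(f"cleavage table missing column {col!r}")
    records = []
    for r in df.itertuples():
        records.append(
            CleavageRecord(
                transcript_id=str(r.transcript),
                position=int(r.position),
                tag_counts={"tags": int(getattr(r, "tags", 0) or 0)},
                region_sequence=(
                    str(r.region_sequence)
                    if "region_sequence" in df.columns
                    and pd.notna(r.region_sequence)
                    else None
                ),
                cdna_sequence=(
                    str(r.cdna_sequence)
                    if "cdna_sequence" in df.columns and pd.notna(r.cdna_sequence)
                    else None
                ),
            )
        )
    return records


def write_verification_table(results: list[VerificationResult], path: str) -> None:
    rows = []
    for v in results:
        site = v.site
        rows.append(
            {
                "miRNA": site.mirna if site else "",
                "transcript": site.transcript_id if site else "",
                "TS_on_cDNA": f"{site.start + 1}-{site.end}" if site else "",
                "matched_span": (
                    f"{v.matched_span[0] + 1}-{v.matched_span[1]}"
                    if v.matched_span
                    else ""
                ),
                "identity": v.identity,
                "verified": v.verified,
                "mode": v.mode,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


__all__ = [
    "CleavageRecord",
    "VerificationResult",
    "extract_site_context",
    "verify_site",
    "verify_sites",
    "load_cleavage_table",
    "write_verification_table",
]
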