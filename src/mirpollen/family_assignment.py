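"""miRNA family assignment against a miRBase-style hairpin reference.

Each candidate miRNA is aligned (sense strand only, ungapped sliding,
best score kept) against all reference hairpins; the modal family among
the co-optimal hits becomes its family.  Each assignment falls into one
of four overlap categories:

1. the read fully covers the seed region (positions 2-8) of an annotated
   mature miRNA on a best-hit hairpin;
2. the read overlaps an annotated mature but does not cover its seed;
3. the read aligns to a hairpin but overlaps no annotated mature;
4. the read aligns to no hairpin at all (no family).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MAX_HITS = 300
SEED_START = 1  # 0-based offset of seed on the mature (positions 2-8)
SEED_END = 8


@dataclass
class MatureAnnotation:
    mature_id: str
    start: int  # 0-based on the hairpin
    end: int  # exclusive


@dataclass
class HairpinReference:
    hairpin_id: str
    sequence: str
    family: str
    matures: list[MatureAnnotation] = field(default_factory=list)


@dataclass(frozen=True)
class HairpinHit:
    hairpin_id: str
    position: int  # 0-based offset of the read on the hairpin
    mismatches: int


@dataclass
class FamilyAssignment:
    mirna: str
    family: str | None
    category: int
    best_hits: list[HairpinHit] = field(default_factory=list)


_FAMILY_RE = re.compile(
    r"^(?:[a-z]{2,4}-)?(mir|miR|MIR|let|lin)[-]?(\d+)", re.IGNORECASE
)


def parse_family(hairpin_id: str) -> str:
    """Family name from a miRBase-dialect hairpin id.

    ``sly-MIR482a`` -> ``miR482``; ``ath-MIR160a-2`` -> ``miR160``.
    Unparseable ids are returned verbatim with a warning.
    """
    m = _FAMILY_RE.match(hairpin_id)
    if not m:
        log.warning("could not parse family from hairpin id %r", hairpin_id)
        return hairpin_id
    stem = m.group(1).lower()
    stem = "let" if stem == "let" else ("lin" if stem == "lin" else "miR")
    return f"{stem}{m.group(2)}"


def load_hairpin_reference(
    hairpin_fasta: dict[str, str],
    mature_table: list[tuple[str, str, int, int]] | None = None,
) -> list[HairpinReference]:
    """Build reference records from a hairpin id->sequence map and a
    mature-coordinate table of (hairpin_id, mature_id, start, end) rows
    with 1-based inclusive coordinates."""
    refs = {
        hid: HairpinReference(
            hid, seq.upper().replace("U", "T"), parse_family(hid)
        )
        for hid, seq in hairpin_fasta.items()
    }
    for hid, mid, start, end in mature_table or []:
        if hid not in refs:
            log.warning("mature %s references unknown hairpin %s", mid, hid)
            continue
        ref = refs[hid]
        s, e = start - 1, end
        if not (0 <= s < e <= len(ref.sequence)):
            raise ValueError(f"mature {mid} outside hairpin {hid}")
        ref.matures.append(MatureAnnotation(mid, s, e))
    return [refs[k] for k in sorted(refs)]


def align_to_hairpins(
    mirna_sequence: str,
    reference: list[HairpinReference],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_hits: int = DEFAULT_MAX_HITS,
) -> list[HairpinHit]:
    """All co-optimal sense-strand ungapped placements of the miRNA on the
    reference hairpins, scored by mismatch count (best = fewest), subject
    to the ``max_mismatches`` floor.  Hit order is deterministic in
    (hairpin_id, position), independent of reference input order."""
    query = mirna_sequence.upper().replace("U", "T")
    L = len(query)
    best = max_mismatches + 1
    hits: list[HairpinHit] = []
    for ref in sorted(reference, key=lambda r: r.hairpin_id):
        seq = ref.sequence
        for pos in range(0, len(seq) - L + 1):
            mm = sum(1 for a, b in zip(query, seq[pos : pos + L]) if a != b)
            if mm < best:
                best = mm
                hits = [HairpinHit(ref.hairpin_id, pos, mm)]
            elif mm == best:
                hits.append(HairpinHit(ref.hairpin_id, pos, mm))
    hits.sort(key=lambda h: (h.hairpin_id, h.position))
    return hits[:max_hits]


def assign_family(
    mirna_name: str,
    mirna_sequence: str,
    hits: list[HairpinHit],
    reference: list[HairpinReference],
    seed_mode: str = "coverage",
) -> FamilyAssignment:
    """Classify a miRNA's best hairpin hits into family and category.

    ``seed_mode="coverage"``: category 1 requires the aligned read to
    fully cover the mature's seed region (mature positions 2-8).
    ``seed_mode="terminus"``: category 1 requires the read 5' terminus to
    fall inside the seed region.
    """
    if not hits:
        return FamilyAssignment(mirna_name, None, 4, [])
    by_id = {r.hairpin_id: r for r in reference}
    fams = Counter(by_id[h.hairpin_id].family for h in hits)
    top = max(fams.values())
    family = min(f for f, c in fams.items() if c == top)
    if len([f for f, c in fams.items() if c == top]) > 1:
        log.info("family tie for %s resolved to %s", mirna_name, family)

    L = len(mirna_sequence)
    category = 3
    for h in hits:
        r0, r1 = h.position, h.position + L  # read span on hairpin
        for mat in by_id[h.hairpin_id].matures:
            if not (r0 < mat.end and mat.start < r1):
                continue  # no overlap with this mature
            seed0 = mat.start + SEED_START
            seed1 = mat.start + SEED_END
            if seed_mode == "coverage":
                is_cat1 = r0 <= seed0 and seed1 <= r1
            elif seed_mode == "terminus":
                is_cat1 = seed0 <= r0 < seed1
            else:
                raise ValueError(f"unknown seed_mode {seed_mode!r}")
            if is_cat1:
                return FamilyAssignment(mirna_name, family, 1, hits)
            category = 2
    return FamilyAssignment(mirna_name, family, category, hits)


def assign_families(
    mirnas: list[tuple[str, str]],
    reference: list[HairpinReference],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_hits: int = DEFAULT_MAX_HITS,
    seed_mode: str = "coverage",
) -> list[FamilyAssignment]:
    """Assign families and categories to (name, sequence) miRNA records."""
    out = []
    for name, seq in mirnas:
        hits = align_to_hairpins(seq, reference, max_mismatches, max_hits)
        out.append(assign_family(name, seq, hits, reference, seed_mode))
    return out


__all__ = [
    "HairpinReference",
    "MatureAnnotation",
    "HairpinHit",
    "FamilyAssignment",
    "parse_family",
    "load_hairpin_reference",
    "align_to_hairpins",
    "assign_family",
    "assign_families",
]
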