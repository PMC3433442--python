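"""Conserved miRNA identification against known hairpin precursors.

Tags are scanned against each precursor (sense strand only — hairpins are
oriented) at every ungapped offset, keeping placements within the mismatch
budget. Hits are assigned to mature / star / other regions with a +-3 nt
start tolerance and a >= 16 nt overlap requirement, mature taking precedence
over star. Mature-region tags sharing a (family, locus) merge into one
candidate whose representative is the most abundant member tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .preprocess import UniqueTag
from .reporting import percent
from .seqs import is_rna, to_rna

__all__ = [
    "Interval",
    "KnownPrecursor",
    "PrecursorHit",
    "MiRNACandidate",
    "map_to_precursors",
    "classify_hit",
    "group_candidates",
    "family_abundance",
]

START_TOLERANCE = 3
MIN_REGION_OVERLAP = 16


@dataclass(frozen=True)
class Interval:
    start: int
    end: int  # 0-based half-open
    arm: str | None = None  # "5p" / "3p" for matures

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class KnownPrecursor:
    id: str
    family: str
    sequence: str
    matures: tuple[Interval, ...]
    stars: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_rna(self.sequence))
        for iv in self.matures + self.stars:
            if iv.end > len(self.sequence):
                raise ValueError(f"{self.id}: interval beyond precursor end")


@dataclass(frozen=True)
class PrecursorHit:
    tag: str
    count: int
    precursor_id: str
    offset: int
    mismatches: int
    region: str = "other"  # mature / star / other


@dataclass
class MiRNACandidate:
    family: str
    precursor_id: str
    locus_start: int
    representative: str
    member_tags: list[str] = field(default_factory=list)
    total_reads: int = 0


def map_to_precursors(
    tags: list[UniqueTag],
    precursors: list[KnownPrecursor],
    max_mismatch: int = 2,
) -> list[PrecursorHit]:
    """All ungapped sense-strand placements with <= max_mismatch substitutions."""
    if not precursors:
        raise ValueError("precursor set is empty")
    hits: list[PrecursorHit] = []
    for tag in tags:
        seq = to_rna(tag.sequence)
        if not is_rna(seq):
            warnings.warn(f"tag {tag.sequence!r} contains non-ACGU characters; skipped")
            continue
        n = len(seq)
        for pre in precursors:
            ref = pre.sequence
            for offset in range(len(ref) - n + 1):
                mm = 0
                for a, b in zip(seq, ref[offset : offset + n]):
                    if a != b:
                        mm += 1
                        if mm > max_mismatch:
                            break
                if mm <= max_mismatch:
                    hit = PrecursorHit(seq, tag.count, pre.id, offset, mm)
                    hits.append(classify_hit(hit, pre))
    return hits


def classify_hit(hit: PrecursorHit, precursor: KnownPrecursor) -> PrecursorHit:
    """Assign the mature/star/other region label (mature > star > other)."""
    start, end = hit.offset, hit.offset + len(hit.tag)

    def matches(intervals: tuple[Interval, ...]) -> bool:
        return any(
            abs(start - iv.start) <= START_TOLERANCE
            and iv.overlap(start, end) >= min(MIN_REGION_OVERLAP, iv.end - iv.start)
            for iv in intervals
        )

    if matches(precursor.matures):
        region = "mature"
    elif matches(precursor.stars):
        region = "star"
    else:
        region = "other"
    return PrecursorHit(hit.tag, hit.count, hit.precursor_id, hit.offset, hit.mismatches, region)


def group_candidates(
    hits: list[PrecursorHit], precursors: list[KnownPrecursor]
) -> list[MiRNACandidate]:
    """Merge mature-region tags sharing a (family, mature locus +-3 nt).

    A tag hitting several families contributes to each; grouping then
    deduplicates by locus so length/end variants of one mature collapse
    into a single candidate.
    """
    by_id = {p.id: p for p in precursors}
    buckets: dict[tuple[str, str, int], list[PrecursorHit]] = {}
    for hit in hits:
        if hit.region != "mature":
            continue
        pre = by_id[hit.precursor_id]
        start = hit.offset
        locus = min(
            (iv for iv in pre.matures if abs(start - iv.start) <= START_TOLERANCE),
            key=lambda iv: abs(start - iv.start),
        )
        buckets.setdefault((pre.family, pre.id, locus.start), []).append(hit)

    # one candidate per (family, locus); identical tag sets hitting duplicated
    # family members collapse onto the first locus encountered
    candidates: list[MiRNACandidate] = []
    seen: dict[tuple[str, frozenset], MiRNACandidate] = {}
    for (family, pre_id, locus_start), bucket in sorted(buckets.items()):
        tag_counts: dict[str, int] = {}
        for hit in bucket:
            tag_counts[hit.tag] = hit.count
        key = (family, frozenset(tag_counts))
        if key in seen:
            continue
        rep = max(tag_counts, key=lambda t: (tag_counts[t], t))
        cand = MiRNACandidate(
            family=family,
            precursor_id=pre_id,
            locus_start=locus_start,
            representative=rep,
            member_tags=sorted(tag_counts),
            total_reads=sum(tag_counts.values()),
        )
        seen[key] = cand
        candidates.append(cand)
    return candidates


def family_abundance(candidates: list[MiRNACandidate]) -> pd.DataFrame:
    """Reads per family with one-decimal percentage of total mature reads."""
    totals: dict[str, int] = {}
    for cand in candidates:
        totals[cand.family] = totals.get(cand.family, 0) + cand.total_reads
    grand_total = sum(totals.values())
    rows = [
        {"family": fam, "reads": reads, "percent": percent(reads, grand_total)}
        for fam, reads in sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["family", "reads", "percent"])
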