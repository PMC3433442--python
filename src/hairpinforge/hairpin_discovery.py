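"""Hairpin-precursor discovery in transcripts.

Tags are mapped exactly to both transcript strands, candidate precursor
windows are excised around each mapped locus, folded with a pluggable
engine, and the resulting miRNA/miRNA* duplex is measured and scored
against the acceptance criteria:

1. supporting reads >= ``min_reads``
2. hairpin free energy dG < ``max_dg`` (strictly below -30 by default)
3. at most ``max_mature_mismatch`` unpaired mature bases in the duplex
4. at most ``max_asym_bulges`` asymmetric bulges within the duplex
5. MFEI >= ``min_mfei`` (at least 0.85 by default)

plus the structural excision bounds (minimal mature pairing, maximal mature
bulge, maximal duplex asymmetry, mature/star spacing, mature length). The
star, when not sequenced, is predicted as the duplex partner of the mature
with a 2-nt 3' overhang.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Iterable, Sequence

from .folding import FoldingEngine, MaxPairEngine, pair_table
from .preprocess import UniqueTag
from .seqs import gc_fraction, reverse_complement, to_rna

logger = logging.getLogger(__name__)

__all__ = [
    "DiscoveryParams",
    "TranscriptLocus",
    "HairpinCandidate",
    "DuplexStats",
    "AnnotationVerdict",
    "Precursor",
    "PrecursorFeature",
    "map_exact",
    "excise_candidates",
    "compute_mfei",
    "duplex_stats",
    "predict_star",
    "annotate_candidate",
    "discover",
    "homology_discover",
    "merge_candidates",
    "detect_features",
    "group_families",
]

MIN_WINDOW = 50
LOCUS_TOLERANCE = 3  # nt jitter absorbed when grouping mature loci


@dataclass(frozen=True)
class DiscoveryParams:
    """Excision and annotation thresholds (defaults per the reference tool set)."""

    min_mirna_len: int = 18
    max_mirna_len: int = 26
    min_ref_len: int = 20
    max_ref_len: int = 24
    uniqueness: int = 280
    min_space: int = 5
    max_space: int = 450
    min_mature_pair: int = 16
    max_mature_bulge: int = 3
    max_duplex_asymmetry: int = 4
    flank: int = 20
    min_reads: int = 2
    max_dg: float = -30.0
    max_mature_mismatch: int = 4
    max_asym_bulges: int = 2
    min_mfei: float = 0.85

    def __post_init__(self) -> None:
        if self.min_mirna_len > self.max_mirna_len or self.min_space > self.max_space:
            raise ValueError("min bound exceeds max bound")

    def space_grid(self) -> list[int]:
        """Spacer values tried between the tag and the putative star side."""
        grid = [5, 10, 15, 20, 25, 30, 35, 40, 50, 60, 70, 85, 100, 120,
                150, 190, 240, 300, 370, 450]
        values = [s for s in grid if self.min_space <= s <= self.max_space]
        for edge in (self.min_space, self.max_space):
            if edge not in values:
                values.append(edge)
        return sorted(values)


@dataclass(frozen=True)
class TranscriptLocus:
    transcript_id: str
    strand: str  # "+" or "-"
    start: int  # 0-based half-open, forward transcript coordinates
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-" or not 0 <= self.start < self.end:
            raise ValueError(f"bad locus {self!r}")


@dataclass(frozen=True)
class DuplexStats:
    paired: int
    mature_unpaired: int
    bulges: tuple[tuple[str, int], ...]  # (arm, run length)
    asym_bulge_count: int
    total_asymmetry: int
    space: int


@dataclass(frozen=True)
class AnnotationVerdict:
    flags: dict[str, bool]
    accepted: bool


@dataclass
class HairpinCandidate:
    """A folded excision window with its mature/star loci.

    Window coordinates (``mature_w``, ``star_w``) are on the folded sequence
    (reverse-complemented for minus-strand loci); ``locus`` and
    ``precursor_interval`` are forward transcript coordinates.
    """

    locus: TranscriptLocus  # excised window, forward coordinates
    sequence: str  # folded orientation
    dot_bracket: str
    dg: float
    gc: float
    mfei: float
    mature_w: tuple[int, int]
    star_w: tuple[int, int] | None
    mature_seq: str
    support: int
    engine: str
    stats: DuplexStats | None = None
    verdict: AnnotationVerdict | None = None

    def _to_forward(self, interval: tuple[int, int]) -> tuple[int, int]:
        a, b = interval
        if self.locus.strand == "+":
            return self.locus.start + a, self.locus.start + b
        return self.locus.end - b, self.locus.end - a

    @property
    def mature_fwd(self) -> tuple[int, int]:
        return self._to_forward(self.mature_w)

    @property
    def star_fwd(self) -> tuple[int, int] | None:
        return self._to_forward(self.star_w) if self.star_w else None

    @property
    def precursor_interval(self) -> tuple[int, int]:
        """Forward-coordinate span from mature through star (the hairpin proper)."""
        m = self.mature_fwd
        s = self.star_fwd
        if s is None:
            return m
        return min(m[0], s[0]), max(m[1], s[1])


def map_exact(
    tags: Iterable[UniqueTag],
    transcripts: dict[str, str],
    uniqueness: int = 280,
) -> dict[str, list[TranscriptLocus]]:
    """Exact matches of each tag on both strands of every transcript.

    Tags hitting more loci than ``uniqueness`` are dropped (repeat filter).
    Minus-strand matches are reported in forward coordinates with strand "-".
    """
    rna = {tid: to_rna(seq) for tid, seq in transcripts.items()}
    out: dict[str, list[TranscriptLocus]] = {}
    for tag in tags:
        seq = to_rna(tag.sequence)
        rc = reverse_complement(seq)
        loci: list[TranscriptLocus] = []
        for tid in sorted(rna):
            ref = rna[tid]
            for strand, query in (("+", seq), ("-", rc)):
                pos = ref.find(query)
                while pos != -1:
                    loci.append(TranscriptLocus(tid, strand, pos, pos + len(query)))
                    pos = ref.find(query, pos + 1)
        if len(loci) > uniqueness:
            logger.info("tag %s dropped: %d loci > uniqueness %d", seq, len(loci), uniqueness)
            continue
        if loci:
            out[seq] = loci
    return out


def excise_candidates(
    locus: TranscriptLocus, transcript: str, params: DiscoveryParams
) -> list[tuple[int, int]]:
    """Candidate window intervals (forward coordinates) around a mapped tag.

    For each trial spacer the window extends by ``space + flank`` on the
    putative star side and ``flank`` on the other, clamped to the transcript;
    windows shorter than 50 nt are skipped.
    """
    n = len(transcript)
    windows: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for space in params.space_grid():
        for star_side in ("down", "up"):
            if star_side == "down":
                w = (locus.start - params.flank, locus.end + space + params.flank)
            else:
                w = (locus.start - space - params.flank, locus.end + params.flank)
            w = (max(0, w[0]), min(n, w[1]))
            if w in seen:
                continue
            seen.add(w)
            if w[1] - w[0] < MIN_WINDOW:
                logger.debug("window %s shorter than %d nt; skipped", w, MIN_WINDOW)
                continue
            windows.append(w)
    return windows


def compute_mfei(dg: float, length: int, gc: float) -> float:
    """MFEI = (|dG| / length x 100) / (GC fraction x 100), reported positive."""
    if length <= 0:
        raise ValueError("length must be positive")
    if gc <= 0:
        raise ValueError("MFEI undefined for GC fraction 0")
    return (abs(dg) / length * 100.0) / (gc * 100.0)


def predict_star(
    table: Sequence[int], mature: tuple[int, int], overhang: int = 2
) -> tuple[int, int] | None:
    """Duplex-partner interval of the mature with a 2-nt 3' overhang.

    Partners inside the mature itself (self-pairing) are ignored. Returns
    None when fewer than 4 mature bases pair outward.
    """
    m_start, m_end = mature
    partners = [
        table[i]
        for i in range(m_start, m_end)
        if table[i] >= 0 and not m_start <= table[i] < m_end
    ]
    if len(partners) < 4:
        return None
    lo, hi = min(partners), max(partners) + 1
    hi = min(hi + overhang, len(table))
    return lo, hi


def duplex_stats(
    dot_bracket: str, mature: tuple[int, int], star: tuple[int, int]
) -> DuplexStats:
    """Pairing statistics of the mature against the star interval.

    A mature base counts as paired only when its partner lies inside the star
    interval. A bulge is a maximal unpaired run between consecutive duplex
    pairs on either arm; it is asymmetric when the opposing arm's run differs
    in length.
    """
    table = pair_table(dot_bracket)
    m_start, m_end = mature
    s_start, s_end = star
    if not (0 <= m_start < m_end <= len(table) and 0 <= s_start < s_end <= len(table)):
        raise ValueError("mature/star interval outside the structure")
    paired_positions = [
        i for i in range(m_start, m_end) if table[i] >= 0 and s_start <= table[i] < s_end
    ]
    paired = len(paired_positions)
    mature_unpaired = (m_end - m_start) - paired

    bulges: list[tuple[str, int]] = []
    asym = 0
    gap_m_total = gap_s_total = 0
    for a, b in zip(paired_positions, paired_positions[1:]):
        gap_m = b - a - 1
        gap_s = abs(table[a] - table[b]) - 1
        gap_m_total += gap_m
        gap_s_total += gap_s
        if gap_m > 0:
            bulges.append(("mature", gap_m))
        if gap_s > 0:
            bulges.append(("star", gap_s))
        if (gap_m > 0 or gap_s > 0) and gap_m != gap_s:
            asym += 1

    if s_start >= m_end:
        space = s_start - m_end
    else:
        space = m_start - s_end
    return DuplexStats(
        paired=paired,
        mature_unpaired=mature_unpaired,
        bulges=tuple(bulges),
        asym_bulge_count=asym,
        total_asymmetry=abs(gap_m_total - gap_s_total),
        space=space,
    )


def annotate_candidate(
    candidate: HairpinCandidate, stats: DuplexStats | None, params: DiscoveryParams
) -> AnnotationVerdict:
    """Per-criterion flags; accepted iff every flag holds."""
    mature_len = candidate.mature_w[1] - candidate.mature_w[0]
    if stats is None:
        stats = DuplexStats(0, mature_len, (), 0, 0, -1)
    mature_bulges = [length for arm, length in stats.bulges if arm == "mature"]
    star_len = (candidate.star_w[1] - candidate.star_w[0]) if candidate.star_w else 0
    flags = {
        "reads": candidate.support >= params.min_reads,
        "energy": candidate.dg < params.max_dg,
        "mature_mismatch": stats.mature_unpaired <= params.max_mature_mismatch,
        "asym_bulges": stats.asym_bulge_count <= params.max_asym_bulges,
        "mfei": candidate.mfei >= params.min_mfei,
        "mature_pair": stats.paired >= params.min_mature_pair,
        "mature_bulge": max(mature_bulges, default=0) <= params.max_mature_bulge,
        "asymmetry": stats.total_asymmetry <= params.max_duplex_asymmetry,
        "space": params.min_space <= stats.space <= params.max_space,
        "mature_len": params.min_mirna_len <= mature_len <= params.max_mirna_len,
        "star_span": star_len <= mature_len + params.max_duplex_asymmetry + 2,
    }
    return AnnotationVerdict(flags=flags, accepted=all(flags.values()))


def _locus_support(
    loci_by_tag: dict[str, list[TranscriptLocus]], counts: dict[str, int]
) -> dict[tuple[str, str, int], int]:
    """Read support per locus, pooling tags whose starts lie within +-3 nt."""
    starts: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for seq, loci in loci_by_tag.items():
        for locus in loci:
            starts.setdefault((locus.transcript_id, locus.strand), []).append(
                (locus.start, counts[seq])
            )
    support: dict[tuple[str, str, int], int] = {}
    for key, entries in starts.items():
        for start, _ in entries:
            support[(*key, start)] = sum(
                c for s, c in entries if abs(s - start) <= LOCUS_TOLERANCE
            )
    return support


def _evaluate_locus(
    tag_seq: str,
    locus: TranscriptLocus,
    transcript: str,
    support: int,
    params: DiscoveryParams,
    engine: FoldingEngine,
    fold_cache: dict,
) -> HairpinCandidate | None:
    """Fold candidate windows around one mapped locus; return the best candidate."""
    best: HairpinCandidate | None = None
    for w_start, w_end in excise_candidates(locus, transcript, params):
        key = (locus.transcript_id, locus.strand, w_start, w_end)
        if key in fold_cache:
            window_seq, structure, dg = fold_cache[key]
        else:
            window_seq = to_rna(transcript[w_start:w_end])
            if locus.strand == "-":
                window_seq = reverse_complement(window_seq)
            try:
                structure, dg = engine.fold(window_seq)
            except Exception:  # pragma: no cover - engine failure path
                logger.warning("folding failed for window %s; skipped", key)
                continue
            fold_cache[key] = (window_seq, structure, dg)
        if locus.strand == "+":
            mature_w = (locus.start - w_start, locus.end - w_start)
        else:
            mature_w = (w_end - locus.end, w_end - locus.start)
        gc = gc_fraction(window_seq)
        candidate = HairpinCandidate(
            locus=TranscriptLocus(locus.transcript_id, locus.strand, w_start, w_end),
            sequence=window_seq,
            dot_bracket=structure,
            dg=dg,
            gc=gc,
            mfei=compute_mfei(dg, len(window_seq), gc) if gc > 0 else 0.0,
            mature_w=mature_w,
            star_w=None,
            mature_seq=tag_seq,
            support=support,
            engine=engine.name,
        )
        table = pair_table(structure)
        star = predict_star(table, mature_w)
        stats = duplex_stats(structure, mature_w, star) if star else None
        candidate.star_w = star
        candidate.stats = stats
        candidate.verdict = annotate_candidate(candidate, stats, params)
        rank = (
            candidate.verdict.accepted,
            stats.paired if stats else 0,
            -(stats.mature_unpaired if stats else len(tag_seq)),
            -candidate.dg,
        )
        if best is None or rank > best._rank:  # type: ignore[attr-defined]
            candidate._rank = rank  # type: ignore[attr-defined]
            best = candidate
        if candidate.verdict.accepted:
            break
    return best


def discover(
    tags: Iterable[UniqueTag],
    transcripts: dict[str, str],
    params: DiscoveryParams | None = None,
    engine: FoldingEngine | None = None,
) -> list[HairpinCandidate]:
    """Run the full per-locus discovery; returns the best candidate per tag locus.

    Accepted candidates carry ``verdict.accepted == True``; rejected loci are
    retained with their per-criterion flags for the verdict table.
    """
    params = params or DiscoveryParams()
    engine = engine or MaxPairEngine()
    tags = list(tags)
    counts = {to_rna(t.sequence): t.count for t in tags}
    loci_by_tag = map_exact(tags, transcripts, params.uniqueness)
    support = _locus_support(loci_by_tag, counts)
    fold_cache: dict = {}
    out: list[HairpinCandidate] = []
    for seq in sorted(loci_by_tag):
        for locus in loci_by_tag[seq]:
            cand = _evaluate_locus(
                seq,
                locus,
                transcripts[locus.transcript_id],
                support[(locus.transcript_id, locus.strand, locus.start)],
                params,
                engine,
                fold_cache,
            )
            if cand is not None:
                out.append(cand)
    return out


def homology_discover(
    matures: dict[str, str],
    transcripts: dict[str, str],
    params: DiscoveryParams | None = None,
    engine: FoldingEngine | None = None,
) -> list[HairpinCandidate]:
    """Discovery seeded by known mature sequences instead of sequenced tags.

    Each query is given synthetic support equal to ``min_reads`` so that the
    read-count criterion reflects homology seeding rather than abundance.
    """
    params = params or DiscoveryParams()
    seeds = [UniqueTag(to_rna(seq), max(1, params.min_reads)) for seq in matures.values()]
    return discover(seeds, transcripts, params, engine)


@dataclass
class Precursor:
    """Accepted candidates merged into one hairpin locus."""

    id: str
    transcript_id: str
    strand: str
    interval: tuple[int, int]  # forward coordinates
    mature_loci: list[HairpinCandidate] = field(default_factory=list)
    star_loci: list[HairpinCandidate] = field(default_factory=list)

    @property
    def multi_mature(self) -> bool:
        return len(self.mature_loci) >= 2


@dataclass
class PrecursorFeature:
    cluster_id: str | None = None
    cluster_members: tuple[str, ...] = ()
    multi_mature_precursors: tuple[str, ...] = ()
    antisense_pairs: tuple[tuple[str, str], ...] = ()


def _near(a: tuple[int, int], b: tuple[int, int], tol: int = LOCUS_TOLERANCE) -> bool:
    return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap as a fraction of the shorter interval."""
    overlap = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    shorter = min(a[1] - a[0], b[1] - b[0])
    return overlap / shorter if shorter else 0.0


def merge_candidates(accepted: Sequence[HairpinCandidate]) -> list[Precursor]:
    """Merge accepted candidates into precursor records.

    Candidates on one transcript strand whose hairpin intervals overlap are
    one precursor. Within a precursor, mature loci within +-3 nt collapse
    (jitter variants; highest support wins) and a candidate whose mature
    matches another candidate's predicted star (+-2 nt extended to +-3) is
    recorded as that duplex's star, not as an extra mature.
    """
    by_strand: dict[tuple[str, str], list[HairpinCandidate]] = {}
    for cand in accepted:
        if not (cand.verdict and cand.verdict.accepted):
            continue
        by_strand.setdefault((cand.locus.transcript_id, cand.locus.strand), []).append(cand)

    precursors: list[Precursor] = []
    for (tid, strand), cands in sorted(by_strand.items()):
        # collapse jitter variants of the same mature locus
        cands = sorted(cands, key=lambda c: (-c.support, c.mature_fwd))
        unique: list[HairpinCandidate] = []
        for cand in cands:
            if not any(_near(cand.mature_fwd, u.mature_fwd) for u in unique):
                unique.append(cand)
        # connected components by hairpin-interval overlap
        unique.sort(key=lambda c: c.precursor_interval)
        components: list[list[HairpinCandidate]] = []
        for cand in unique:
            placed = False
            for comp in components:
                lo = min(c.precursor_interval[0] for c in comp)
                hi = max(c.precursor_interval[1] for c in comp)
                if cand.precursor_interval[0] < hi and cand.precursor_interval[1] > lo:
                    comp.append(cand)
                    placed = True
                    break
            if not placed:
                components.append([cand])
        for comp in components:
            matures: list[HairpinCandidate] = []
            stars: list[HairpinCandidate] = []
            for cand in comp:
                is_star = any(
                    other is not cand
                    and other.star_fwd is not None
                    and _overlap_frac(cand.mature_fwd, other.star_fwd) >= 0.7
                    and other.support >= cand.support
                    for other in comp
                )
                (stars if is_star else matures).append(cand)
            lo = min(c.precursor_interval[0] for c in comp)
            hi = max(c.precursor_interval[1] for c in comp)
            precursors.append(
                Precursor(
                    id=f"{tid}:{strand}:{lo}-{hi}",
                    transcript_id=tid,
                    strand=strand,
                    interval=(lo, hi),
                    mature_loci=matures,
                    star_loci=stars,
                )
            )
    return precursors


def detect_features(precursors: Sequence[Precursor]) -> PrecursorFeature:
    """Clusters, multi-mature precursors and antisense pairs among precursors."""
    if not precursors:
        raise ValueError("no accepted precursors")
    features = PrecursorFeature()

    multi = tuple(p.id for p in precursors if p.multi_mature)
    features.multi_mature_precursors = multi

    clusters: list[tuple[str, ...]] = []
    by_transcript: dict[str, list[Precursor]] = {}
    for p in precursors:
        by_transcript.setdefault(p.transcript_id, []).append(p)
    antisense: list[tuple[str, str]] = []
    for tid, group in sorted(by_transcript.items()):
        non_overlapping = [
            (a, b)
            for i, a in enumerate(group)
            for b in group[i + 1 :]
            if a.interval[1] <= b.interval[0] or b.interval[1] <= a.interval[0]
        ]
        if non_overlapping:
            members = sorted({p.id for pair in non_overlapping for p in pair})
            clusters.append(tuple(members))
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if (
                    a.strand != b.strand
                    and a.interval[0] < b.interval[1]
                    and b.interval[0] < a.interval[1]
                ):
                    antisense.append(tuple(sorted((a.id, b.id))))
    features.antisense_pairs = tuple(sorted(antisense))
    if clusters:
        features.cluster_id = "cluster1"
        features.cluster_members = clusters[0] if len(clusters) == 1 else tuple(
            m for c in clusters for m in c
        )
    # expose all clusters for callers needing more than the flagship one
    features.clusters = tuple(clusters)  # type: ignore[attr-defined]
    return features


def group_families(precursors: Sequence[Precursor], transcripts: dict[str, str],
                   min_identity: float = 0.8) -> list[list[str]]:
    """Single-linkage family grouping of precursors at >= 80% global identity."""
    seqs = {}
    for p in precursors:
        seq = to_rna(transcripts[p.transcript_id][p.interval[0]: p.interval[1]])
        if p.strand == "-":
            seq = reverse_complement(seq)
        seqs[p.id] = seq
    ids = sorted(seqs)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if SequenceMatcher(None, seqs[a], seqs[b]).ratio() >= min_identity:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values())
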