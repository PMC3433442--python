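"""miRNA target prediction by weighted penalty score.

Each transcript window of length len(miRNA) +- ``max_gaps`` is aligned
antiparallel against the miRNA by a gap-limited dynamic program minimizing
the summed penalty: mismatch 1, G:U wobble 0.5, gap 2, each doubled when the
miRNA position lies in the seed range (positions 2-13, 1-based from the
miRNA 5' end). Sites at or below the cutoff (inclusive at 3.0) are reported
with a rendered pairing string and the predicted cleavage coordinate
(transcript base opposite miRNA positions 10-11, 1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqs import is_rna, reverse_complement, to_rna

__all__ = ["ScoringScheme", "TargetSite", "score_duplex", "scan_targets", "shared_targets"]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}

_INF = float("inf")


@dataclass(frozen=True)
class ScoringScheme:
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    gap_penalty: float = 2.0
    seed_range: tuple[int, int] = (2, 13)  # 1-based, inclusive, from miRNA 5'
    seed_multiplier: float = 2.0
    max_gaps: int = 1
    cutoff: float = 3.0

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gu_penalty, self.gap_penalty, self.cutoff) < 0:
            raise ValueError("penalties and cutoff must be non-negative")

    def weight(self, mirna_pos: int) -> float:
        """Seed multiplier for a 1-based miRNA position."""
        lo, hi = self.seed_range
        return self.seed_multiplier if lo <= mirna_pos <= hi else 1.0

    def column_penalty(self, mirna_base: str, target_base: str, mirna_pos: int) -> float:
        if _COMPLEMENT[mirna_base] == target_base:
            return 0.0
        if (mirna_base, target_base) in _WOBBLE:
            return self.gu_penalty * self.weight(mirna_pos)
        return self.mismatch_penalty * self.weight(mirna_pos)


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based window start on the transcript
    window: str
    penalty: float
    pairing: str  # one symbol per column: | WC, o G:U, space mismatch, - gap
    cleavage_pos: int  # 1-based transcript coordinate opposite miRNA pos 10
    strand: str = "+"


def score_duplex(
    mirna: str, window: str, scheme: ScoringScheme | None = None
) -> tuple[float, list[tuple[int | None, int | None]]]:
    """Optimal penalty and alignment of a miRNA against one site window.

    Returns ``(penalty, columns)`` where each column is a pair of 0-based
    indices ``(mirna_index, window_index)``; None marks the gapped side. The
    window is given 5'->3' on the transcript; pairing is antiparallel.
    """
    scheme = scheme or ScoringScheme()
    mirna = to_rna(mirna)
    window = to_rna(window)
    if not (is_rna(mirna) and is_rna(window)):
        raise ValueError("non-RNA characters in miRNA or window")
    if abs(len(mirna) - len(window)) > scheme.max_gaps:
        raise ValueError("length difference exceeds max_gaps")
    m, w = len(mirna), len(window)
    site = window[::-1]  # align miRNA 5'->3' against the site 3'->5'

    # dp[g][i][j]: minimal penalty aligning mirna[:i] with site[:j] using g gaps
    G = scheme.max_gaps
    dp = [[[_INF] * (w + 1) for _ in range(m + 1)] for _ in range(G + 1)]
    dp[0][0][0] = 0.0
    for g in range(G + 1):
        for i in range(m + 1):
            for j in range(w + 1):
                cur = dp[g][i][j]
                if cur == _INF:
                    continue
                if i < m and j < w:
                    cost = cur + scheme.column_penalty(mirna[i], site[j], i + 1)
                    if cost < dp[g][i + 1][j + 1]:
                        dp[g][i + 1][j + 1] = cost
                if g < G:
                    if i < m:  # miRNA base unaligned (gap in target)
                        cost = cur + scheme.gap_penalty * scheme.weight(i + 1)
                        if cost < dp[g + 1][i + 1][j]:
                            dp[g + 1][i + 1][j] = cost
                    if j < w:  # target bulge (gap in miRNA)
                        cost = cur + scheme.gap_penalty * scheme.weight(min(i + 1, m))
                        if cost < dp[g + 1][i][j + 1]:
                            dp[g + 1][i][j + 1] = cost

    best_g = min(range(G + 1), key=lambda g: dp[g][m][w])
    penalty = dp[best_g][m][w]

    # deterministic traceback mirroring the fill order
    columns: list[tuple[int | None, int | None]] = []
    g, i, j = best_g, m, w
    while i > 0 or j > 0:
        cur = dp[g][i][j]
        if i > 0 and j > 0 and dp[g][i - 1][j - 1] + scheme.column_penalty(
            mirna[i - 1], site[j - 1], i
        ) == cur:
            columns.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif g > 0 and i > 0 and dp[g - 1][i - 1][j] + scheme.gap_penalty * scheme.weight(i) == cur:
            columns.append((i - 1, None))
            g, i = g - 1, i - 1
        else:
            columns.append((None, j - 1))
            g, j = g - 1, j - 1
    columns.reverse()
    # convert site indices back to window (5'->3') indices
    columns = [
        (mi, (w - 1 - sj) if sj is not None else None) for mi, sj in columns
    ]
    return penalty, columns


def _render(mirna: str, window: str, columns) -> str:
    symbols = []
    for mi, wi in columns:
        if mi is None or wi is None:
            symbols.append("-")
            continue
        a, b = mirna[mi], window[wi]
        if _COMPLEMENT[a] == b:
            symbols.append("|")
        elif (a, b) in _WOBBLE:
            symbols.append("o")
        else:
            symbols.append(" ")
    # columns run miRNA 5'->3'; render 3'->5' miRNA over 5'->3' site
    return "".join(reversed(symbols))


def _cleavage(columns, start: int, cleave_pos: int = 10) -> int:
    for mi, wi in columns:
        if mi == cleave_pos - 1 and wi is not None:
            return start + wi + 1  # 1-based
    # position 10 gapped: fall back to its neighbour (position 11)
    for mi, wi in columns:
        if mi == cleave_pos and wi is not None:
            return start + wi + 1
    return start + 1


def scan_targets(
    mirna_id: str,
    mirna: str,
    transcripts: dict[str, str],
    scheme: ScoringScheme | None = None,
    both_strands: bool = False,
) -> list[TargetSite]:
    """All windows at or below the penalty cutoff, best site per locus.

    Overlapping windows reporting the same site keep only the lowest-penalty
    one. Results sort by (penalty, transcript, position). With
    ``both_strands`` the reverse strand is scanned too (orientation-unknown
    transcripts) and flagged via ``strand``.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    scheme = scheme or ScoringScheme()
    mirna = to_rna(mirna)
    m = len(mirna)
    raw: list[TargetSite] = []
    for tid in sorted(transcripts):
        for strand in ("+", "-") if both_strands else ("+",):
            seq = to_rna(transcripts[tid])
            if strand == "-":
                seq = reverse_complement(seq)
            n = len(seq)
            for length in range(m - scheme.max_gaps, m + scheme.max_gaps + 1):
                if length < 1:
                    continue
                for start in range(0, n - length + 1):
                    window = seq[start : start + length]
                    penalty, columns = score_duplex(mirna, window, scheme)
                    if penalty <= scheme.cutoff:
                        raw.append(
                            TargetSite(
                                mirna_id=mirna_id,
                                transcript_id=tid,
                                start=start,
                                window=window,
                                penalty=penalty,
                                pairing=_render(mirna, window, columns),
                                cleavage_pos=_cleavage(columns, start),
                                strand=strand,
                            )
                        )
    # suppress overlapping windows of one locus, best penalty first
    raw.sort(key=lambda s: (s.penalty, s.transcript_id, s.start, len(s.window)))
    kept: list[TargetSite] = []
    for site in raw:
        clash = any(
            k.transcript_id == site.transcript_id
            and k.strand == site.strand
            and site.start < k.start + len(k.window)
            and k.start < site.start + len(site.window)
            for k in kept
        )
        if not clash:
            kept.append(site)
    return kept


def shared_targets(sites_by_mirna: dict[str, list[TargetSite]]) -> dict[str, list[str]]:
    """Transcripts targeted by two or more distinct miRNAs."""
    if len(sites_by_mirna) < 2:
        raise ValueError("shared_targets requires site lists from >= 2 miRNAs")
    hits: dict[str, set[str]] = {}
    for mirna_id, sites in sites_by_mirna.items():
        for site in sites:
            hits.setdefault(site.transcript_id, set()).add(mirna_id)
    return {
        tid: sorted(mirnas)
        for tid, mirnas in sorted(hits.items())
        if len(mirnas) >= 2
    }
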