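"""Raw FASTQ to clean, collapsed unique tags plus population summaries.

Cleaning removes a 3' adapter (best ungapped prefix match, >= 6 nt overlap,
<= 1 mismatch), then applies quality, N and length filters and converts the
retained inserts to the RNA alphabet. "Low quality" is defined here as mean
Phred < ``min_mean_q`` or more than ``max_n`` N calls; both are configurable.
Reads in which no adapter is found are kept if the full read already lies
within the length bounds, unless ``require_adapter`` is set.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .reporting import percent
from .seqs import to_rna

__all__ = [
    "RawRead",
    "UniqueTag",
    "parse_fastq",
    "find_adapter",
    "clean_reads",
    "collapse",
    "size_distribution",
    "first_base_profile",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
]

PHRED_OFFSET = 33


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    @property
    def mean_quality(self) -> float:
        if not self.quality:
            return 0.0
        return sum(ord(c) - PHRED_OFFSET for c in self.quality) / len(self.quality)


@dataclass(frozen=True, order=True)
class UniqueTag:
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


def parse_fastq(path: str | Path) -> Iterator[RawRead]:
    """Minimal Sanger-FASTQ parser; raises with the record index on malformed input."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        record = 0
        while True:
            header = handle.readline()
            if not header:
                return
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record at index {record}")
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record at index {record}: length mismatch")
            yield RawRead(header[1:].split()[0], seq.upper(), qual)
            record += 1


def find_adapter(
    sequence: str, adapter: str, min_overlap: int = 6, max_mismatch: int = 1
) -> int | None:
    """Start of the best ungapped 3' adapter match, or None.

    Every suffix position is compared against the adapter prefix of the
    overlapping length; the match with the fewest mismatches wins, ties going
    to the leftmost (longest-insert-removing ... i.e. earliest) position.
    """
    best_pos, best_mm = None, max_mismatch + 1
    for pos in range(len(sequence) - min_overlap + 1):
        overlap = min(len(adapter), len(sequence) - pos)
        if overlap < min_overlap:
            break
        mm = sum(a != b for a, b in zip(sequence[pos : pos + overlap], adapter[:overlap]))
        if mm < best_mm:
            best_pos, best_mm = pos, mm
    return best_pos if best_mm <= max_mismatch else None


def clean_reads(
    raw: Iterable[RawRead],
    adapter: str,
    min_len: int = 18,
    max_len: int = 30,
    min_mean_q: float = 20.0,
    max_n: int = 0,
    require_adapter: bool = False,
) -> Iterator[str]:
    """Yield clean insert sequences (RNA alphabet) surviving all filters."""
    if adapter and len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    adapter = adapter.upper().replace("U", "T")
    for read in raw:
        if read.mean_quality < min_mean_q:
            continue
        seq = read.sequence
        if adapter:
            pos = find_adapter(seq, adapter)
            if pos is not None:
                seq = seq[:pos]
            elif require_adapter:
                continue
        if seq.count("N") > max_n:
            continue
        if not (min_len <= len(seq) <= max_len):
            continue
        yield to_rna(seq)


def collapse(clean: Iterable[str]) -> list[UniqueTag]:
    """Collapse clean sequences to unique tags, ordered count desc then lexicographic."""
    counts = Counter(to_rna(s) for s in clean)
    return [
        UniqueTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def size_distribution(
    tags: Sequence[UniqueTag], min_len: int = 18, max_len: int = 30
) -> pd.DataFrame:
    """Read- and unique-weighted length histograms with one-decimal percentages."""
    lengths = list(range(min_len, max_len + 1))
    read_counts = {n: 0 for n in lengths}
    unique_counts = {n: 0 for n in lengths}
    for tag in tags:
        n = len(tag.sequence)
        if n in read_counts:
            read_counts[n] += tag.count
            unique_counts[n] += 1
    total_reads = sum(read_counts.values())
    total_unique = sum(unique_counts.values())
    return pd.DataFrame(
        {
            "length": lengths,
            "read_count": [read_counts[n] for n in lengths],
            "unique_count": [unique_counts[n] for n in lengths],
            "read_percent": [percent(read_counts[n], total_reads) for n in lengths],
            "unique_percent": [percent(unique_counts[n], total_unique) for n in lengths],
        }
    )


def first_base_profile(tags: Sequence[UniqueTag]) -> pd.DataFrame:
    """Per-length 5' nucleotide fractions over unique tags; absent lengths omitted."""
    by_length: dict[int, Counter] = {}
    for tag in tags:
        by_length.setdefault(len(tag.sequence), Counter())[tag.sequence[0]] += 1
    rows = []
    for length in sorted(by_length):
        counts = by_length[length]
        total = sum(counts.values())
        rows.append(
            {"length": length, **{b: counts.get(b, 0) / total for b in "ACGU"}}
        )
    return pd.DataFrame(rows, columns=["length", "A", "C", "G", "U"])


def write_collapsed_fasta(tags: Sequence[UniqueTag], path: str | Path) -> None:
    with open(path, "w") as handle:
        for i, tag in enumerate(tags, start=1):
            handle.write(f">tag{i}_x{tag.count}\n{tag.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> list[UniqueTag]:
    tags = []
    with open(path) as handle:
        header = None
        for line in handle:
            line = line.strip()
            if line.startswith(">"):
                header = line[1:]
            elif line and header is not None:
                count = int(header.rsplit("_x", 1)[1]) if "_x" in header else 1
                tags.append(UniqueTag(to_rna(line), count))
                header = None
    return tags
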