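"""Ground-truth simulators for every downstream stage.

Three generators share one seeded RNG stream (sub-generators draw from it in
a fixed order, so a fixed seed reproduces every output byte-for-byte):

- :func:`generate_transcriptome` plants near-perfect inverted-repeat hairpin
  precursors (including two-precursor clusters, multi-mature precursors and
  antisense partners) and stem-free decoy windows inside random transcripts,
  returning the FASTA sequences plus a truth table.
- :func:`simulate_reads` emits adaptered mature/star/decoy/background reads
  with configurable end jitter, per-base error and low-quality spike-ins.
- :func:`generate_cq_table` produces qPCR Cq tables with planted log2
  effects on top of per-assay baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .seqs import reverse_complement, to_dna

__all__ = [
    "SimConfig",
    "TruthRecord",
    "CqDesign",
    "generate_transcriptome",
    "simulate_reads",
    "generate_cq_table",
    "write_fasta",
    "write_fastq",
    "write_truth_tsv",
    "read_truth_tsv",
    "load_config",
]

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    seed: int = 0
    n_transcripts: int = 10
    n_planted_mirnas: int = 5
    n_decoys: int = 0
    mature_len_range: tuple[int, int] = (20, 24)
    stem_len: int = 35
    loop_len: int = 8
    read_error_rate: float = 0.0
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"
    depth_mu: float = 2.5  # log-normal depth model (log scale)
    depth_sigma: float = 0.8
    depth_min: int = 1
    background_tag_rate: int = 0
    jitter_prob: float = 0.0
    low_quality_fraction: float = 0.0
    star_depth_divisor: int = 5  # star reads = max(1, depth // divisor); 0 disables
    stem_mutation_rate: float = 0.08  # <= 10% keeps stems >= 90% paired
    n_clusters: int = 0
    n_multi_mature: int = 0
    n_antisense: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.read_error_rate < 1:
            raise ValueError("read_error_rate must be in [0, 1)")
        lo, hi = self.mature_len_range
        if not (18 <= lo <= hi <= 26):
            raise ValueError("mature_len_range must lie within [18, 26]")
        if self.n_transcripts == 0 and self.n_planted_mirnas > 0:
            raise ValueError("n_transcripts = 0 with planted miRNAs requested")
        if self.stem_len < hi + 4:
            raise ValueError("stem_len too short for the mature length range")
        structured = 2 * (self.n_clusters + self.n_multi_mature + self.n_antisense)
        if self.n_planted_mirnas and structured > self.n_planted_mirnas:
            raise ValueError("structured elements exceed n_planted_mirnas")


@dataclass
class TruthRecord:
    name: str
    transcript_id: str
    strand: str
    precursor_id: str
    precursor_start: int
    precursor_end: int
    mature_seq: str = ""
    star_seq: str = ""
    mature_start: int = -1
    mature_end: int = -1
    star_start: int = -1
    star_end: int = -1
    arm: str = ""
    planted_depth: int = 0
    is_decoy: bool = False
    cluster_id: str = ""
    antisense_partner: str = ""
    decoy_tag: str = ""


def load_config(path: str | Path) -> SimConfig:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if "mature_len_range" in raw:
        raw["mature_len_range"] = tuple(raw["mature_len_range"])
    return SimConfig(**raw)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


_WOBBLE = {"G": "T", "T": "G"}


def _mutate_base(
    rng: np.random.Generator, base: str, no_pair_with: str | None = None
) -> str:
    """A substitute base; with ``no_pair_with`` set, one that cannot pair it."""
    choices = [b for b in "ACGT" if b != base and b != _COMP[base]]
    if no_pair_with is not None:
        banned = {_COMP[no_pair_with], _WOBBLE.get(no_pair_with)}
        choices = [b for b in choices if b not in banned] or ["A" if base != "A" else "C"]
    return choices[rng.integers(0, len(choices))]


@dataclass
class _Hairpin:
    sequence: str
    matures: list[tuple[int, int, str]]  # (start, end, arm) in precursor coords
    stars: list[tuple[int, int]]


def _build_hairpin(
    rng: np.random.Generator,
    config: SimConfig,
    n_matures: int = 1,
    mutate: bool = True,
    duplex_mismatch: int = 1,
) -> _Hairpin:
    """A near-perfect inverted repeat with 1..2 clean mature duplexes.

    The stem keeps >= 90% of its columns paired; stem mutations land on the
    arm opposite each mature, outside the mature's pairing columns, so the
    planted duplexes stay essentially perfect. ``duplex_mismatch`` then
    plants that many non-pairing bases opposite the middle of each mature —
    harmless against the annotation criteria, but it keeps mature and star
    tags from mapping exactly onto the opposite transcript strand, so only
    deliberately planted antisense partners look bidirectional.
    """
    stem, loop_len = config.stem_len, config.loop_len
    lo, hi = config.mature_len_range
    length = int(rng.integers(lo, hi + 1))
    if n_matures == 2:
        stem = max(stem, 2 * length + 8)
    arm5 = list(_random_seq(rng, stem))
    loop = _random_seq(rng, loop_len)
    arm3 = [_COMP[b] for b in reversed(arm5)]
    total = 2 * stem + loop_len

    # mature columns (index into arm5); a column c pairs arm3 position stem-1-c
    offsets = [2] if n_matures == 1 else [2, length + 5]
    arms = ["5p"] if n_matures == 1 else ["5p", "5p"]
    if n_matures == 1 and rng.random() < 0.5:
        arms = ["3p"]
    protected: set[int] = set()
    for off in offsets:
        protected.update(range(off - 1, off + length + 1))

    if mutate:
        k = max(1, int(stem * config.stem_mutation_rate))
        free = [c for c in range(stem) if c not in protected]
        if free and k:
            for c in rng.choice(len(free), size=min(k, len(free)), replace=False):
                col = free[int(c)]
                pos3 = stem - 1 - col
                arm3[pos3] = _mutate_base(rng, arm3[pos3])

    if duplex_mismatch:
        for off, arm in zip(offsets, arms):
            cols = rng.choice(
                range(off + 2, off + length - 2), size=duplex_mismatch, replace=False
            )
            for col in cols:
                col = int(col)
                pos3 = stem - 1 - col
                if arm == "5p":
                    arm3[pos3] = _mutate_base(rng, arm3[pos3], no_pair_with=arm5[col])
                else:
                    arm5[col] = _mutate_base(rng, arm5[col], no_pair_with=arm3[pos3])

    seq = "".join(arm5) + loop + "".join(arm3)
    matures: list[tuple[int, int, str]] = []
    stars: list[tuple[int, int]] = []
    for off, arm in zip(offsets, arms):
        if arm == "5p":
            m = (off, off + length)
            s = (total - off - length, min(total - off + 2, total))
        else:
            m = (total - off - length, total - off)
            s = (off, min(off + length + 2, total))
        matures.append((m[0], m[1], arm))
        stars.append(s)
    return _Hairpin(seq, matures, stars)


def _draw_depth(rng: np.random.Generator, config: SimConfig) -> int:
    depth = int(round(float(rng.lognormal(config.depth_mu, config.depth_sigma))))
    return max(config.depth_min, depth)


def generate_transcriptome(
    config: SimConfig,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Plant hairpin precursors and decoys inside random transcripts."""
    rng = np.random.default_rng(config.seed)
    transcripts: dict[str, str] = {}
    truth: list[TruthRecord] = []
    if config.n_transcripts == 0:
        return transcripts, truth

    n_structured = config.n_clusters + config.n_multi_mature + config.n_antisense
    n_single = config.n_planted_mirnas - 2 * n_structured
    needed = n_single + config.n_clusters + config.n_multi_mature + config.n_antisense
    needed += config.n_decoys
    if needed > config.n_transcripts:
        raise ValueError(
            f"n_transcripts={config.n_transcripts} too small for "
            f"{needed} planted transcripts"
        )

    mirna_no = 0
    precursor_no = 0
    tindex = 0

    def new_transcript_id() -> str:
        nonlocal tindex
        tindex += 1
        return f"transcript{tindex:04d}"

    def plant(hairpins: list[_Hairpin], kind: str) -> tuple[str, list[TruthRecord]]:
        """Embed hairpins sequentially in one transcript with random padding."""
        nonlocal mirna_no, precursor_no
        tid = new_transcript_id()
        parts: list[str] = [_random_seq(rng, int(rng.integers(40, 90)))]
        offset = len(parts[0])
        records: list[TruthRecord] = []
        for hp in hairpins:
            precursor_no += 1
            pid = f"precursor{precursor_no:03d}"
            for (m0, m1, arm), (s0, s1) in zip(hp.matures, hp.stars):
                mirna_no += 1
                records.append(
                    TruthRecord(
                        name=f"sim-miR{mirna_no:03d}",
                        transcript_id=tid,
                        strand="+",
                        precursor_id=pid,
                        precursor_start=offset,
                        precursor_end=offset + len(hp.sequence),
                        mature_seq=to_dna(hp.sequence[m0:m1]),
                        star_seq=to_dna(hp.sequence[s0:s1]),
                        mature_start=offset + m0,
                        mature_end=offset + m1,
                        star_start=offset + s0,
                        star_end=offset + s1,
                        arm=arm,
                        planted_depth=_draw_depth(rng, config),
                        cluster_id=f"cluster{precursor_no}" if kind == "cluster" else "",
                    )
                )
            parts.append(hp.sequence)
            offset += len(hp.sequence)
            spacer = _random_seq(rng, int(rng.integers(40, 90)))
            parts.append(spacer)
            offset += len(spacer)
        transcripts[tid] = "".join(parts)
        return tid, records

    # fixed generation order keeps the stream reproducible: singles, clusters,
    # multi-mature, antisense, decoys, then padding transcripts
    for _ in range(max(0, n_single)):
        _, recs = plant([_build_hairpin(rng, config)], "single")
        truth.extend(recs)

    for c in range(config.n_clusters):
        _, recs = plant(
            [_build_hairpin(rng, config), _build_hairpin(rng, config)], "cluster"
        )
        cid = f"cluster{c + 1}"
        for rec in recs:
            rec.cluster_id = cid
        truth.extend(recs)

    for _ in range(config.n_multi_mature):
        _, recs = plant([_build_hairpin(rng, config, n_matures=2, mutate=False)], "multi")
        truth.extend(recs)

    for _ in range(config.n_antisense):
        tid, recs = plant(
            [_build_hairpin(rng, config, mutate=False, duplex_mismatch=0)], "antisense"
        )
        sense = recs[0]
        mirna_no_anti = mirna_no + 1
        anti = TruthRecord(
            name=f"sim-miR{mirna_no_anti:03d}",
            transcript_id=tid,
            strand="-",
            precursor_id=sense.precursor_id + "as",
            precursor_start=sense.precursor_start,
            precursor_end=sense.precursor_end,
            mature_seq=to_dna(reverse_complement(sense.mature_seq)),
            star_seq=to_dna(reverse_complement(sense.star_seq)),
            mature_start=sense.mature_start,
            mature_end=sense.mature_end,
            star_start=sense.star_start,
            star_end=sense.star_end,
            arm="3p" if sense.arm == "5p" else "5p",
            planted_depth=_draw_depth(rng, config),
            antisense_partner=sense.name,
        )
        sense.antisense_partner = anti.name
        mirna_no = mirna_no_anti
        truth.extend(recs)
        truth.append(anti)

    for d in range(config.n_decoys):
        tid = new_transcript_id()
        window = _random_seq(rng, 2 * config.stem_len + config.loop_len)
        left = _random_seq(rng, int(rng.integers(40, 90)))
        right = _random_seq(rng, int(rng.integers(40, 90)))
        transcripts[tid] = left + window + right
        lo, hi = config.mature_len_range
        length = int(rng.integers(lo, hi + 1))
        tag_off = (len(window) - length) // 2
        truth.append(
            TruthRecord(
                name=f"sim-decoy{d + 1:03d}",
                transcript_id=tid,
                strand="+",
                precursor_id=f"decoy{d + 1:03d}",
                precursor_start=len(left),
                precursor_end=len(left) + len(window),
                planted_depth=_draw_depth(rng, config),
                is_decoy=True,
                decoy_tag=window[tag_off : tag_off + length],
            )
        )

    while tindex < config.n_transcripts:
        tid = new_transcript_id()
        transcripts[tid] = _random_seq(rng, int(rng.integers(200, 500)))

    return transcripts, truth


def simulate_reads(
    truth: list[TruthRecord], config: SimConfig
) -> list[tuple[str, str, str]]:
    """Simulated raw reads as (id, sequence, quality) triples.

    Non-background reads are mature/star/decoy tag sequences with optional
    end jitter (trimming up to 2 nt) and per-base substitution errors, the 3'
    adapter appended, and constant high-Phred qualities except for a planted
    low-quality fraction.
    """
    if len(config.adapter_seq) < 6:
        raise ValueError("adapter_seq must be at least 6 nt")
    rng = np.random.default_rng(config.seed + 1)
    reads: list[tuple[str, str, str]] = []

    def emit(name: str, insert: str, n: int) -> None:
        for i in range(n):
            seq = insert
            if config.jitter_prob and rng.random() < config.jitter_prob:
                trim = int(rng.integers(1, 3))
                if rng.random() < 0.5:
                    seq = seq[trim:]
                else:
                    seq = seq[:-trim]
                if len(seq) < 18:
                    seq = insert
            if config.read_error_rate:
                chars = list(seq)
                for p in range(len(chars)):
                    if rng.random() < config.read_error_rate:
                        chars[p] = _mutate_base(rng, chars[p])
                seq = "".join(chars)
            full = seq + config.adapter_seq
            low = config.low_quality_fraction and rng.random() < config.low_quality_fraction
            qual = ("#" if low else "I") * len(full)
            reads.append((f"{name}_r{i + 1}", full, qual))

    for rec in truth:
        if rec.is_decoy:
            emit(rec.name, rec.decoy_tag, rec.planted_depth)
            continue
        emit(rec.name, rec.mature_seq, rec.planted_depth)
        if config.star_depth_divisor and rec.star_seq:
            emit(rec.name + "_star", rec.star_seq, max(1, rec.planted_depth // config.star_depth_divisor))

    for b in range(config.background_tag_rate):
        length = int(rng.integers(18, 31))
        emit(f"bg{b + 1:05d}", _random_seq(rng, length), int(rng.integers(1, 3)))

    return reads


@dataclass
class CqDesign:
    conditions: list[str]
    assays: list[str]
    reference_assay: str
    calibrator: str
    replicates: int = 3
    baselines: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_assay not in self.assays:
            raise ValueError("design must include the reference assay")
        if self.calibrator not in self.conditions:
            raise ValueError("design must include the calibrator condition")
        if self.replicates < 1:
            raise ValueError("at least one replicate required")

    def baseline(self, assay: str) -> float:
        default = 18.0 if assay == self.reference_assay else 25.0
        return self.baselines.get(assay, default)


def generate_cq_table(
    design: CqDesign,
    effects: dict[tuple[str, str], float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cq = baseline - planted log2 effect + Gaussian noise.

    ``effects`` maps (assay, condition) to a planted log2 fold change versus
    the calibrator; the reference assay must carry no effect.
    """
    effects = effects or {}
    for (assay, _), value in effects.items():
        if assay == design.reference_assay and value != 0:
            raise ValueError("reference assay must have zero planted effect")
    rng = np.random.default_rng(seed)
    rows = []
    for condition in design.conditions:
        for assay in design.assays:
            effect = effects.get((assay, condition), 0.0)
            for rep in range(1, design.replicates + 1):
                noise = float(rng.normal(0.0, noise_sd)) if noise_sd else 0.0
                rows.append(
                    {
                        "condition": condition,
                        "assay": assay,
                        "replicate": rep,
                        "cq": design.baseline(assay) - effect + noise,
                    }
                )
    return pd.DataFrame(rows)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name in sequences:
            handle.write(f">{name}\n{sequences[name]}\n")


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rid, seq, qual in reads:
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(rec) for rec in truth]).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [TruthRecord(**row) for row in df.to_dict("records")]
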