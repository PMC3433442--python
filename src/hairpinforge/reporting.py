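"""Shared summary arithmetic, packaged annotation fixtures, and run reports.

The two packaged TSV fixtures under ``data/`` transcribe the published
non-conserved miRNA table (mature and star rows with read counts, MFEI and
host unigene) and the non-conserved target table (family, target function,
unigene, penalty score). SHA-256 checksums guard the transcriptions against
accidental drift.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

__all__ = [
    "percent",
    "load_table1",
    "load_table2",
    "fixture_counts",
    "FixtureSummary",
    "run_report",
]

_TABLE1_SHA256 = "16a0e8c68e5c1cd0ae1654d8d9419e41214a12ca986e34a8651e88c193b928e6"
_TABLE2_SHA256 = "c6d6f3341e14ad9f4a42e08482dacb656c90a693d413d1788983fe26214aceda"


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage with decimal (not binary) half-up rounding.

    ``denominator == 0`` returns 0.0 so that empty categories render cleanly.
    """
    if numerator < 0 or denominator < 0:
        raise ValueError("percent() requires non-negative inputs")
    if denominator == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def _read_fixture(name: str, expected_sha256: str) -> pd.DataFrame:
    ref = resources.files("hairpinforge.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha256:
        raise ValueError(
            f"fixture {name} checksum mismatch: {digest} != {expected_sha256}"
        )
    with ref.open("r") as handle:
        return pd.read_csv(handle, sep="\t")


_MIRNA_NAME = re.compile(
    r"^miR(?P<family>\d+)(?P<member>[a-z]*)"
    r"(?:\.(?P<sub>\d+))?(?:-(?P<arm>[53]p))?(?P<star>\*)?$"
)


def parse_mirna_name(name: str) -> dict:
    """Split a miRNA name into family / member letter / sub-index / arm / star flag."""
    m = _MIRNA_NAME.match(name)
    if m is None:
        raise ValueError(f"unparseable miRNA name: {name!r}")
    d = m.groupdict()
    return {
        "family": f"MIR{d['family']}",
        "member": d["member"] or "",
        "sub": d["sub"],
        "arm": d["arm"],
        "is_star": d["star"] is not None,
    }


def load_table1(validate: bool = True) -> pd.DataFrame:
    """Packaged non-conserved miRNA/miRNA* table with derived key columns.

    Adds ``family`` (from the name), ``member`` (family member letter) and
    ``precursor_key`` — one hairpin per (unigene, strand, member), so rows
    that share a hairpin (sub-indexed matures, arm pairs, star rows) collapse
    onto a single key.
    """
    df = _read_fixture("table1.tsv", _TABLE1_SHA256)
    parsed = df["name"].map(parse_mirna_name)
    df["family"] = [p["family"] for p in parsed]
    df["member"] = [p["member"] for p in parsed]
    df["is_star"] = df["is_star"].astype(bool) | pd.Series(
        [p["is_star"] for p in parsed], index=df.index
    )
    df["precursor_key"] = [
        f"{u}:{s}:{fam}{mem}"
        for u, s, fam, mem in zip(
            df["unigene_id"], df["strand"], df["family"], df["member"]
        )
    ]
    if validate:
        _validate_table1(df)
    return df


def _validate_table1(df: pd.DataFrame) -> None:
    for _, row in df.iterrows():
        if len(row["sequence"]) != row["size_nt"]:
            raise ValueError(
                f"fixture row {row['name']}: size {row['size_nt']} != "
                f"sequence length {len(row['sequence'])}"
            )
        if row["reads"] < 1:
            raise ValueError(f"fixture row {row['name']}: reads < 1")
        if not set(row["sequence"]) <= set("ACGTU"):
            raise ValueError(f"fixture row {row['name']}: non-nucleotide characters")


def load_table2(validate: bool = True) -> pd.DataFrame:
    df = _read_fixture("table2.tsv", _TABLE2_SHA256)
    if validate:
        bad = df[(df["penalty"] < 0) | (df["penalty"] > 3)]
        if len(bad):
            raise ValueError(f"fixture penalty out of [0, 3] for: {list(bad['unigene_id'])}")
    return df


@dataclass
class FixtureSummary:
    """Counts derived from the packaged fixtures."""

    mature_count: int
    star_count: int
    precursor_count: int
    family_members: dict[str, int] = field(default_factory=dict)
    target_count: int = 0


def fixture_counts(
    table1: pd.DataFrame | None = None, table2: pd.DataFrame | None = None
) -> FixtureSummary:
    """Summarize the packaged tables (or externally supplied frames).

    Mature rows exclude stars; precursors are distinct precursor keys; family
    member counts are precursors per family.
    """
    if table1 is None:
        table1 = load_table1()
    if table2 is None:
        table2 = load_table2()
    if len(table1):
        mature = table1[~table1["is_star"]]
        precursors = table1.drop_duplicates("precursor_key")
        family_members = precursors.groupby("family")["precursor_key"].nunique().to_dict()
        summary = FixtureSummary(
            mature_count=len(mature),
            star_count=int(table1["is_star"].sum()),
            precursor_count=len(precursors),
            family_members=family_members,
        )
    else:
        summary = FixtureSummary(mature_count=0, star_count=0, precursor_count=0)
    summary.target_count = len(table2)
    return summary


def run_report(sections: dict[str, pd.DataFrame | dict | str], meta: dict | None = None) -> str:
    """Stitch stage outputs into one markdown report.

    ``sections`` maps a section title to a data frame (rendered as a table),
    a dict (rendered as key/value bullets) or a preformatted string. At least
    one section is required. The same inputs always produce the same text.
    """
    if not sections:
        raise ValueError("run_report requires at least one stage output")
    lines = ["# hairpinforge run report", ""]
    if meta:
        for key in sorted(meta):
            lines.append(f"- {key}: {meta[key]}")
        lines.append("")
    for title, payload in sections.items():
        lines.append(f"## {title}")
        lines.append("")
        if isinstance(payload, pd.DataFrame):
            lines.append(payload.to_csv(sep="\t", index=False).rstrip())
        elif isinstance(payload, dict):
            for key in sorted(payload):
                lines.append(f"- {key}: {payload[key]}")
        else:
            lines.append(str(payload))
        lines.append("")
    return "\n".join(lines)
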