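"""Sequence alphabet helpers shared across stages.

The internal alphabet is RNA (A/C/G/U); all entry points accept DNA (T) and
convert on the way in.
"""

from __future__ import annotations

RNA_BASES = "ACGU"

_TO_RNA = str.maketrans("tT", "uU")
_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")

#: Watson-Crick plus G:U wobble pairs on the RNA alphabet.
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
CANONICAL_PAIRS = WC_PAIRS | WOBBLE_PAIRS


def to_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().translate(_TO_RNA)


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """Reverse complement on the RNA alphabet (accepts T, returns U)."""
    return to_rna(seq).translate(_COMPLEMENT)[::-1]


def is_rna(seq: str) -> bool:
    return bool(seq) and all(b in RNA_BASES for b in seq)


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def read_fasta(path) -> dict[str, str]:
    """FASTA file as an ordered {id: sequence} dict (Biopython-backed)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
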