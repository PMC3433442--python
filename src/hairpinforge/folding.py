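"""Pluggable RNA secondary-structure engines.

The bundled :class:`MaxPairEngine` is a deterministic maximum-base-pairing
folder (Nussinov-style dynamic program) with fixed per-pair energies
(GC -3, AU -2, GU -1 kcal/mol) and a minimum hairpin loop of 3 nt, so the
pipeline and its tests never require external thermodynamic software. If the
ViennaRNA python bindings are importable, :func:`get_engine` can return a
wrapper around them instead; reported energies are engine-relative and the
engine identity is carried in output metadata.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np

from .seqs import to_rna

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


MIN_LOOP = 3

# Pair energies indexed by encoded base (A=0, C=1, G=2, U=3); 0 = not pairable.
_PAIR_ENERGY = np.zeros((4, 4), dtype=np.int32)
_PAIR_ENERGY[2, 1] = _PAIR_ENERGY[1, 2] = 3  # G:C
_PAIR_ENERGY[0, 3] = _PAIR_ENERGY[3, 0] = 2  # A:U
_PAIR_ENERGY[2, 3] = _PAIR_ENERGY[3, 2] = 1  # G:U

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@njit(cache=True)
def _fill(enc, pair_energy, min_loop):  # pragma: no cover - numba kernel
    n = enc.shape[0]
    best = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            score = best[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                e = pair_energy[enc[i], enc[k]]
                if e > 0:
                    cand = e + best[i + 1, k - 1]
                    if k + 1 <= j:
                        cand += best[k + 1, j]
                    if cand > score:
                        score = cand
            best[i, j] = score
    return best


def _traceback(enc: np.ndarray, best: np.ndarray, min_loop: int) -> list[tuple[int, int]]:
    """Deterministic traceback: the smallest pairing partner wins ties."""
    pairs: list[tuple[int, int]] = []
    stack = [(0, enc.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        score = best[i, j]
        if score == 0:
            continue
        found = False
        for k in range(i + min_loop + 1, j + 1):
            e = _PAIR_ENERGY[enc[i], enc[k]]
            if e > 0:
                cand = e + best[i + 1, k - 1] + (best[k + 1, j] if k + 1 <= j else 0)
                if cand == score:
                    pairs.append((i, k))
                    stack.append((i + 1, k - 1))
                    if k + 1 <= j:
                        stack.append((k + 1, j))
                    found = True
                    break
        if not found:
            stack.append((i + 1, j))
    return pairs


class FoldingEngine(Protocol):
    name: str

    def fold(self, sequence: str) -> tuple[str, float]:
        """Return (dot-bracket structure, free energy in kcal/mol)."""
        ...


class MaxPairEngine:
    """Bundled deterministic maximum-base-pairing folder."""

    name = "maxpair"

    def fold(self, sequence: str) -> tuple[str, float]:
        seq = to_rna(sequence)
        if not seq:
            return "", 0.0
        if not set(seq) <= set(_ENCODE):
            raise ValueError(f"non-ACGU characters in sequence: {seq!r}")
        enc = np.array([_ENCODE[b] for b in seq], dtype=np.int8)
        if len(seq) <= MIN_LOOP + 1:
            return "." * len(seq), 0.0
        best = _fill(enc, _PAIR_ENERGY, MIN_LOOP)
        pairs = _traceback(enc, best, MIN_LOOP)
        structure = ["."] * len(seq)
        for i, j in pairs:
            structure[i] = "("
            structure[j] = ")"
        return "".join(structure), -float(best[0, len(seq) - 1])


class ViennaEngine:  # pragma: no cover - optional dependency
    """Wrapper around the ViennaRNA python bindings (optional)."""

    name = "viennarna"

    def __init__(self) -> None:
        import RNA

        self._rna = RNA

    def fold(self, sequence: str) -> tuple[str, float]:
        structure, mfe = self._rna.fold(to_rna(sequence))
        return structure, float(mfe)


def get_engine(name: str = "maxpair") -> FoldingEngine:
    if name == "maxpair":
        return MaxPairEngine()
    if name == "viennarna":  # pragma: no cover
        return ViennaEngine()
    raise ValueError(f"unknown folding engine: {name!r}")


def pair_table(dot_bracket: str) -> list[int]:
    """Partner index per position (-1 = unpaired) from a dot-bracket string."""
    table = [-1] * len(dot_bracket)
    stack: list[int] = []
    for idx, char in enumerate(dot_bracket):
        if char == "(":
            stack.append(idx)
        elif char == ")":
            if not stack:
                raise ValueError(f"unbalanced brackets at position {idx}")
            j = stack.pop()
            table[idx] = j
            table[j] = idx
        elif char != ".":
            raise ValueError(f"unexpected structure character {char!r}")
    if stack:
        raise ValueError("unbalanced brackets: unmatched '('")
    return table
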