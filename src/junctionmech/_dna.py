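"""Small DNA string utilities shared across modules.

Everything here operates on plain uppercase A/C/G/T strings; coordinates are
0-based half-open throughout the package.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str) -> None:
    """Raise ValueError naming the first offending offset if seq is not A/C/G/T."""
    for i, c in enumerate(seq):
        if c not in "ACGT":
            raise ValueError(f"non-ACGT character {c!r} at offset {i}")


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.48) -> str:
    """Random sequence with the given expected GC content."""
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])
    return "".join(BASES[i] for i in idx)


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply uniform substitutions at the given per-base rate (no indels)."""
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alternatives = [b for b in BASES if b != out[i]]
        out[i] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def lcp_len(a: str, b: str) -> int:
    """Length of the longest common prefix of two strings."""
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def common_suffix_len(a: str, b: str) -> int:
    """Length of the longest common suffix of two strings."""
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n
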