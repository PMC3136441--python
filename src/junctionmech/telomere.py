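"""Detection of de novo telomere hexamer arrays and fusion-point microhomology.

Telomere healing leaves an array of GGTTAG units (the G-rich strand of the
human telomere repeat) attached directly to the truncated chromosomal
sequence.  Arrays observed at healed junctions run from a few to several
dozen units and may contain variant units one substitution away from the
canonical hexamer, such as GGTGAG or GGTCAG.  The fusion point frequently
shares 1-5 bases with the canonical repeat, reflecting the template that
telomerase anneals to the broken end; those shared bases make the exact
breakpoint ambiguous within a small interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from ._dna import hamming, revcomp, validate_dna

CANONICAL_UNIT = "GGTTAG"
UNIT = len(CANONICAL_UNIT)


@dataclass
class TelomereArrayHit:
    """A run of consecutive telomere hexamer units within a query sequence.

    ``start``/``end`` are 0-based half-open query positions covering whole
    units only (``end - start == 6 * copies``).  ``phase`` is ``start % 6``.
    ``canonical`` is False when fewer than half of the units are exact
    GGTTAG copies (e.g. a pure variant-unit run); downstream classification
    does not treat such arrays as evidence of telomere healing.
    """

    start: int
    end: int
    copies: int
    canonical_copies: int
    variant_units: list[tuple[int, str]] = field(default_factory=list)
    phase: int = 0
    canonical: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variant_units"] = [list(v) for v in self.variant_units]
        return d


def _unit_ok(unit: str) -> bool:
    return len(unit) == UNIT and hamming(unit, CANONICAL_UNIT) <= 1


def _trim_isolated_edge_variants(units: list[str], start: int) -> tuple[list[str], int]:
    """Drop a single variant unit at either run edge when it abuts a canonical one.

    An isolated variant unit at the boundary of an otherwise canonical run is
    better explained as flanking genomic sequence that happens to share five
    bases with the repeat (i.e. fusion microhomology) than as a telomere unit.
    Blocks of two or more consecutive variant units -- the (GGTCAG)6 pattern
    seen ahead of a canonical array -- are kept.
    """
    while (
        len(units) >= 2
        and units[0] != CANONICAL_UNIT
        and units[1] == CANONICAL_UNIT
    ):
        units = units[1:]
        start += UNIT
    while (
        len(units) >= 2
        and units[-1] != CANONICAL_UNIT
        and units[-2] == CANONICAL_UNIT
    ):
        units = units[:-1]
    return units, start


def find_telomere_array(
    seq: str,
    min_copies: int = 3,
    max_variant_fraction: float = 0.5,
) -> TelomereArrayHit | None:
    """Locate the longest telomere hexamer array in ``seq`` (G-rich strand only).

    The array is the longest run of consecutive, in-phase 6-mers each within
    Hamming distance 1 of GGTTAG.  Runs shorter than ``min_copies`` are not
    reported.  A run whose canonical fraction falls below
    ``1 - max_variant_fraction`` is still reported but flagged
    ``canonical=False``.

    Raises ValueError (naming the offset) on non-ACGT input.
    """
    validate_dna(seq)
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    best: TelomereArrayHit | None = None
    n = len(seq)
    for phase in range(UNIT):
        pos = phase
        run_units: list[str] = []
        run_start = pos
        while pos + UNIT <= n + UNIT:  # one extra lap to flush the last run
            unit = seq[pos : pos + UNIT]
            if pos + UNIT <= n and _unit_ok(unit):
                if not run_units:
                    run_start = pos
                run_units.append(unit)
                pos += UNIT
                continue
            if run_units:
                units, start = _trim_isolated_edge_variants(run_units, run_start)
                if len(units) >= min_copies:
                    canon = sum(u == CANONICAL_UNIT for u in units)
                    hit = TelomereArrayHit(
                        start=start,
                        end=start + UNIT * len(units),
                        copies=len(units),
                        canonical_copies=canon,
                        variant_units=[
                            (start + UNIT * i, u)
                            for i, u in enumerate(units)
                            if u != CANONICAL_UNIT
                        ],
                        phase=start % UNIT,
                        canonical=(canon / len(units)) >= 1.0 - max_variant_fraction,
                    )
                    if best is None or hit.copies > best.copies or (
                        hit.copies == best.copies and hit.start < best.start
                    ):
                        best = hit
                run_units = []
            pos += UNIT
    return best


def telomere_fusion_microhomology(proximal_ref_suffix: str, array: TelomereArrayHit) -> int:
    """Microhomology between the reference suffix and the telomere repeat.

    Returns the maximal k in [0, 6] such that the last k reference bases
    match the canonical hexamer at the fusion point, in either annealing
    register: the k bases an in-phase telomere extension would place
    immediately before the array's first unit (the suffix of GGTTAG, e.g.
    ``...GTTAG|GGTTAG``), or the first k bases of a unit completed by the
    new telomere (the prefix of GGTTAG, e.g. ``...GGTTA|G GTTAG...``).
    Computed by brute force over k = 6..0.
    """
    if array is None:
        raise ValueError("array phase undefined: no telomere array hit")
    if len(proximal_ref_suffix) < UNIT:
        raise ValueError("proximal reference suffix must be >= 6 bp")
    for k in range(UNIT, 0, -1):
        tail = proximal_ref_suffix[-k:]
        if tail == CANONICAL_UNIT[UNIT - k :] or tail == CANONICAL_UNIT[:k]:
            return k
    return 0


def find_inverted_palindrome(
    seq: str, min_arm: int = 5, max_loop: int = 10
) -> list[tuple[int, int, int]]:
    """Find inverted-repeat palindromes: arms whose reverse complement matches
    across a loop of at most ``max_loop`` bases.

    Returns ``(arm_start, arm_len, loop_len)`` tuples for maximal arms,
    suppressing hits whose span overlaps a longer-armed hit.
    """
    validate_dna(seq)
    n = len(seq)
    raw: list[tuple[int, int, int]] = []
    for j in range(min_arm, n):  # j = end (exclusive) of the left arm
        for loop in range(0, max_loop + 1):
            right = j + loop
            k = 0
            while j - k - 1 >= 0 and right + k < n and seq[j - k - 1] == _comp(seq[right + k]):
                k += 1
            if k >= min_arm:
                # maximal arm only: skip if extending the loop outward reproduces it
                raw.append((j - k, k, loop))
    # deduplicate identical spans, keep longest arms, suppress overlapped shorter hits
    raw.sort(key=lambda h: (-h[1], h[0], h[2]))
    kept: list[tuple[int, int, int]] = []
    for h in raw:
        span = (h[0], h[0] + 2 * h[1] + h[2])
        if all(span[1] <= k[0] or span[0] >= k[0] + 2 * k[1] + k[2] for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h[0])
    return kept


def _comp(base: str) -> str:
    return revcomp(base)
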