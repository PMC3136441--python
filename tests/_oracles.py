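"""Brute-force oracles used to cross-check the optimized implementations.

These are written as plain exhaustive enumerations from the definitions;
they share no code with the package internals.
"""

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
HEX = "GGTTAG"


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def fusion_mh_oracle(ref_suffix: str) -> int:
    """k-loop: longest tail of the suffix equal to either register of the
    canonical hexamer at the fusion point."""
    best = 0
    for k in range(1, 7):
        tail = ref_suffix[-k:]
        if tail == HEX[6 - k :] or tail == HEX[:k]:
            best = k
    return best


def junction_overlap_oracle(seq_a: str, bp: int, seq_b: str, d: int) -> int:
    """Exhaustive-k junction overlap for the fusion A[:bp] + B[d:]: forward
    extension of the proximal reference plus backward extension of the
    distal reference, each checked base by base."""
    a = 0
    while bp + a < len(seq_a) and d + a < len(seq_b) and seq_a[bp + a] == seq_b[d + a]:
        a += 1
    s = 0
    while s < bp and s < d and seq_a[bp - s - 1] == seq_b[d - s - 1]:
        s += 1
    return a + s


def _unit_ok(u: str) -> bool:
    return len(u) == 6 and sum(x != y for x, y in zip(u, HEX)) <= 1


def telomere_array_oracle(seq: str, min_copies: int = 3, max_variant_fraction: float = 0.5):
    """Exhaustive 6-phase scan: every maximal run of consecutive in-phase
    Hamming<=1 units, with isolated edge variants adjacent to a canonical
    unit trimmed; returns (start, copies, canonical_copies, canonical_flag)
    of the longest (leftmost on ties), or None."""
    runs = []
    for start in range(0, len(seq) - 5):
        if start >= 6 and _unit_ok(seq[start - 6 : start]):
            continue  # not maximal on the left
        units = []
        pos = start
        while _unit_ok(seq[pos : pos + 6]):
            units.append(seq[pos : pos + 6])
            pos += 6
        if not units:
            continue
        # trim isolated edge variants
        while len(units) >= 2 and units[0] != HEX and units[1] == HEX:
            units = units[1:]
            start += 6
        while len(units) >= 2 and units[-1] != HEX and units[-2] == HEX:
            units = units[:-1]
        if len(units) >= min_copies:
            canon = sum(u == HEX for u in units)
            runs.append(
                (start, len(units), canon, canon / len(units) >= 1 - max_variant_fraction)
            )
    if not runs:
        return None
    return max(runs, key=lambda r: (r[1], -r[0]))


def palindrome_oracle(seq: str, min_arm: int = 5, max_loop: int = 10):
    """O(n^2 * arm) enumeration of maximal inverted-repeat arms, with the
    same longest-arm overlap suppression as the implementation."""
    raw = []
    n = len(seq)
    for start in range(n):
        for loop in range(0, max_loop + 1):
            for arm in range(min_arm, (n - start - loop) // 2 + 1):
                left = seq[start : start + arm]
                right = seq[start + arm + loop : start + 2 * arm + loop]
                if rc(left) != right:
                    continue
                # maximal: cannot extend outward by one base on both sides
                if (
                    start > 0
                    and start + 2 * arm + loop < n
                    and seq[start - 1] == COMP[seq[start + 2 * arm + loop]]
                ):
                    continue
                # maximal: cannot extend inward (longer arm, same span start)
                bigger = arm + 1
                if start + 2 * bigger + loop <= n and rc(
                    seq[start : start + bigger]
                ) == seq[start + bigger + loop : start + 2 * bigger + loop]:
                    continue
                raw.append((start, arm, loop))
    raw.sort(key=lambda h: (-h[1], h[0], h[2]))
    kept = []
    for h in raw:
        span = (h[0], h[0] + 2 * h[1] + h[2])
        if all(span[1] <= k[0] or span[0] >= k[0] + 2 * k[1] + k[2] for k in kept):
            kept.append(h)
    return sorted(kept)


def inverted_template_oracle(insert: str, search: str, min_len: int = 15):
    """Brute substring scan of both strands for the longest exact
    (sub)segment of the insert; returns (src_start, src_end, orientation)."""
    best = None
    for s in range(len(insert)):
        for e in range(s + min_len, len(insert) + 1):
            seg = insert[s:e]
            for orientation, target in (("reverse_complement", rc(seg)), ("forward", seg)):
                pos = search.find(target)
                if pos >= 0:
                    cand = (e - s, s, pos, orientation)
                    if best is None or cand[0] > best[0]:
                        best = cand
    if best is None:
        return None
    length, s, pos, orientation = best
    return pos, pos + length, orientation
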