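"""Decompose a junction read against the reference.

A junction read is modelled as a proximal segment that anchors uniquely on
the reference, followed by a distal segment that is either a de novo
telomere array, a copy of subtelomeric (TAR / foreign chromosome end)
sequence, or a second genomic locus.  Between the two attributed segments
there is either microhomology (the two sides overlap on the read, making
the breakpoint ambiguous within an interval), an untemplated insertion, or
a templated insertion copied -- usually in inverted orientation -- from
inside the deleted interval (the FoSTeS/MMBIR signature).

The decomposition is ungapped per side: each side of the junction lies on a
single alignment diagonal found by exact 20-mer seeding, and the junction
itself is resolved by an optimal split of the read between the two
diagonals (match +1, mismatch -1, unattributed gap bases 0).  On clean
reads the set of optimal split points *is* the microhomology interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from ._dna import revcomp
from .reference import ReferenceGenome
from .telomere import (
    CANONICAL_UNIT,
    TelomereArrayHit,
    find_telomere_array,
    telomere_fusion_microhomology,
)

SEED_K = 20


@dataclass
class Anchor:
    """An ungapped placement of part of the read on the reference."""

    seq_name: str
    ref_interval: tuple[int, int]
    query_interval: tuple[int, int]
    strand: str = "+"
    identity: float = 1.0
    unique: bool = True
    n_matches: int = 0
    ambiguity_count: int = 1

    @property
    def diagonal(self) -> int:
        """Reference position of read base 0 under this placement."""
        return self.ref_interval[0] - self.query_interval[0]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DistalAssignment:
    kind: str  # telomere_array | tar_block | foreign_subtelomere | genomic_locus | unassigned
    anchor: Anchor | TelomereArrayHit | None
    ambiguity_count: int = 1

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "anchor": None if self.anchor is None else self.anchor.to_dict(),
            "ambiguity_count": self.ambiguity_count,
        }


@dataclass
class TemplateInsert:
    """A templated insertion traced back to its source interval."""

    seq_name: str
    source_interval: tuple[int, int]
    orientation: str  # forward | reverse_complement
    mh_prox: int = 0
    mh_dist: int = 0

    @property
    def length(self) -> int:
        return self.source_interval[1] - self.source_interval[0]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class JunctionCall:
    read_id: str
    proximal: Anchor | None = None
    distal: DistalAssignment | None = None
    microhomology_len: int = 0
    microhomology_seq: str = ""
    untemplated_insert: str = ""
    template_insert: TemplateInsert | None = None
    breakpoint_interval: tuple[int, int] | None = None
    hexamer_copies: int | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "read_id": self.read_id,
            "proximal": None if self.proximal is None else self.proximal.to_dict(),
            "distal": None if self.distal is None else self.distal.to_dict(),
            "microhomology_len": self.microhomology_len,
            "microhomology_seq": self.microhomology_seq,
            "untemplated_insert": self.untemplated_insert,
            "template_insert": None
            if self.template_insert is None
            else self.template_insert.to_dict(),
            "breakpoint_interval": self.breakpoint_interval,
            "hexamer_copies": self.hexamer_copies,
            "error": self.error,
        }


# ---------------------------------------------------------------------------
# diagonal arithmetic


def _match_profile(read: str, ref_seq: str, diagonal: int) -> list[int]:
    """pm[i] = 1 iff read[i] matches ref_seq[diagonal + i] (0 outside the ref)."""
    n = len(ref_seq)
    return [
        1 if 0 <= diagonal + i < n and c == ref_seq[diagonal + i] else 0
        for i, c in enumerate(read)
    ]


def _telomere_profile(read: str, array_start: int) -> list[int]:
    """Match profile against an infinite canonical telomere aligned at array_start."""
    return [
        1 if c == CANONICAL_UNIT[(i - array_start) % 6] else 0
        for i, c in enumerate(read)
    ]


def _optimal_split(pm: list[int], dm: list[int]) -> tuple[int, int, int, int]:
    """Best split of the read between the proximal and distal diagonals.

    Returns ``(i, j, mh_lo, mh_hi)``: read bases [0, i) are attributed to the
    proximal side, [j, n) to the distal side and [i, j) to an insertion.
    When the optimum has no gap, ``[mh_lo, mh_hi]`` is the contiguous run of
    optimal split points connected by positions where both sides match
    (the microhomology interval; ``mh_hi - mh_lo`` = microhomology length),
    and ``i == j`` is its right edge.
    """
    n = len(pm)
    p_score = [0] * (n + 1)  # score of attributing read[:i] to proximal
    d_score = [0] * (n + 1)  # score of attributing read[j:] to distal
    for t in range(n):
        p_score[t + 1] = p_score[t] + (1 if pm[t] else -1)
    for t in range(n - 1, -1, -1):
        d_score[t] = d_score[t + 1] + (1 if dm[t] else -1)

    # prefix max of p_score with rightmost argmax
    best_p = [0] * (n + 1)
    best_p_at = [0] * (n + 1)
    cur, cur_at = p_score[0], 0
    for i in range(n + 1):
        if p_score[i] >= cur:
            cur, cur_at = p_score[i], i
        best_p[i], best_p_at[i] = cur, cur_at

    total_best = None
    j_best = 0
    for j in range(n + 1):
        tot = best_p[j] + d_score[j]
        gap = j - best_p_at[j]
        if total_best is None or tot > total_best[0] or (
            tot == total_best[0] and gap < total_best[1]
        ):
            total_best = (tot, gap)
            j_best = j
    i_best = best_p_at[j_best]

    if i_best < j_best:  # insertion present
        return i_best, j_best, i_best, i_best

    # no gap: expand the run of equivalent split points through positions
    # where both diagonals match (true homology)
    k = i_best
    lo = k
    while lo > 0 and pm[lo - 1] == 1 and dm[lo - 1] == 1:
        lo -= 1
    hi = k
    while hi < n and pm[hi] == 1 and dm[hi] == 1:
        hi += 1
    return hi, hi, lo, hi


# ---------------------------------------------------------------------------
# anchoring


def _scored_prefix_placement(read: str, ref_seq: str, diagonal: int) -> tuple[int, int]:
    """Greedy prefix extension (+1 match / -2 mismatch); returns (end, matches)."""
    best_end, best_score = 0, 0
    score = matches = 0
    best_matches = 0
    n = len(ref_seq)
    for i, c in enumerate(read):
        j = diagonal + i
        if 0 <= j < n and c == ref_seq[j]:
            score += 1
            matches += 1
        else:
            score -= 2
        if score > best_score:
            best_score, best_end, best_matches = score, i + 1, matches
        if score < best_score - 30:
            break
    return best_end, best_matches


def _seed_diagonals(read: str, ref: ReferenceGenome, offsets, max_hits: int = 80):
    index = ref.kmer_index(SEED_K)
    seen = set()
    for off in offsets:
        if off < 0 or off + SEED_K > len(read):
            continue
        for name, pos in index.get(read[off : off + SEED_K], [])[:max_hits]:
            seen.add((name, pos - off))
    return seen


def anchor_proximal(read: str, ref: ReferenceGenome, min_len: int = 40) -> Anchor:
    """Anchor the read prefix on the reference by exact-seed + scored extension.

    The anchor is the highest-scoring >=95%-identity placement of the read
    prefix; ``unique=False`` when a second placement ties within 2 matches.
    Raises ValueError("unanchored read") when no placement reaches
    ``min_len`` aligned bases.
    """
    if len(read) < 60:
        raise ValueError("unanchored read: read shorter than 60 bp")
    cands = _seed_diagonals(read, ref, range(0, 61, 7))
    placements = []
    for name, diag in cands:
        if diag < 0:
            continue
        end, matches = _scored_prefix_placement(read, ref.sequences[name], diag)
        if end >= min_len and matches / end >= 0.95:
            placements.append((matches, end, name, diag))
    if not placements:
        raise ValueError("unanchored read: no prefix placement >= %d bp" % min_len)
    placements.sort(key=lambda p: (-p[0], p[2], p[3]))
    m_best, end, name, diag = placements[0]
    ties = sum(1 for p in placements if p[0] >= m_best - 2)
    return Anchor(
        seq_name=name,
        ref_interval=(diag, diag + end),
        query_interval=(0, end),
        identity=m_best / end,
        unique=ties == 1,
        n_matches=m_best,
        ambiguity_count=ties,
    )


def _scored_window_placement(
    read: str, ref_seq: str, diagonal: int, seed_off: int
) -> tuple[int, int, int]:
    """Bidirectional scored extension from a seed; returns (q_lo, q_hi, matches)."""
    n = len(ref_seq)

    def step(rng_iter):
        best_pos, best_score, score, matches, best_matches = None, 0, 0, 0, 0
        for i in rng_iter:
            j = diagonal + i
            if 0 <= j < n and read[i] == ref_seq[j]:
                score += 1
                matches += 1
            else:
                score -= 2
            if score > best_score:
                best_score, best_pos, best_matches = score, i, matches
            if score < best_score - 30:
                break
        return best_pos, best_matches

    hi_pos, m_right = step(range(seed_off, len(read)))
    lo_pos, m_left = step(range(seed_off - 1, -1, -1))
    q_hi = seed_off if hi_pos is None else hi_pos + 1
    q_lo = seed_off if lo_pos is None else lo_pos
    return q_lo, q_hi, m_right + m_left


def assign_distal(
    read: str,
    proximal: Anchor,
    ref: ReferenceGenome,
    max_gap: int = 20,
    min_len: int = 30,
) -> DistalAssignment:
    """Assign the post-anchor portion of the read.

    Candidates are tried in interpretive priority order: a telomere array
    beginning at (or within ``max_gap`` of) the junction; then TAR /
    foreign-subtelomere features; then any genomic locus.
    """
    prox_qend = proximal.query_interval[1]

    hit = find_telomere_array(read)
    if (
        hit is not None
        and hit.end >= len(read) - 12
        and hit.start <= prox_qend + max_gap + 6
    ):
        return DistalAssignment(kind="telomere_array", anchor=hit, ambiguity_count=1)

    qs0 = max(prox_qend - 24, 0)
    cands = _seed_diagonals(read, ref, range(qs0, len(read) - SEED_K + 1, 7))
    cands.discard((proximal.seq_name, proximal.diagonal))
    placements = []
    for name, diag in cands:
        q_lo, q_hi, matches = _scored_window_placement(
            read, ref.sequences[name], diag, _first_seed_off(read, ref, name, diag, qs0)
        )
        length = q_hi - q_lo
        if length < min_len or matches / max(length, 1) < 0.95:
            continue
        if q_hi < prox_qend + 20 or q_lo > prox_qend + 60:
            continue  # must take over near the junction
        placements.append((matches, q_lo, q_hi, name, diag))
    if not placements:
        return DistalAssignment(kind="unassigned", anchor=None, ambiguity_count=0)
    placements.sort(key=lambda p: (-p[0], p[3], p[4]))
    m_best, q_lo, q_hi, name, diag = placements[0]
    ties = sum(1 for p in placements if p[0] >= m_best - 2)
    anchor = Anchor(
        seq_name=name,
        ref_interval=(diag + q_lo, diag + q_hi),
        query_interval=(q_lo, q_hi),
        identity=m_best / (q_hi - q_lo),
        unique=ties == 1,
        n_matches=m_best,
        ambiguity_count=ties,
    )
    kind = _distal_kind(anchor, proximal, ref)
    return DistalAssignment(kind=kind, anchor=anchor, ambiguity_count=ties)


def _first_seed_off(read, ref, name, diag, qs0):
    """Recover one seed offset supporting this diagonal (for extension start)."""
    index = ref.kmer_index(SEED_K)
    for off in range(qs0, len(read) - SEED_K + 1, 7):
        for nm, pos in index.get(read[off : off + SEED_K], [])[:80]:
            if nm == name and pos - off == diag:
                return off
    return max(qs0, 0)


def _distal_kind(anchor: Anchor, proximal: Anchor, ref: ReferenceGenome) -> str:
    feats = ref.feature_at(anchor.seq_name, *anchor.ref_interval)
    kinds = {f.kind for f in feats}
    if anchor.seq_name == proximal.seq_name:
        if "tar_block" in kinds:
            return "tar_block"
        return "genomic_locus"
    # different sequence: its chromosome end counts as a foreign subtelomere
    seq_len = len(ref.sequences[anchor.seq_name])
    if {"tar_block", "telomere_array"} & kinds or anchor.ref_interval[1] >= seq_len - 1500:
        return "foreign_subtelomere"
    return "genomic_locus"


# ---------------------------------------------------------------------------
# junction resolution


def junction_microhomology(
    proximal: Anchor, distal: Anchor, ref: ReferenceGenome, read: str
) -> tuple[int, str]:
    """Microhomology between two genomic anchors: the overlap of the two
    alignments on the read (equivalently, the run of split points that are
    all optimal and matched on both diagonals)."""
    if proximal.query_interval[1] - distal.query_interval[0] > 50:
        raise ValueError("anchor conflict: anchors overlap by more than 50 bp on the read")
    pm = _match_profile(read, ref.sequences[proximal.seq_name], proximal.diagonal)
    dm = _match_profile(read, ref.sequences[distal.seq_name], distal.diagonal)
    i, j, lo, hi = _optimal_split(pm, dm)
    if j > i:
        return 0, ""
    return hi - lo, read[lo:hi]


def detect_untemplated_insert(read: str, proximal: Anchor, distal: Anchor, ref: ReferenceGenome) -> str:
    """Read bases between the two anchors that match neither side."""
    pm = _match_profile(read, ref.sequences[proximal.seq_name], proximal.diagonal)
    dm = _match_profile(read, ref.sequences[distal.seq_name], distal.diagonal)
    i, j, _, _ = _optimal_split(pm, dm)
    return read[i:j]


def find_inverted_template(
    insert_or_gap: str, search_interval_seq: str, min_len: int = 15
) -> tuple[int, int, str, int] | None:
    """Locate the insert (or its longest sub-segment >= min_len) as an exact
    substring of the search interval, in reverse-complement or forward
    orientation.

    Returns ``(source_start, source_end, orientation, insert_offset)`` with
    positions relative to ``search_interval_seq``, or None.
    """
    n = len(insert_or_gap)
    if n < min_len:
        return None
    for length in range(n, min_len - 1, -1):
        for s in range(0, n - length + 1):
            seg = insert_or_gap[s : s + length]
            pos = search_interval_seq.find(revcomp(seg))
            if pos >= 0:
                return pos, pos + length, "reverse_complement", s
            pos = search_interval_seq.find(seg)
            if pos >= 0:
                return pos, pos + length, "forward", s
    return None


def _extend_template(
    read: str, gap_i: int, gap_j: int, core_off: int,
    ref_seq: str, a: int, b: int, orientation: str,
) -> tuple[int, int, int, int]:
    """Extend an exact template core match outward in read coordinates.

    Returns the extended source interval (a, b) and the extension amounts
    (left, right) in read space beyond the gap boundaries.
    """
    iT = gap_i + core_off
    jT = iT + (b - a)
    if orientation == "reverse_complement":
        while iT > 0 and b < len(ref_seq) and read[iT - 1] == revcomp(ref_seq[b]):
            iT -= 1
            b += 1
        while jT < len(read) and a > 0 and read[jT] == revcomp(ref_seq[a - 1]):
            jT += 1
            a -= 1
    else:
        while iT > 0 and a > 0 and read[iT - 1] == ref_seq[a - 1]:
            iT -= 1
            a -= 1
        while jT < len(read) and b < len(ref_seq) and read[jT] == ref_seq[b]:
            jT += 1
            b += 1
    return a, b, max(gap_i - iT, 0), max(jT - gap_j, 0)


def call_junction(read_id: str, read: str, ref: ReferenceGenome, max_gap: int = 20) -> JunctionCall:
    """Full deterministic decomposition of one junction read."""
    try:
        proximal = anchor_proximal(read, ref)
    except ValueError as exc:
        return JunctionCall(read_id=read_id, error=str(exc))
    distal = assign_distal(read, proximal, ref, max_gap=max_gap)
    call = JunctionCall(read_id=read_id, proximal=proximal, distal=distal)
    ref_p = ref.sequences[proximal.seq_name]
    pm = _match_profile(read, ref_p, proximal.diagonal)

    if distal.kind == "telomere_array":
        hit: TelomereArrayHit = distal.anchor
        dm = _telomere_profile(read, hit.start)
        i, j, lo, hi = _optimal_split(pm, dm)
        j = min(j, hit.start) if j > i else j
        call.hexamer_copies = hit.copies
        if j > i:
            call.untemplated_insert = read[i:j]
            call.breakpoint_interval = _to_ref(proximal, i, i)
        else:
            junction = min(hi, hit.start)
            mh = telomere_fusion_microhomology(
                ref_p[: proximal.diagonal + junction], hit
            )
            call.microhomology_len = mh
            call.microhomology_seq = read[junction - mh : junction]
            call.breakpoint_interval = _to_ref(proximal, junction - mh, junction)
        return call

    if distal.kind == "unassigned" or distal.anchor is None:
        call.error = "distal side unassigned"
        return call

    d_anchor: Anchor = distal.anchor
    dm = _match_profile(read, ref.sequences[d_anchor.seq_name], d_anchor.diagonal)
    i, j, lo, hi = _optimal_split(pm, dm)
    if j > i:
        gap = read[i:j]
        template = _search_template(read, i, j, gap, proximal, d_anchor, ref)
        if template is not None:
            call.template_insert = template
            # the switch microhomology makes the proximal breakpoint ambiguous
            call.breakpoint_interval = _to_ref(proximal, i - template.mh_prox, i)
        else:
            call.untemplated_insert = gap
            call.breakpoint_interval = _to_ref(proximal, i, i)
    else:
        call.microhomology_len = hi - lo
        call.microhomology_seq = read[lo:hi]
        call.breakpoint_interval = _to_ref(proximal, lo, hi)
    return call


def _to_ref(proximal: Anchor, lo: int, hi: int) -> tuple[int, int]:
    """Breakpoint interval on the proximal reference (width = mh + 1)."""
    d = proximal.diagonal
    return (d + lo, d + hi + 1)


def _search_template(
    read: str,
    gap_i: int,
    gap_j: int,
    gap: str,
    proximal: Anchor,
    distal: Anchor,
    ref: ReferenceGenome,
    min_len: int = 15,
) -> TemplateInsert | None:
    """Search the deleted interval for the (inverted) template of an insertion."""
    if distal.seq_name != proximal.seq_name:
        return None
    p_end = proximal.diagonal + gap_i
    d_start = distal.diagonal + gap_j
    if d_start <= p_end:  # no deleted interval (ring-type topology)
        return None
    ref_seq = ref.sequences[proximal.seq_name]
    w_lo = max(p_end - 40, 0)
    w_hi = min(d_start + 40, len(ref_seq))
    hit = find_inverted_template(gap, ref_seq[w_lo:w_hi], min_len=min_len)
    if hit is None:
        return None
    a, b, orientation, off = hit
    a, b, ext_l, ext_r = _extend_template(
        read, gap_i, gap_j, off, ref_seq, w_lo + a, w_lo + b, orientation
    )
    return TemplateInsert(
        seq_name=proximal.seq_name,
        source_interval=(a, b),
        orientation=orientation,
        mh_prox=ext_l,
        mh_dist=ext_r,
    )
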