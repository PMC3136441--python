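"""Simulate junction reads with known truth for every repair-mechanism class.

Each simulator emits a junction read (proximal genomic flank fused to a
mechanism-specific distal segment) together with a truth record carrying
the exact engineered signature: breakpoint position(s), telomere hexamer
copy count, fusion/junction microhomology, untemplated insertion, and the
source interval of any templated insert.

Signatures are engineered by scanning candidate breakpoints for positions
whose local sequence realizes the requested microhomology *exactly* (no
more, no less), and every constructed read is validated with a brute-force
split scan -- an exhaustive O(w^2) enumeration of junction splits,
independent of the optimized resolver in :mod:`junctionmech.align` -- so
that the recorded truth is precisely the maximal analyzer-visible signal.
Reads failing validation (e.g. an insertion that coincidentally extends a
flank) are resampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._dna import common_suffix_len, lcp_len, mutate, random_dna, revcomp
from .reference import ReferenceGenome
from .telomere import CANONICAL_UNIT, find_telomere_array, _unit_ok

MECHANISMS = (
    "telomere_healing",
    "telomere_capture",
    "nhej_interstitial",
    "fostes_mmbir",
    "ring_junction",
    "translocation",
)

#: cohort mixture echoing the catalog's class sizes: 30 terminal (27 healed /
#: 3 captured), 6 ring, 3 translocation, 5 interstitial (4 end-joined / 1
#: replication-templated)
DEFAULT_MIXTURE = {
    "telomere_healing": 27,
    "telomere_capture": 3,
    "ring_junction": 6,
    "translocation": 3,
    "nhej_interstitial": 4,
    "fostes_mmbir": 1,
}

FLANK = 180
UNIT = CANONICAL_UNIT


@dataclass
class RearrangementTruth:
    """Ground truth for one simulated junction read."""

    mechanism: str
    read_id: str
    seed: int
    breakpoints: list[int] = field(default_factory=list)
    proximal_seq: str = "chrT"
    distal: dict | None = None
    hexamer_copies: int | None = None
    fusion_microhomology: int = 0
    untemplated_insertion: str = ""
    template_insert: dict | None = None
    deletion: tuple[int, int] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


class SimulationError(RuntimeError):
    """A requested signature could not be realized on this reference."""


# ---------------------------------------------------------------------------
# brute-force junction validation (oracle formulation)


def _split_profiles(read: str, ref_seq: str, diag: int, dm: list[int]):
    n = len(read)
    pm = [
        1 if 0 <= diag + i < len(ref_seq) and read[i] == ref_seq[diag + i] else 0
        for i in range(n)
    ]
    P = [0] * (n + 1)
    D = [0] * (n + 1)
    for t in range(n):
        P[t + 1] = P[t] + (1 if pm[t] else -1)
    for t in range(n - 1, -1, -1):
        D[t] = D[t + 1] + (1 if dm[t] else -1)
    return pm, P, D


def _brute_best_splits(read, ref_seq, diag, dm, w_lo, w_hi):
    """Exhaustively score every split (i, j), i<=j, inside the window.

    Returns (best_score, min_gap_at_best, splits) where splits is the list of
    (i, j) pairs achieving the best score at the minimal gap.
    """
    pm, P, D = _split_profiles(read, ref_seq, diag, dm)
    n = len(read)
    w_lo = max(w_lo, 0)
    w_hi = min(w_hi, n)
    best = None
    for i in range(w_lo, w_hi + 1):
        for j in range(i, w_hi + 1):
            s = P[i] + D[j]
            key = (-s, j - i)
            if best is None or key < best[0]:
                best = (key, [(i, j)])
            elif key == best[0]:
                best[1].append((i, j))
    (neg_s, gap), splits = best
    return -neg_s, gap, splits, pm


def _validate_split(read, ref_seq, diag, dm, expect_i, expect_j, expect_lo=None, expect_hi=None):
    """Check that the engineered junction is the brute-force optimum.

    For a gapless junction, the optimal zero-gap split positions connected
    through both-sides-matching bases must be exactly [expect_lo, expect_hi].
    For an insertion, (expect_i, expect_j) must be the unique minimal-gap
    optimum.
    """
    w_lo = expect_i - 45
    w_hi = expect_j + 45
    score, gap, splits, pm = _brute_best_splits(read, ref_seq, diag, dm, w_lo, w_hi)
    if expect_i == expect_j:
        if gap != 0:
            return False
        ks = sorted(i for i, j in splits)
        run = [k for k in ks if expect_lo <= k <= expect_hi]
        if run != list(range(expect_lo, expect_hi + 1)):
            return False
        # no optimal split may extend the homology run beyond the engineered one
        for k in ks:
            if k < expect_lo or k > expect_hi:
                lo_k = min(k, expect_lo)
                hi_k = max(k, expect_hi)
                if all(pm[t] and dm[t] for t in range(lo_k, hi_k)):
                    return False
        return True
    if gap != expect_j - expect_i:
        return False
    return splits == [(expect_i, expect_j)]


def _telomere_dm(read: str, array_start: int) -> list[int]:
    return [1 if c == UNIT[(i - array_start) % 6] else 0 for i, c in enumerate(read)]


def _diag_dm(read: str, ref_seq: str, diag: int) -> list[int]:
    return [
        1 if 0 <= diag + i < len(ref_seq) and c == ref_seq[diag + i] else 0
        for i, c in enumerate(read)
    ]


# ---------------------------------------------------------------------------
# breakpoint scanning


def _fusion_k(A: str, b: int) -> int:
    """Fusion microhomology at b, either annealing register (see telomere)."""
    for k in range(6, 0, -1):
        tail = A[b - k : b]
        if tail == UNIT[6 - k :] or tail == UNIT[:k]:
            return k
    return 0


def _suffix_register_k(A: str, b: int) -> int:
    """In-phase-extension (suffix register) component of the fusion overlap."""
    for k in range(6, 0, -1):
        if A[b - k : b] == UNIT[6 - k :]:
            return k
    return 0


def _pair_overlap(A: str, bp: int, B: str, d: int) -> tuple[int, int]:
    """(forward, backward) components of the junction overlap for A[:bp]+B[d:]."""
    a = lcp_len(A[bp : bp + 24], B[d : d + 24])
    s = common_suffix_len(A[max(bp - 24, 0) : bp], B[max(d - 24, 0) : d])
    return a, s


def _q_arm_range(ref: ReferenceGenome, flank: int) -> tuple[int, int]:
    cfg = ref.config
    lo = cfg.p_arm_len + 10_000 + cfg.paralog_len + flank + 200
    hi = cfg.chrom_len - 6 * cfg.telomere_units - cfg.tar_len - flank - 200
    return lo, hi


def _scan_position(rng, lo, hi, pred, tries=40_000):
    span = hi - lo
    start = int(rng.integers(0, span))
    for t in range(min(tries, span)):
        b = lo + (start + t * 7919) % span  # co-prime stride covers the range
        if pred(b):
            return b
    raise SimulationError("no breakpoint realizes the requested signature")


def _spiral(center, lo, hi, radius):
    yield center
    for r in range(1, radius):
        if center + r < hi:
            yield center + r
        if center - r >= lo:
            yield center - r


# ---------------------------------------------------------------------------
# simulators


def simulate_terminal_healing(
    ref: ReferenceGenome,
    del_size: int | None = None,
    copies: int = 6,
    mh: int = 0,
    insert: str = "",
    seed: int = 0,
    flank: int = FLANK,
    read_id: str | None = None,
) -> tuple[tuple[str, str], RearrangementTruth]:
    """Terminal deletion healed by de novo telomere addition.

    The read is ``[>=flank bp proximal flank][insert][copies x GGTTAG]``.
    When ``mh > 0`` the breakpoint is placed where the reference suffix
    equals the in-phase hexamer suffix of exactly that length.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if not 0 <= mh <= 6:
        raise ValueError("mh must be in [0, 6]")
    if insert and mh > 0:
        raise ValueError("an untemplated insertion and fusion microhomology are mutually exclusive")
    rng = np.random.default_rng(seed)
    A = ref.sequences["chrT"]
    L = len(A)
    lo, hi = _q_arm_range(ref, flank)
    if del_size is not None and del_size >= L:
        raise ValueError("del_size beyond chromosome length")

    def ok(b):
        if not ref.uniquely_mappable("chrT", b - flank - 10, b + 10):
            return False
        if A[b] == "G":  # keep the junction phase-unambiguous on the right
            return False
        if _unit_ok(A[b - 6 : b]) and _unit_ok(A[b - 12 : b - 6]):
            return False  # a variant-unit block would absorb into the array
        return _fusion_k(A, b) == mh

    if del_size is not None:
        target = max(lo, min(L - del_size, hi - 1))
        b = next((c for c in _spiral(target, lo, hi, 8_000) if ok(c)), None)
        if b is None:
            b = _scan_position(rng, lo, hi, ok)
    else:
        b = _scan_position(rng, lo, hi, ok)

    for _ in range(100):
        read = A[b - flank : b] + insert + UNIT * copies
        hit = find_telomere_array(read)
        if (
            hit is not None
            and hit.start == flank + len(insert)
            and hit.copies == copies
            and not hit.variant_units
        ):
            dm = _telomere_dm(read, hit.start)
            if insert:
                valid = _validate_split(read, A, b - flank, dm, flank, flank + len(insert))
            else:
                # only the suffix-register (in-phase extension) component of the
                # fusion overlap appears as a split-point tie on the read
                s_k = _suffix_register_k(A, b)
                valid = _validate_split(read, A, b - flank, dm, flank, flank, flank - s_k, flank)
            if valid:
                break
        if not insert:
            raise SimulationError("healing junction failed validation")
        insert = random_dna(rng, len(insert))
    else:
        raise SimulationError("could not realize the requested untemplated insertion")

    rid = read_id or f"healing_s{seed}"
    truth = RearrangementTruth(
        mechanism="telomere_healing",
        read_id=rid,
        seed=seed,
        breakpoints=[b],
        distal={"kind": "telomere_array"},
        hexamer_copies=copies,
        fusion_microhomology=0 if insert else mh,
        untemplated_insertion=insert,
        deletion=(b, L),
    )
    return (rid, read), truth


def simulate_telomere_capture(
    ref: ReferenceGenome,
    del_size: int | None = None,
    source: str = "tar_block",
    seed: int = 0,
    mutation_rate: float = 0.005,
    flank: int = FLANK,
    block_len: int = 600,
    append_telomere_units: int = 8,
    read_id: str | None = None,
) -> tuple[tuple[str, str], RearrangementTruth]:
    """Terminal deletion repaired by capturing subtelomeric sequence.

    ``source='tar_block'`` copies a block of the TAR feature (optionally
    followed by a short telomere array); ``source='foreign_subtelomere'``
    copies the terminal 450 bp of the second chromosome end.  The copy is
    mutated by uniform substitutions at ``mutation_rate``.
    """
    if source not in ("tar_block", "foreign_subtelomere"):
        raise ValueError(f"unknown capture source {source!r}")
    rng = np.random.default_rng(seed)
    A = ref.sequences["chrT"]
    L = len(A)
    lo, hi = _q_arm_range(ref, flank)
    if del_size is not None and del_size >= L:
        raise ValueError("del_size beyond chromosome length")

    def ok(b):
        return ref.uniquely_mappable("chrT", b - flank - 10, b + 10)

    if del_size is not None:
        target = max(lo, min(L - del_size, hi - 1))
        b = next((c for c in _spiral(target, lo, hi, 2_000) if ok(c)), None) or _scan_position(rng, lo, hi, ok)
    else:
        b = _scan_position(rng, lo, hi, ok)

    if source == "tar_block":
        tar = ref.features_of_kind("tar_block", "chrT")[0]
        off = int(rng.integers(0, tar.end - tar.start - block_len))
        src_seq_name, src_start = "chrT", tar.start + off
        block = mutate(A[src_start : src_start + block_len], mutation_rate, rng)
        suffix = block + UNIT * append_telomere_units
    else:
        O = ref.sequences["chrO"]
        src_seq_name = "chrO"
        src_start = len(O) - ref.config.foreign_subtelomere_len
        suffix = mutate(O[src_start:], mutation_rate, rng)

    read = A[b - flank : b] + suffix
    # measure the junction microhomology the analyzer will see (brute force)
    dm = _diag_dm(read, ref.sequences[src_seq_name], src_start - flank)
    _, gap, splits, pm = _brute_best_splits(read, A, b - flank, dm, flank - 45, flank + 45)
    measured_mh = 0
    if gap == 0:
        ks = sorted(i for i, j in splits)
        k0 = min(ks, key=lambda k: abs(k - flank))
        lo_k = hi_k = k0
        while lo_k - 1 in ks and pm[lo_k - 1] and dm[lo_k - 1]:
            lo_k -= 1
        while hi_k in ks and hi_k < len(read) and pm[hi_k] and dm[hi_k]:
            hi_k += 1
        measured_mh = hi_k - lo_k

    rid = read_id or f"capture_s{seed}"
    truth = RearrangementTruth(
        mechanism="telomere_capture",
        read_id=rid,
        seed=seed,
        breakpoints=[b],
        distal={"kind": source, "seq_name": src_seq_name, "pos": src_start},
        fusion_microhomology=measured_mh,
        deletion=(b, L),
    )
    return (rid, read), truth


def _two_locus_read(
    ref, rng, A_name, bp, B_name, d_lo, d_hi, mh, insert, flank, forbid_same_diag=True
):
    """Scan the distal range for a locus realizing the junction overlap ``mh``
    exactly, then build and validate the fused read."""
    A = ref.sequences[A_name]
    B = ref.sequences[B_name]

    def ok(d):
        if forbid_same_diag and A_name == B_name and abs(d - bp) < flank * 2 + 60:
            return False
        if not ref.uniquely_mappable(B_name, d - 10, d + flank + 10):
            return False
        a, s = _pair_overlap(A, bp, B, d)
        if insert:
            return a == 0 and s == 0
        return a + s == mh

    d = _scan_position(rng, d_lo, d_hi, ok)
    a, s = _pair_overlap(A, bp, B, d)
    ins = insert
    for _ in range(100):
        read = A[bp - flank : bp] + ins + B[d : d + flank]
        dm = _diag_dm(read, B, d - flank - len(ins))
        if ins:
            valid = _validate_split(read, A, bp - flank, dm, flank, flank + len(ins))
        else:
            valid = _validate_split(read, A, bp - flank, dm, flank + a, flank + a, flank - s, flank + a)
        if valid:
            return read, d, ins
        if not ins:
            raise SimulationError("junction overlap failed validation")
        ins = random_dna(rng, len(ins))
    raise SimulationError("could not realize the requested untemplated insertion")


def simulate_interstitial_nhej(
    ref: ReferenceGenome,
    del_size: int = 5_000,
    mh: int = 0,
    insert: str = "",
    seed: int = 0,
    flank: int = FLANK,
    read_id: str | None = None,
) -> tuple[tuple[str, str], RearrangementTruth]:
    """Interstitial deletion joined by non-homologous end joining."""
    if insert and mh > 0:
        raise ValueError("an untemplated insertion and junction microhomology are mutually exclusive")
    rng = np.random.default_rng(seed)
    lo, hi = _q_arm_range(ref, flank)
    if del_size <= 0 or del_size > ref.config.max_del_size:
        raise ValueError("del_size must be in (0, max_del_size]")

    A = ref.sequences["chrT"]
    for _ in range(40):
        bp = _scan_position(
            rng, lo, hi - del_size - 2_500,
            lambda b: ref.uniquely_mappable("chrT", b - flank - 10, b + 10),
        )
        try:
            read, bd, ins = _two_locus_read(
                ref, rng, "chrT", bp, "chrT",
                bp + max(del_size - 2_000, flank * 2 + 80), bp + del_size + 2_000,
                mh, insert, flank, forbid_same_diag=False,
            )
            break
        except SimulationError:
            continue
    else:
        raise SimulationError("no interstitial junction realizes the requested signature")

    rid = read_id or f"nhej_s{seed}"
    truth = RearrangementTruth(
        mechanism="nhej_interstitial",
        read_id=rid,
        seed=seed,
        breakpoints=[bp, bd],
        distal={"kind": "genomic_locus", "seq_name": "chrT", "pos": bd},
        fusion_microhomology=0 if ins else mh,
        untemplated_insertion=ins,
        deletion=(bp, bd),
    )
    return (rid, read), truth


def simulate_fostes(
    ref: ReferenceGenome,
    del_size: int = 5_000,
    template_len: int = 24,
    mh_prox: int = 4,
    mh_dist: int = 2,
    seed: int = 0,
    orientation: str = "reverse_complement",
    flank: int = FLANK,
    read_id: str | None = None,
) -> tuple[tuple[str, str], RearrangementTruth]:
    """Interstitial deletion with a templated insert copied from the deleted
    interval (fork stalling / template switching), flanked by the requested
    switch-point microhomologies."""
    if template_len == 0:
        return simulate_interstitial_nhej(
            ref, del_size=del_size, mh=0, seed=seed, flank=flank, read_id=read_id
        )
    if orientation not in ("reverse_complement", "forward"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rng = np.random.default_rng(seed)
    lo, hi = _q_arm_range(ref, flank)
    A = ref.sequences["chrT"]
    Lt = template_len
    core_len = Lt - mh_prox - mh_dist
    if core_len < 15:
        raise ValueError("template minus switch microhomologies must leave a >=15 bp core")

    for _ in range(200):
        bp = _scan_position(
            rng, lo, hi - del_size - 200,
            lambda b: ref.uniquely_mappable("chrT", b - flank - 10, b + 10),
        )
        bd = bp + del_size
        if not ref.uniquely_mappable("chrT", bd - 10, bd + flank + 10):
            continue
        seg_of = (lambda t0: revcomp(A[t0 : t0 + Lt])) if orientation == "reverse_complement" else (
            lambda t0: A[t0 : t0 + Lt]
        )

        def ok(t0):
            seg = seg_of(t0)
            if lcp_len(seg, A[bp : bp + Lt]) != mh_prox:
                return False
            if common_suffix_len(seg, A[bd - Lt : bd]) != mh_dist:
                return False
            t1 = t0 + Lt
            if orientation == "reverse_complement":
                if bp > 0 and A[bp - 1] == revcomp(A[t1]):
                    return False  # template extension would overrun t1
                if A[bd] == revcomp(A[t0 - 1]):
                    return False
            else:
                if bp > 0 and A[bp - 1] == A[t0 - 1]:
                    return False
                if A[bd] == A[t1]:
                    return False
            core = seg[mh_prox : Lt - mh_dist]
            window = A[bp - 40 : bd + 40]
            rc_core = revcomp(core)
            if orientation == "reverse_complement":
                return window.count(rc_core) == 1 and window.count(core) == 0
            return window.count(core) == 1 and window.count(rc_core) == 0

        try:
            t0 = _scan_position(rng, bp + 60, bd - 60 - Lt, ok, tries=del_size)
        except SimulationError:
            continue
        seg = seg_of(t0)
        read = A[bp - flank : bp] + seg + A[bd : bd + flank]
        dm = _diag_dm(read, A, bd - flank - Lt)
        if _validate_split(read, A, bp - flank, dm, flank + mh_prox, flank + Lt - mh_dist):
            break
    else:
        raise SimulationError("no templated junction realizes the requested signature")

    rid = read_id or f"fostes_s{seed}"
    truth = RearrangementTruth(
        mechanism="fostes_mmbir",
        read_id=rid,
        seed=seed,
        breakpoints=[bp, bd],
        distal={"kind": "genomic_locus", "seq_name": "chrT", "pos": bd},
        template_insert={
            "start": t0,
            "end": t0 + Lt,
            "orientation": orientation,
            "mh_prox": mh_prox,
            "mh_dist": mh_dist,
        },
        deletion=(bp, bd),
    )
    return (rid, read), truth


def simulate_ring_junction(
    ref: ReferenceGenome,
    q_del_size: int = 20_000,
    mh: int = 0,
    seed: int = 0,
    flank: int = FLANK,
    p_arm_locus: int | None = None,
    read_id: str | None = None,
) -> tuple[tuple[str, str], RearrangementTruth]:
    """Ring-chromosome junction: the broken q arm joins the p arm of the same
    chromosome (reading around the circle, both segments are forward)."""
    rng = np.random.default_rng(seed)
    A = ref.sequences["chrT"]
    cfg = ref.config
    lo, hi = _q_arm_range(ref, flank)
    bq = len(A) - q_del_size
    if q_del_size <= 0 or bq - flank < lo:
        raise ValueError("q_del_size beyond the usable chromosome length")
    bq = min(bq, hi)
    if not ref.uniquely_mappable("chrT", bq - flank - 10, bq + 10):
        bq = _scan_position(
            rng, max(bq - 2_000, lo), min(bq + 2_000, hi),
            lambda b: ref.uniquely_mappable("chrT", b - flank - 10, b + 10),
        )

    if p_arm_locus is not None:
        p0 = p_arm_locus
        read = A[bq - flank : bq] + A[p0 : p0 + flank]
        a, s = _pair_overlap(A, bq, A, p0)
        measured = a + s
    else:
        read, p0, _ = _two_locus_read(
            ref, rng, "chrT", bq, "chrT", 300, cfg.p_arm_len - flank - 20, mh, "", flank
        )
        measured = mh

    rid = read_id or f"ring_s{seed}"
    truth = RearrangementTruth(
        mechanism="ring_junction",
        read_id=rid,
        seed=seed,
        breakpoints=[bq, p0],
        distal={"kind": "genomic_locus", "seq_name": "chrT", "pos": p0},
        fusion_microhomology=measured,
        deletion=(bq, len(A)),
    )
    return (rid, read), truth


def simulate_translocation_junction(
    ref: ReferenceGenome,
    mh: int = 0,
    seed: int = 0,
    del_size: int | None = None,
    flank: int = FLANK,
    read_id: str | None = None,
) -> tuple[tuple[str, str], RearrangementTruth]:
    """Unbalanced-translocation junction joining chrT to the second chromosome
    with the requested junction microhomology."""
    rng = np.random.default_rng(seed)
    A = ref.sequences["chrT"]
    O = ref.sequences["chrO"]
    lo, hi = _q_arm_range(ref, flank)
    if del_size is not None:
        b_target = max(lo, min(len(A) - del_size, hi - 1))
        b = _scan_position(
            rng, max(b_target - 2_000, lo), min(b_target + 2_000, hi),
            lambda x: ref.uniquely_mappable("chrT", x - flank - 10, x + 10),
        )
    else:
        b = _scan_position(
            rng, lo, hi, lambda x: ref.uniquely_mappable("chrT", x - flank - 10, x + 10)
        )
    o_hi = len(O) - 6 * ref.config.telomere_units - 700 - flank - 1_000
    read, c, _ = _two_locus_read(ref, rng, "chrT", b, "chrO", 300, o_hi, mh, "", flank)

    rid = read_id or f"transloc_s{seed}"
    truth = RearrangementTruth(
        mechanism="translocation",
        read_id=rid,
        seed=seed,
        breakpoints=[b, c],
        distal={"kind": "genomic_locus", "seq_name": "chrO", "pos": c},
        fusion_microhomology=mh,
        deletion=(b, len(A)),
    )
    return (rid, read), truth


# ---------------------------------------------------------------------------
# cohorts and panels


def _draw_params(mechanism: str, rng: np.random.Generator) -> dict:
    """Per-read signature parameters mirroring the observed ranges: 3-48
    hexamer copies, 0-5 bp fusion/junction microhomologies, untemplated
    inserts up to 20 bp (healing) or 10 bp (end joining), 22-30 bp inverted
    templates with switch microhomologies."""
    if mechanism == "telomere_healing":
        if rng.random() < 0.6:
            return {"copies": int(rng.integers(3, 49)), "mh": int(rng.integers(0, 6)), "insert": ""}
        return {
            "copies": int(rng.integers(3, 49)),
            "mh": 0,
            "insert": random_dna(rng, int(rng.integers(1, 21))),
        }
    if mechanism == "telomere_capture":
        return {"source": "tar_block" if rng.random() < 2 / 3 else "foreign_subtelomere"}
    if mechanism == "nhej_interstitial":
        params = {"del_size": int(rng.integers(2_000, 15_001))}
        if rng.random() < 0.7:
            params.update(mh=int(rng.integers(0, 6)), insert="")
        else:
            params.update(mh=0, insert=random_dna(rng, int(rng.integers(1, 11))))
        return params
    if mechanism == "fostes_mmbir":
        while True:
            lt = int(rng.integers(22, 31))
            mp = int(rng.integers(0, 5))
            md = int(rng.integers(0, 5))
            if lt - mp - md >= 16:
                return {
                    "del_size": int(rng.integers(3_000, 15_001)),
                    "template_len": lt,
                    "mh_prox": mp,
                    "mh_dist": md,
                }
    if mechanism == "ring_junction":
        return {"q_del_size": int(rng.integers(5_000, 150_001)), "mh": int(rng.integers(0, 5))}
    if mechanism == "translocation":
        return {"mh": int(rng.integers(0, 6))}
    raise ValueError(f"unknown mechanism {mechanism!r}")


_SIMULATORS = {
    "telomere_healing": simulate_terminal_healing,
    "telomere_capture": simulate_telomere_capture,
    "nhej_interstitial": simulate_interstitial_nhej,
    "fostes_mmbir": simulate_fostes,
    "ring_junction": simulate_ring_junction,
    "translocation": simulate_translocation_junction,
}


def _simulate_one(ref, mechanism, seed, read_id, capture_mutation_rate=0.0):
    rng = np.random.default_rng(seed)
    params = _draw_params(mechanism, rng)
    if mechanism == "telomere_capture":
        params["mutation_rate"] = capture_mutation_rate
    return _SIMULATORS[mechanism](ref, seed=seed, read_id=read_id, **params)


def add_read_noise(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform substitution noise applied to an emitted read."""
    return mutate(seq, rate, rng)


def simulate_cohort(
    ref: ReferenceGenome,
    n: int,
    mixture: dict[str, float] | None = None,
    seed: int = 0,
    read_noise: float = 0.0,
    capture_mutation_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], list[RearrangementTruth]]:
    """Simulate ``n`` junction reads with mechanisms drawn from ``mixture``."""
    mixture = mixture or DEFAULT_MIXTURE
    mechs = sorted(mixture)
    weights = np.array([mixture[m] for m in mechs], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(mechs), size=n, p=weights)
    reads, truths = [], []
    for i, k in enumerate(picks):
        mech = mechs[k]
        child = int(rng.integers(0, 2**31 - 1))
        rid = f"{mech}_{i:04d}"
        (rid, seq), truth = _simulate_one(ref, mech, child, rid, capture_mutation_rate)
        if read_noise > 0:
            seq = add_read_noise(seq, read_noise, rng)
        reads.append((rid, seq))
        truths.append(truth)
    return reads, truths


def simulate_mechanism_panel(
    ref: ReferenceGenome,
    per_mechanism: int = 100,
    seed_start: int = 1,
    read_noise: float = 0.0,
) -> tuple[list[tuple[str, str]], list[RearrangementTruth]]:
    """Balanced benchmark panel: ``per_mechanism`` reads of each mechanism,
    consecutive seeds starting at ``seed_start``."""
    reads, truths = [], []
    noise_rng = np.random.default_rng(seed_start + 987_654)
    for m_idx, mech in enumerate(MECHANISMS):
        for k in range(per_mechanism):
            s = seed_start + m_idx * per_mechanism + k
            (rid, seq), truth = _simulate_one(ref, mech, s, f"{mech}_s{s}")
            if read_noise > 0:
                seq = add_read_noise(seq, read_noise, noise_rng)
            reads.append((rid, seq))
            truths.append(truth)
    return reads, truths


# ---------------------------------------------------------------------------
# serialization


def reads_to_fasta(reads: list[tuple[str, str]]) -> str:
    out = []
    for rid, seq in reads:
        out.append(f">{rid}\n")
        for i in range(0, len(seq), 70):
            out.append(seq[i : i + 70] + "\n")
    return "".join(out)


def truths_to_jsonl(truths: list[RearrangementTruth]) -> str:
    return "".join(json.dumps(t.to_dict()) + "\n" for t in truths)
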