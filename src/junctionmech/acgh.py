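"""Probe-level aCGH log2-ratio profiles: simulation, QC, segmentation, and
mosaic-fraction estimation.

A heterozygous deletion present in a fraction f of cells shifts the
expected log2 test/reference ratio of every probe in the deleted region to

    L = log2((2 - f) / 2),

so f = 0 gives 0, a clonal single-copy loss gives -1, and a 30% mosaic
gives about -0.23.  Inverting the model, ``estimate_fraction`` maps a
segment mean back to the deleted-cell fraction, f = 2 (1 - 2^L).

Nested mosaic terminal deletions -- several cell lines sharing a terminal
deletion but with different breakpoints -- produce a stepped profile whose
per-step means become progressively more negative toward the telomere;
``call_stepped_mosaic`` recognizes that pattern from the segmentation.

Noise is quantified by the derivative log-ratio (DLR) spread, a robust
estimate of the per-probe noise SD computed from consecutive-probe
differences: IQR(diff) / (1.349 * sqrt(2)).  Arrays with DLR spread >= 0.30
fail QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from math import log, sqrt

import numpy as np
import pandas as pd


@dataclass
class Profile:
    positions: np.ndarray  # bp, strictly increasing
    log2_ratios: np.ndarray
    spacing: float | None = None  # target probe spacing, bp

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.log2_ratios = np.asarray(self.log2_ratios, dtype=float)
        if self.positions.shape != self.log2_ratios.shape:
            raise ValueError("positions and ratios must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        if not np.all(np.isfinite(self.log2_ratios)):
            raise ValueError("log2 ratios must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    def to_tsv(self) -> str:
        out = StringIO()
        pd.DataFrame({"position": self.positions.astype(int), "log2_ratio": self.log2_ratios}).to_csv(
            out, sep="\t", index=False
        )
        return out.getvalue()

    @classmethod
    def from_tsv(cls, path_or_buffer) -> "Profile":
        df = pd.read_csv(path_or_buffer, sep="\t")
        return cls(df["position"].to_numpy(), df["log2_ratio"].to_numpy())


@dataclass
class Segment:
    start: int  # probe indices, half-open
    end: int
    mean_log2: float
    fraction_estimate: float
    n_probes: int


@dataclass
class SteppedMosaicCall:
    breakpoints: list[float]  # bp positions, ascending
    fractions: list[float]  # per-step deleted-cell fractions, toward the telomere
    monotone: bool
    diagnostic: str = ""


def expected_log2(fraction: float) -> float:
    """Forward model: expected log2 ratio for a heterozygous loss in a
    fraction ``fraction`` of cells."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return float(np.log2((2.0 - fraction) / 2.0))


def estimate_fraction(mean_log2: float) -> float:
    """Invert the single-copy-loss mixture model: f = 2 (1 - 2^L), clipped to [0, 1]."""
    return float(np.clip(2.0 * (1.0 - 2.0**mean_log2), 0.0, 1.0))


def simulate_profile(
    segments: list[tuple[int, float]],
    spacing: int = 400,
    noise_sd: float = 0.1,
    seed: int = 0,
    start: int = 0,
) -> Profile:
    """Simulate a probe-level profile from ``(length_bp, deleted_fraction)``
    segments with Gaussian probe noise."""
    rng = np.random.default_rng(seed)
    positions, ratios = [], []
    pos = start
    for length, f in segments:
        mean = expected_log2(f)
        n = max(int(round(length / spacing)), 1)
        for _ in range(n):
            positions.append(pos)
            ratios.append(mean)
            pos += spacing
    noise = rng.normal(0.0, noise_sd, size=len(ratios)) if noise_sd > 0 else 0.0
    return Profile(np.array(positions, dtype=float), np.array(ratios) + noise, spacing)


def dlr_spread(profile: Profile) -> float:
    """Derivative log-ratio spread: IQR of consecutive-probe differences
    scaled to estimate the per-probe noise SD."""
    if len(profile) < 3:
        raise ValueError("too few probes for DLR spread (need >= 3)")
    d = np.diff(profile.log2_ratios)
    q75, q25 = np.percentile(d, [75, 25])
    return float((q75 - q25) / (1.349 * sqrt(2.0)))


def qc_pass(profile: Profile, threshold: float = 0.30) -> bool:
    """Array QC rule: only experiments with DLR spread below the threshold pass."""
    return dlr_spread(profile) < threshold


def _best_split(y: np.ndarray, c1: np.ndarray, c2: np.ndarray, lo: int, hi: int, min_seg: int):
    """Best single changepoint of y[lo:hi] by residual-sum-of-squares gain."""
    n = hi - lo
    if n < 2 * min_seg:
        return None, 0.0
    s_tot = c1[hi] - c1[lo]
    ss_tot = c2[hi] - c2[lo]
    rss0 = ss_tot - s_tot**2 / n
    best_k, best_gain = None, 0.0
    for k in range(lo + min_seg, hi - min_seg + 1):
        s1 = c1[k] - c1[lo]
        n1 = k - lo
        s2 = s_tot - s1
        n2 = hi - k
        rss = (c2[k] - c2[lo] - s1**2 / n1) + (ss_tot - (c2[k] - c2[lo]) - s2**2 / n2)
        gain = rss0 - rss
        if gain > best_gain:
            best_k, best_gain = k, gain
    return best_k, best_gain


def segment_profile(
    profile: Profile, min_seg_probes: int = 10, penalty: float | None = None
) -> list[Segment]:
    """Binary segmentation on segment means with a BIC-style penalty.

    A split is accepted while its residual-sum-of-squares gain exceeds
    ``penalty`` (default ``3 * sigma^2 * log(n)`` with sigma from the DLR
    spread).  Adjacent segments whose means differ by less than twice the
    standard error of the difference are merged back.  Deterministic.
    """
    y = np.asarray(profile.log2_ratios, dtype=float)
    n = len(y)
    if n < min_seg_probes:
        raise ValueError("profile shorter than one minimal segment")
    sigma = max(dlr_spread(profile), 1e-6)
    if penalty is None:
        penalty = 3.0 * sigma**2 * log(n)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y**2)])

    boundaries = [0, n]
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        k, gain = _best_split(y, c1, c2, lo, hi, min_seg_probes)
        if k is not None and gain > penalty:
            boundaries.append(k)
            stack.extend([(lo, k), (k, hi)])
    boundaries = sorted(set(boundaries))

    # merge adjacent segments with statistically indistinguishable means
    merged = True
    while merged and len(boundaries) > 2:
        merged = False
        for b in range(1, len(boundaries) - 1):
            lo, mid, hi = boundaries[b - 1], boundaries[b], boundaries[b + 1]
            m1 = (c1[mid] - c1[lo]) / (mid - lo)
            m2 = (c1[hi] - c1[mid]) / (hi - mid)
            se = sigma * sqrt(1.0 / (mid - lo) + 1.0 / (hi - mid))
            if abs(m1 - m2) < 2.0 * se:
                boundaries.pop(b)
                merged = True
                break

    segments = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        mean = float((c1[hi] - c1[lo]) / (hi - lo))
        segments.append(
            Segment(lo, hi, mean, estimate_fraction(mean), hi - lo)
        )
    return segments


def call_stepped_mosaic(
    segments: list[Segment], profile: Profile | None = None, deleted_below: float = -0.1
) -> SteppedMosaicCall:
    """Identify a nested mosaic terminal deletion from a segmentation.

    The call is the maximal terminal run of segments whose means decrease
    strictly toward the telomere (profile end); breakpoints fall at the
    segment boundaries and each step carries its own deleted-cell fraction.
    A profile with apparently deleted segments outside that run violates the
    nesting expectation and is rejected (``monotone=False``).
    """
    if not segments:
        raise ValueError("no segments")
    means = [s.mean_log2 for s in segments]
    run_start = len(segments) - 1
    while run_start > 0 and means[run_start - 1] > means[run_start] + 1e-12:
        run_start -= 1
    offending = [
        i for i in range(run_start) if means[i] < deleted_below
    ]
    monotone = not offending
    breakpoints: list[float] = []
    for s in segments[max(run_start, 1) :]:
        if profile is not None:
            prev_pos = profile.positions[s.start - 1]
            breakpoints.append(float((prev_pos + profile.positions[s.start]) / 2.0))
        else:
            breakpoints.append(float(s.start))
    fractions = [s.fraction_estimate for s in segments[max(run_start, 1) :]]
    diagnostic = (
        "" if monotone else f"segments {offending} are deleted but outside the terminal nested run"
    )
    return SteppedMosaicCall(breakpoints, fractions, monotone, diagnostic)
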