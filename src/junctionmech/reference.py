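"""Toy reference genome with the sequence features terminal-deletion repair needs.

The simulated reference is deliberately small (a 200 kb main chromosome
instead of ~49 Mb of real 22q) but carries literal-scale local sequence
features, since junction analysis only ever looks at local sequence:

* ``chrT`` -- the main chromosome: a short p-arm with identical repeat-decoy
  copies, a near-identical paralog block (the RABL2A/RABL2B situation), a toy
  gene model with a GC-rich simple-repeat hotspot, a subtelomeric TAR block,
  and a terminal (GGTTAG)n telomere array.
* ``chrO`` -- a second chromosome end providing the paralog partner and a
  foreign subtelomere (TAR-like block + telomere array) that telomere-capture
  junctions can acquire.

Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from io import StringIO

import numpy as np

from ._dna import mutate, random_dna
from .telomere import CANONICAL_UNIT

FEATURE_KINDS = frozenset(
    {
        "telomere_array",
        "tar_block",
        "paralog_block",
        "repeat_decoy",
        "gc_rich_hotspot",
        "gene_model",
    }
)


@dataclass
class FeatureAnnotation:
    seq_name: str
    start: int
    end: int
    kind: str
    label: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"feature {self.label!r}: start must be < end")


@dataclass
class SimConfig:
    """Dimensions of the toy reference.

    ``chrom_len`` must be at least ten times ``max_del_size`` so that every
    simulated deletion leaves ample intact sequence for anchoring.
    """

    chrom_len: int = 200_000
    other_len: int = 60_000
    tar_len: int = 2_000
    telomere_units: int = 50
    paralog_len: int = 2_000
    paralog_identity: float = 0.995
    p_arm_len: int = 20_000
    decoy_len: int = 500
    decoy_copies: int = 3
    gc: float = 0.48
    max_del_size: int = 15_000
    foreign_subtelomere_len: int = 450


@dataclass
class ReferenceGenome:
    sequences: dict[str, str]
    features: list[FeatureAnnotation]
    seed: int
    config: SimConfig = field(default_factory=SimConfig)
    _kmer_index: dict | None = field(default=None, repr=False, compare=False)

    @property
    def primary(self) -> str:
        return "chrT"

    def feature_at(self, seq_name: str, start: int, end: int) -> list[FeatureAnnotation]:
        """Features overlapping the given interval."""
        return [
            f
            for f in self.features
            if f.seq_name == seq_name and f.start < end and start < f.end
        ]

    def features_of_kind(self, kind: str, seq_name: str | None = None) -> list[FeatureAnnotation]:
        return [
            f
            for f in self.features
            if f.kind == kind and (seq_name is None or f.seq_name == seq_name)
        ]

    def uniquely_mappable(self, seq_name: str, start: int, end: int) -> bool:
        """True when the interval avoids multi-copy features (decoys, paralogs)
        and the telomere/TAR region, so a read flank from it anchors uniquely."""
        for f in self.feature_at(seq_name, start - 10, end + 10):
            if f.kind in ("repeat_decoy", "paralog_block", "telomere_array", "tar_block"):
                return False
        return True

    def kmer_index(self, k: int = 20) -> dict[str, list[tuple[str, int]]]:
        """Forward-strand exact k-mer hash over all sequences (built lazily)."""
        if self._kmer_index is None:
            index: dict[str, list[tuple[str, int]]] = {}
            for name, seq in self.sequences.items():
                for i in range(len(seq) - k + 1):
                    index.setdefault(seq[i : i + k], []).append((name, i))
            self._kmer_index = index
        return self._kmer_index

    def to_fasta(self) -> str:
        out = StringIO()
        for name, seq in self.sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")
        return out.getvalue()

    def features_to_bed(self) -> str:
        return "".join(
            f"{f.seq_name}\t{f.start}\t{f.end}\t{f.kind}:{f.label}\n" for f in self.features
        )


def build_reference(config: SimConfig | None = None, seed: int = 0) -> ReferenceGenome:
    """Build the toy two-chromosome reference deterministically from (config, seed)."""
    cfg = config or SimConfig()
    if cfg.telomere_units < 1:
        raise ValueError("telomere_units must be >= 1")
    if cfg.chrom_len < 10 * cfg.max_del_size:
        raise ValueError(
            "chrom_len must be at least 10x max_del_size "
            f"({cfg.chrom_len} < {10 * cfg.max_del_size})"
        )
    telomere_len = 6 * cfg.telomere_units
    if cfg.p_arm_len + cfg.tar_len + telomere_len + 40_000 > cfg.chrom_len:
        raise ValueError("chrom_len too small for the requested features")

    rng = np.random.default_rng(seed)
    features: list[FeatureAnnotation] = []

    chrT = list(random_dna(rng, cfg.chrom_len, cfg.gc))
    chrO = list(random_dna(rng, cfg.other_len, cfg.gc))

    def plant(target: list[str], start: int, block: str) -> None:
        target[start : start + len(block)] = block

    # identical repeat-decoy copies on the p-arm
    decoy = random_dna(rng, cfg.decoy_len)
    decoy_starts = [2_000 + i * 4_000 for i in range(cfg.decoy_copies)]
    for i, s in enumerate(decoy_starts):
        if s + cfg.decoy_len > cfg.p_arm_len:
            raise ValueError("p_arm_len too small for the requested decoy copies")
        plant(chrT, s, decoy)
        features.append(FeatureAnnotation("chrT", s, s + cfg.decoy_len, "repeat_decoy", f"decoy{i + 1}"))

    # near-identical paralog pair (one copy per chromosome)
    paralog = random_dna(rng, cfg.paralog_len)
    pA = cfg.p_arm_len + 10_000
    plant(chrT, pA, paralog)
    features.append(FeatureAnnotation("chrT", pA, pA + cfg.paralog_len, "paralog_block", "paralogA"))
    pB = 10_000
    plant(chrO, pB, mutate(paralog, 1.0 - cfg.paralog_identity, rng))
    features.append(FeatureAnnotation("chrO", pB, pB + cfg.paralog_len, "paralog_block", "paralogB"))

    # toy gene model with a GC-rich simple-repeat hotspot in one "intron"
    g0 = cfg.chrom_len - 50_000
    features.append(FeatureAnnotation("chrT", g0, g0 + 10_000, "gene_model", "toy_gene"))
    hotspot = ("GCCGGGGCGGGG" * 5)[:60]
    plant(chrT, g0 + 5_000, hotspot)
    features.append(
        FeatureAnnotation("chrT", g0 + 5_000, g0 + 5_000 + 60, "gc_rich_hotspot", "toy_gene_intron_repeat")
    )

    # subtelomere: TAR block immediately proximal to the terminal telomere array
    tel_start = cfg.chrom_len - telomere_len
    tar_start = tel_start - cfg.tar_len
    plant(chrT, tar_start, random_dna(rng, cfg.tar_len))
    plant(chrT, tel_start, CANONICAL_UNIT * cfg.telomere_units)
    features.append(FeatureAnnotation("chrT", tar_start, tel_start, "tar_block", "TAR_22q"))
    features.append(FeatureAnnotation("chrT", tel_start, cfg.chrom_len, "telomere_array", "tel_22q"))

    # foreign chromosome end: TAR-like block + telomere array
    o_tel_start = cfg.other_len - telomere_len
    o_tar_start = o_tel_start - 700
    plant(chrO, o_tar_start, random_dna(rng, 700))
    plant(chrO, o_tel_start, CANONICAL_UNIT * cfg.telomere_units)
    features.append(FeatureAnnotation("chrO", o_tar_start, o_tel_start, "tar_block", "TAR_other"))
    features.append(FeatureAnnotation("chrO", o_tel_start, cfg.other_len, "telomere_array", "tel_other"))

    return ReferenceGenome(
        sequences={"chrT": "".join(chrT), "chrO": "".join(chrO)},
        features=features,
        seed=seed,
        config=cfg,
    )
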