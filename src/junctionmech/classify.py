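"""Map a junction decomposition to a repair-mechanism label.

The decision table formalizes the interpretive logic used for terminal-
deletion junctions: a canonical telomere array fused (near-)directly to
chromosomal sequence is de novo telomere addition; subtelomeric (TAR or
foreign chromosome-end) sequence at the distal side is telomere capture; a
templated (usually inverted) insert is replication-based template switching
(FoSTeS/MMBIR); a plain two-locus junction with at most a few bases of
microhomology and at most a short untemplated insert is non-homologous end
joining.  The thresholds have no canonical values in the field; the
defaults bracket the observed ranges (inserts up to 20 bp, microhomologies
well under 10 bp, templated inserts of ~20-30 bp) and are all configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import Anchor, JunctionCall

LABELS = ("telomere_healing", "telomere_capture", "NHEJ", "FoSTeS_MMBIR", "unresolved")


@dataclass
class ClassifierConfig:
    max_healing_gap: int = 20  # longest untemplated insert still called healing
    max_nhej_microhomology: int = 10
    max_nhej_insert: int = 20
    min_template_len: int = 15


@dataclass
class MechanismLabel:
    label: str
    subtype: str = "none"
    evidence: list[str] = field(default_factory=list)
    confidence: str = "high"

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "subtype": self.subtype,
            "evidence": list(self.evidence),
            "confidence": self.confidence,
        }


def classify_junction(call: JunctionCall, config: ClassifierConfig | None = None) -> MechanismLabel:
    """Deterministic first-match decision table over a complete junction call."""
    cfg = config or ClassifierConfig()
    if call.error or call.proximal is None or call.distal is None:
        return MechanismLabel(
            "unresolved", "none", [f"incomplete call: {call.error or 'missing anchors'}"], "low"
        )

    low_conf = not call.proximal.unique
    distal = call.distal
    if isinstance(distal.anchor, Anchor) and not distal.anchor.unique:
        low_conf = True
    confidence = "low" if low_conf else "high"
    gap = len(call.untemplated_insert)

    if distal.kind == "telomere_array" and distal.anchor is not None:
        if distal.anchor.canonical and gap <= cfg.max_healing_gap:
            subtype = "with_untemplated_insert" if gap > 0 else "direct"
            ev = [
                f"canonical telomere array of {distal.anchor.copies} units at the junction",
                f"fusion microhomology {call.microhomology_len} bp",
            ]
            if gap:
                ev.append(f"untemplated insert of {gap} bp")
            return MechanismLabel("telomere_healing", subtype, ev, confidence)
        ev = [
            "telomere-like array without canonical-unit majority"
            if not distal.anchor.canonical
            else f"untemplated gap of {gap} bp exceeds {cfg.max_healing_gap}"
        ]
        return MechanismLabel("unresolved", "none", ev, "low")

    if distal.kind in ("tar_block", "foreign_subtelomere"):
        subtype = "tar_capture" if distal.kind == "tar_block" else "foreign_subtelomere_capture"
        ev = [f"distal side maps to {distal.kind}"]
        return MechanismLabel("telomere_capture", subtype, ev, confidence)

    if call.template_insert is not None and call.template_insert.length >= cfg.min_template_len:
        t = call.template_insert
        ev = [
            f"{t.length} bp {t.orientation} templated insert from "
            f"{t.seq_name}:{t.source_interval[0]}-{t.source_interval[1]}",
            f"switch microhomologies {t.mh_prox}/{t.mh_dist} bp",
        ]
        return MechanismLabel("FoSTeS_MMBIR", "none", ev, confidence)

    if (
        distal.kind == "genomic_locus"
        and isinstance(distal.anchor, Anchor)
        and call.microhomology_len <= cfg.max_nhej_microhomology
        and gap <= cfg.max_nhej_insert
    ):
        same_seq = distal.anchor.seq_name == call.proximal.seq_name
        if not same_seq:
            subtype = "translocation_candidate"
        elif distal.anchor.ref_interval[0] < call.proximal.ref_interval[1]:
            # the distal locus lies upstream: circularization topology
            subtype = "ring_candidate"
        else:
            subtype = "none"
        ev = [
            f"two-anchor junction with {call.microhomology_len} bp microhomology",
        ]
        if gap:
            ev.append(f"untemplated insert of {gap} bp")
        return MechanismLabel("NHEJ", subtype, ev, confidence)

    return MechanismLabel("unresolved", "none", ["no decision rule matched"], "low")


def summarize_mechanisms(labels: list[MechanismLabel]) -> dict:
    """Count table per label and per label/subtype; totals preserved."""
    by_label = Counter(lbl.label for lbl in labels)
    by_subtype = Counter((lbl.label, lbl.subtype) for lbl in labels)
    return {
        "n": len(labels),
        "by_label": {lab: by_label.get(lab, 0) for lab in LABELS},
        "by_subtype": {f"{lab}/{sub}": c for (lab, sub), c in sorted(by_subtype.items())},
    }
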