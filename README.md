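# junctionmech

Terminal chromosome deletions are stabilized by a handful of repair
mechanisms — de novo telomere addition (telomere healing), acquisition of
another chromosome end's subtelomeric sequence (telomere capture),
non-homologous end joining (producing interstitial deletions, ring
chromosomes and unbalanced translocations), and replication-based template
switching (FoSTeS/MMBIR) — and each leaves a distinctive signature in the
breakpoint-junction sequence. `junctionmech` is a toolkit for geneticists
and method developers working on such rearrangements (the 22q13 /
Phelan-McDermid setting is the motivating case): it decomposes junction
reads into their evidence, classifies the repair mechanism, analyses
probe-level aCGH profiles of (possibly mosaic) deletions, and ships a
44-subject cohort catalog with its aggregate statistics.

## What it computes

Given a junction read and a reference, `call_junction` reports:

* the **proximal anchor** (seed-and-extend, ≥95% identity, with explicit
  ambiguity flags for paralogous/repeated placements);
* the **distal assignment**: telomere hexamer array (GGTTAG units,
  Hamming-1 variants tolerated, 1–5 bp fusion microhomology with the
  canonical repeat), TAR/foreign-subtelomere copy, or a second genomic
  locus;
* **junction microhomology** (the breakpoint is an interval of width
  microhomology + 1, never a point), **untemplated insertions**, and
  **templated insertions** traced to their (usually inverted) source inside
  the deleted interval with their switch-point microhomologies.

`classify_junction` maps that evidence to
`telomere_healing / telomere_capture / NHEJ / FoSTeS_MMBIR / unresolved`
with subtypes (ring vs translocation is decided topologically) and a
confidence downgraded on any ambiguous anchor.

The aCGH module models a deletion in a fraction *f* of cells as an expected
log2 ratio `L = log2((2 − f)/2)`, inverts it (`f = 2(1 − 2^L)`), QCs arrays
by the derivative log-ratio spread (`IQR(diff)/(1.349·√2) < 0.30`),
segments profiles by binary segmentation with a BIC-style penalty, and
recognizes nested mosaic terminal deletions as a terminal run of segments
with strictly decreasing means.

A synthetic-rearrangement module builds a feature-annotated toy reference
(200 kb main chromosome with TAR block, terminal telomere array, paralog
pair, repeat decoys) and simulates junction reads with exact truth records
for all six mechanism classes — the test bed for everything above.

## Worked example

```python
import junctionmech as jm

ref = jm.build_reference(seed=1)
(rid, read), truth = jm.simulate_terminal_healing(ref, copies=12, mh=4, seed=42)
call = jm.call_junction(rid, read, ref)
label = jm.classify_junction(call)
print("distal kind:    ", call.distal.kind)
print("hexamer copies: ", call.hexamer_copies)
print("fusion mh (bp): ", call.microhomology_len, repr(call.microhomology_seq))
print("breakpoint:     ", call.breakpoint_interval)
print("label:          ", label.label, "/", label.subtype, f"({label.confidence})")
print("truth breakpoint:", truth.breakpoints[0], " truth mh:", truth.fusion_microhomology)
```

prints

```
distal kind:     telomere_array
hexamer copies:  12
fusion mh (bp):  4 'GGTT'
breakpoint:      (127227, 127232)
label:           telomere_healing / direct (high)
truth breakpoint: 127231  truth mh: 4
```

— a terminal deletion healed by 12 de novo GGTTAG units whose fusion point
shares 4 bases with the canonical repeat, so the breakpoint is only defined
up to the 5-bp interval 127227–127232 (the truth breakpoint sits inside
it). The same pipeline runs from the shell:

```bash
junctionmech simulate --mechanism cohort --n 44 --seed 1 --out-prefix out/demo
junctionmech analyze --reads out/demo.reads.fa --ref out/demo.ref.fa \
    --features out/demo.ref.bed --out out/calls.jsonl
junctionmech classify out/calls.jsonl --out out/labels.tsv
junctionmech acgh --profile profile.tsv --out segments.tsv
junctionmech cohort --out report.json
```

`junctionmech cohort` prints the catalog aggregates:

```
cohort: 44 subjects
  terminal_deletion: 30 (68.2%)
  interstitial_deletion: 5 (11.4%)
  ring22: 6 (13.6%)
  derivative: 3 (6.8%)
  de novo del22: 19/25 paternal (76%)
  de novo ring22: 3/5 paternal (60%)
  de novo total: 22/30 paternal (73%)
```

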