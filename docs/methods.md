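# Methods

`junctionmech` infers the repair mechanism that stabilized a broken
chromosome end from the sequence of the breakpoint junction, and estimates
mosaic deletion structure from probe-level aCGH log2 ratios. This note
documents the models, the conventions, the tunable parameters, and what the
synthetic data generator does and does not emulate.

## The junction model

A junction read is modelled as an ungapped **proximal segment** (the intact
chromosomal flank, anchored on the reference by exact 20-mer seeding and
scored extension) followed by a **distal segment** that is one of:

* a de novo telomere hexamer array (telomere healing),
* a copy of subtelomeric sequence — the TAR block of the same chromosome
  end or the terminus of another chromosome (telomere capture),
* a second genomic locus on the same or a different chromosome (end
  joining: interstitial deletion, ring, or translocation),

optionally separated from the proximal segment by an **untemplated
insertion** or by a **templated insertion** copied, usually in inverted
orientation, from inside the deleted interval (the FoSTeS/MMBIR
signature).

Each side of the junction lies on a single alignment diagonal; the junction
itself is resolved by the optimal split of the read between the two
diagonals (match +1, mismatch −1, unattributed bases 0). On clean reads
the set of optimal split points connected through positions that match
*both* sides is exactly the microhomology interval, so the breakpoint is
reported as an interval of width `microhomology + 1`, never as a point.
Microhomology and untemplated insertion are mutually exclusive by
definition: a positive inter-anchor gap forces microhomology 0.

### Telomere arrays

`find_telomere_array` reports the longest run of consecutive, in-phase
6-mers each within Hamming distance 1 of GGTTAG (single-substitution
variant units such as GGTGAG and GGTCAG are tolerated; distance-2 units
break the run). Two refinements matter:

* **Edge trimming.** A single variant unit at the run edge abutting a
  canonical unit is trimmed and treated as flanking sequence. Any genomic
  suffix sharing ≥ 4 bases with the hexamer — precisely the 1–5 bp fusion
  microhomology the method must measure — would otherwise be absorbed as a
  "variant unit", corrupting both the copy count and the breakpoint.
  Blocks of ≥ 2 consecutive variant units (e.g. a (GGTCAG)₆ tract ahead of
  a canonical array) are kept as array.
* **Canonical flag.** A run whose canonical fraction falls below 0.5 is
  still reported but flagged `canonical=False`; classification does not
  accept such arrays (e.g. a pure (GGTGAG)ₙ tract) as evidence of
  telomere healing.

### Fusion microhomology

The fusion microhomology at a healed junction is the longest tail (≤ 6 bp)
of the reference suffix matching the canonical hexamer in *either*
annealing register: the bases an in-phase extension would place before the
array's first unit (`...GTTAG | GGTTAG…`) or the first bases of a unit
completed by the new telomere (`...GGTTA | G GTTAG…`). Telomerase can
anneal its template at any register, so both read as homology between the
broken end and the repeat. The cap at one unit (6 bp) reflects that beyond
a full unit the breakpoint position itself becomes phase-ambiguous.

### Distal assignment order

Candidates are tried in interpretive priority order: a telomere array
beginning at (or within the maximum untemplated-insert distance, 20 bp, of)
the junction; then TAR / foreign-subtelomere features; then any genomic
locus. A capture read that *ends* in a telomere array is therefore still
assigned to its subtelomeric source, because the array does not begin at
the junction. Near-identical multi-copy regions (paralog blocks, repeat
decoys) produce tied placements; ties within 2 matches set `unique=False`
and an `ambiguity_count`, and any non-unique anchor downgrades the final
call's confidence to `low` rather than guessing a placement.

### Decision table

First match wins:

1. distal = canonical telomere array and untemplated gap ≤ 20 bp →
   **telomere_healing** (`with_untemplated_insert` if the gap is non-empty);
2. distal = TAR block / foreign subtelomere → **telomere_capture**;
3. templated insert ≥ 15 bp (either orientation) → **FoSTeS_MMBIR**;
4. distal = genomic locus, microhomology ≤ 10 bp, insert ≤ 20 bp →
   **NHEJ**, subtyped topologically: distal upstream on the same sequence
   (circularization) → `ring_candidate`; a different sequence →
   `translocation_candidate`; downstream on the same sequence (plain
   interstitial deletion) → `none`;
5. otherwise **unresolved**.

No quantitative thresholds for "NHEJ-compatible" exist in the field; the
defaults above bracket the observed ranges (inserts of 2–20 bp,
microhomologies of ≤ 5 bp, templated inserts of ~20–30 bp) and are all
exposed in `ClassifierConfig`. FoSTeS is checked before NHEJ because a
templated insert subsumes a two-anchor junction. The breakpoint interval
of a templated junction spans the proximal switch microhomology, matching
the interval convention elsewhere.

## The synthetic reference and read generator

The toy reference scales a ~49 Mb chromosome arm down to 200 kb while
keeping every *local* signature at literal size, since the analysis only
ever reads local sequence: a p-arm with three identical 500 bp repeat
decoys, a 2 kb paralog block duplicated at 99.5% identity on a second
60 kb chromosome (the RABL2-type ambiguity), a toy gene model containing a
60 bp GC-rich simple repeat, a 2 kb TAR block, and a terminal (GGTTAG)₅₀
array; the second chromosome carries its own subtelomere (TAR-like block +
telomere array) as a capture source. Background GC is 0.48. Coordinates
are 0-based half-open internally everywhere.

Simulators engineer each requested signature *exactly*: breakpoints are
scanned for positions whose local sequence realizes the requested
microhomology (no more, no less), inserts are rejection-sampled so they
extend neither flank, and every constructed read is validated against a
brute-force split enumeration (an independent O(w²) oracle formulation)
before the truth record is emitted. The recorded truth is therefore the
maximal analyzer-visible signal, which is what makes exact round-trip
comparison meaningful. Healing breakpoints additionally avoid sites whose
preceding 12 bp form two consecutive telomere-like units (which would
legitimately extend the array) and sites followed by a reference `G`
(which would make the junction phase-ambiguous on the right).

Default study conditions (per-read parameter draws): hexamer copies
3–48; fusion/junction microhomologies 0–5 bp; untemplated inserts up to
20 bp (healing) or 10 bp (end joining); templated inserts 22–30 bp with
switch microhomologies 0–4 bp and an exact core of ≥ 16 bp; interstitial
deletions 2–15 kb; terminal/ring deletions up to 150 kb (scaled). The
default cohort mixture echoes the catalog class sizes (27 healed + 3
captured terminal, 6 ring, 3 translocation, 4 end-joined + 1 templated
interstitial per 44 reads). Capture sources are mutated by uniform
substitutions (no indels) at a configurable rate, default 0.005 for the
standalone operation and 0 in the noiseless benchmark panels. Read-level
noise is uniform substitution at 0.005 in the noisy benchmark.

One random stream per operation call, keyed by a single integer seed, makes
every FASTA/JSON output byte-reproducible.

**What the generator does not emulate:** real human subtelomeric repeat
structure (satellites, segmental duplications at scale), indel or chimera
sequencing errors, diploid genotypes, and breakpoints inside truly
unmappable repeats. Passing round-trip tests therefore demonstrate that the
decomposition logic is correct and self-consistent under substitution
noise, not that anchoring would be unambiguous on a real genome — on real
data the `unique=False`/`ambiguity_count` machinery is expected to carry
much more weight.

## The aCGH model

A heterozygous deletion in a fraction *f* of cells shifts the expected
probe log2 ratio to `L = log2((2 − f)/2)`; inversion gives
`f = 2 (1 − 2^L)`, clipped to [0, 1]. The model assumes pure single-copy
loss mixtures — no homozygous loss, no gains — which matches the
deletion-only setting it is used in; `estimate_fraction ∘ forward` is the
identity exactly on [0, 1].

* **Noise/QC.** The derivative log-ratio spread is computed as
  `IQR(consecutive differences) / (1.349 √2)`, a robust estimate of the
  per-probe noise SD (the field names the metric but not a formula; this is
  the standard robust-IQR convention). QC passes below 0.30.
* **Segmentation.** Binary segmentation on means with a BIC-style
  acceptance `gain > 3 σ² log n` (σ from the DLR spread), minimum segment
   10 probes, followed by a merge pass collapsing adjacent segments whose
  means differ by less than twice the standard error of the difference.
  Deterministic; penalty and minimum size are exposed.
* **Stepped mosaics.** A nested mosaic terminal deletion — several
  embryonic cell lines sharing a terminal deletion with different
  breakpoints — produces segment means strictly decreasing toward the
  telomere. `call_stepped_mosaic` reports the maximal such terminal run,
  breakpoints at segment boundaries (midpoint between flanking probes),
  and per-step fractions; apparently deleted segments outside the run
  violate nesting and set `monotone=False` with a diagnostic. A deepest
  step observed near −0.8 is reported as f ≈ 0.85 rather than forced to a
  clonal 1.0.

At the simulated benchmark conditions (segment means 0/−0.3/−0.5/−0.8,
250 probes per segment at 400 bp spacing, noise SD 0.1) the smallest step
(0.2 in log2) still yields a boundary-localization error of ≤ 2 probes in
well over 95% of runs; a ~0.6%-per-run chance of a 3-probe error on that
step is inherent to the noise level, which is why boundary accuracy is
stated as a ≥ 95% property rather than a certainty.

## The cohort catalog

The bundled table stores one row per subject: class, size (with an
`approximate` flag for sizes printed with "~", which are excluded from
min/max summaries), cloned-junction repair mechanism, parental origin, and
mosaic percentage. Derivative chromosomes were inherited from
balanced-translocation carrier parents and are excluded from the de novo
parental-origin table. `cohort_report` recomputes all percentages from the
records (e.g. terminal deletions are 30/44 = 68.2% of the cohort); note
that a cohort description quoting "72%" for the same count is using a
different implicit denominator, so recomputed and quoted percentages can
differ by a few points — the report only ever emits recomputed values.

## Numerical and engineering choices

* Seed-and-extend anchoring: exact 20-mer seeds, scored extension
  (+1/−2 with a 30-point x-drop), acceptance at ≥ 95% identity over
  ≥ 40 bp (30 bp for the distal side); these are choices made for clean
  Sanger-length junction fragments, not short-read mappers.
* Benchmarks scale: 600-read panels (100 per mechanism), 500-junction
  oracle comparisons, 20-seed segmentation runs — sizes chosen so the full
  suite runs in well under a minute per arm on one CPU.
* Degenerate inputs: reads < 60 bp or without a ≥ 40 bp anchor produce a
  structured error record (not an exception) from `call_junction`;
  profiles with < 3 probes reject DLR; empty segment lists reject the
  mosaic caller; catalog rows that fail validation name their row number.

## Known limitations

Strand handling is forward-only for anchors (inverted *templated inserts*
are detected, inverted distal segments are not); alignment is ungapped per
side, so indel-containing junctions would mis-resolve; telomere detection
is G-rich-strand only and tolerates no indels within units; the classifier
is a deterministic rule table, not a calibrated probabilistic model; and
the catalog is a fixed 44-subject table, not a general cohort schema.
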