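import numpy as np
import pytest

from junctionmech import (
    anchor_proximal,
    assign_distal,
    call_junction,
    find_inverted_template,
    junction_microhomology,
    simulate_fostes,
    simulate_interstitial_nhej,
    simulate_ring_junction,
    simulate_terminal_healing,
    simulate_telomere_capture,
    simulate_translocation_junction,
)
from junctionmech._dna import random_dna, revcomp

from _oracles import inverted_template_oracle, junction_overlap_oracle


class TestAnchorProximal:
    def test_healing_anchor_ends_at_breakpoint(self, ref):
        (rid, read), truth = simulate_terminal_healing(ref, copies=8, mh=0, seed=51)
        anchor = anchor_proximal(read, ref)
        assert anchor.seq_name == "chrT"
        assert anchor.unique and anchor.identity == 1.0
        assert anchor.ref_interval[1] == truth.breakpoints[0]

    def test_paralog_read_flagged_ambiguous(self, ref):
        block = ref.features_of_kind("paralog_block", "chrT")[0]
        read = ref.sequences["chrT"][block.start + 200 : block.start + 400]
        anchor = anchor_proximal(read, ref)
        assert not anchor.unique
        assert anchor.ambiguity_count >= 2

    def test_short_read_rejected(self, ref):
        with pytest.raises(ValueError, match="unanchored"):
            anchor_proximal("ACGT" * 8, ref)

    def test_random_read_unanchored(self, ref):
        read = random_dna(np.random.default_rng(424_242), 200)
        with pytest.raises(ValueError, match="unanchored"):
            anchor_proximal(read, ref)


class TestAssignDistal:
    def test_healing_read_assigned_to_telomere(self, ref):
        (rid, read), _ = simulate_terminal_healing(ref, copies=6, seed=52)
        d = assign_distal(read, anchor_proximal(read, ref), ref)
        assert d.kind == "telomere_array"

    def test_capture_read_assigned_to_tar(self, ref):
        (rid, read), _ = simulate_telomere_capture(ref, source="tar_block", seed=53, mutation_rate=0.0)
        d = assign_distal(read, anchor_proximal(read, ref), ref)
        assert d.kind == "tar_block"

    def test_foreign_capture_assigned_to_foreign_subtelomere(self, ref):
        (rid, read), _ = simulate_telomere_capture(
            ref, source="foreign_subtelomere", seed=54, mutation_rate=0.0
        )
        d = assign_distal(read, anchor_proximal(read, ref), ref)
        assert d.kind == "foreign_subtelomere"

    def test_random_suffix_unassigned(self, ref):
        (rid, read), truth = simulate_terminal_healing(ref, copies=3, seed=55)
        b = truth.breakpoints[0]
        junk = ref.sequences["chrT"][b - 180 : b] + random_dna(np.random.default_rng(2), 10)
        d = assign_distal(junk, anchor_proximal(junk, ref), ref)
        assert d.kind == "unassigned"

    def test_ring_distal_in_decoy_is_ambiguous(self, ref):
        decoy = ref.features_of_kind("repeat_decoy", "chrT")[0]
        (rid, read), _ = simulate_ring_junction(
            ref, q_del_size=30_000, seed=56, p_arm_locus=decoy.start + 100
        )
        call = call_junction(rid, read, ref)
        assert call.distal.kind == "genomic_locus"
        assert call.distal.ambiguity_count == 3
        assert not call.distal.anchor.unique


class TestJunctionMicrohomology:
    def test_blunt_junction(self, ref):
        (rid, read), _ = simulate_interstitial_nhej(ref, del_size=5_000, mh=0, seed=57)
        prox = anchor_proximal(read, ref)
        dist = assign_distal(read, prox, ref)
        assert junction_microhomology(prox, dist.anchor, ref, read) == (0, "")

    def test_engineered_five_base_overlap(self, ref):
        (rid, read), truth = simulate_translocation_junction(ref, mh=5, seed=58)
        prox = anchor_proximal(read, ref)
        dist = assign_distal(read, prox, ref)
        length, seq = junction_microhomology(prox, dist.anchor, ref, read)
        assert length == 5 and len(seq) == 5

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_oracle(self, ref, seed):
        rng = np.random.default_rng(seed)
        mh = int(rng.integers(0, 6))
        (rid, read), truth = simulate_interstitial_nhej(
            ref, del_size=int(rng.integers(2_000, 12_000)), mh=mh, seed=1_000 + seed
        )
        call = call_junction(rid, read, ref)
        bp, bd = truth.breakpoints
        A = ref.sequences["chrT"]
        assert call.microhomology_len == junction_overlap_oracle(A, bp, A, bd) == mh


class TestTemplates:
    def test_short_insert_below_min_len(self):
        assert find_inverted_template("ACGTACGT", "A" * 200, min_len=15) is None

    @pytest.mark.parametrize("orientation", ["reverse_complement", "forward"])
    def test_orientation_detected(self, ref, orientation):
        (rid, read), truth = simulate_fostes(
            ref, del_size=5_000, template_len=24, mh_prox=0, mh_dist=0,
            seed=60, orientation=orientation,
        )
        call = call_junction(rid, read, ref)
        t = truth.template_insert
        assert call.template_insert is not None
        assert call.template_insert.orientation == orientation
        assert call.template_insert.source_interval == (t["start"], t["end"])

    @pytest.mark.parametrize("seed", range(10))
    def test_core_matches_brute_substring_scan(self, ref, seed):
        (rid, read), truth = simulate_fostes(ref, del_size=5_000, seed=2_000 + seed)
        bp, bd = truth.breakpoints
        t = truth.template_insert
        gap = read[180 + t["mh_prox"] : 180 + (t["end"] - t["start"]) - t["mh_dist"]]
        w_lo = bp - 40
        oracle = inverted_template_oracle(gap, ref.sequences["chrT"][w_lo : bd + 40])
        assert oracle is not None
        src = (oracle[0] + w_lo, oracle[1] + w_lo)
        assert src == (t["start"] + t["mh_dist"], t["end"] - t["mh_prox"])
        assert oracle[2] == "reverse_complement"


class TestCallJunction:
    def test_idempotent_and_serializable(self, ref):
        (rid, read), _ = simulate_terminal_healing(ref, copies=5, mh=2, seed=61)
        a = call_junction(rid, read, ref)
        b = call_junction(rid, read, ref)
        assert a.to_dict() == b.to_dict()

    def test_unanchored_read_gives_structured_error(self, ref):
        call = call_junction("junk", random_dna(np.random.default_rng(3), 120), ref)
        assert call.error is not None and "unanchored" in call.error
        assert call.proximal is None

    def test_breakpoint_interval_width_is_mh_plus_one(self, ref, panel_noiseless):
        reads, truths = panel_noiseless
        for (rid, read), truth in list(zip(reads, truths))[:120]:
            call = call_junction(rid, read, ref)
            if call.error or call.breakpoint_interval is None:
                continue
            lo, hi = call.breakpoint_interval
            if call.template_insert is None:
                assert hi - lo == call.microhomology_len + 1
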