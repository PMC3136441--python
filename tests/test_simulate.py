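import json

import numpy as np
import pytest

from junctionmech import (
    build_reference,
    find_telomere_array,
    reads_to_fasta,
    simulate_cohort,
    simulate_fostes,
    simulate_interstitial_nhej,
    simulate_ring_junction,
    simulate_telomere_capture,
    simulate_terminal_healing,
    simulate_translocation_junction,
    truths_to_jsonl,
)
from junctionmech._dna import random_dna, revcomp

from _oracles import fusion_mh_oracle, junction_overlap_oracle


class TestTerminalHealing:
    def test_read_ends_in_exact_hexamer_array(self, ref):
        (rid, read), truth = simulate_terminal_healing(ref, copies=6, mh=0, seed=3)
        assert read.endswith("GGTTAG" * 6)
        assert not read.endswith("GGTTAG" * 7)
        assert truth.hexamer_copies == 6
        assert len(read) >= 180 + 36

    @pytest.mark.parametrize("mh", [0, 1, 2, 3, 4, 5])
    def test_engineered_fusion_microhomology(self, ref, mh):
        (rid, read), truth = simulate_terminal_healing(ref, copies=5, mh=mh, seed=11 + mh)
        b = truth.breakpoints[0]
        # oracle on the emitted read: the flank suffix before the array
        flank_suffix = read[: len(read) - 30]
        assert fusion_mh_oracle(flank_suffix) == mh
        assert fusion_mh_oracle(ref.sequences["chrT"][:b]) == mh

    def test_untemplated_insert_visible(self, ref):
        insert = random_dna(np.random.default_rng(8), 14)
        (rid, read), truth = simulate_terminal_healing(ref, copies=4, insert=insert, seed=9)
        hit = find_telomere_array(read)
        gap = read[180 : hit.start]
        assert len(gap) == 14 == len(truth.untemplated_insertion)
        assert gap == truth.untemplated_insertion

    def test_del_size_validation(self, ref):
        with pytest.raises(ValueError, match="beyond chromosome"):
            simulate_terminal_healing(ref, del_size=10**7, seed=1)
        with pytest.raises(ValueError):
            simulate_terminal_healing(ref, copies=0, seed=1)
        with pytest.raises(ValueError):
            simulate_terminal_healing(ref, mh=3, insert="ACGT", seed=1)


class TestCapture:
    def test_tar_source_maps_to_tar_feature(self, ref):
        (rid, read), truth = simulate_telomere_capture(ref, source="tar_block", seed=2, mutation_rate=0.0)
        tar = ref.features_of_kind("tar_block", "chrT")[0]
        src = truth.distal["pos"]
        assert tar.start <= src < tar.end
        assert read[180 : 180 + 60] == ref.sequences["chrT"][src : src + 60]

    def test_foreign_source_is_second_chromosome_terminus(self, ref):
        (rid, read), truth = simulate_telomere_capture(
            ref, source="foreign_subtelomere", seed=2, mutation_rate=0.0
        )
        O = ref.sequences["chrO"]
        assert truth.distal["seq_name"] == "chrO"
        assert read[180:] == O[-450:]

    def test_mutated_copy_stays_high_identity(self, ref):
        (rid, read), truth = simulate_telomere_capture(ref, source="tar_block", seed=4, mutation_rate=0.01)
        src = truth.distal["pos"]
        block = read[180 : 180 + 600]
        ref_block = ref.sequences["chrT"][src : src + 600]
        ident = sum(a == b for a, b in zip(block, ref_block)) / 600
        assert ident >= 0.95

    def test_unknown_source_rejected(self, ref):
        with pytest.raises(ValueError):
            simulate_telomere_capture(ref, source="centromere", seed=1)


class TestTwoLocusJunctions:
    @pytest.mark.parametrize("mh", [0, 3, 5])
    def test_nhej_overlap_matches_oracle(self, ref, mh):
        (rid, read), truth = simulate_interstitial_nhej(ref, del_size=6_000, mh=mh, seed=21 + mh)
        bp, bd = truth.breakpoints
        A = ref.sequences["chrT"]
        assert junction_overlap_oracle(A, bp, A, bd) == mh
        assert read == A[bp - 180 : bp] + A[bd : bd + 180]

    def test_nhej_insert(self, ref):
        insert = random_dna(np.random.default_rng(5), 10)
        (rid, read), truth = simulate_interstitial_nhej(ref, del_size=4_000, insert=insert, seed=31)
        assert truth.untemplated_insertion == read[180:190]

    def test_fostes_template_recoverable_by_brute_scan(self, ref):
        (rid, read), truth = simulate_fostes(
            ref, del_size=5_000, template_len=24, mh_prox=4, mh_dist=2, seed=13
        )
        bp, bd = truth.breakpoints
        t = truth.template_insert
        A = ref.sequences["chrT"]
        # the inserted segment is the reverse complement of the recorded
        # source interval, which lies inside the deleted interval
        assert bp < t["start"] < t["end"] < bd
        assert read[180 : 180 + 24] == revcomp(A[t["start"] : t["end"]])
        # exhaustive scan of the deleted interval recovers it
        core = read[180 + 4 : 180 + 22]
        hits = [
            i for i in range(bp, bd - 18) if revcomp(A[i : i + 18]) == core
        ]
        assert hits == [t["start"] + 2]

    def test_fostes_zero_template_degenerates_to_nhej(self, ref):
        (rid, read), truth = simulate_fostes(ref, del_size=4_000, template_len=0, seed=17)
        assert truth.mechanism == "nhej_interstitial"

    def test_ring_joins_q_arm_to_p_arm(self, ref):
        (rid, read), truth = simulate_ring_junction(ref, q_del_size=25_000, mh=2, seed=19)
        bq, p0 = truth.breakpoints
        assert p0 < ref.config.p_arm_len < bq
        assert find_telomere_array(read) is None
        with pytest.raises(ValueError):
            simulate_ring_junction(ref, q_del_size=10**7, seed=1)

    @pytest.mark.parametrize("mh", [0, 4, 5])
    def test_translocation_microhomology(self, ref, mh):
        (rid, read), truth = simulate_translocation_junction(ref, mh=mh, seed=41 + mh)
        b, c = truth.breakpoints
        assert junction_overlap_oracle(
            ref.sequences["chrT"], b, ref.sequences["chrO"], c
        ) == mh


class TestCohort:
    def test_reproducible_and_mixture_sums(self, ref):
        reads1, truths1 = simulate_cohort(ref, 44, seed=6)
        reads2, truths2 = simulate_cohort(ref, 44, seed=6)
        assert reads_to_fasta(reads1) == reads_to_fasta(reads2)
        assert truths_to_jsonl(truths1) == truths_to_jsonl(truths2)
        assert len(reads1) == 44
        for line in truths_to_jsonl(truths1).splitlines():
            json.loads(line)

    def test_single_mechanism_mixture(self, ref):
        reads, truths = simulate_cohort(ref, 20, mixture={"telomere_healing": 1}, seed=3)
        assert len(truths) == 20
        assert all(t.mechanism == "telomere_healing" for t in truths)

    def test_all_reads_have_unique_proximal_flank(self, ref):
        reads, truths = simulate_cohort(ref, 30, seed=9)
        for (rid, read), truth in zip(reads, truths):
            b = truth.breakpoints[0]
            seq = ref.sequences[truth.proximal_seq]
            assert read[:180] == seq[b - 180 : b]
            assert ref.uniquely_mappable(truth.proximal_seq, b - 180, b)
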