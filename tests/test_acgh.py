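import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from junctionmech import (
    Profile,
    call_stepped_mosaic,
    dlr_spread,
    estimate_fraction,
    expected_log2,
    qc_pass,
    segment_profile,
    simulate_profile,
)

P20_FRACTIONS = [0.0, estimate_fraction(-0.3), estimate_fraction(-0.5), estimate_fraction(-0.8)]
P20_MEANS = [0.0, -0.3, -0.5, -0.8]


class TestForwardModel:
    @pytest.mark.parametrize(
        "fraction,expect",
        [(1.0, -1.0), (0.0, 0.0), (0.3, np.log2(0.85))],
    )
    def test_closed_form(self, fraction, expect):
        profile = simulate_profile([(10_000, fraction)], noise_sd=0.0, seed=0)
        assert np.allclose(profile.log2_ratios, expect)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            expected_log2(1.5)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_estimate_inverts_forward_model_exactly(self, fraction):
        assert estimate_fraction(expected_log2(fraction)) == pytest.approx(fraction, abs=1e-12)

    def test_estimate_clipping(self):
        assert estimate_fraction(0.4) == 0.0
        assert estimate_fraction(-3.0) == 1.0
        assert estimate_fraction(-0.3) == pytest.approx(0.3755, abs=1e-3)


class TestDlrSpread:
    def test_constant_profile_is_zero(self):
        p = Profile(np.arange(10) * 400.0, np.zeros(10))
        assert dlr_spread(p) == 0.0

    def test_consistency_on_iid_noise(self):
        p = simulate_profile([(4_000_000, 0.0)], spacing=400, noise_sd=0.2, seed=1)
        assert dlr_spread(p) == pytest.approx(0.20, abs=0.01)

    def test_too_few_probes(self):
        with pytest.raises(ValueError, match="too few probes"):
            dlr_spread(Profile(np.array([0.0, 400.0]), np.array([0.0, 0.1])))

    def test_qc_rule(self):
        good = simulate_profile([(400_000, 0.0)], noise_sd=0.1, seed=2)
        bad = simulate_profile([(400_000, 0.0)], noise_sd=0.5, seed=2)
        assert qc_pass(good)
        assert not qc_pass(bad)
        assert not qc_pass(good, threshold=0.05)


class TestSegmentation:
    def test_flat_profile_single_segment(self):
        p = simulate_profile([(100_000, 0.0)], noise_sd=0.1, seed=3)
        segs = segment_profile(p)
        assert len(segs) == 1
        assert segs[0].n_probes == len(p)

    def test_single_step_boundary_recovery(self):
        p = simulate_profile([(100_000, 0.0), (100_000, 1.0)], noise_sd=0.1, seed=4)
        segs = segment_profile(p)
        assert len(segs) == 2
        assert abs(segs[1].start - 250) <= 2
        assert segs[0].mean_log2 == pytest.approx(0.0, abs=0.05)
        assert segs[1].mean_log2 == pytest.approx(-1.0, abs=0.05)

    def test_segments_partition_profile(self):
        p = simulate_profile([(60_000, 0.0), (60_000, 0.6)], noise_sd=0.1, seed=5)
        segs = segment_profile(p)
        assert segs[0].start == 0 and segs[-1].end == len(p)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end == b.start
        assert all(s.n_probes >= 10 for s in segs)

    def test_segment_means_are_sufficient_statistics(self):
        # permuting probe order within each true segment leaves boundaries
        # and segment means unchanged on a well-separated profile
        p = simulate_profile([(40_000, 0.0), (40_000, 1.0)], noise_sd=0.05, seed=6)
        segs = segment_profile(p)
        rng = np.random.default_rng(0)
        y = p.log2_ratios.copy()
        y[:100] = rng.permutation(y[:100])
        y[100:] = rng.permutation(y[100:])
        segs2 = segment_profile(Profile(p.positions, y))
        assert [(s.start, s.end) for s in segs2] == [(s.start, s.end) for s in segs]
        assert np.allclose(
            [s.mean_log2 for s in segs2], [s.mean_log2 for s in segs], atol=1e-12
        )


class TestSteppedMosaic:
    def test_three_step_nested_mosaic(self):
        p = simulate_profile(
            [(100_000, f) for f in P20_FRACTIONS], spacing=400, noise_sd=0.1, seed=7
        )
        segs = segment_profile(p)
        assert len(segs) == 4
        call = call_stepped_mosaic(segs, p)
        assert call.monotone
        assert len(call.breakpoints) == 3
        assert call.fractions == sorted(call.fractions)
        for mean, seg in zip(P20_MEANS, segs):
            assert seg.mean_log2 == pytest.approx(mean, abs=0.05)

    def test_single_deletion_single_breakpoint(self):
        p = simulate_profile([(80_000, 0.0), (80_000, 1.0)], noise_sd=0.1, seed=8)
        call = call_stepped_mosaic(segment_profile(p), p)
        assert len(call.breakpoints) == 1
        assert call.fractions[0] == pytest.approx(1.0, abs=0.05)
        assert call.monotone

    def test_non_monotone_rejected(self):
        # a deleted region followed by a shallower one violates nesting
        p = simulate_profile(
            [(80_000, 0.0), (80_000, 0.8), (80_000, 0.3)], noise_sd=0.05, seed=9
        )
        call = call_stepped_mosaic(segment_profile(p), p)
        assert not call.monotone
        assert call.diagnostic


class TestProfileIO:
    def test_tsv_round_trip(self, tmp_path):
        p = simulate_profile([(20_000, 0.5)], noise_sd=0.1, seed=10)
        path = tmp_path / "profile.tsv"
        path.write_text(p.to_tsv())
        q = Profile.from_tsv(path)
        assert np.allclose(p.positions, q.positions)
        assert np.allclose(p.log2_ratios, q.log2_ratios, atol=1e-6)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            Profile(np.array([0.0, 0.0, 400.0]), np.zeros(3))
        with pytest.raises(ValueError):
            Profile(np.array([0.0, 400.0, 800.0]), np.array([0.0, np.nan, 0.1]))
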