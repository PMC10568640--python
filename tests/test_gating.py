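"""Gate primitives, quantiles, KDE and the two-peak cutpoint."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from myodiff.errors import DegenerateDistributionError, InsufficientDataError
from myodiff.gating import (
    QuadrantScheme,
    RangeBin,
    RectGate,
    SplitConfig,
    apply_range_bin,
    apply_rect_gate,
    empirical_quantile,
    find_density_peaks,
    kde_density,
    mindensity_cutpoint,
    quadrant_counts,
    silverman_bandwidth,
    singlet_mask,
)
from myodiff.simulator import SimConfig, simulate_sample
from myodiff.transforms import TransformSpec, apply_transform, invert_transform

from conftest import make_sample

BIEXP = TransformSpec("biexponential", cofactor=5.0)


class TestEmpiricalQuantile:
    def test_constant_vector(self):
        assert empirical_quantile(np.full(25, 7.0), 0.99) == 7.0

    def test_type7_hand_evaluation(self):
        # sorted x_1..x_100 = 1..100: h = 99*0.99 = 98.01,
        # result = x_99 + 0.01*(x_100 - x_99) = 99.01
        values = np.arange(1.0, 101.0)
        h = (values.size - 1) * 0.99
        lo = int(np.floor(h))
        expected = values[lo] + (h - lo) * (values[lo + 1] - values[lo])
        assert expected == pytest.approx(99.01)
        assert empirical_quantile(values, 0.99) == pytest.approx(expected)

    def test_fraction_at_or_below_within_one_event(self):
        rng = np.random.default_rng(5)
        v = 10.0 ** rng.normal(0.7, 0.15, size=30_000)
        q = empirical_quantile(v, 0.99)
        frac = np.mean(v <= q)
        assert abs(frac - 0.99) <= 1.0 / v.size

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientDataError):
            empirical_quantile([], 0.5)

    @given(
        values=st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=50),
        q1=st.floats(min_value=0.01, max_value=0.98),
        dq=st.floats(min_value=0.0, max_value=0.01),
        scale=st.floats(min_value=0.1, max_value=10.0),
        shift=st.floats(min_value=-50, max_value=50),
    )
    def test_monotone_in_q_and_affine_equivariant(self, values, q1, dq, scale, shift):
        v = np.array(values)
        assert empirical_quantile(v, q1) <= empirical_quantile(v, q1 + dq)
        lhs = empirical_quantile(scale * v + shift, q1)
        assert lhs == pytest.approx(scale * empirical_quantile(v, q1) + shift, rel=1e-9, abs=1e-9)


class TestRectGate:
    def test_full_range_gate_keeps_everything(self):
        rng = np.random.default_rng(0)
        s = make_sample(rng.uniform(0, 1000, (500, 4)))
        gate = RectGate("FSC-HLin", "SSC-HLin")
        assert apply_rect_gate(s, gate).all()

    def test_empty_sample(self):
        s = make_sample(np.zeros((0, 4)))
        assert apply_rect_gate(s, RectGate("FSC-HLin", "SSC-HLin", 0, 10, 0, 10)).shape == (0,)

    def test_matches_per_event_brute_force(self):
        rng = np.random.default_rng(1)
        s = make_sample(rng.uniform(0, 200, (1000, 4)))
        gate = RectGate("FSC-HLin", "SSC-HLin", x_min=50, x_max=150, y_min=25, y_max=175)
        mask = apply_rect_gate(s, gate)
        for i in range(s.n_events):
            x, y = s.events[i, 0], s.events[i, 1]
            assert mask[i] == (50 <= x < 150 and 25 <= y < 175)


class TestRangeBin:
    def test_all_below_bin(self):
        s = make_sample(np.full((20, 4), 5.0))
        assert not apply_range_bin(s, RangeBin("GFP-low", "GRN-B-HLin", 10, 100)).any()

    def test_half_open_boundaries(self):
        s = make_sample(np.array([[0, 0, 10.0, 0], [0, 0, 100.0, 0]]))
        mask = apply_range_bin(s, RangeBin("GFP-low", "GRN-B-HLin", 10, 100))
        assert mask.tolist() == [True, False]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        s = make_sample(rng.uniform(0, 2000, (1000, 4)))
        rbin = RangeBin("GFP-medium", "GRN-B-HLin", 100, 1000)
        mask = apply_range_bin(s, rbin)
        for i in range(s.n_events):
            assert mask[i] == (100 <= s.events[i, 2] < 1000)


class TestQuadrants:
    def test_all_double_negative_fall_in_q3(self):
        rng = np.random.default_rng(3)
        ev = rng.uniform(0, 9, (300, 4))
        s = make_sample(ev)
        counts = quadrant_counts(s, QuadrantScheme(10, 10), np.ones(300, bool),
                                 "GRN-B-HLin", "RED-R-HLin")
        assert counts == {"Q1": 0, "Q2": 0, "Q3": 300, "Q4": 0}

    def test_single_double_positive_event(self):
        s = make_sample(np.array([[0, 0, 100.0, 100.0]]))
        counts = quadrant_counts(s, QuadrantScheme(10, 10), np.ones(1, bool),
                                 "GRN-B-HLin", "RED-R-HLin")
        assert counts["Q2"] == 1 and sum(counts.values()) == 1

    def test_partition_and_brute_force(self):
        rng = np.random.default_rng(4)
        s = make_sample(rng.uniform(0, 50, (5000, 4)))
        base = rng.random(5000) < 0.7
        scheme = QuadrantScheme(20, 30)
        counts = quadrant_counts(s, scheme, base, "GRN-B-HLin", "RED-R-HLin")
        expected = {"Q1": 0, "Q2": 0, "Q3": 0, "Q4": 0}
        for i in np.nonzero(base)[0]:
            g, m = s.events[i, 2], s.events[i, 3]
            if g < 20 and m >= 30:
                expected["Q1"] += 1
            elif g >= 20 and m >= 30:
                expected["Q2"] += 1
            elif g < 20:
                expected["Q3"] += 1
            else:
                expected["Q4"] += 1
        assert counts == expected
        assert sum(counts.values()) == int(base.sum())


class TestKde:
    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 1, 10_000)
        grid, dens = kde_density(v, TransformSpec("linear"))
        at_zero = dens[np.argmin(np.abs(grid))]
        assert abs(at_zero - norm.pdf(0)) / norm.pdf(0) < 0.15

    def test_trapezoidal_integral_close_to_one(self):
        rng = np.random.default_rng(7)
        v = 10.0 ** rng.normal(1.5, 0.5, 5000)
        grid, dens = kde_density(v, BIEXP)
        assert dens.min() >= 0
        assert abs(np.trapezoid(dens, grid) - 1.0) < 0.01

    def test_duplication_identical_with_n_held(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 1, 2000)
        g1, d1 = kde_density(v, TransformSpec("linear"))
        g2, d2 = kde_density(np.concatenate([v, v]), TransformSpec("linear"),
                             n_effective=v.size)
        np.testing.assert_allclose(g2, g1)
        np.testing.assert_allclose(d2, d1, rtol=1e-12)

    def test_degenerate_input_raises(self):
        with pytest.raises(DegenerateDistributionError):
            kde_density(np.full(100, 3.0), TransformSpec("linear"))


class TestPeakFinding:
    def test_unimodal_density_one_peak(self):
        rng = np.random.default_rng(9)
        grid, dens = kde_density(rng.normal(0, 1, 5000), TransformSpec("linear"))
        assert find_density_peaks(grid, dens).size == 1

    def test_two_bumps_located_near_component_means(self):
        rng = np.random.default_rng(10)
        t = np.concatenate([rng.normal(0.7, 0.15, 5000), rng.normal(2.5, 0.15, 5000)])
        bw = silverman_bandwidth(t)
        grid, dens = kde_density(t, TransformSpec("linear"))
        peaks = np.sort(find_density_peaks(grid, dens))
        assert peaks.size == 2
        assert abs(peaks[0] - 0.7) < 2 * bw
        assert abs(peaks[1] - 2.5) < 2 * bw

    def test_flat_zero_density_no_peaks(self):
        grid = np.linspace(0, 1, 100)
        assert find_density_peaks(grid, np.zeros(100)).size == 0


class TestMindensity:
    def test_symmetric_mixture_cut_near_midpoint(self):
        rng = np.random.default_rng(12)
        t = np.concatenate([rng.normal(0.7, 0.15, 10_000), rng.normal(2.5, 0.15, 10_000)])
        v = invert_transform(t, BIEXP)
        res = mindensity_cutpoint(v, SplitConfig())
        assert res.method == "density_valley"
        cut_t = apply_transform([res.cutpoint], BIEXP)[0]
        peaks_t = np.sort(apply_transform(np.array(res.peak_positions[:2]), BIEXP))
        assert abs(cut_t - peaks_t.mean()) < 0.1

    def test_unimodal_background_falls_back_to_10_rfu(self):
        rng = np.random.default_rng(13)
        v = 10.0 ** rng.normal(0.7, 0.15, 20_000)
        res = mindensity_cutpoint(v, SplitConfig())
        assert res.method == "fallback_threshold"
        assert res.cutpoint == 10.0

    def test_below_min_events_raises(self):
        with pytest.raises(InsufficientDataError):
            mindensity_cutpoint(np.arange(10.0), SplitConfig())

    def test_duplication_invariant_with_bandwidth_n_held(self):
        rng = np.random.default_rng(14)
        t = np.concatenate([rng.normal(0.7, 0.15, 4000), rng.normal(2.5, 0.15, 4000)])
        v = invert_transform(t, BIEXP)
        res1 = mindensity_cutpoint(v, SplitConfig())
        res2 = mindensity_cutpoint(np.concatenate([v, v]), SplitConfig(), n_effective=v.size)
        assert res2.cutpoint == pytest.approx(res1.cutpoint, rel=1e-12)


class TestSingletMask:
    def test_perfect_singlets_all_kept(self):
        fsc = np.full(100, 500.0)
        ev = np.column_stack([fsc, fsc, fsc, fsc, fsc])  # height == area
        s = make_sample(ev, channel_names=("FSC-HLin", "SSC-HLin", "GRN-B-HLin",
                                           "RED-R-HLin", "FSC-H"))
        assert singlet_mask(s, 0.25).all()

    def test_simulated_doublets_removed(self):
        sample = simulate_sample(SimConfig(seed=15, doublet_fraction=0.1), "target")
        mask = singlet_mask(sample, 0.25)
        doublets = sample.truth.per_event["is_doublet"].to_numpy()
        removed = np.mean(~mask[doublets])
        assert removed >= 0.99

    def test_empty_sample(self):
        s = make_sample(np.zeros((0, 5)), channel_names=("FSC-HLin", "SSC-HLin",
                                                         "GRN-B-HLin", "RED-R-HLin", "FSC-H"))
        assert singlet_mask(s).shape == (0,)
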