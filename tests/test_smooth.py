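import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsascan import (KernelSpec, expected_gprime_profile, haldane_r,
                     kernel_weight_sumsq, recommend_bandwidth, smooth_gprime,
                     smoothing_matrix, tricube_weights)


def cm_spec(half, shape="tricube"):
    return KernelSpec(half_width=half, unit="cm", shape=shape)


class TestTricubeWeights:
    def test_kernel_shape_values(self):
        spec = cm_spec(2.0)
        w = tricube_weights([0.0, 1.0, 2.0], spec)
        # unnormalised kernel is 1 at D=0, (1 - 0.5^3)^3 at D=0.5, 0 at D=1
        assert w[2] == 0.0
        assert w[1] / w[0] == pytest.approx(0.669921875, rel=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_window_rejected(self):
        with pytest.raises(ValueError):
            tricube_weights([0.0, 3.0], cm_spec(2.0))

    @given(st.lists(st.floats(-1.99, 1.99), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_weights_always_normalised(self, offsets):
        w = tricube_weights([0.0] + offsets, cm_spec(2.0))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()


class TestSmoothGprime:
    def test_constant_series_is_fixed_point_even_at_edges(self):
        pos = np.arange(30.0)
        spec = KernelSpec(half_width=7.0, unit="bp")
        out = smooth_gprime(pos, np.full(30, 3.25), spec)
        assert out == pytest.approx(np.full(30, 3.25), abs=1e-12)

    def test_window_below_spacing_is_identity(self):
        pos = np.arange(0.0, 50.0, 5.0)
        g = np.arange(10.0)
        out = smooth_gprime(pos, g, KernelSpec(half_width=2.0, unit="bp", shape="rectangular"))
        assert out == pytest.approx(g)

    def test_central_rectangular_average(self):
        # 5 equally spaced sites, rectangular kernel spanning all 5 from the centre
        pos = np.arange(1.0, 6.0)
        g = np.array([0.0, 0.0, 8.0, 0.0, 0.0])
        out = smooth_gprime(pos, g, KernelSpec(half_width=2.0, unit="bp", shape="rectangular"))
        assert out[2] == pytest.approx(1.6, rel=1e-12)

    def test_chromosomes_smoothed_independently(self):
        pos = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        chroms = np.array(["a", "a", "a", "b", "b", "b"])
        g = np.array([1.0, 1.0, 1.0, 9.0, 9.0, 9.0])
        out = smooth_gprime(pos, g, KernelSpec(half_width=10.0, unit="bp"), chroms=chroms)
        assert out == pytest.approx(g)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            smooth_gprime([3.0, 1.0, 2.0], [1, 1, 1], KernelSpec(half_width=1.0, unit="bp"))

    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 30.0))
    @settings(max_examples=30, deadline=None)
    def test_convex_combination_bounds(self, seed, half):
        r = np.random.default_rng(seed)
        pos = np.sort(r.uniform(0, 100, 40))
        g = r.exponential(2.0, 40)
        out = smooth_gprime(pos, g, KernelSpec(half_width=half, unit="bp"))
        assert (out >= g.min() - 1e-12).all() and (out <= g.max() + 1e-12).all()

    def test_matches_smoothing_matrix(self, rng):
        pos = np.sort(rng.uniform(0, 50, 25))
        g = rng.exponential(1.0, 25)
        spec = KernelSpec(half_width=8.0, unit="bp")
        K = smoothing_matrix(pos, spec)
        assert K.sum(axis=1) == pytest.approx(np.ones(25), abs=1e-12)
        assert K @ g == pytest.approx(smooth_gprime(pos, g, spec), abs=1e-12)


class TestKernelWeightSumsq:
    def test_single_site_window(self):
        out = kernel_weight_sumsq(np.array([5.0]), KernelSpec(half_width=1.0, unit="bp"))
        assert out[0] == pytest.approx(1.0)

    def test_rectangular_is_one_over_m(self):
        # 21 sites, focal at centre, window exactly covering the series
        pos = np.arange(21.0)
        out = kernel_weight_sumsq(pos, KernelSpec(half_width=10.0, unit="bp", shape="rectangular"))
        assert out[10] == pytest.approx(1 / 21)

    def test_tricube_between_equal_weight_and_single_site(self):
        pos = np.arange(21.0)
        spec = KernelSpec(half_width=10.0, unit="bp")
        out = kernel_weight_sumsq(pos, spec)
        # brute-force oracle: square of the explicit weight vector
        w = tricube_weights(pos - 10.0, KernelSpec(half_width=10.0, unit="bp"))
        assert out[10] == pytest.approx(np.dot(w, w), rel=1e-12)
        assert 1 / 21 < out[10] < 1.0

    def test_variance_reduction_of_white_noise(self, rng):
        pos = np.arange(401.0)
        spec = KernelSpec(half_width=25.0, unit="bp")
        k2 = kernel_weight_sumsq(pos, spec)[200]
        noise = rng.standard_normal((4000, 401))
        sm = noise @ smoothing_matrix(pos, spec).T
        ratio = sm[:, 200].var() / noise[:, 200].var()
        assert ratio == pytest.approx(k2, rel=0.1)


class TestBandwidthGuidance:
    def test_single_peak_30cm_window(self):
        spec = recommend_bandwidth("single_peak", cm_per_kb=0.3)
        # full window 30 cM / 0.3 cM/kb = 100 kb, i.e. half-width 50 kb
        assert spec.half_width == pytest.approx(50_000.0)

    def test_rate_proportionality(self):
        w1 = recommend_bandwidth("single_peak", 0.2).half_width
        w2 = recommend_bandwidth("single_peak", 0.4).half_width
        assert w1 == pytest.approx(2 * w2)

    def test_adjacent_peaks_need_narrower_kernel(self):
        wide = recommend_bandwidth("single_peak", 0.3).half_width
        narrow = recommend_bandwidth("resolve_adjacent_peaks", 0.3).half_width
        assert narrow < wide

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            recommend_bandwidth("single_peak", 0.0)


class TestExpectedProfile:
    def test_peak_at_origin_and_null_at_infinity(self):
        grid = np.array([0.0, 5.0, 50.0, 400.0])
        prof, _ = expected_gprime_profile(0.5, 1.0, coverage=50, effective_alleles=300,
                                          distance_grid_cm=grid)
        assert np.argmax(prof) == 0
        assert np.all(np.diff(prof) < 0)
        assert prof[-1] == pytest.approx(1 + 50 / 300, rel=1e-3)

    def test_half_width_at_half_maximum(self):
        # causal allele fixed in one bulk, 0.5 in the other
        _, hwhm = expected_gprime_profile(0.5, 1.0, coverage=50, effective_alleles=300,
                                          distance_grid_cm=np.linspace(0, 40, 5))
        assert hwhm == pytest.approx(12.42, abs=0.01)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            expected_gprime_profile(1.2, 0.5, 50, 300, np.array([0.0]))


def test_haldane_limits():
    assert haldane_r(0.0) == 0.0
    assert haldane_r(1e9) == pytest.approx(0.5)
    assert haldane_r(50.0) == pytest.approx(0.5 * (1 - np.exp(-1.0)))
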