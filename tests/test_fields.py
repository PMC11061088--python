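"""Unit and property tests for the neural field / node dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldground.fields import (
    DimensionSpec,
    Field,
    FieldParams,
    IndexDimension,
    KernelParams,
    Node,
    NodeParams,
    detect_peaks,
    field_step,
    kernel_preset,
    make_kernel,
    node_step,
    settle_field,
    sigmoid,
)


def dims2d(n=48):
    return [DimensionSpec("x", 0, 100, n), DimensionSpec("y", 0, 100, n)]


def gauss_blob(dims, x0, y0, amp=6.0, w=2.5):
    X, Y = np.meshgrid(dims[0].grid, dims[1].grid, indexing="ij")
    return amp * np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2 * w * w))


NOISELESS = FieldParams(q=0.0)


class TestSigmoid:
    def test_midpoint_is_half(self):
        for beta in (0.5, 1.0, 4.0):
            assert sigmoid(0.0, beta) == pytest.approx(0.5)

    def test_odd_symmetry(self):
        assert sigmoid(2.0, 1.0) + sigmoid(-2.0, 1.0) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.floats(-30, 30, allow_nan=False),
        st.floats(0.05, 10, allow_nan=False),
    )
    def test_odd_symmetry_property(self, u, beta):
        assert sigmoid(u, beta) + sigmoid(-u, beta) == pytest.approx(1.0, abs=1e-9)

    def test_reference_value(self):
        # 1/(1 + e^-4), high-precision reference
        assert sigmoid(4.0, 1.0) == pytest.approx(0.9820137900379085, abs=1e-12)

    def test_strictly_increasing(self):
        u = np.linspace(-6, 6, 101)
        g = sigmoid(u, 4.0)
        assert np.all(np.diff(g) > 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            sigmoid(np.nan, 1.0)
        with pytest.raises(ValueError):
            sigmoid(1.0, 0.0)


class TestKernel:
    def test_zero_distance(self):
        kp = KernelParams(w_exc=2.0, w_inhib=0.5, sigma=3.0)
        dim = DimensionSpec("x", 0, 100, 101)
        k = make_kernel(kp, dim)
        assert k[0] == pytest.approx(kp.w_exc - kp.w_inhib)

    def test_far_distance_is_global_inhibition(self):
        kp = KernelParams(w_exc=2.0, w_inhib=0.5, sigma=3.0)
        k = make_kernel(kp, DimensionSpec("x", 0, 100, 101))
        assert k[50] == pytest.approx(-kp.w_inhib, abs=1e-12)

    def test_reference_value_at_one_sigma(self):
        # 2 * exp(-0.5) - 0.5 at distance 3 with sigma 3
        kp = KernelParams(w_exc=2.0, w_inhib=0.5, sigma=3.0)
        k = make_kernel(kp, DimensionSpec("x", 0, 100, 101))
        assert k[3] == pytest.approx(2.0 * math.exp(-0.5) - 0.5, abs=1e-12)

    def test_circular_wraparound_distance(self):
        kp = KernelParams(w_exc=1.0, w_inhib=0.0, sigma=30.0)
        dim = DimensionSpec("hue", 0, 360, 36, circular=True)
        k = make_kernel(kp, dim)
        # sample 35 is 10 degrees from sample 0 going the short way round
        assert k[35] == pytest.approx(k[1])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(w_exc=-1.0, w_inhib=0.0, sigma=1.0)
        with pytest.raises(ValueError):
            KernelParams(w_exc=1.0, w_inhib=0.0, sigma=0.0)


class TestFieldStep:
    def test_fixed_point_is_h_plus_s(self):
        f = Field(dims2d(16), NOISELESS, kernel=None)
        settle_field(f, 3.0, dt=1.0, max_ms=400, tol=0.0)
        assert np.allclose(f.u, -2.0, atol=1e-6)

    def test_relaxation_time_constant_recovered(self):
        # exponential fit of the relaxation toward the attractor
        f = Field([DimensionSpec("x", 0, 100, 16)], NOISELESS, kernel=None)
        dt, t_end = 0.05, 40.0
        ts, us = [], []
        t = 0.0
        while t < t_end:
            f.step(2.0, dt)
            t += dt
            ts.append(t)
            us.append(float(f.u[0]))
        dev = np.abs(np.array(us) - (-3.0))
        keep = dev > 1e-8
        slope = np.polyfit(np.array(ts)[keep], np.log(dev[keep]), 1)[0]
        tau_fit = -1.0 / slope
        assert tau_fit == pytest.approx(f.params.tau, rel=0.02)

    def test_noise_free_determinism(self):
        d = dims2d(24)
        s = gauss_blob(d, 40, 60)
        f1 = Field(d, NOISELESS, kernel_preset("detect", d))
        f2 = Field(d, NOISELESS, kernel_preset("detect", d))
        r1 = np.random.default_rng(1)
        r2 = np.random.default_rng(999)
        for _ in range(50):
            f1.step(s, 1.0, r1)
            f2.step(s, 1.0, r2)
        assert np.array_equal(f1.u, f2.u)

    def test_dt_guard(self):
        f = Field(dims2d(16), NOISELESS)
        with pytest.raises(ValueError):
            f.step(0.0, dt=5.0)

    def test_shape_mismatch_rejected(self):
        f = Field(dims2d(16), NOISELESS)
        with pytest.raises(ValueError):
            f.step(np.zeros((3, 3)), dt=1.0)

    def test_functional_step_leaves_original(self):
        f = Field(dims2d(16), NOISELESS)
        u0 = f.u.copy()
        g = field_step(f, 1.0, 1.0)
        assert np.array_equal(f.u, u0)
        assert not np.array_equal(g.u, u0)

    def test_global_inhibition_matches_literal_kernel(self):
        # the scalar global-inhibition shortcut equals correlating with the
        # literal kernel (Gaussian minus constant) on a 1-D field
        dim = DimensionSpec("x", 0, 100, 64)
        kp = KernelParams(w_exc=0.8, w_inhib=0.05, sigma=4.0)
        rng = np.random.default_rng(3)
        f = Field([dim], NOISELESS, kp, u=rng.normal(0, 2, 64))
        got = f.interaction()
        # literal correlation, zero-padded, grid-spacing weighted
        offsets = (np.arange(64)[:, None] - np.arange(64)[None, :]) * dim.spacing
        w = kp.w_exc * np.exp(-(offsets**2) / (2 * kp.sigma**2)) - kp.w_inhib
        want = w @ f.output() * dim.spacing
        assert np.allclose(got, want, atol=5e-3 * np.abs(want).max())


class TestNode:
    def test_converges_to_h_plus_s(self):
        n = Node(NodeParams(q=0.0, w_se=0.0))
        for _ in range(300):
            n.step(2.0, dt=1.0)
        assert n.u == pytest.approx(-3.0, abs=1e-6)

    def test_bistable_on_state_persists(self):
        n = Node(NodeParams(h=-2.0, q=0.0, w_se=6.0))
        for _ in range(100):
            n.step(4.0, dt=1.0)
        assert n.output() > 0.9
        for _ in range(500):
            n.step(0.0, dt=1.0)
        assert n.output() > 0.9  # on-state survives input removal

    def test_off_state_without_transient(self):
        n = Node(NodeParams(h=-2.0, q=0.0, w_se=6.0))
        for _ in range(500):
            n.step(0.0, dt=1.0)
        assert n.output() < 0.1

    def test_competition_selects_exactly_one(self):
        params = NodeParams(h=-2.0, q=0.05, w_se=6.0, w_comp=8.0)
        a, b = Node(params, "a"), Node(params, "b")
        rng = np.random.default_rng(7)
        for _ in range(600):
            oa, ob = a.output(), b.output()
            a.step(3.0, [ob], dt=1.0, rng=rng)
            b.step(3.0, [oa], dt=1.0, rng=rng)
        assert (a.output() > 0.9) != (b.output() > 0.9)

    def test_functional_node_step(self):
        n = Node(NodeParams(q=0.0))
        m = node_step(n, 1.0)
        assert m.u != n.u


class TestDetectPeaks:
    def test_subthreshold_field_has_no_peaks(self):
        f = Field(dims2d(24), NOISELESS)
        assert detect_peaks(f) == []

    def test_single_bump_centroid_matches_argmax(self):
        d = dims2d(48)
        f = Field(d, NOISELESS)
        f.u = gauss_blob(d, 30.0, 60.0, amp=3.0) - 1.0
        peaks = detect_peaks(f)
        assert len(peaks) == 1
        step = d[0].spacing
        assert abs(peaks[0].location[0] - 30.0) <= step
        assert abs(peaks[0].location[1] - 60.0) <= step

    def test_two_separated_bumps_are_two_peaks(self):
        d = dims2d(48)
        f = Field(d, NOISELESS)
        f.u = gauss_blob(d, 20, 20, amp=3) + gauss_blob(d, 80, 80, amp=3) - 1.0
        assert len(detect_peaks(f)) == 2

    def test_circular_wraparound_bump_is_one_peak(self):
        dim = DimensionSpec("hue", 0, 360, 36, circular=True)
        f = Field([dim], NOISELESS)
        dist = dim.distance(dim.grid, 5.0)
        f.u = 3.0 * np.exp(-(dist**2) / (2 * 20.0**2)) - 1.0
        peaks = detect_peaks(f)
        assert len(peaks) == 1
        # circular mean lands near 5 degrees, not near 180
        assert abs(dim.distance(peaks[0].location[0], 5.0)) <= 2 * dim.spacing

    def test_discrete_axis_cells_do_not_merge(self):
        d = [IndexDimension("idx", 4), DimensionSpec("x", 0, 100, 16)]
        f = Field(d, NOISELESS)
        f.u[0, 5] = 1.0
        f.u[1, 5] = 1.0
        assert len(detect_peaks(f)) == 2


class TestRegimes:
    def test_detection_hysteresis_has_positive_margin(self):
        d = dims2d(48)
        f = Field(d, NOISELESS, kernel_preset("detect", d))
        up = down = None
        for amp in np.arange(0.0, 8.01, 0.25):
            settle_field(f, gauss_blob(d, 50, 50, amp=amp), max_ms=150, tol=1e-4)
            if detect_peaks(f):
                up = amp
                break
        assert up is not None
        for amp in np.arange(up, -0.01, -0.25):
            settle_field(f, gauss_blob(d, 50, 50, amp=amp), max_ms=150, tol=1e-4)
            if not detect_peaks(f):
                down = amp
                break
        assert down is not None and down < up

    @pytest.mark.parametrize("seed", range(8))
    def test_selection_regime_keeps_one_peak(self, seed):
        # subthreshold bimodal drive + rising boost: exactly one winner
        from fieldground.fields import select_by_boost

        d = dims2d(48)
        rng = np.random.default_rng(seed)
        a = rng.uniform(15, 85, 2)
        b = rng.uniform(15, 85, 2)
        while np.hypot(*(a - b)) < 25:
            b = rng.uniform(15, 85, 2)
        s = gauss_blob(d, *a, amp=rng.uniform(2.4, 3.8), w=3.0) + gauss_blob(
            d, *b, amp=rng.uniform(2.4, 3.8), w=3.0
        )
        f = Field(d, NOISELESS, kernel_preset("select", d))
        peaks = select_by_boost(f, s)
        assert len(peaks) == 1

    def test_boost_selection_prefers_stronger_input(self):
        from fieldground.fields import select_by_boost

        d = dims2d(48)
        s = gauss_blob(d, 30, 30, amp=3.0, w=3.0) + gauss_blob(d, 70, 70, amp=3.4, w=3.0)
        f = Field(d, NOISELESS, kernel_preset("select", d))
        peaks = select_by_boost(f, s)
        assert len(peaks) == 1
        assert peaks[0].location == pytest.approx((70, 70), abs=2 * d[0].spacing)

    def test_boost_selection_empty_input_returns_none(self):
        from fieldground.fields import select_by_boost

        d = dims2d(32)
        f = Field(d, NOISELESS, kernel_preset("select", d))
        assert select_by_boost(f, np.zeros(f.shape)) == []

    def test_memory_regime_sustains_peaks_1000ms(self):
        d = dims2d(48)
        f = Field(d, NOISELESS, kernel_preset("memory", d))
        s = gauss_blob(d, 30, 40) + gauss_blob(d, 70, 60)
        settle_field(f, s, max_ms=150, tol=1e-4)
        assert len(detect_peaks(f)) == 2
        settle_field(f, 0.0, max_ms=1000, tol=0.0)
        peaks = detect_peaks(f)
        assert len(peaks) == 2
        locs = sorted(p.location for p in peaks)
        assert locs[0] == pytest.approx((30, 40), abs=2 * d[0].spacing)
        assert locs[1] == pytest.approx((70, 60), abs=2 * d[0].spacing)

    def test_presets_resolution_invariant(self):
        # same physical behavior on coarse and fine grids
        for n in (32, 64):
            d = dims2d(n)
            f = Field(d, NOISELESS, kernel_preset("memory", d))
            settle_field(f, gauss_blob(d, 51, 62), max_ms=150, tol=1e-4)
            settle_field(f, 0.0, max_ms=600, tol=0.0)
            peaks = detect_peaks(f)
            assert len(peaks) == 1
            assert peaks[0].location == pytest.approx((51, 62), abs=2 * d[0].spacing)


class TestDimensionSpec:
    def test_invariants(self):
        with pytest.raises(ValueError):
            DimensionSpec("x", 0, 100, 4)
        with pytest.raises(ValueError):
            DimensionSpec("x", 10, 10, 16)

    def test_circular_index_wraps(self):
        dim = DimensionSpec("hue", 0, 360, 36, circular=True)
        assert dim.index_of(359.0) in (0, 35)
        assert dim.index_of(370.0) == 1
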