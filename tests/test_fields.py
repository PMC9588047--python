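"""Field-engine unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfvwm.fields import (
    DynamicNode,
    Field,
    InteractionKernel,
    SigmoidSpec,
    circular_distance,
    detect_peaks,
    euler_step,
    lateral_input,
    node_step,
    sigmoid,
)


class TestSigmoid:
    def test_midpoint_and_saturation(self):
        spec = SigmoidSpec(beta=4.0, theta=0.0)
        assert sigmoid(0.0, spec) == pytest.approx(0.5)
        assert sigmoid(1e3, spec) == pytest.approx(1.0)
        assert sigmoid(-1e3, spec) == pytest.approx(0.0)

    def test_closed_form_value(self):
        # logistic at u=1 with beta=4: 1/(1+e^-4)
        assert sigmoid(1.0, SigmoidSpec(beta=4.0)) == pytest.approx(
            1.0 / (1.0 + np.exp(-4.0)), abs=1e-12)

    def test_threshold_shift(self):
        spec = SigmoidSpec(beta=2.0, theta=1.5)
        assert sigmoid(1.5, spec) == pytest.approx(0.5)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            sigmoid(np.array([0.0, np.nan]))

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_bounded(self, a, b):
        spec = SigmoidSpec(beta=4.0)
        ga, gb = float(sigmoid(a, spec)), float(sigmoid(b, spec))
        assert 0.0 <= ga <= 1.0
        if a < b:
            assert ga <= gb


class TestKernel:
    def test_surround_structure_enforced(self):
        with pytest.raises(ValueError):
            InteractionKernel(c_exc=1.0, sigma_exc=10.0, c_inh=1.0, sigma_inh=5.0)

    def test_negative_global_inhibition_rejected(self):
        with pytest.raises(ValueError):
            InteractionKernel(g_inh=-0.1)

    def test_difference_of_gaussians_shape(self):
        k = InteractionKernel(c_exc=2.0, sigma_exc=4.0, c_inh=0.5, sigma_inh=12.0)
        prof = k.profile((360,))
        # maximum at zero distance, negative surround, symmetric
        assert prof[0] == pytest.approx(1.5)
        assert prof.min() < 0
        assert np.allclose(prof[1:], prof[1:][::-1], atol=1e-12)

    def test_too_wide_kernel_rejected(self):
        k = InteractionKernel(c_exc=1.0, sigma_exc=400.0)
        with pytest.raises(ValueError):
            k.profile((360,))


class TestLateralInput:
    def brute_force(self, field):
        """O(n^2) direct evaluation of the interaction integral."""
        g = field.output()
        n = field.shape[0]
        coords = field.coords()
        k = field.kernel
        out = np.zeros(n)
        for i in range(n):
            for j in range(n):
                d = circular_distance(coords[i], coords[j])
                w = (k.c_exc * np.exp(-0.5 * (d / k.sigma_exc) ** 2)
                     - k.c_inh * np.exp(-0.5 * (d / k.sigma_inh) ** 2)
                     - k.g_inh)
                out[i] += w * g[j]
        return out * field.cell

    @pytest.mark.parametrize("n_sites", [60, 120])
    def test_matches_brute_force(self, n_sites):
        rng = np.random.default_rng(42)
        f = Field("f", (n_sites,),
                  kernel=InteractionKernel(c_exc=1.5, sigma_exc=5.0,
                                           c_inh=0.6, sigma_inh=15.0,
                                           g_inh=0.1))
        f.u = rng.normal(0.0, 3.0, n_sites)
        assert np.max(np.abs(lateral_input(f) - self.brute_force(f))) < 1e-8

    def test_impulse_reproduces_kernel(self):
        # one saturated site, all others far below threshold: lateral input
        # approximates the kernel centered at that site
        n = 120
        f = Field("f", (n,), kernel=InteractionKernel(c_exc=2.0, sigma_exc=6.0))
        f.u = np.full(n, -1e3)
        f.u[40] = 1e3
        lat = lateral_input(f)
        prof = f.kernel.profile((n,)) * f.cell
        assert np.allclose(lat, np.roll(prof, 40), atol=1e-9)

    def test_zero_output_gives_zero(self):
        f = Field("f", (90,), kernel=InteractionKernel(c_exc=1.0, sigma_exc=5.0))
        f.u = np.full(90, -1e3)
        assert np.max(np.abs(lateral_input(f))) < 1e-12

    def test_requires_kernel(self):
        with pytest.raises(ValueError):
            lateral_input(Field("f", (90,)))


class TestEulerStep:
    def test_fixed_point_at_rest(self):
        f = Field("f", (90,), h=-3.0)
        u0 = f.u.copy()
        euler_step(f, None, 2.0)
        assert np.allclose(f.u, u0, atol=1e-12)

    def test_exponential_relaxation_to_input(self):
        # u(t) = h + s + (u0 - h - s) exp(-t/tau); after 5 tau the residual
        # is below 1% of the input amplitude
        f = Field("f", (4,), h=-5.0, tau=20.0)
        s = 3.0
        steps = int(5 * f.tau / 0.5)
        for _ in range(steps):
            euler_step(f, np.full(4, s), 0.5)
        assert np.max(np.abs(f.u - (f.h + s))) < 0.01 * s

    def test_relaxation_matches_closed_form(self):
        f = Field("f", (1,), h=0.0, tau=25.0)
        f.u = np.array([4.0])
        t, dt = 0.0, 0.1
        for _ in range(500):
            euler_step(f, None, dt)
            t += dt
        assert f.u[0] == pytest.approx(4.0 * np.exp(-t / 25.0), rel=5e-3)

    def test_unstable_dt_rejected(self):
        f = Field("f", (8,), tau=10.0)
        with pytest.raises(ValueError):
            euler_step(f, None, 10.0)
        with pytest.raises(ValueError):
            euler_step(f, None, -1.0)

    def test_deterministic_without_noise_and_reproducible_with(self):
        def evolve(seed=None, q=0.0):
            f = Field("f", (60,), q=q,
                      kernel=InteractionKernel(c_exc=1.0, sigma_exc=5.0))
            rng = np.random.default_rng(seed) if seed is not None else None
            for _ in range(100):
                euler_step(f, None, 2.0, rng)
            return f.u

        assert np.array_equal(evolve(q=0.0), evolve(q=0.0))
        assert np.array_equal(evolve(seed=7, q=0.2), evolve(seed=7, q=0.2))
        assert not np.array_equal(evolve(seed=7, q=0.2), evolve(seed=8, q=0.2))

    def test_noise_requires_rng(self):
        f = Field("f", (8,), q=0.1)
        with pytest.raises(ValueError):
            euler_step(f, None, 2.0)


class TestDetectPeaks:
    def test_flat_subthreshold_field_empty(self):
        f = Field("f", (120,))
        assert detect_peaks(f, 0.0) == []

    def test_single_bump_located(self):
        f = Field("f", (120,))
        d = circular_distance(f.coords(), 90.0)
        f.u = -5.0 + 10.0 * np.exp(-0.5 * (d / 10.0) ** 2)
        peaks = detect_peaks(f, 0.0)
        assert len(peaks) == 1
        assert circular_distance(peaks[0][0], 90.0) <= 3.0  # one grid step

    def test_two_bumps_match_brute_force(self):
        f = Field("f", (120,))
        c = f.coords()
        f.u = (-5.0
               + 9.0 * np.exp(-0.5 * (circular_distance(c, 80.0) / 8.0) ** 2)
               + 7.0 * np.exp(-0.5 * (circular_distance(c, 280.0) / 8.0) ** 2))
        peaks = detect_peaks(f, 0.0)
        assert len(peaks) == 2
        # sorted by descending activation; brute-force argmax agrees
        assert circular_distance(peaks[0][0], c[np.argmax(f.u)]) <= 3.0
        assert circular_distance(peaks[0][0], 80.0) <= 3.0
        assert circular_distance(peaks[1][0], 280.0) <= 3.0

    def test_wraparound_peak(self):
        f = Field("f", (120,))
        d = circular_distance(f.coords(), 0.0)
        f.u = -5.0 + 8.0 * np.exp(-0.5 * (d / 6.0) ** 2)
        peaks = detect_peaks(f, 0.0)
        assert len(peaks) == 1
        assert circular_distance(peaks[0][0], 0.0) <= 3.0


class TestDynamicNode:
    def test_rest_is_fixed_point(self):
        nd = DynamicNode("n", h=-3.0, tau=15.0)
        node_step(nd, 0.0, 1.0)
        assert nd.u == pytest.approx(-3.0)

    def test_strong_drive_activates_within_10_tau(self):
        nd = DynamicNode("n", h=-2.0, tau=20.0, self_exc=1.0)
        t, dt = 0.0, 1.0
        while t < 10 * nd.tau and nd.output() < 0.5:
            node_step(nd, 6.0, dt)
            t += dt
        assert nd.output() >= 0.5

    def test_decays_when_drive_removed(self):
        nd = DynamicNode("n", h=-2.0, tau=20.0, self_exc=1.0)
        for _ in range(200):
            node_step(nd, 6.0, 1.0)
        assert nd.output() > 0.9
        for _ in range(int(10 * nd.tau)):
            node_step(nd, 0.0, 1.0)
        assert nd.output() < 0.1


class TestGridRefinement:
    def _equilibrium_peak(self, n, dt):
        f = Field("f", (n,), h=-4.5,
                  kernel=InteractionKernel(c_exc=1.35, sigma_exc=4.0))
        inh_reach = 12.0
        d = circular_distance(f.coords(), 123.0)
        stim = 8.0 * np.exp(-0.5 * (d / 5.0) ** 2)
        for _ in range(int(400 / dt)):
            euler_step(f, stim, dt)
        peaks = detect_peaks(f, 0.0)
        assert peaks
        return peaks[0][0]

    def test_halving_dt_stable(self):
        p1 = self._equilibrium_peak(180, 2.0)
        p2 = self._equilibrium_peak(180, 1.0)
        assert circular_distance(p1, p2) < 0.5

    def test_doubling_sites_stable(self):
        p1 = self._equilibrium_peak(180, 2.0)
        p2 = self._equilibrium_peak(360, 2.0)
        assert circular_distance(p1, p2) < 0.5
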