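import math

import numpy as np
import pytest

from frozenframes import (
    BiphasicParams,
    FrameStack,
    SeparableSTFilter,
    apply_separable,
    make_biphasic,
    make_filter_pair,
    make_spatial_gaussian,
    make_temporal_highpass,
    make_temporal_lowpass,
)
from frozenframes.filters import default_temporal_size
from scipy import ndimage


class TestSpatialGaussian:
    def test_size_and_normalization_at_default_scale(self):
        k = make_spatial_gaussian(9.0, truncate=3.0)
        assert k.shape == (55, 55)
        assert abs(k.sum() - 1.0) < 1e-12

    def test_subpixel_std_acts_as_delta(self):
        k = make_spatial_gaussian(0.25)
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 255, size=(16, 16))
        out = ndimage.convolve(frame, k, mode="reflect")
        assert np.abs(out - frame).max() < 1.0

    def test_isotropy(self):
        k = make_spatial_gaussian(3.0)
        np.testing.assert_allclose(k, k[::-1, ::-1])
        np.testing.assert_allclose(k, k.T)

    def test_invalid_std(self):
        with pytest.raises(ValueError):
            make_spatial_gaussian(0.0)


class TestTemporalKernels:
    def test_box_kernels(self):
        np.testing.assert_allclose(make_temporal_lowpass("box", 2), [0.5, 0.5])
        np.testing.assert_allclose(make_temporal_lowpass("box", 8), [0.125] * 8)

    def test_gaussian_kernel_is_symmetric_unimodal_unit_sum(self):
        phi = make_temporal_lowpass("gaussian", 8)
        assert abs(phi.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(phi, phi[::-1])
        peak = np.argmax(phi)
        assert np.all(np.diff(phi[: peak + 1]) >= 0)
        assert np.all(np.diff(phi[peak:]) <= 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_temporal_lowpass("box", 1)

    @pytest.mark.parametrize("kind,size", [("box", 2), ("box", 8), ("gaussian", 6)])
    def test_derivative_kernel_sums_to_zero(self, kind, size):
        psi = make_temporal_highpass(make_temporal_lowpass(kind, size))
        assert abs(psi.sum()) < 1e-12

    def test_two_tap_box_gives_antisymmetric_pair(self):
        psi = make_temporal_highpass(np.array([0.5, 0.5]))
        assert psi[0] > 0
        np.testing.assert_allclose(psi, [0.25, -0.25])

    def test_gaussian_derivative_matches_analytic_form(self):
        # psi for a well-truncated Gaussian phi samples -t/s^2 * g(t)
        size, s = 41, 4.0  # +-5 std: negligible tail truncation
        t = np.arange(size) - (size - 1) / 2.0
        g = np.exp(-0.5 * (t / s) ** 2)
        g /= g.sum()
        psi = make_temporal_highpass(g)
        analytic = -t / s**2 * g
        # central differences are second-order accurate: error ~ h^2 |g'''|/6
        assert np.abs(psi - analytic).max() < 3e-2 * np.abs(analytic).max()
        np.testing.assert_allclose(psi, -psi[::-1], atol=1e-15)

    def test_default_size_follows_frame_rate(self):
        assert default_temporal_size(25) == 2
        assert default_temporal_size(200) == 8
        assert default_temporal_size(30) == 2


class TestBiphasic:
    def test_raw_response_vanishes_at_origin(self):
        # (kt)^n at t=0 is 0 for n >= 1, so the first tap only carries
        # the mean subtraction
        params = BiphasicParams(n=3, k=1.0, support=10.0)
        kernel = make_biphasic(params)
        raw0 = kernel[0] - (-np.mean(kernel - kernel))  # mean already removed
        assert abs((kernel - kernel.mean())[0] - kernel[0]) < 1e-15
        t = np.arange(0, 21, dtype=float)
        raw = t**3 * np.exp(-t) * (1 / math.factorial(3) - t**2 / math.factorial(5))
        assert raw[0] == 0.0
        np.testing.assert_allclose(kernel, raw - raw.mean())

    def test_sign_change_at_analytic_root(self):
        # bracket changes sign where (kt)^2 = (n+2)!/n! = 20 for n=3, k=1
        t = np.linspace(0, 20, 20001)
        raw = t**3 * np.exp(-t) * (1 / math.factorial(3) - t**2 / math.factorial(5))
        crossings = t[1:][np.sign(raw[1:]) * np.sign(raw[:-1]) < 0]
        assert len(crossings) == 1
        assert abs(crossings[0] - math.sqrt(20)) < 1e-2

    def test_single_sign_change_and_zero_sum(self):
        kernel = make_biphasic(BiphasicParams(n=3, k=1.0, support=12.0))
        assert abs(kernel.sum()) < 1e-12
        interior = kernel[1:]  # skip the origin tap
        signs = np.sign(interior[np.abs(interior) > 1e-10])
        assert np.sum(np.diff(signs) != 0) == 1

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            BiphasicParams(n=0, k=1.0, support=5.0)
        with pytest.raises(ValueError):
            BiphasicParams(n=3, k=1.0, support=1.0)


class TestSeparableFilter:
    def test_pair_invariants(self):
        ll, lh = make_filter_pair(rho_std=2.0, phi_kind="box", phi_size=4)
        assert abs(ll.rho.sum() - 1.0) < 1e-9
        assert abs(ll.phi.sum() - 1.0) < 1e-9
        assert abs(lh.psi.sum()) < 1e-9
        assert ll.mode == "LL" and lh.mode == "LH"
        np.testing.assert_array_equal(ll.rho, lh.rho)

    def test_constant_stack_ll_identity_lh_annihilation(self, constant_stack, small_pair):
        ll, lh = small_pair
        np.testing.assert_allclose(
            apply_separable(constant_stack, ll).frames, constant_stack.frames, atol=1e-9
        )
        np.testing.assert_allclose(
            apply_separable(constant_stack, lh).frames, 0.0, atol=1e-9
        )

    def test_spatial_and_temporal_stages_commute(self, random_stack):
        ll, _ = make_filter_pair(rho_std=1.5, phi_kind="box", phi_size=4)
        spatial_first = apply_separable(random_stack, ll)
        # temporal first: convolve time axis, then feed through a purely
        # spatial version of the filter
        tmp = ndimage.convolve1d(random_stack.frames, ll.phi, axis=0, mode="reflect")
        temporal_first = ndimage.convolve1d(tmp, ll.rho_1d, axis=1, mode="reflect")
        temporal_first = ndimage.convolve1d(temporal_first, ll.rho_1d, axis=2, mode="reflect")
        np.testing.assert_allclose(spatial_first.frames, temporal_first, atol=1e-9)

    def test_linearity(self, random_stack):
        ll, _ = make_filter_pair(rho_std=1.0, phi_kind="box", phi_size=2)
        rng = np.random.default_rng(3)
        other = FrameStack(rng.uniform(0, 255, random_stack.frames.shape), fps=25.0)
        combo = FrameStack(
            2.0 * random_stack.frames + 0.5 * other.frames, fps=25.0
        )
        lhs = apply_separable(combo, ll).frames
        rhs = (
            2.0 * apply_separable(random_stack, ll).frames
            + 0.5 * apply_separable(other, ll).frames
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_stack_shorter_than_kernel_rejected(self):
        stack = FrameStack(np.zeros((3, 4, 4)), fps=25.0)
        ll, _ = make_filter_pair(rho_std=1.0, phi_kind="box", phi_size=8)
        with pytest.raises(ValueError, match="size 8"):
            apply_separable(stack, ll)

    def test_bad_kernels_rejected(self):
        with pytest.raises(ValueError, match="unit DC"):
            SeparableSTFilter(rho=np.ones((3, 3)), phi=np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="mode"):
            SeparableSTFilter(
                rho=np.full((3, 3), 1 / 9), phi=np.array([0.5, 0.5]), mode="HH"
            )
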