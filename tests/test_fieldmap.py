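"""Spatial/temporal unwrapping and field-map regression."""

import numpy as np
import pytest
from scipy import ndimage

from refrase import (EchoSeries, fit_fieldmap, smooth_first_echo,
                     unwrap_spatial, unwrap_temporal, wrap_phase)
from refrase.fieldmap import reference_voxel, unwrap_1d


def _deref(x, truth, mask):
    """Remove the single global 2*pi*k the unwrapper cannot know."""
    k = np.round(np.mean(x[mask] - truth[mask]) / (2 * np.pi))
    return x - 2 * np.pi * k


def _series_from_field(b, tes, mag=None):
    phase = np.stack([wrap_phase(2 * np.pi * b * t) for t in tes])
    mag = np.ones_like(phase) if mag is None else mag
    return EchoSeries(phase=phase, magnitude=mag, tes=np.asarray(tes))


class TestUnwrapSpatial:
    def test_linear_ramp_recovered_exactly(self, ball_mask_32):
        x = np.arange(32, dtype=float)
        truth = 0.4 * np.pi * x[:, None, None] * np.ones((32, 32, 32))
        res = unwrap_spatial(wrap_phase(truth), ball_mask_32)
        dev = _deref(res.unwrapped, truth, ball_mask_32) - truth
        assert np.abs(dev[ball_mask_32]).max() < 1e-9

    def test_rewrap_reproduces_input(self, ball_mask_32):
        rng = np.random.default_rng(2)
        phase = wrap_phase(rng.uniform(-np.pi, np.pi, (32, 32, 32)))
        res = unwrap_spatial(phase, ball_mask_32)
        m = ball_mask_32
        np.testing.assert_allclose(wrap_phase(res.unwrapped)[m], phase[m],
                                   atol=1e-9)
        # the k volume is exactly the applied multiple
        np.testing.assert_allclose(res.unwrapped[m],
                                   (phase + 2 * np.pi * res.k)[m], atol=0)

    def test_wrap_free_input_only_shifted(self, ball_mask_32):
        smooth = ndimage.gaussian_filter(np.random.default_rng(3)
                                         .standard_normal((32, 32, 32)), 6)
        smooth -= smooth.mean()
        smooth *= 0.9 * np.pi / np.abs(smooth).max()   # within (-pi, pi)
        assert np.abs(smooth).max() < np.pi
        res = unwrap_spatial(smooth, ball_mask_32)
        dev = res.unwrapped[ball_mask_32] - smooth[ball_mask_32]
        k = np.round(dev[0] / (2 * np.pi))
        np.testing.assert_allclose(dev, 2 * np.pi * k, atol=1e-9)

    def test_disconnected_mask_raises_with_sizes(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[2:5, 2:5, 2:5] = True
        mask[10:14, 10:14, 10:14] = True
        with pytest.raises(ValueError, match="components"):
            unwrap_spatial(np.zeros((16, 16, 16)), mask)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_smooth_nyquist_fields_exact(self, seed, ball_mask_32):
        """Any smooth field with max gradient < 0.9*pi/voxel unwraps exactly."""
        rng = np.random.default_rng(seed)
        f = ndimage.gaussian_filter(rng.standard_normal((32, 32, 32)), 4)
        gmax = max(np.abs(np.diff(f, axis=a)).max() for a in range(3))
        truth = f * (0.9 * np.pi / gmax)
        res = unwrap_spatial(wrap_phase(truth), ball_mask_32)
        dev = _deref(res.unwrapped, truth, ball_mask_32) - truth
        assert np.abs(dev[ball_mask_32]).max() < 1e-6


class TestUnwrapTemporal:
    def test_minimal_jump_continuation(self):
        tes = [1e-3, 2e-3, 3e-3]
        phase = np.array([[[[0.9 * np.pi]]],
                          [[[wrap_phase(1.8 * np.pi)]]],
                          [[[wrap_phase(2.7 * np.pi)]]]])
        s = EchoSeries(phase=phase, magnitude=np.ones_like(phase), tes=tes)
        out = unwrap_temporal(s, (0, 0, 0))
        np.testing.assert_allclose(out.phase[:, 0, 0, 0],
                                   [0.9 * np.pi, 1.8 * np.pi, 2.7 * np.pi],
                                   atol=1e-12)

    def test_already_continuous_unchanged(self):
        tes = [4e-3, 16e-3, 28e-3]
        b = 10.0
        phase = np.array([np.full((3, 3, 3), 2 * np.pi * b * t) for t in tes])
        s = EchoSeries(phase=phase, magnitude=np.ones_like(phase), tes=tes)
        out = unwrap_temporal(s, (1, 1, 1))
        np.testing.assert_allclose(out.phase, phase, atol=1e-12)

    def test_single_echo_unchanged(self):
        phase = np.full((1, 3, 3, 3), 0.3)
        s = EchoSeries(phase=phase, magnitude=np.ones_like(phase), tes=[4e-3])
        out = unwrap_temporal(s, (1, 1, 1))
        np.testing.assert_allclose(out.phase, phase, atol=1e-12)

    def test_reference_outside_mask_raises(self):
        phase = np.zeros((2, 4, 4, 4))
        s = EchoSeries(phase=phase, magnitude=np.ones_like(phase),
                       tes=[1e-3, 2e-3])
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            unwrap_temporal(s, (2, 2, 2), mask)


class TestFitFieldmap:
    def test_exact_linear_model(self):
        tes = [4e-3, 16e-3]
        s = _series_from_field(np.full((4, 4, 4), 10.0), tes)
        s.phase = np.stack([2 * np.pi * 10.0 * t * np.ones((4, 4, 4)) for t in tes])
        fm = fit_fieldmap(s, np.ones((4, 4, 4), bool))
        np.testing.assert_allclose(fm.data, 10.0, atol=1e-10)

    def test_intercept_model(self):
        tes = [4e-3, 16e-3, 28e-3]
        phase = np.stack([(0.5 + 2 * np.pi * 10.0 * t) * np.ones((4, 4, 4))
                          for t in tes])
        s = EchoSeries(phase=phase, magnitude=np.ones_like(phase), tes=tes)
        fm = fit_fieldmap(s, np.ones((4, 4, 4), bool), include_intercept=True)
        np.testing.assert_allclose(fm.data, 10.0, atol=1e-9)

    def test_zero_phase_zero_field_and_linearity(self):
        tes = [4e-3, 16e-3, 28e-3]
        shape = (6, 6, 6)
        rng = np.random.default_rng(4)
        b1 = rng.standard_normal(shape)
        b2 = rng.standard_normal(shape)
        mask = np.ones(shape, bool)

        def unwrapped_series(b):
            phase = np.stack([2 * np.pi * b * t for t in tes])
            return EchoSeries(phase=phase, magnitude=np.ones_like(phase), tes=tes)

        z = fit_fieldmap(unwrapped_series(np.zeros(shape)), mask)
        assert np.all(z.data == 0)
        f1 = fit_fieldmap(unwrapped_series(b1), mask).data
        f2 = fit_fieldmap(unwrapped_series(b2), mask).data
        f12 = fit_fieldmap(unwrapped_series(b1 + b2), mask).data
        np.testing.assert_allclose(f12, f1 + f2, atol=1e-9)

    def test_intercept_requires_two_echoes(self):
        phase = np.zeros((1, 3, 3, 3))
        s = EchoSeries(phase=phase, magnitude=np.ones_like(phase), tes=[4e-3])
        with pytest.raises(ValueError, match="two echoes"):
            fit_fieldmap(s, np.ones((3, 3, 3), bool), include_intercept=True)


class TestSmoothFirstEcho:
    def test_constant_phase_preserved(self):
        phase = np.full((2, 8, 8, 8), 0.7)
        mag = np.abs(np.random.default_rng(5).standard_normal((2, 8, 8, 8))) + 0.1
        s = EchoSeries(phase=phase, magnitude=mag, tes=[1e-3, 2e-3])
        out = smooth_first_echo(s, sigma=2.0)
        np.testing.assert_allclose(out.phase[0], 0.7, atol=1e-12)

    def test_later_echoes_untouched(self):
        rng = np.random.default_rng(6)
        phase = rng.uniform(-np.pi, np.pi, (3, 8, 8, 8))
        s = EchoSeries(phase=phase, magnitude=np.ones_like(phase),
                       tes=[1e-3, 2e-3, 3e-3])
        out = smooth_first_echo(s)
        assert np.array_equal(out.phase[1:], phase[1:])
        assert np.array_equal(out.magnitude, s.magnitude)

    def test_impulse_attenuated_like_gaussian(self):
        """A small phase impulse behaves linearly: the smoothed phase equals
        the Gaussian-filtered phase of the impulse to first order."""
        shape = (1, 16, 16, 16)
        phase = np.zeros(shape)
        phase[0, 8, 8, 8] = 0.2     # small-angle regime
        s = EchoSeries(phase=phase, magnitude=np.ones_like(phase), tes=[1e-3])
        out = smooth_first_echo(s, sigma=2.0)
        oracle = ndimage.gaussian_filter(phase[0], 2.0)
        np.testing.assert_allclose(out.phase[0], oracle, atol=2e-3)
        assert out.phase[0, 8, 8, 8] < 0.2


def test_reference_voxel_is_nearest_in_mask_to_centroid():
    mask = np.zeros((10, 10, 10), bool)
    mask[1, 1, 1] = True
    mask[7:10, 7:10, 7:10] = True   # centroid pulled toward the block
    ref = reference_voxel(mask)
    assert mask[ref]
    assert ref != (1, 1, 1)


def test_unwrap_1d_recovers_steep_ramp():
    truth = np.linspace(0, 40, 200)
    out = unwrap_1d(wrap_phase(truth))
    np.testing.assert_allclose(out, truth, atol=1e-9)
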