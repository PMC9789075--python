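"""Sampling-mask geometry, calibration, echo sharing and volume transform."""

import numpy as np
import pytest

from accelt2 import (SamplingPlan, make_elliptical_support, make_poisson_mask,
                     make_sampling_mask, share_echo_lines, undersample_volume)
from accelt2.phantom import EchoSeries
from accelt2.undersample import _elliptical_radius


class TestEllipticalSupport:
    def test_default_fraction_on_acquisition_grid(self):
        e = make_elliptical_support(128, 22, 0.7)
        assert 0.69 <= e.mean() <= 0.71

    def test_full_fraction_is_rectangle(self):
        assert make_elliptical_support(16, 16, 1.0).all()

    def test_corners_excluded(self):
        for shape in ((128, 22), (64, 8), (32, 32)):
            e = make_elliptical_support(*shape, 0.7)
            assert not e[0, 0] and not e[0, -1]
            assert not e[-1, 0] and not e[-1, -1]

    def test_unreachable_fraction_raises_with_achievable(self):
        with pytest.raises(ValueError, match="achievable"):
            make_elliptical_support(4, 4, 0.05)


class TestPoissonMask:
    def test_realized_acceleration_within_tolerance(self):
        for R in (2.0, 8.0):
            plan = SamplingPlan(R=R, grid=(128, 22), seed=3)
            _, realized = make_poisson_mask(plan, 0, return_realized=True)
            assert abs(realized - R) / R <= plan.calibration_tolerance

    def test_r1_samples_whole_ellipse(self):
        plan = SamplingPlan(R=1.0, grid=(64, 16), seed=0)
        mask = make_poisson_mask(plan, 0)
        ell = make_elliptical_support(64, 16, plan.ellipse_area_fraction)
        assert np.array_equal(mask, ell)

    def test_unique_pattern_per_echo_and_reproducible(self):
        plan = SamplingPlan(R=4.0, grid=(64, 16), seed=5)
        m0 = make_poisson_mask(plan, 0)
        m1 = make_poisson_mask(plan, 1)
        m0b = make_poisson_mask(plan, 0)
        assert not np.array_equal(m0, m1)
        assert np.array_equal(m0, m0b)

    def test_central_square_always_sampled(self):
        plan = SamplingPlan(R=8.0, grid=(64, 16), seed=2)
        mask = make_poisson_mask(plan, 0)
        hy = int(round(np.sqrt(0.05) * 64)) | 1
        hz = int(round(np.sqrt(0.05) * 16)) | 1
        y0, z0 = (64 - hy) // 2, (16 - hz) // 2
        square = np.zeros((64, 16), dtype=bool)
        square[y0:y0 + hy, z0:z0 + hz] = True
        ell = make_elliptical_support(64, 16, plan.ellipse_area_fraction)
        assert mask[square & ell].all()

    def test_center_weighted_density_profile(self):
        plan = SamplingPlan(R=4.0, grid=(128, 22), seed=1)
        mask = make_poisson_mask(plan, 0)
        ell = make_elliptical_support(128, 22, plan.ellipse_area_fraction)
        d = _elliptical_radius(128, 22)
        fracs = []
        for lo, hi in ((0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1.0)):
            sel = ell & (d >= lo) & (d < hi)
            fracs.append(mask[sel].mean())
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_mask_subset_of_ellipse(self):
        plan = SamplingPlan(R=6.0, grid=(64, 16), seed=9)
        sm = make_sampling_mask(plan)
        assert not (sm.masks & ~sm.ellipse[None]).any()


class TestShareEchoLines:
    tes = (0.0, 12.9, 25.7, 51.4)

    def _kspace(self, rng):
        return (rng.normal(size=(4, 6, 3, 5)) +
                1j * rng.normal(size=(4, 6, 3, 5)))

    def test_fully_sampled_lines_unchanged(self, rng):
        k = self._kspace(rng)
        masks = np.ones((4, 6, 5), dtype=bool)
        out = share_echo_lines(k, masks, self.tes)
        assert np.array_equal(out, k)

    def test_line_sampled_only_at_te0_shared_to_all(self, rng):
        k = self._kspace(rng)
        masks = np.zeros((4, 6, 5), dtype=bool)
        masks[0, 2, 3] = True
        out = share_echo_lines(k, masks, self.tes)
        for e in range(4):
            assert np.array_equal(out[e, 2, :, 3], k[0, 2, :, 3])

    def test_unsampled_lines_zero_filled(self, rng):
        k = self._kspace(rng)
        masks = np.zeros((4, 6, 5), dtype=bool)
        out = share_echo_lines(k, masks, self.tes)
        assert (out == 0).all()

    def test_temporally_closest_donor_with_tie_to_earlier(self, rng):
        k = self._kspace(rng)
        tes = (0.0, 10.0, 20.0, 30.0)
        masks = np.zeros((4, 6, 5), dtype=bool)
        masks[0, 1, 1] = True   # TE 0
        masks[2, 1, 1] = True   # TE 20
        out = share_echo_lines(k, masks, tes)
        # echo 1 (TE 10) is equidistant from TE 0 and TE 20: earlier wins
        assert np.array_equal(out[1, 1, :, 1], k[0, 1, :, 1])
        # echo 3 (TE 30) takes the closest sampled (TE 20)
        assert np.array_equal(out[3, 1, :, 1], k[2, 1, :, 1])

    def test_never_invents_data(self, rng):
        k = self._kspace(rng)
        masks = np.random.default_rng(0).random((4, 6, 5)) < 0.4
        out = share_echo_lines(k, masks, self.tes)
        for e in range(4):
            for y in range(6):
                for z in range(5):
                    line = out[e, y, :, z]
                    if np.any(line != 0):
                        assert any(np.array_equal(line, k[d, y, :, z])
                                   for d in range(4))

    def test_shape_mismatch_raises(self, rng):
        k = self._kspace(rng)
        with pytest.raises(ValueError):
            share_echo_lines(k, np.ones((4, 7, 5), dtype=bool), self.tes)


class TestUndersampleVolume:
    def test_identity_at_r1_full_coverage(self, clean_phantom):
        plan = SamplingPlan(R=1.0, grid=(32, 8), ellipse_area_fraction=1.0,
                            central_square_area_fraction=0.05)
        out, _ = undersample_volume(clean_phantom.echo_series, plan)
        assert np.allclose(out.data, clean_phantom.echo_series.data,
                           atol=1e-9)

    def test_energy_outside_support_is_zero(self, clean_phantom):
        # sharing never writes outside the elliptical coverage: the shared
        # k-space (before the magnitude step) is empty there
        from accelt2.undersample import make_sampling_mask
        plan = SamplingPlan(R=3.0, grid=(32, 8), seed=4)
        sm = make_sampling_mask(plan)
        k = np.fft.fftshift(np.fft.fftn(
            clean_phantom.echo_series.data.astype(complex), axes=(1, 3)),
            axes=(1, 3))
        k *= sm.ellipse[None, :, None, :]
        shared = share_echo_lines(k, sm.masks & sm.ellipse[None],
                                  clean_phantom.echo_series.echo_times)
        outside = ~sm.ellipse
        assert np.abs(shared[:, outside[:, None, :].repeat(32, 1)]).max() == 0

    def test_grid_mismatch_raises(self, clean_phantom):
        plan = SamplingPlan(R=2.0, grid=(16, 8))
        with pytest.raises(ValueError, match="grid"):
            undersample_volume(clean_phantom.echo_series, plan)

    def test_aliasing_changes_images(self, knee_phantom):
        plan = SamplingPlan(R=4.0, grid=(32, 8), seed=0)
        out, _ = undersample_volume(knee_phantom.echo_series, plan)
        assert not np.allclose(out.data, knee_phantom.echo_series.data)


def test_plan_validation():
    with pytest.raises(ValueError):
        SamplingPlan(R=0.5, grid=(64, 16))
    with pytest.raises(ValueError):
        SamplingPlan(R=2, grid=(64, 16), ellipse_area_fraction=1.2)
    with pytest.raises(ValueError):
        SamplingPlan(R=2, grid=(64, 16), central_square_area_fraction=0.8)
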