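"""Pixel-wise pipeline: binning, barycenter lifetime maps, f_D maps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flimfret import (
    FLIMStack,
    IRFSpec,
    TCSPCConfig,
    TwoSpeciesParams,
    block_bin_2x2,
    decay_origin,
    delta_irf,
    fraction_map,
    mean_lifetime,
    mean_lifetime_map,
    model_decay,
    simulate_flim_image,
    spatial_bin_2x2,
    donor_only_scene,
)

TAU_D = 2.65
TAU_F = 0.83


def _uniform_stack(config, irf, counts_per_pixel_channel, shape=(6, 6)):
    counts = np.full((*shape, config.n_channels), counts_per_pixel_channel, dtype=int)
    return FLIMStack(counts=counts, config=config, irf=irf)


class TestBinning:
    def test_constant_image_interior_quadruples(self, config, gauss_irf):
        stack = _uniform_stack(config, gauss_irf, 2)
        binned = spatial_bin_2x2(stack)
        assert np.all(binned.counts[:-1, :-1] == 8)  # 4 pixels x 2 counts
        # edge pixels sum only the available neighbors
        assert np.all(binned.counts[-1, :-1] == 4)
        assert binned.counts[-1, -1, 0] == 2

    def test_single_nonzero_pixel_spreads_to_neighborhood(self, config, gauss_irf):
        counts = np.zeros((5, 5, config.n_channels), dtype=int)
        counts[2, 2, 100] = 7
        binned = spatial_bin_2x2(FLIMStack(counts=counts, config=config, irf=gauss_irf))
        img = binned.photon_image()
        nz = np.argwhere(img > 0)
        assert set(map(tuple, nz)) == {(1, 1), (1, 2), (2, 1), (2, 2)}
        assert np.all(img[img > 0] == 7)

    def test_block_binning_conserves_photons(self, config, gauss_irf, rng):
        counts = rng.poisson(0.3, size=(8, 8, config.n_channels))
        stack = FLIMStack(counts=counts, config=config, irf=gauss_irf)
        binned = block_bin_2x2(stack)
        assert binned.counts.sum() == counts.sum()
        assert binned.shape == (4, 4)

    def test_one_pixel_wide_rejected(self, config, gauss_irf):
        counts = np.zeros((1, 5, config.n_channels), dtype=int)
        with pytest.raises(ValueError):
            spatial_bin_2x2(FLIMStack(counts=counts, config=config, irf=gauss_irf))


class TestDecayOrigin:
    def test_delta_irf_origin(self, config):
        assert decay_origin(np.zeros(config.n_channels), delta_irf(config, 17), config) == 17

    def test_gaussian_irf_origin_is_center_channel(self, config, gauss_irf):
        # 0.5 ns / 20 ps = channel 25
        assert decay_origin(np.zeros(config.n_channels), gauss_irf, config) == 25

    def test_noisy_stack_origin_near_irf_peak(self, config, gauss_irf):
        scene = donor_only_scene(image_shape=(12, 12), n_puncta=2, seed=4)
        for s in range(5):
            stack = simulate_flim_image(
                scene, TwoSpeciesParams(f_D=0.0), config, gauss_irf, seed=s
            )
            est = decay_origin(stack.counts.sum(axis=(0, 1)))
            assert abs(est - 25) <= 2


class TestMeanLifetime:
    def test_truncated_exponential_closed_form(self, config, delta0):
        """Noiseless tau=2.65 ns decay over the 24 ns window: barycenter
        equals tau - T e^{-T/tau} / (1 - e^{-T/tau}) with T = 24 ns."""
        m = model_decay(TwoSpeciesParams(f_D=0.0, total_intensity=1e4), config, delta0)
        T = config.analysis_channels * config.channel_width
        closed = TAU_D - T * math.exp(-T / TAU_D) / (1 - math.exp(-T / TAU_D))
        assert closed == pytest.approx(2.647, abs=5e-4)
        assert mean_lifetime(m, config, origin=0) == pytest.approx(closed, rel=0.005)

    def test_single_channel_gives_its_midpoint(self, config):
        decay = np.zeros(config.n_channels)
        decay[300] = 50
        assert mean_lifetime(decay, config, origin=0) == pytest.approx(
            300.5 * config.channel_width
        )

    def test_uniform_counts_give_half_window(self, config):
        decay = np.ones(config.n_channels)
        T = config.analysis_channels * config.channel_width
        assert mean_lifetime(decay, config, origin=0) == pytest.approx(
            T / 2, abs=config.channel_width
        )

    def test_map_masks_low_count_pixels(self, config, gauss_irf):
        counts = np.zeros((3, 3, config.n_channels), dtype=int)
        counts[0, 0, 30:40] = 100  # 1000 photons: valid
        counts[1, 1, 30] = 10  # 10 photons: below threshold
        lmap = mean_lifetime_map(
            FLIMStack(counts=counts, config=config, irf=gauss_irf), threshold=150
        )
        assert lmap.valid_mask[0, 0]
        assert not lmap.valid_mask[1, 1]
        assert math.isnan(lmap.tau_mean[1, 1])
        assert math.isnan(lmap.tau_mean[2, 2])  # all-zero pixel masked, no error

    def test_robust_at_100_photons(self, config, delta0):
        """Replicate scatter of <tau> at ~100 photons stays below 10%."""
        p = TwoSpeciesParams(f_D=0.0, total_intensity=100.0)
        expected = model_decay(p, config, delta0)
        rng = np.random.default_rng(31)
        taus = []
        for _ in range(300):
            taus.append(mean_lifetime(rng.poisson(expected), config, origin=0))
        taus = np.asarray(taus)
        assert np.std(taus) / np.mean(taus) < 0.10


class TestFractionMap:
    def _make_lmap(self, tau):
        from flimfret.maps import LifetimeMap

        tau = np.atleast_2d(np.asarray(tau, dtype=float))
        return LifetimeMap(
            tau_mean=tau,
            photon_count=np.full(tau.shape, 1000),
            valid_mask=np.isfinite(tau),
            origin_channel=0,
            threshold=150,
        )

    def test_boundary_values(self):
        lmap = self._make_lmap([[TAU_D, TAU_F]])
        for est in ("linear", "intensity-weighted-inversion"):
            fmap = fraction_map(lmap, TAU_D, TAU_F, estimator=est)
            assert fmap.f_D[0, 0] == pytest.approx(0.0, abs=1e-12)
            assert fmap.f_D[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_closed_forms(self):
        lmap = self._make_lmap([[2.52]])
        lin = fraction_map(lmap, TAU_D, TAU_F, estimator="linear").f_D[0, 0]
        inv = fraction_map(
            lmap, TAU_D, TAU_F, estimator="intensity-weighted-inversion"
        ).f_D[0, 0]
        assert lin == pytest.approx(0.0714, abs=5e-4)
        assert inv == pytest.approx(0.197, abs=5e-4)

    def test_out_of_range_clipped_and_flagged(self):
        lmap = self._make_lmap([[2.9, 0.5, 2.0]])
        fmap = fraction_map(lmap, TAU_D, TAU_F, estimator="linear")
        assert fmap.f_D[0, 0] == 0.0 and fmap.out_of_range[0, 0]
        assert fmap.f_D[0, 1] == 1.0 and fmap.out_of_range[0, 1]
        assert not fmap.out_of_range[0, 2]

    def test_invalid_pixels_carry_nan_not_zero(self):
        lmap = self._make_lmap([[2.0, np.nan]])
        fmap = fraction_map(lmap, TAU_D, TAU_F)
        assert math.isnan(fmap.f_D[0, 1])

    @given(
        tau_pair=st.tuples(
            st.floats(0.84, 2.64), st.floats(0.84, 2.64)
        ).filter(lambda t: abs(t[0] - t[1]) > 1e-6)
    )
    def test_estimators_strictly_decreasing_in_tau(self, tau_pair):
        lo, hi = sorted(tau_pair)
        lmap = self._make_lmap([[lo, hi]])
        for est in ("linear", "intensity-weighted-inversion"):
            f = fraction_map(lmap, TAU_D, TAU_F, estimator=est).f_D
            assert f[0, 0] > f[0, 1]

    def test_noiseless_truth_recovery_and_linear_deficit(self, config):
        """On noiseless stacks the inversion estimator recovers the truth
        f_D to < 0.01 absolute; the linear estimator underestimates
        interior f_D (its known bias for barycenter <tau>)."""
        irf = delta_irf(config, 0)
        f_values = [0.0, 0.1, 0.3, 0.5, 0.7, 0.9]
        n = len(f_values)
        counts = np.zeros((1, n, config.n_channels))
        for j, f in enumerate(f_values):
            counts[0, j] = model_decay(
                TwoSpeciesParams(f_D=f, total_intensity=5e4), config, irf
            )
        stack = FLIMStack(counts=counts, config=config, irf=irf)  # exact expectations
        lmap = mean_lifetime_map(stack, origin=0)
        inv = fraction_map(lmap, TAU_D, TAU_F, estimator="intensity-weighted-inversion")
        lin = fraction_map(lmap, TAU_D, TAU_F, estimator="linear")
        for j, f in enumerate(f_values):
            assert inv.f_D[0, j] == pytest.approx(f, abs=0.01)
            if 0.0 < f < 1.0:
                assert f - lin.f_D[0, j] >= 0.0
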