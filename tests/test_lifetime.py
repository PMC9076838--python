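"""Mean-arrival lifetime estimator: centroid arithmetic, bias law, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flimaggr as fa
from flimaggr.exceptions import (
    IncompatibleInputError,
    InvalidInputError,
    InvalidParameterError,
)

from conftest import BIN, REP


def _hist(counts, bin_width=0.5, rep_period=None):
    counts = np.asarray(counts, dtype=float)
    if rep_period is None:
        rep_period = counts.size * bin_width
    return fa.TCSPCHistogram(counts, bin_width, rep_period)


class TestIrfCentroid:
    def test_delta_at_origin_is_zero(self):
        counts = np.zeros(16)
        counts[0] = 10
        assert fa.irf_centroid(_hist(counts)) == 0.0

    def test_two_spike_mean(self):
        counts = np.zeros(8)
        counts[2] = 5
        counts[4] = 5
        assert fa.irf_centroid(_hist(counts, bin_width=0.5)) == pytest.approx(1.5)

    def test_empty_irf_rejected(self):
        with pytest.raises(InvalidInputError):
            fa.irf_centroid(_hist(np.zeros(8)))

    @given(shift=st.integers(min_value=0, max_value=10))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_shift_equivariance(self, shift):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 50, size=20).astype(float)
        base[0] += 1  # non-empty
        shifted = np.concatenate([np.zeros(shift), base])
        c0 = fa.irf_centroid(_hist(base, bin_width=0.5, rep_period=32.0))
        c1 = fa.irf_centroid(_hist(shifted, bin_width=0.5, rep_period=32.0))
        assert c1 == pytest.approx(c0 + shift * 0.5)


class TestMeanArrival:
    @pytest.mark.parametrize(
        "tau,expected",
        [
            (3.3, 3.3000),      # truncation correction < 2e-5 ns at T=50
            (7.6, 7.5304),      # tau - T e^{-T/tau}/(1 - e^{-T/tau})
        ],
    )
    def test_noiseless_monoexponential(self, tau, expected, delta_irf):
        decay = fa.expected_decay_histogram([(tau, 1.0)], REP, BIN, total=1e6)
        est = fa.mean_arrival_lifetime(decay, delta_irf)
        # binning quantises both centroids; agreement to within one channel
        assert est == pytest.approx(expected, abs=BIN)

    def test_equal_photon_mixture(self, delta_irf):
        decay = fa.expected_decay_histogram([(3.3, 0.5), (7.6, 0.5)], REP, BIN, total=1e6)
        est = fa.mean_arrival_lifetime(decay, delta_irf)
        assert est == pytest.approx((3.3000 + 7.5304) / 2, abs=BIN)

    def test_photon_list_oracle_equivalence(self, gaussian_irf):
        """Centroid subtraction equals the brute-force photon-list mean."""
        decay = fa.simulate_tcspc([(3.3, 1.0)], 20_000, REP, BIN, irf=(2.0, 0.2), seed=5)
        est = fa.mean_arrival_lifetime(decay, gaussian_irf)

        def photon_list_mean(hist):
            idx = np.repeat(np.arange(hist.n_bins), hist.counts.astype(int))
            return idx.mean() * hist.bin_width

        oracle = photon_list_mean(decay) - photon_list_mean(gaussian_irf)
        assert est == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("tau", [1.0, 3.3, 5.0, 7.6])
    def test_truncation_bias_law(self, tau, delta_irf):
        """Noiseless estimate follows tau − T e^{−T/tau}/(1 − e^{−T/tau})."""
        decay = fa.expected_decay_histogram([(tau, 1.0)], REP, BIN, total=1.0)
        est = fa.mean_arrival_lifetime(decay, delta_irf)
        assert est == pytest.approx(
            fa.truncated_exponential_mean(tau, REP), abs=BIN / 2
        )

    @pytest.mark.parametrize("tau", [1.0, 3.3, 5.0, 7.6])
    def test_truncation_correction_inverts_bias(self, tau, delta_irf):
        biased = fa.truncated_exponential_mean(tau, REP)
        assert fa.invert_truncation_bias(biased, REP) == pytest.approx(tau, rel=1e-9)

    def test_monotone_in_lifetime(self, delta_irf):
        taus = [1.0, 2.0, 3.3, 5.0, 7.6, 12.0]
        ests = [
            fa.mean_arrival_lifetime(
                fa.expected_decay_histogram([(t, 1.0)], REP, BIN), delta_irf
            )
            for t in taus
        ]
        assert np.all(np.diff(ests) > 0)

    def test_mixture_linearity(self, delta_irf):
        """Estimator on a fraction mixture = fraction-weighted single estimates."""
        f = 0.3
        single = [
            fa.mean_arrival_lifetime(
                fa.expected_decay_histogram([(t, 1.0)], REP, BIN), delta_irf
            )
            for t in (2.0, 6.0)
        ]
        mixed = fa.mean_arrival_lifetime(
            fa.expected_decay_histogram([(2.0, f), (6.0, 1 - f)], REP, BIN), delta_irf
        )
        assert mixed == pytest.approx(f * single[0] + (1 - f) * single[1], abs=1e-9)

    def test_mismatched_binning_rejected(self, delta_irf):
        decay = fa.expected_decay_histogram([(3.3, 1.0)], REP, 0.5)
        with pytest.raises(IncompatibleInputError):
            fa.mean_arrival_lifetime(decay, delta_irf)

    def test_zero_photons_rejected(self, delta_irf):
        empty = fa.TCSPCHistogram(np.zeros(int(REP / BIN)), BIN, REP)
        with pytest.raises(InvalidInputError):
            fa.mean_arrival_lifetime(empty, delta_irf)


class TestLifetimeImage:
    def test_uniform_scene_mode_near_native(self, gaussian_irf):
        """A uniform tau=3.3 field yields a unimodal distribution at 3.3 ns."""
        spec = fa.SceneSpec(
            image_size=(32, 32),
            cells=(fa.CellSpec((16.0, 16.0), (15.0, 15.0), 1),),
            native_tau_sd=0.0,
            puncta_per_cell=0,
            photons_per_pixel=500.0,
            seed=21,
        )
        stack, truth = fa.simulate_flim_scene(spec, REP, BIN)
        img = fa.lifetime_image(stack, gaussian_irf, min_photons=100)
        vals = img.tau[truth.cell_labels > 0]
        vals = vals[~np.isnan(vals)]
        h, edges = np.histogram(vals, bins=np.arange(2.0, 5.0, 0.05))
        mode = 0.5 * (edges[np.argmax(h)] + edges[np.argmax(h) + 1])
        assert abs(mode - 3.3) < 0.05

    def test_all_pixels_below_threshold_all_invalid(self, gaussian_irf):
        data = np.ones((4, 4, int(REP / BIN)), dtype=int)  # 200 photons total < 1000
        stack = fa.FLIMStack(data, BIN, REP, 0.1)
        img = fa.lifetime_image(stack, gaussian_irf, min_photons=10_000)
        assert not img.valid.any()

    def test_count_scaling_invariance(self, gaussian_irf):
        decay = fa.simulate_tcspc([(3.3, 1.0)], 5000, REP, BIN, irf=(2.0, 0.2), seed=3)
        data = np.stack([decay.counts, 2 * decay.counts]).reshape(2, 1, -1)
        stack = fa.FLIMStack(data.astype(int), BIN, REP, 0.1)
        img = fa.lifetime_image(stack, gaussian_irf, min_photons=1)
        assert img.tau[0, 0] == pytest.approx(img.tau[1, 0], abs=1e-12)

    def test_min_photons_must_be_positive(self, gaussian_irf):
        stack = fa.FLIMStack(np.ones((2, 2, int(REP / BIN)), dtype=int), BIN, REP, 0.1)
        with pytest.raises(InvalidParameterError):
            fa.lifetime_image(stack, gaussian_irf, min_photons=0)


class TestPixelStats:
    def _image(self, tau_field):
        tau = np.asarray(tau_field, dtype=float)
        return fa.LifetimeImage(tau, np.full(tau.shape, 1000.0), 100, REP)

    def test_single_region_all_native(self):
        img = self._image(np.full((4, 4), 3.3))
        stats = fa.pixel_lifetime_stats(img, np.ones((4, 4), int), np.arange(0, 10, 0.5))
        assert stats.mean_ns[0] == pytest.approx(3.3)
        # all mass in the bin containing 3.3 ns
        assert stats.histograms[0][6] == pytest.approx(1.0)

    def test_half_and_half_mean(self):
        field = np.full((4, 4), 3.3)
        field[:2] = 6.0
        img = self._image(field)
        stats = fa.pixel_lifetime_stats(img, np.ones((4, 4), int), np.arange(0, 10, 0.5))
        assert stats.mean_ns[0] == pytest.approx(4.65)

    def test_histograms_normalised_and_empty_region_flagged(self):
        field = np.full((4, 4), 3.3)
        field[2:] = np.nan
        img = self._image(field)
        mask = np.ones((4, 4), int)
        mask[2:] = 2   # region 2 has no valid pixels
        stats = fa.pixel_lifetime_stats(img, mask, np.arange(0, 10, 0.5))
        assert stats.histograms[0].sum() == pytest.approx(1.0)
        assert stats.empty[1] and np.isnan(stats.mean_ns[1])
        assert stats.histograms[1].sum() == 0.0
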