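"""Spectra, GP histograms, Gaussian model selection, object summaries."""

import numpy as np
import pytest

import sgp
from sgp.gp import ChannelPair, GPMap
from sgp.segmentation import CircleDetection

PAIR = ChannelPair(
    lambda_b_nm=440, lambda_r_nm=490, index_b=0, index_r=1, actual_b_nm=440, actual_r_nm=490
)


def _gpmap_from_values(values: np.ndarray, valid=None) -> GPMap:
    valid = np.ones(values.shape, dtype=bool) if valid is None else valid
    gp = np.where(valid, values, np.nan)
    return GPMap(gp=gp, valid=valid, channel_pair=PAIR)


class TestMeanSpectrum:
    def test_constant_stack_full_mask(self):
        stack = sgp.SpectralStack(
            np.full((8, 8, 5), 7.0), wavelengths=[400, 410, 420, 430, 440]
        )
        prof = sgp.mean_spectrum(stack, np.ones((8, 8), dtype=bool))
        np.testing.assert_allclose(prof.mean_intensity, 7.0)
        assert prof.n_pixels == 64

    def test_single_pixel_mask(self, rng):
        data = rng.random((6, 6, 4)) * 50
        stack = sgp.SpectralStack(data, wavelengths=[1, 2, 3, 4])
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 3] = True
        prof = sgp.mean_spectrum(stack, mask)
        np.testing.assert_array_equal(prof.mean_intensity, data[2, 3])

    def test_matches_naive_loop_oracle(self, rng):
        data = rng.random((10, 12, 6)) * 100
        stack = sgp.SpectralStack(data, wavelengths=np.arange(6.0) + 1)
        mask = rng.random((10, 12)) > 0.5
        prof = sgp.mean_spectrum(stack, mask)
        for c in range(6):
            acc, n = 0.0, 0
            for y in range(10):
                for x in range(12):
                    if mask[y, x]:
                        acc += data[y, x, c]
                        n += 1
            assert prof.mean_intensity[c] == pytest.approx(acc / n)

    def test_empty_mask_errors(self):
        stack = sgp.SpectralStack(np.ones((4, 4, 2)), wavelengths=[1, 2])
        with pytest.raises(ValueError, match="empty"):
            sgp.mean_spectrum(stack, np.zeros((4, 4), dtype=bool))


class TestGPHistogram:
    def test_all_zero_gp_single_bin(self):
        gm = _gpmap_from_values(np.zeros((20, 20)))
        centers, counts = sgp.gp_histogram(gm)
        assert counts.sum() == 400
        nz = np.nonzero(counts)[0]
        assert len(nz) == 1
        assert abs(centers[nz[0]]) < 1.0 / 201  # the bin containing 0

    def test_conservation_with_invalid_pixels(self, rng):
        vals = rng.uniform(-1, 1, (30, 30))
        valid = rng.random((30, 30)) > 0.3
        gm = _gpmap_from_values(vals, valid)
        _, counts = sgp.gp_histogram(gm)
        assert counts.sum() == valid.sum()

    def test_uniform_samples_binomial_bound(self, rng):
        n = 200_000
        vals = rng.uniform(-1, 1, n).reshape(400, 500)
        gm = _gpmap_from_values(vals)
        _, counts = sgp.gp_histogram(gm)
        p = 1.0 / 201
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 5 * sigma)

    def test_no_valid_pixels_errors(self):
        gm = _gpmap_from_values(np.zeros((5, 5)), np.zeros((5, 5), dtype=bool))
        with pytest.raises(ValueError, match="no valid"):
            sgp.gp_histogram(gm)


class TestGaussianFitting:
    def test_single_gaussian_recovery(self, rng):
        vals = rng.normal(0.30, 0.10, 100_000)
        fit = sgp.fit_gp_samples(np.clip(vals, -1, 1))
        assert fit.n_peaks == 1
        assert abs(fit.means[0] - 0.30) < 0.01
        assert abs(fit.sigmas[0] - 0.10) < 0.02

    def test_balanced_mixture_recovery(self, rng):
        vals = np.concatenate(
            [rng.normal(-0.40, 0.05, 50_000), rng.normal(0.40, 0.05, 50_000)]
        )
        fit = sgp.fit_gp_samples(vals)
        assert fit.n_peaks == 2
        assert abs(fit.means[0] + 0.40) < 0.02
        assert abs(fit.means[1] - 0.40) < 0.02
        assert np.all(fit.sigmas > 0)
        assert fit.means[0] < fit.means[1]  # ascending order contract

    def test_selected_model_has_lower_rmse(self, rng):
        vals = rng.normal(0.1, 0.15, 20_000)
        fit = sgp.fit_gp_samples(vals)
        if fit.n_peaks == 1:
            assert fit.rmse_1 <= fit.rmse_2
        elif fit.n_peaks == 2:
            assert fit.rmse_2 <= fit.rmse_1

    def test_degenerate_histogram_errors(self):
        centers = np.linspace(-1, 1, 201)
        counts = np.zeros(201)
        counts[100] = 500
        with pytest.raises(ValueError, match="nonzero bins"):
            sgp.fit_gp_distribution(centers, counts)

    def test_model_selection_rate_on_unimodal(self):
        """1-peak model chosen in >= 95% of seeded unimodal replicates."""
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            fit = sgp.fit_gp_samples(np.clip(r.normal(0.2, 0.1, 10_000), -1, 1))
            wins += fit.n_peaks == 1
        assert wins >= 0.95 * n_rep

    def test_mixture_mean_error_across_replicates(self):
        errs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            vals = np.concatenate(
                [r.normal(-0.40, 0.05, 5_000), r.normal(0.40, 0.05, 5_000)]
            )
            fit = sgp.fit_gp_samples(vals)
            assert fit.n_peaks == 2
            errs.append(abs(fit.means[0] + 0.4))
            errs.append(abs(fit.means[1] - 0.4))
        assert np.mean(errs) < 0.02


class TestSummarizeObject:
    def test_diameter_from_circle(self):
        gm = _gpmap_from_values(np.full((32, 32), 0.25))
        circle = CircleDetection(center_yx=(16, 16), radius_px=10.0, score=1.0)
        rec = sgp.summarize_object(
            gm, np.ones((32, 32), bool), circle=circle, pixel_size_um=0.5, fit=False
        )
        assert rec.diameter_um == pytest.approx(10.0)
        assert rec.radius_px == pytest.approx(10.0)

    def test_constant_gp_means(self):
        gm = _gpmap_from_values(np.full((16, 16), 0.25))
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        rec = sgp.summarize_object(
            gm, mask, membrane_mask=mask, pixel_size_um=2.0, fit=False
        )
        assert rec.mean_gp == pytest.approx(0.25)
        assert rec.membrane_mean_gp == pytest.approx(0.25)
        assert rec.area_px == 64
        assert rec.area_um2 == pytest.approx(64 * 4.0)

    def test_membrane_mean_exceeds_whole_for_ordered_membrane(self):
        vals = np.full((40, 40), -0.2)  # cytosol-like
        yy, xx = np.mgrid[:40, :40]
        ring = (np.hypot(yy - 20, xx - 20) <= 15) & (np.hypot(yy - 20, xx - 20) >= 12)
        vals[ring] = 0.4  # ordered membrane
        gm = _gpmap_from_values(vals)
        obj = np.hypot(yy - 20, xx - 20) <= 15
        rec = sgp.summarize_object(gm, obj, membrane_mask=ring, fit=False)
        assert rec.membrane_mean_gp > rec.mean_gp

    def test_no_valid_pixels_errors(self):
        gm = _gpmap_from_values(np.zeros((8, 8)), np.zeros((8, 8), bool))
        with pytest.raises(ValueError, match="no valid"):
            sgp.summarize_object(gm, np.ones((8, 8), bool))
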