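"""Error statistics, CoV/CNR/variability and denoising diagnostics."""

import numpy as np
import pandas as pd
import pytest

from cordqmri.evaluation import (IQR_TO_SD, cnr, cov, estimate_snr,
                                 pooled_relative_error, relative_error_stats,
                                 residual_diagnostics,
                                 scan_rescan_variability, sigma_trend_report)
from cordqmri.protocol import default_protocol


def _mask(shape=(4, 4, 2)):
    return np.ones(shape, dtype=bool)


class TestRelativeError:
    def test_exact_and_biased_inputs(self, rng):
        truth = rng.uniform(1, 2, size=(4, 4, 2, 5))
        mask = _mask()
        s = relative_error_stats(truth.copy(), truth, mask)
        assert s.median_eps == 0 and s.iqr_eps == 0
        s = relative_error_stats(1.10 * truth, truth, mask)
        assert np.isclose(s.median_eps, 10.0, rtol=1e-10)
        assert np.isclose(s.iqr_eps, 0.0, atol=1e-9)

    def test_gaussian_noise_closed_form(self, rng):
        # sigma/truth = 0.10 everywhere: IQR of eps = 1.349 * 10 = 13.49
        truth = np.full((10, 10, 10, 20), 2.0)
        noisy = truth + rng.normal(0, 0.2, size=truth.shape)
        s = relative_error_stats(noisy, truth, _mask((10, 10, 10)))
        assert np.isclose(s.iqr_eps, IQR_TO_SD * 10.0, rtol=0.02)
        assert abs(s.median_eps) < 0.1

    def test_row_selection_and_realization_pooling(self, rng):
        truth = np.full((2, 2, 1, 6), 1.0)
        d1 = truth * 1.2
        d2 = truth * 0.8
        eps = pooled_relative_error([d1, d2], truth, _mask((2, 2, 1)),
                                    rows=np.array([0, 1]))
        assert eps.size == 2 * 4 * 2
        assert set(np.round(eps, 9)) == {20.0, -20.0}

    def test_nonpositive_truth_rejected(self):
        truth = np.zeros((2, 2, 1, 3))
        with pytest.raises(ValueError):
            pooled_relative_error(truth, truth, _mask((2, 2, 1)))


class TestCov:
    def test_constant_map(self):
        assert cov(np.full((3, 3), 5.0), np.ones((3, 3), bool)) == 0.0

    def test_documented_quantile_rule(self):
        # {1..5}: linear-interpolation quartiles give IQR 2, median 3
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.isclose(cov(vals, np.ones(5, bool)), 100 * 2 / 3)

    def test_scale_invariance(self, rng):
        m = rng.uniform(1, 2, size=(6, 6))
        mask = np.ones((6, 6), bool)
        assert np.isclose(cov(m, mask), cov(7.3 * m, mask), rtol=1e-12)

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            cov(np.array([-1.0, 0.0, 1.0]), np.ones(3, bool))


class TestVariability:
    def test_identical_and_offset_maps(self, rng):
        m = rng.uniform(1, 2, size=(5, 5))
        mask = np.ones((5, 5), bool)
        assert scan_rescan_variability(m, m, mask) == 0.0
        assert np.isclose(scan_rescan_variability(m, m + 0.3, mask), 0.0,
                          atol=1e-9)

    def test_gaussian_closed_form(self, rng):
        mu, s = 10.0, 0.5
        m1 = mu + rng.normal(0, s, size=200_000)
        m2 = mu + rng.normal(0, s, size=200_000)
        got = scan_rescan_variability(m1, m2, np.ones(200_000, bool))
        expected = 100 * IQR_TO_SD * s * np.sqrt(2) / mu
        assert np.isclose(got, expected, rtol=0.02)


class TestCNR:
    def test_identical_distributions(self, rng):
        vals = rng.normal(5, 1, size=(10, 10))
        wm = np.zeros((10, 10), bool)
        gm = np.zeros((10, 10), bool)
        wm[:5] = True
        gm[:5] = True  # same voxels: identical distributions
        assert cnr(vals, wm, gm) == pytest.approx(0.0)

    def test_gaussian_closed_form(self, rng):
        vals = np.concatenate([rng.normal(1, 1, 300_000),
                               rng.normal(2, 1, 300_000)])
        wm = np.zeros(600_000, bool)
        gm = np.zeros(600_000, bool)
        wm[:300_000] = True
        gm[300_000:] = True
        assert np.isclose(cnr(vals, wm, gm), 1 / np.sqrt(2), rtol=0.02)

    def test_monotone_in_median_gap(self, rng):
        base = rng.normal(0, 1, 50_000)
        wm = np.zeros(100_000, bool)
        gm = ~wm
        wm[:50_000] = True
        gm = ~wm
        vals1 = np.concatenate([base + 1, base])
        vals2 = np.concatenate([base + 3, base])
        assert cnr(vals2, wm, gm) > cnr(vals1, wm, gm)


class TestEstimateSNR:
    def test_scaling_and_invariance(self, rng):
        protocol = default_protocol()
        data = rng.uniform(0.5, 1.0, size=(4, 4, 2, 131))
        mask = _mask()
        sigma_map = np.full((4, 4, 2), 0.05)
        snr = estimate_snr(data, protocol, sigma_map, mask)
        assert np.isclose(estimate_snr(data, protocol, 2 * sigma_map, mask),
                          snr / 2, rtol=1e-12)
        tampered = data.copy()
        tampered[..., 70:] *= 3.0  # non-DW rows are irrelevant
        assert estimate_snr(tampered, protocol, sigma_map, mask) == snr

    def test_zero_sigma_rejected(self):
        protocol = default_protocol()
        with pytest.raises(ValueError):
            estimate_snr(np.ones((2, 2, 1, 131)), protocol,
                         np.zeros((2, 2, 1)), np.ones((2, 2, 1), bool))


class TestResidualDiagnostics:
    def test_degenerate_equal_inputs(self, rng):
        noisy = rng.normal(size=(4, 4, 2, 10))
        diag = residual_diagnostics(noisy, noisy.copy(), 1.0, _mask())
        assert diag.mean == 0 and diag.sd == 0

    def test_gaussian_residuals_near_standard(self, rng):
        noisy = rng.normal(0, 2.0, size=(6, 6, 3, 40))
        denoised = np.zeros_like(noisy)
        diag = residual_diagnostics(noisy, denoised, 2.0, _mask((6, 6, 3)))
        assert abs(diag.mean) < 0.05
        assert 0.95 < diag.sd < 1.05
        assert abs(diag.skewness) < 0.1
        assert abs(diag.lag1_autocorr) < 0.05

    def test_flags_over_truncation(self, small_phantom, protocol):
        """Forcing rank-1 reconstruction leaves signal in the residuals."""
        from cordqmri import noise as noise_mod
        from cordqmri.forward import synthesize_dataset
        from cordqmri.mppca import mp_pca
        clean = synthesize_dataset(small_phantom, protocol)
        mask = small_phantom.fractions.cord_mask
        sigma = noise_mod.sigma_from_snr(small_phantom, protocol, 20,
                                         clean=clean)
        noisy = noise_mod.add_gaussian_noise(clean, sigma, seed=31)
        den = noisy.copy()
        for z in range(clean.shape[2]):
            idx = np.argwhere(mask[:, :, z])
            A = noisy[idx[:, 0], idx[:, 1], z].T
            res = mp_pca(A)
            U, s, Vt = np.linalg.svd(A, full_matrices=False)
            den[idx[:, 0], idx[:, 1], z] = ((U[:, :1] * s[:1]) @ Vt[:1]).T
        diag = residual_diagnostics(noisy, den, sigma, mask)
        assert diag.sd > 1.1 or abs(diag.skewness) > 0.1

    def test_zero_sigma_rejected(self, rng):
        noisy = rng.normal(size=(2, 2, 1, 4))
        with pytest.raises(ValueError):
            residual_diagnostics(noisy, noisy, 0.0, _mask((2, 2, 1)))


class TestSigmaTrendReport:
    def test_empty_run_list(self):
        table = sigma_trend_report([])
        assert isinstance(table, pd.DataFrame) and table.empty

    def test_sigma_agreement_and_spread(self, small_phantom, protocol):
        """On homoscedastic data DW-alone and joint noise estimates agree;
        the 7-measurement mTE estimate is the least stable."""
        from cordqmri import noise as noise_mod
        from cordqmri.forward import synthesize_dataset
        from cordqmri.mppca import denoise_slicewise
        clean = synthesize_dataset(small_phantom, protocol)
        mask = small_phantom.fractions.cord_mask
        sigma = noise_mod.sigma_from_snr(small_phantom, protocol, 15,
                                         clean=clean)
        runs = []
        for seed in range(41, 49):
            noisy = noise_mod.add_gaussian_noise(clean, sigma, seed=seed)
            runs.append(denoise_slicewise(noisy, mask, protocol, "individual"))
            runs.append(denoise_slicewise(noisy, mask, protocol, "joint_all"))
        table = sigma_trend_report(runs)
        med = table.groupby("block")["sigma_hat"].median()
        assert abs(med["DW"] / sigma - 1) < 0.10
        assert abs(med["all"] / sigma - 1) < 0.10
        spread = table.groupby("block")["sigma_hat"].std()
        assert spread["mTE"] > spread["DW"]
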