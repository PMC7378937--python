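"""MP-PCA estimator and slice-wise denoising strategies."""

import numpy as np
import pytest

from cordqmri import noise
from cordqmri.mppca import (DenoiseStrategy, SignalMatrix, denoise_slicewise,
                            mp_pca, snr_gain_estimate, sv_spectrum)


class TestSVSpectrum:
    def test_diagonal_matrix(self):
        A = np.zeros((3, 5))
        A[0, 0], A[1, 1], A[2, 2] = 3, 2, 1
        assert np.allclose(sv_spectrum(A), [9, 4, 1])

    def test_column_permutation_invariance(self, rng):
        A = rng.normal(size=(10, 20))
        perm = rng.permutation(20)
        assert np.allclose(sv_spectrum(A), sv_spectrum(A[:, perm]))

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(5):
            A = rng.normal(size=(10, 20))
            ev = np.sort(np.linalg.eigvalsh(A @ A.T))[::-1]
            assert np.allclose(sv_spectrum(A), ev, atol=1e-10)

    def test_zero_matrix(self):
        assert np.all(sv_spectrum(np.zeros((4, 6))) == 0)


class TestMPPCA:
    def test_sigma_recovery_on_pure_noise(self, rng):
        """Noise sd recovered within a few % and few components retained."""
        sigmas, Ps = [], []
        for _ in range(100):
            res = mp_pca(rng.normal(0, 1, size=(50, 500)))
            sigmas.append(res.sigma_hat)
            Ps.append(res.P)
        assert 0.95 <= np.median(sigmas) <= 1.05
        assert np.median(Ps) <= 3

    def test_protocol_shaped_sigma_recovery(self, rng):
        """131 x 44 matrices (more measurements than voxels per slice)."""
        sigmas = [mp_pca(rng.normal(0, 2.5, size=(131, 44))).sigma_hat
                  for _ in range(100)]
        assert abs(np.median(sigmas) / 2.5 - 1) < 0.10

    def test_rank_recovery_and_error_reduction(self, rng):
        hits, improved = 0, 0
        n_trials = 100
        for _ in range(n_trials):
            truth = (rng.normal(size=(50, 3)) @ rng.normal(size=(3, 500))) * 10
            noisy = truth + rng.normal(size=truth.shape)
            res = mp_pca(noisy)
            hits += res.P == 3
            rmse_den = np.sqrt(np.mean((res.denoised - truth) ** 2))
            rmse_noisy = np.sqrt(np.mean((noisy - truth) ** 2))
            improved += rmse_den < rmse_noisy
        assert hits >= 90  # occasional P=4 on borderline draws
        assert improved >= 95

    def test_noise_free_low_rank_matrix_preserved(self, rng):
        truth = rng.normal(size=(20, 2)) @ rng.normal(size=(2, 50))
        res = mp_pca(truth)
        assert np.allclose(res.denoised, truth, atol=1e-8)

    def test_denoised_rank_bounded_by_p(self, rng):
        noisy = (rng.normal(size=(30, 3)) @ rng.normal(size=(3, 200)) * 5
                 + rng.normal(size=(30, 200)))
        res = mp_pca(noisy)
        sv2 = sv_spectrum(res.denoised)
        if res.P < len(sv2):
            assert sv2[res.P] < 1e-10 * sv2[0]

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            mp_pca(np.full((5, 5), np.nan))
        with pytest.raises(ValueError):
            mp_pca(np.ones((1, 10)))


class TestStrategies:
    def test_strategy_blocks(self, protocol):
        assert len(DenoiseStrategy("individual").blocks(protocol)) == 4
        (label, rows), = DenoiseStrategy("joint_all").blocks(protocol)
        assert rows.size == 131
        (label, rows), = DenoiseStrategy("dwi+mte").blocks(protocol)
        assert rows.size == 68 + 7
        with pytest.raises(ValueError):
            DenoiseStrategy("bogus")


@pytest.fixture(scope="module")
def noisy_small(small_phantom, protocol):
    from cordqmri.forward import synthesize_dataset
    clean = synthesize_dataset(small_phantom, protocol)
    sigma = noise.sigma_from_snr(small_phantom, protocol, 15, clean=clean)
    noisy = noise.add_gaussian_noise(clean, sigma, seed=21)
    return small_phantom, clean, noisy


class TestSlicewiseDenoising:
    def test_joint_all_matrix_has_131_rows(self, noisy_small, protocol):
        ph, clean, noisy = noisy_small
        run = denoise_slicewise(noisy, ph.fractions.cord_mask, protocol,
                                "joint_all")
        assert (run.records["M"] == 131).all()
        assert run.records["N"].between(30, 55).all()

    def test_individual_isolates_modalities(self, noisy_small, protocol):
        """Perturbing qMT rows must not change the mTE output."""
        ph, clean, noisy = noisy_small
        mask = ph.fractions.cord_mask
        rows = protocol.modality_rows
        base = denoise_slicewise(noisy, mask, protocol, "individual")
        tampered = noisy.copy()
        tampered[..., rows["qMT"]] *= 1.7
        other = denoise_slicewise(tampered, mask, protocol, "individual")
        assert np.array_equal(base.denoised[..., rows["mTE"]],
                              other.denoised[..., rows["mTE"]])

    def test_partner_strategy_changes_mte_output(self, noisy_small, protocol):
        ph, clean, noisy = noisy_small
        mask = ph.fractions.cord_mask
        rows = protocol.modality_rows
        ind = denoise_slicewise(noisy, mask, protocol, "individual")
        dwi_mte = denoise_slicewise(noisy, mask, protocol, "dwi+mte")
        assert not np.allclose(ind.denoised[..., rows["mTE"]],
                               dwi_mte.denoised[..., rows["mTE"]])
        # rows outside the DW+mTE blocks pass through untouched
        assert np.array_equal(dwi_mte.denoised[..., rows["IR"]],
                              noisy[..., rows["IR"]])

    def test_joint_beats_individual_for_mte_precision(self, noisy_small,
                                                      protocol):
        """Low-redundancy mTE gains precision when denoised jointly."""
        from cordqmri.evaluation import pooled_relative_error
        ph, clean, noisy = noisy_small
        mask = ph.fractions.cord_mask
        rows = protocol.modality_rows["mTE"]
        ind = denoise_slicewise(noisy, mask, protocol, "individual")
        joint = denoise_slicewise(noisy, mask, protocol, "joint_all")
        iqr = {}
        for name, run in (("ind", ind), ("joint", joint)):
            eps = pooled_relative_error(run.denoised, clean, mask, rows)
            q1, q3 = np.percentile(eps, [25, 75])
            iqr[name] = q3 - q1
        assert iqr["joint"] < iqr["ind"]

    def test_sigma_map_broadcast_and_records(self, noisy_small, protocol):
        ph, clean, noisy = noisy_small
        mask = ph.fractions.cord_mask
        run = denoise_slicewise(noisy, mask, protocol, "joint_all")
        z = 1
        sig = run.sigma_maps["all"][:, :, z]
        assert np.unique(sig[mask[:, :, z]]).size == 1
        assert np.all(sig[~mask[:, :, z]] == 0)

    def test_sparse_slice_passes_through(self, protocol, rng):
        data = rng.normal(size=(8, 8, 1, 131)) + 5
        mask = np.zeros((8, 8, 1), dtype=bool)
        mask[4, 4, 0] = True  # single voxel: cannot form a matrix
        run = denoise_slicewise(data, mask, protocol, "joint_all")
        assert np.array_equal(run.denoised, data)
        assert len(run.records) == 0


class TestSNRGain:
    def test_values_and_monotonicity(self):
        assert snr_gain_estimate(131, 131) == 1.0
        assert snr_gain_estimate(131, 10) == pytest.approx(13.1)
        gains = [snr_gain_estimate(131, p) for p in range(1, 10)]
        assert all(a > b for a, b in zip(gains, gains[1:]))
        with pytest.raises(ValueError):
            snr_gain_estimate(131, 0)
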