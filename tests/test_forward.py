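"""Forward signal model: closed forms, lineshape and Bloch oracles."""

import numpy as np
import pytest

from cordqmri import bloch
from cordqmri.forward import (MTWeightingCache, diffusion_attenuation,
                              ir_factor, simulate_mt_weighting,
                              super_lorentzian, synthesize_dataset,
                              synthesize_tissue_signal, synthesize_voxel,
                              te_factor)
from cordqmri.phantom import build_phantom, generate_geometry
from cordqmri.protocol import (Measurement, PulseTrainSpec, QMT_FLIP_ANGLES,
                               QMT_OFFSETS, default_protocol)

WM = dict(rho=0.70, T1=1000.0, T2=70.0, T2F=70.0, AD=2.10, RD=0.40,
          k=2.3, T2B=12.0, BPF=0.14)


class TestClosedFormFactors:
    def test_diffusion_attenuation_axial_and_radial(self):
        z = (0.0, 0.0, 1.0)
        x = (1.0, 0.0, 0.0)
        assert diffusion_attenuation(0, z, 2.10, 0.40) == 1.0
        assert np.isclose(diffusion_attenuation(1000, z, 2.10, 0.40),
                          np.exp(-2.1), rtol=1e-12)
        assert np.isclose(diffusion_attenuation(1000, x, 2.10, 0.40),
                          np.exp(-0.4), rtol=1e-12)

    def test_diffusion_attenuation_errors(self):
        with pytest.raises(ValueError):
            diffusion_attenuation(-1, (0, 0, 1), 2.0, 0.4)
        with pytest.raises(ValueError):
            diffusion_attenuation(1000, (0, 0, 2), 2.0, 0.4)

    def test_ir_factor_null_point_and_limits(self):
        assert np.isclose(ir_factor(1000 * np.log(2), 1000), 0.0, atol=1e-12)
        assert np.isclose(ir_factor(1e9, 1000), 1.0)
        assert np.isclose(ir_factor(200, 1000),
                          abs(1 - 2 * np.exp(-0.2)), rtol=1e-12)
        with pytest.raises(ValueError):
            ir_factor(200, -1)

    def test_te_factor(self):
        assert te_factor(0, 70) == 1.0
        assert np.isclose(te_factor(70, 70), np.exp(-1), rtol=1e-12)
        with pytest.raises(ValueError):
            te_factor(10, 0)


class TestSuperLorentzian:
    def test_symmetry_and_positivity(self):
        for d in (1.0, 2.7, 14.13):
            g = super_lorentzian(d, 12.0)
            assert g > 0
            assert np.isclose(g, super_lorentzian(-d, 12.0), rtol=1e-12)

    def test_against_fine_grid_trapezoid_oracle(self):
        # independent brute-force quadrature at 1e6 points
        t2b_s = 12e-6
        delta_hz = 2700.0
        phi = np.linspace(0.0, np.pi / 2, 1_000_001)
        u = 3 * np.cos(phi) ** 2 - 1
        with np.errstate(divide="ignore"):
            integrand = (np.sin(phi) * np.sqrt(2 / np.pi) * t2b_s / np.abs(u)
                         * np.exp(-2 * (2 * np.pi * delta_hz * t2b_s / u) ** 2))
        integrand[~np.isfinite(integrand)] = 0.0
        oracle = np.trapezoid(integrand, phi)
        assert np.isclose(super_lorentzian(2.7, 12.0), oracle, rtol=1e-6)

    def test_invalid_t2b(self):
        with pytest.raises(ValueError):
            super_lorentzian(2.0, 0.0)


class TestMTWeighting:
    def test_zero_flip_angle_gives_unity(self):
        train = PulseTrainSpec(0.0, 0.0, 17.0)
        assert simulate_mt_weighting(train, WM) == 1.0

    def test_saturation_monotone_in_flip_angle(self):
        strong = PulseTrainSpec(1465.0, 1.01, 17.0)
        weak = PulseTrainSpec(426.0, 1.07, 17.0)
        assert (simulate_mt_weighting(strong, WM)
                < simulate_mt_weighting(weak, WM) < 1.0)

    def test_step_refinement_convergence(self):
        # halving the integration step changes w by < 1e-4 for all pairs
        trains = [PulseTrainSpec(th, df, 17.0)
                  for th, df in zip(QMT_FLIP_ANGLES, QMT_OFFSETS) if th > 0]
        params = {k: WM[k] for k in ("T1", "T2F", "k", "T2B", "BPF")}
        w1 = bloch.mt_weighting(trains, params)
        w2 = bloch.mt_weighting(trains, params,
                                n_segments=2 * bloch.DEFAULT_N_SEGMENTS)
        assert np.max(np.abs(w1 - w2)) < 1e-4

    def test_bpf_one_rejected(self):
        train = PulseTrainSpec(426.0, 1.07, 17.0)
        bad = dict(WM, BPF=1.0)
        with pytest.raises(ValueError):
            simulate_mt_weighting(train, bad)

    def test_csf_direct_saturation_near_unity(self):
        csf = dict(T1=4000.0, T2F=800.0, k=0.0, T2B=0.0, BPF=0.0)
        train = PulseTrainSpec(1465.0, 8.39, 17.0)
        w = bloch.mt_weighting([train], csf)[0, 0]
        assert 0.95 < w <= 1.0


class TestSignalSynthesis:
    def test_tissue_signal_closed_forms(self):
        mte = Measurement("mTE", te_ms=25.0)
        assert np.isclose(synthesize_tissue_signal(mte, WM),
                          0.70 * np.exp(-25 / 70), rtol=1e-12)
        b0 = Measurement("DW", te_ms=72.0, b_s_mm2=0.0)
        assert np.isclose(synthesize_tissue_signal(b0, WM),
                          0.70 * np.exp(-72 / 70), rtol=1e-12)
        null = Measurement("IR", te_ms=24.0, ti_ms=1000 * np.log(2))
        assert np.isclose(synthesize_tissue_signal(null, WM), 0.0, atol=1e-12)

    def test_voxel_mixing_linearity(self):
        m = Measurement("mTE", te_ms=40.0)
        gm = dict(WM, rho=0.80, T2=80.0, T2F=80.0)
        csf = dict(rho=1.0, T1=4000.0, T2=800.0, T2F=800.0, AD=3.0, RD=3.0,
                   k=0.0, T2B=0.0, BPF=0.0)
        pure = synthesize_voxel(m, (1, 0, 0), WM, gm, csf)
        assert pure.S_TOT == pure.S_WM
        mix = synthesize_voxel(m, (0.5, 0.5, 0), WM, gm, csf)
        assert np.isclose(mix.S_TOT, 0.5 * (mix.S_WM + mix.S_GM), rtol=1e-12)

    def test_bad_fractions_rejected(self):
        m = Measurement("mTE", te_ms=40.0)
        with pytest.raises(ValueError, match="sum to 1"):
            synthesize_voxel(m, (0.5, 0.2, 0.2), WM, WM, WM)

    def test_dataset_matches_per_voxel_oracle(self):
        """Vectorised synthesis equals a one-voxel-at-a-time reference loop."""
        phantom = build_phantom(generate_geometry(nslices=1, seed=3), seed=3)
        protocol = default_protocol()
        sub = [protocol[i] for i in (0, 10, 70, 75, 112, 120, 126, 130)]
        from cordqmri.protocol import Protocol
        small = Protocol(list(sub))
        data = synthesize_dataset(phantom, small)
        assert np.all(data >= 0)
        wm_lookup = {tuple(ix): phantom.wm_params[j]
                     for j, ix in enumerate(phantom.wm_index)}
        gm_lookup = {tuple(ix): phantom.gm_params[j]
                     for j, ix in enumerate(phantom.gm_index)}
        rng = np.random.default_rng(0)
        coords = np.argwhere(phantom.fractions.cord_mask)
        picks = coords[rng.choice(len(coords), size=5, replace=False)]
        vf = phantom.fractions
        for (x, y, z) in picks:
            for j, m in enumerate(small):
                expected = 0.0
                if vf.vWM[x, y, z] > 0:
                    expected += vf.vWM[x, y, z] * synthesize_tissue_signal(
                        m, wm_lookup[(x, y, z)])
                if vf.vGM[x, y, z] > 0:
                    expected += vf.vGM[x, y, z] * synthesize_tissue_signal(
                        m, gm_lookup[(x, y, z)])
                if vf.vCSF[x, y, z] > 0:
                    expected += vf.vCSF[x, y, z] * synthesize_tissue_signal(
                        m, phantom.csf_params)
                assert np.isclose(data[x, y, z, j], expected, rtol=1e-10)

    def test_mt_cache_reuse(self, tmp_path):
        phantom = build_phantom(generate_geometry(nslices=1, seed=3), seed=3)
        protocol = default_protocol()
        cache = MTWeightingCache(tmp_path / "mt.npz")
        a = synthesize_dataset(phantom, protocol, mt_cache=cache)
        cache.save()
        cache2 = MTWeightingCache(tmp_path / "mt.npz")
        b = synthesize_dataset(phantom, protocol, mt_cache=cache2)
        assert np.array_equal(a, b)
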