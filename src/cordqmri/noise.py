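"""Noise corruption and Rician floor mitigation.

The noise level sigma is referenced to the mean noise-free b=0 signal in
white matter: sigma = S_WM(b=0) / SNR. Gaussian corruption adds i.i.d.
N(0, sigma^2); Rician corruption takes the magnitude of a complex signal
with independent Gaussian noise on both channels. After denoising of
magnitude data, the residual Rician floor is mitigated with the
second-moment (method-of-moments) inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import Phantom
from .protocol import Protocol

__all__ = [
    "NoiseSpec",
    "sigma_from_snr",
    "add_gaussian_noise",
    "add_rician_noise",
    "add_noise",
    "floor_correct",
    "realization_seed",
]

NOISE_MODELS = ("gaussian", "rician")


@dataclass(frozen=True)
class NoiseSpec:
    """One cell of the noise study grid."""

    model: str
    snr: float
    sigma: float
    seed: int
    realization_index: int = 0

    def __post_init__(self) -> None:
        if self.model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def realization_seed(base_seed: int, snr: float, model: str,
                     realization_index: int) -> int:
    """Deterministic per-cell seed so any grid cell is independently
    reproducible."""
    ss = np.random.SeedSequence([int(base_seed), int(round(snr * 1000)),
                                 NOISE_MODELS.index(model),
                                 int(realization_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def sigma_from_snr(phantom: Phantom, protocol: Protocol, snr: float,
                   clean: np.ndarray | None = None,
                   wm_threshold: float = 0.99) -> float:
    """sigma = mean noise-free b=0 DW signal over near-pure WM voxels / SNR.

    ``clean`` may supply a pre-synthesized noise-free dataset aligned with
    ``protocol``; otherwise only the b=0 measurements are synthesized here.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    b0_rows = [i for i, m in enumerate(protocol)
               if m.modality == "DW" and m.b_s_mm2 == 0]
    if not b0_rows:
        raise ValueError("protocol has no b=0 DW measurements")
    wm_mask = phantom.pure_tissue_mask("WM", threshold=wm_threshold)
    if not np.any(wm_mask):
        raise ValueError("no voxels with near-pure white matter")
    if clean is not None:
        mean_b0 = float(clean[wm_mask][:, b0_rows].mean())
    else:
        from .forward import synthesize_tissue_signal
        # b=0 signal is rho*exp(-TE/T2) per voxel; evaluate on the WM draws
        in_mask = wm_mask[tuple(phantom.wm_index.T)]
        p = phantom.wm_params[in_mask]
        te = protocol[b0_rows[0]].te_ms
        vals = np.asarray(p.rho) * np.exp(-te / np.asarray(p.T2))
        mean_b0 = float(vals.mean())
    return mean_b0 / snr


def add_gaussian_noise(data: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """data + N(0, sigma^2), i.i.d. over voxels and measurements."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return data + rng.normal(0.0, sigma, size=data.shape) if sigma > 0 else data.copy()


def add_rician_noise(data: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Magnitude of (data + n1) + i n2 with n1, n2 ~ N(0, sigma^2)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if np.any(data < 0):
        raise ValueError("Rician corruption requires non-negative signals")
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=data.shape)
    n2 = rng.normal(0.0, sigma, size=data.shape)
    return np.sqrt((data + n1) ** 2 + n2 ** 2)


def add_noise(data: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    if spec.model == "gaussian":
        return add_gaussian_noise(data, spec.sigma, spec.seed)
    return add_rician_noise(data, spec.sigma, spec.seed)


def floor_correct(denoised_value: np.ndarray, sigma_hat: float | np.ndarray) -> np.ndarray:
    """Second-moment Rician floor inversion sqrt(max(m^2 - 2 sigma^2, 0))."""
    if np.any(np.asarray(sigma_hat) < 0):
        raise ValueError("sigma_hat must be >= 0")
    m = np.asarray(denoised_value, dtype=float)
    return np.sqrt(np.maximum(m ** 2 - 2.0 * np.asarray(sigma_hat) ** 2, 0.0))
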