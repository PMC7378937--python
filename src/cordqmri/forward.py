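"""Noise-free multi-contrast signal synthesis.

Each tissue's signal for a measurement with sequence parameters
(TE, TI, b, g, theta, offset) is the product

    S = rho * exp(-TE/T2) * |1 - 2 exp(-TI/T1)| * exp(-b g' D g) * w

with an axially symmetric diffusion tensor aligned with the cord axis
z = (0, 0, 1) and the MT weighting w from the two-pool Bloch simulation;
factors default to 1 when the corresponding mechanism is absent from the
measurement. The voxel signal is the volume-fraction-weighted sum of the
WM, GM and CSF signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from . import bloch
from .phantom import Phantom, TissueParams
from .protocol import Measurement, Protocol, PulseTrainSpec

__all__ = [
    "CORD_AXIS",
    "SignalComponents",
    "MTWeightingCache",
    "diffusion_attenuation",
    "ir_factor",
    "te_factor",
    "super_lorentzian",
    "simulate_mt_weighting",
    "synthesize_tissue_signal",
    "synthesize_voxel",
    "synthesize_dataset",
]

#: Cord longitudinal axis (slice-select direction).
CORD_AXIS = np.array([0.0, 0.0, 1.0])

# re-export: the lineshape is part of the forward model's public surface
super_lorentzian = bloch.super_lorentzian


def diffusion_attenuation(b: float, g, AD, RD):
    """Diffusion attenuation exp(-b g' [(AD-RD) zz' + RD I] g), in (0, 1].

    ``b`` in s/mm^2, diffusivities in um^2/ms (so b*D carries a 1e-3
    factor). ``g`` must be a unit vector when b > 0.
    """
    if np.any(np.asarray(b) < 0):
        raise ValueError("b-value must be >= 0")
    b = np.asarray(b, dtype=float)
    if np.all(b == 0):
        return np.ones_like(b * np.asarray(AD, dtype=float))
    g = np.asarray(g, dtype=float)
    if abs(np.linalg.norm(g) - 1.0) > 1e-6:
        raise ValueError("gradient direction must have unit norm when b > 0")
    gz2 = float(g @ CORD_AXIS) ** 2
    AD = np.asarray(AD, dtype=float)
    RD = np.asarray(RD, dtype=float)
    return np.exp(-1e-3 * b * (RD + (AD - RD) * gz2))


def ir_factor(TI, T1):
    """Magnitude inversion-recovery factor |1 - 2 exp(-TI/T1)|."""
    if np.any(np.asarray(T1) <= 0):
        raise ValueError("T1 must be strictly positive")
    return np.abs(1.0 - 2.0 * np.exp(-np.asarray(TI, dtype=float)
                                     / np.asarray(T1, dtype=float)))


def te_factor(TE, T2):
    """Echo-time decay exp(-TE/T2)."""
    if np.any(np.asarray(T2) <= 0):
        raise ValueError("T2 must be strictly positive")
    if np.any(np.asarray(TE) < 0):
        raise ValueError("TE must be >= 0")
    return np.exp(-np.asarray(TE, dtype=float) / np.asarray(T2, dtype=float))


def simulate_mt_weighting(train: PulseTrainSpec,
                          params: Mapping[str, float] | TissueParams,
                          n_segments: int = bloch.DEFAULT_N_SEGMENTS) -> float:
    """MT weighting w in (0, 1] for one pulse train and one parameter set."""
    p = _params_dict(params)
    if np.any(np.asarray(p["BPF"]) >= 1):
        raise ValueError("BPF must be < 1")
    w = bloch.mt_weighting([train], p, n_segments=n_segments)
    return float(w[0, 0])


def _params_dict(params) -> dict[str, np.ndarray]:
    if isinstance(params, TissueParams):
        return {"T1": params.T1, "T2F": params.T2F, "k": params.k,
                "T2B": params.T2B, "BPF": params.BPF,
                "rho": params.rho, "T2": params.T2,
                "AD": params.AD, "RD": params.RD}
    return {key: np.asarray(val, dtype=float) for key, val in dict(params).items()}


def synthesize_tissue_signal(m: Measurement, params,
                             n_segments: int = bloch.DEFAULT_N_SEGMENTS) -> float:
    """Noise-free signal of one tissue for one measurement."""
    p = _params_dict(params)
    s = float(p["rho"]) * float(te_factor(m.te_ms, p["T2"]))
    if m.ti_ms is not None:
        s *= float(ir_factor(m.ti_ms, p["T1"]))
    if m.b_s_mm2 > 0:
        s *= float(diffusion_attenuation(m.b_s_mm2, m.g, p["AD"], p["RD"]))
    if m.mt_train is not None and m.mt_train.flip_angle_deg > 0:
        s *= simulate_mt_weighting(m.mt_train, params, n_segments=n_segments)
    return s


@dataclass
class SignalComponents:
    """Per-tissue signals and their fraction-weighted sum for one measurement."""

    S_WM: float
    S_GM: float
    S_CSF: float
    S_TOT: float


def synthesize_voxel(m: Measurement, fractions, wm, gm, csf) -> SignalComponents:
    """Partial-volume voxel signal S_TOT = vWM S_WM + vGM S_GM + vCSF S_CSF."""
    vwm, vgm, vcsf = (float(f) for f in fractions)
    if abs(vwm + vgm + vcsf - 1.0) > 1e-6:
        raise ValueError("volume fractions must sum to 1")
    s_wm = synthesize_tissue_signal(m, wm)
    s_gm = synthesize_tissue_signal(m, gm)
    s_csf = synthesize_tissue_signal(m, csf)
    return SignalComponents(S_WM=s_wm, S_GM=s_gm, S_CSF=s_csf,
                            S_TOT=vwm * s_wm + vgm * s_gm + vcsf * s_csf)


class MTWeightingCache:
    """Keyed store of batched MT weightings, persistable as an .npz table.

    Bloch integration dominates synthesis cost; the cache lets repeated
    synthesis of the same phantom/protocol (e.g. across noise realizations
    or processes) reuse the weightings.
    """

    def __init__(self, path: Optional[str | Path] = None):
        self.path = Path(path) if path is not None else None
        self._store: dict[str, np.ndarray] = {}
        if self.path is not None and self.path.exists():
            with np.load(self.path) as fh:
                self._store = {key: fh[key] for key in fh.files}

    def get(self, key: str) -> Optional[np.ndarray]:
        return self._store.get(key)

    def put(self, key: str, value: np.ndarray) -> None:
        self._store[key] = value

    def save(self) -> None:
        if self.path is not None:
            np.savez_compressed(self.path, **self._store)


def _batch_tissue_signals(protocol: Protocol, params: dict[str, np.ndarray],
                          cache_key: Optional[str],
                          cache: Optional[MTWeightingCache],
                          n_segments: int) -> np.ndarray:
    """(n_voxels, n_measurements) noise-free signals for one tissue batch."""
    nvox = np.broadcast(*(np.atleast_1d(v) for v in params.values())).shape[0]
    nvox = max(np.atleast_1d(params["rho"]).shape[0], 1)
    nmeas = len(protocol)
    out = np.empty((nvox, nmeas))

    trains = [m.mt_train for m in protocol if m.mt_train is not None]
    w_all = None
    if trains:
        w_all = cache.get(cache_key) if (cache and cache_key) else None
        if w_all is None or w_all.shape != (nvox, len(trains)):
            w_all = bloch.mt_weighting(trains, params, n_segments=n_segments)
            if cache is not None and cache_key is not None:
                cache.put(cache_key, w_all)

    rho = np.atleast_1d(params["rho"])
    T1 = np.atleast_1d(params["T1"])
    T2 = np.atleast_1d(params["T2"])
    AD = np.atleast_1d(params["AD"])
    RD = np.atleast_1d(params["RD"])
    i_mt = 0
    for j, m in enumerate(protocol):
        s = rho * np.exp(-m.te_ms / T2)
        if m.ti_ms is not None:
            s = s * np.abs(1.0 - 2.0 * np.exp(-m.ti_ms / T1))
        if m.b_s_mm2 > 0:
            gz2 = m.g[2] ** 2
            s = s * np.exp(-1e-3 * m.b_s_mm2 * (RD + (AD - RD) * gz2))
        if m.mt_train is not None:
            s = s * w_all[:, i_mt]
            i_mt += 1
        out[:, j] = s
    return out


def synthesize_dataset(phantom: Phantom, protocol: Protocol,
                       n_segments: int = bloch.DEFAULT_N_SEGMENTS,
                       mt_cache: Optional[MTWeightingCache] = None,
                       zero_background: bool = False) -> np.ndarray:
    """Noise-free 4D image of shape grid_shape + (n_measurements,).

    Every voxel's signal mixes the per-voxel WM/GM draws and the shared CSF
    parameters by their volume fractions. With ``zero_background`` the
    pure-CSF far field outside a 2-voxel dilation of the cord is zeroed.
    """
    nmeas = len(protocol)
    shape = phantom.grid_shape

    def key(tissue: str) -> str:
        return f"{tissue}_seed{phantom.seed}_seg{n_segments}_m{nmeas}"

    csf = _batch_tissue_signals(protocol, _params_dict(phantom.csf_params),
                                key("csf"), mt_cache, n_segments)[0]
    data = np.broadcast_to(csf * 1.0, shape + (nmeas,)).copy()
    data *= phantom.fractions.vCSF[..., None]

    for tissue, index, params in (("wm", phantom.wm_index, phantom.wm_params),
                                  ("gm", phantom.gm_index, phantom.gm_params)):
        if len(index) == 0:
            continue
        sig = _batch_tissue_signals(protocol, _params_dict(params),
                                    key(tissue), mt_cache, n_segments)
        frac = (phantom.fractions.vWM if tissue == "wm"
                else phantom.fractions.vGM)[tuple(index.T)]
        data[tuple(index.T)] += frac[:, None] * sig

    if zero_background:
        from scipy.ndimage import binary_dilation
        keep = binary_dilation(phantom.fractions.cord_mask,
                               iterations=2)
        data[~keep] = 0.0
    return data
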