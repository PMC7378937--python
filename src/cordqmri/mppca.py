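"""Marchenko-Pastur PCA denoising of slice-wise signal matrices.

A noisy matrix of M measurements x N cord voxels is decomposed by SVD and
the smallest singular values — those whose distribution is consistent with
the Marchenko-Pastur law for pure noise — are nullified. The procedure
simultaneously yields a noise-level estimate sigma_hat and the number of
retained components P. Joint (multi-contrast) denoising concatenates the
measurement blocks of several modalities into one matrix, so modalities
with few measurements borrow redundancy from richer ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .protocol import MODALITIES, Protocol

__all__ = [
    "SignalMatrix",
    "DenoiseResult",
    "DenoiseStrategy",
    "STRATEGY_NAMES",
    "sv_spectrum",
    "mp_pca",
    "denoise_slicewise",
    "snr_gain_estimate",
]

logger = logging.getLogger(__name__)

STRATEGY_NAMES = ("individual", "joint_all", "dwi+mte", "dwi+ir", "dwi+qmt")
_PARTNER = {"dwi+mte": "mTE", "dwi+ir": "IR", "dwi+qmt": "qMT"}


@dataclass
class SignalMatrix:
    """Slice-wise unit of work: measurements along rows, voxels along columns.

    ``voxel_index`` holds the in-plane grid coordinates of each column, in
    the fixed lexicographic (first-axis-major) order over the slice mask,
    so results are reproducible bit-for-bit.
    """

    values: np.ndarray
    modality_of_row: Sequence[str]
    voxel_index: np.ndarray
    slice_id: int = 0


@dataclass
class DenoiseResult:
    """Output of one MP-PCA call."""

    denoised: np.ndarray
    sigma_hat: float
    P: int
    sv_squared: np.ndarray


@dataclass(frozen=True)
class DenoiseStrategy:
    """One of the three schemes: per-modality denoising, joint denoising of
    all modalities, or DW imaging concatenated with a single partner."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}; "
                             f"choose from {STRATEGY_NAMES}")

    @property
    def partner_modality(self) -> Optional[str]:
        return _PARTNER.get(self.name)

    def blocks(self, protocol: Protocol) -> list[tuple[str, np.ndarray]]:
        """(block label, protocol row indices) pairs to denoise jointly."""
        rows = protocol.modality_rows
        if self.name == "individual":
            return [(mod, rows[mod]) for mod in MODALITIES if mod in rows]
        if self.name == "joint_all":
            return [("all", np.arange(len(protocol)))]
        partner = self.partner_modality
        return [(f"DW+{partner}",
                 np.concatenate([rows["DW"], rows[partner]]))]


def sv_spectrum(A: np.ndarray | SignalMatrix) -> np.ndarray:
    """Squared singular values, descending."""
    values = A.values if isinstance(A, SignalMatrix) else np.asarray(A)
    s = np.linalg.svd(values, compute_uv=False)
    return np.sort(s ** 2)[::-1]


def mp_pca(A: np.ndarray | SignalMatrix) -> DenoiseResult:
    """Denoise one matrix by Marchenko-Pastur singular value truncation.

    Let lambda_1 >= ... >= lambda_R be the squared singular values divided
    by the larger matrix dimension. The retained component count P is the
    smallest p for which the MP-range noise estimate
    (lambda_{p+1} - lambda_R) / (4 sqrt((R - p)/N_large)) does not exceed
    the tail-mean estimate mean(lambda_{p+1..R}); sigma_hat^2 is the tail
    mean at that p. If no p qualifies the input is treated as noise-free
    and returned unchanged (P = R, sigma_hat = 0).
    """
    values = A.values if isinstance(A, SignalMatrix) else np.asarray(A, dtype=float)
    if values.ndim != 2 or min(values.shape) < 2:
        raise ValueError("need a 2D matrix with both dimensions >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite entries")
    M, N = values.shape
    R, n_large = min(M, N), max(M, N)
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    lam = s ** 2 / n_large  # descending

    P = None
    sigma2 = 0.0
    for p in range(R):
        tail = lam[p:]
        sigma2_mean = tail.mean()
        sigma2_range = (lam[p] - lam[-1]) / (4.0 * np.sqrt((R - p) / n_large))
        if sigma2_range <= sigma2_mean:
            P, sigma2 = p, sigma2_mean
            break
    if P is None:
        return DenoiseResult(denoised=values.copy(), sigma_hat=0.0, P=R,
                             sv_squared=s ** 2)
    denoised = (U[:, :P] * s[:P]) @ Vt[:P]
    return DenoiseResult(denoised=denoised, sigma_hat=float(np.sqrt(sigma2)),
                         P=P, sv_squared=s ** 2)


def snr_gain_estimate(M: int, P: int) -> float:
    """Rough SNR gain of truncating M measurements to P components: M/P."""
    if P < 1:
        raise ValueError("P must be >= 1")
    return M / P


@dataclass
class SlicewiseDenoiseResult:
    """Slice-by-slice denoising output for one strategy."""

    denoised: np.ndarray
    sigma_maps: dict[str, np.ndarray]
    p_maps: dict[str, np.ndarray]
    records: pd.DataFrame
    strategy: DenoiseStrategy


def denoise_slicewise(data: np.ndarray, cord_mask: np.ndarray,
                      protocol: Protocol,
                      strategy: DenoiseStrategy | str) -> SlicewiseDenoiseResult:
    """Denoise all cord voxels of each slice as one MP-PCA matrix.

    The rows entering each MP-PCA call are selected by the strategy (one
    modality at a time; all concatenated; or DW plus one partner); rows
    outside the strategy's blocks pass through untouched. Per-slice
    sigma_hat and P are broadcast over the slice's cord voxels in
    ``sigma_maps`` / ``p_maps`` (one map per block label).
    """
    if isinstance(strategy, str):
        strategy = DenoiseStrategy(strategy)
    if data.ndim != 4:
        raise ValueError("expected a 4D (x, y, slice, measurement) array")
    if data.shape[-1] != len(protocol):
        raise ValueError("4th dimension must match the protocol length")
    if cord_mask.shape != data.shape[:3]:
        raise ValueError("mask shape must match the image grid")

    blocks = strategy.blocks(protocol)
    denoised = data.copy()
    nz = data.shape[2]
    sigma_maps = {label: np.zeros(data.shape[:3]) for label, _ in blocks}
    p_maps = {label: np.zeros(data.shape[:3], dtype=int) for label, _ in blocks}
    rows_out = []

    for z in range(nz):
        mask_z = cord_mask[:, :, z]
        idx = np.argwhere(mask_z)  # fixed first-axis-major column order
        if len(idx) < 2:
            logger.warning("slice %d has %d cord voxels; passing through",
                           z, len(idx))
            continue
        cols = (idx[:, 0], idx[:, 1])
        for label, sel in blocks:
            matrix = data[cols[0], cols[1], z][:, sel].T  # M_block x N_vox
            res = mp_pca(matrix)
            block_out = res.denoised.T
            for j, row in enumerate(sel):
                denoised[cols[0], cols[1], z, row] = block_out[:, j]
            sigma_maps[label][cols[0], cols[1], z] = res.sigma_hat
            p_maps[label][cols[0], cols[1], z] = res.P
            rows_out.append(dict(slice=z, block=label, M=matrix.shape[0],
                                 N=matrix.shape[1], P=res.P,
                                 sigma_hat=res.sigma_hat))
    records = pd.DataFrame(rows_out,
                           columns=["slice", "block", "M", "N", "P", "sigma_hat"])
    return SlicewiseDenoiseResult(denoised=denoised, sigma_maps=sigma_maps,
                                  p_maps=p_maps, records=records,
                                  strategy=strategy)
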