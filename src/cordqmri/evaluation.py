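"""Study statistics: denoising error, map variability, contrast, diagnostics.

Accuracy and precision of denoising are summarised by the median and
interquartile range (IQR) of the percentage relative error between denoised
and noise-free signals, pooled over cord voxels, measurements and noise
realizations. Map quality uses robust statistics throughout: the
coefficient of variation CoV = 100% x IQR/median, the scan-rescan
variability 100% x IQR(m1 - m2)/median((m1 + m2)/2), and the WM/GM
contrast-to-noise ratio with IQR/1.349 as the robust spread estimate. All
quantiles use linear interpolation (the "type 7" rule), fixed
project-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .protocol import Protocol

__all__ = [
    "ErrorSummary",
    "relative_error_stats",
    "pooled_relative_error",
    "cov",
    "scan_rescan_variability",
    "cnr",
    "estimate_snr",
    "ResidualDiagnostics",
    "residual_diagnostics",
    "sigma_trend_report",
    "IQR_TO_SD",
]

#: IQR of a standard normal distribution; divides an IQR into a sd estimate.
IQR_TO_SD = 1.349


@dataclass
class ErrorSummary:
    """Pooled percentage-relative-error statistics for one study cell."""

    modality: str
    strategy: str
    noise_model: str
    snr: float
    median_eps: float
    iqr_eps: float
    n_realizations: int
    n_samples: int = 0


def pooled_relative_error(denoised, truth: np.ndarray, mask: np.ndarray,
                          rows: Optional[np.ndarray] = None) -> np.ndarray:
    """Percentage relative errors 100 (denoised - truth)/truth, pooled.

    ``denoised`` is one 4D array or a sequence of them (noise
    realizations); errors are pooled over mask voxels, the selected
    measurement rows and all realizations.
    """
    if isinstance(denoised, np.ndarray):
        denoised = [denoised]
    truth_sel = truth[mask]
    if rows is not None:
        truth_sel = truth_sel[:, rows]
    if np.any(truth_sel <= 0):
        raise ValueError("ground truth must be strictly positive in the mask")
    parts = []
    for d in denoised:
        d_sel = d[mask]
        if rows is not None:
            d_sel = d_sel[:, rows]
        parts.append((100.0 * (d_sel - truth_sel) / truth_sel).ravel())
    return np.concatenate(parts)


def relative_error_stats(denoised, truth: np.ndarray, mask: np.ndarray,
                         rows: Optional[np.ndarray] = None, *,
                         modality: str = "", strategy: str = "",
                         noise_model: str = "", snr: float = np.nan
                         ) -> ErrorSummary:
    """Median (accuracy) and IQR (precision) of the pooled error
    distribution."""
    n_real = 1 if isinstance(denoised, np.ndarray) else len(denoised)
    eps = pooled_relative_error(denoised, truth, mask, rows)
    q1, med, q3 = np.percentile(eps, [25, 50, 75])
    return ErrorSummary(modality=modality, strategy=strategy,
                        noise_model=noise_model, snr=snr,
                        median_eps=float(med), iqr_eps=float(q3 - q1),
                        n_realizations=n_real, n_samples=eps.size)


def _finite(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    return values[np.isfinite(values)]


def cov(map_values: np.ndarray, tissue_mask: np.ndarray) -> float:
    """Percentage coefficient of variation 100 x IQR / median."""
    vals = _finite(np.asarray(map_values)[tissue_mask])
    if vals.size == 0:
        raise ValueError("empty tissue mask")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    if med == 0:
        raise ValueError("zero median; CoV undefined")
    return float(100.0 * (q3 - q1) / med)


def scan_rescan_variability(m1: np.ndarray, m2: np.ndarray,
                            tissue_mask: np.ndarray) -> float:
    """100 x IQR(m1 - m2) / median((m1 + m2)/2) over the tissue mask."""
    a = np.asarray(m1, dtype=float)[tissue_mask]
    b = np.asarray(m2, dtype=float)[tissue_mask]
    ok = np.isfinite(a) & np.isfinite(b)
    if not np.any(ok):
        raise ValueError("empty tissue mask")
    diff = a[ok] - b[ok]
    med_avg = float(np.percentile((a[ok] + b[ok]) / 2.0, 50))
    if med_avg == 0:
        raise ValueError("zero median average; variability undefined")
    q1, q3 = np.percentile(diff, [25, 75])
    return float(100.0 * (q3 - q1) / med_avg)


def cnr(map_values: np.ndarray, wm_mask: np.ndarray, gm_mask: np.ndarray) -> float:
    """WM/GM contrast over the pooled robust spread:
    |median_WM - median_GM| / sqrt((IQR_WM/1.349)^2 + (IQR_GM/1.349)^2)."""
    wm = _finite(np.asarray(map_values)[wm_mask])
    gm = _finite(np.asarray(map_values)[gm_mask])
    if wm.size == 0 or gm.size == 0:
        raise ValueError("both tissue masks must be non-empty")
    q1w, mw, q3w = np.percentile(wm, [25, 50, 75])
    q1g, mg, q3g = np.percentile(gm, [25, 50, 75])
    spread = np.hypot((q3w - q1w) / IQR_TO_SD, (q3g - q1g) / IQR_TO_SD)
    if spread == 0:
        if mw == mg:
            return 0.0
        raise ValueError("zero spread with unequal medians; CNR undefined")
    return float(abs(mw - mg) / spread)


def estimate_snr(data: np.ndarray, protocol: Protocol, sigma_map: np.ndarray,
                 cord_mask: np.ndarray) -> float:
    """Mean cord SNR: mean b=0 image normalised by the noise-sd estimate.

    ``sigma_map`` should come from denoising the DW block alone, following
    the in-vivo workflow.
    """
    b0_rows = [i for i, m in enumerate(protocol)
               if m.modality == "DW" and m.b_s_mm2 == 0]
    if not b0_rows:
        raise ValueError("protocol has no b=0 DW measurements")
    mean_b0 = data[..., b0_rows].mean(axis=-1)
    sig = np.asarray(sigma_map, dtype=float)
    sel = cord_mask & (sig > 0)
    if not np.any(sel):
        raise ValueError("no cord voxels with a positive noise estimate")
    return float(np.mean(mean_b0[sel] / sig[sel]))


@dataclass
class ResidualDiagnostics:
    """Moments of normalised denoising residuals plus spatial correlation.

    For well-behaved denoising the residuals (noisy - denoised)/sigma_hat
    should be near-Gaussian: mean ~ 0, sd slightly below 1 (the removed
    components carry some noise), small skewness/excess kurtosis and low
    in-plane neighbour correlation.
    """

    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    lag1_autocorr: float
    n: int

    def flags(self, sd_band: tuple[float, float] = (0.8, 1.1),
              mean_tol: float = 0.05) -> dict[str, bool]:
        return {
            "mean_ok": abs(self.mean) < mean_tol,
            "sd_ok": sd_band[0] <= self.sd <= sd_band[1],
        }


def residual_diagnostics(noisy: np.ndarray, denoised: np.ndarray,
                         sigma_hat, mask: np.ndarray) -> ResidualDiagnostics:
    """Summary statistics of (noisy - denoised)/sigma_hat within the mask."""
    sig = np.asarray(sigma_hat, dtype=float)
    if np.all(sig == 0):
        raise ValueError("sigma_hat is zero; residuals undefined")
    r4d = (noisy - denoised) / np.where(sig == 0, np.nan, sig)[..., None] \
        if sig.ndim == 3 else (noisy - denoised) / sig
    r = r4d[mask].ravel()
    r = r[np.isfinite(r)]
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    z = (r - mean) / sd if sd > 0 else r * 0
    skew = float(np.mean(z ** 3))
    kurt = float(np.mean(z ** 4) - 3.0)

    # lag-1 in-plane neighbour correlation, pooled over both axes
    pairs_a, pairs_b = [], []
    for axis in (0, 1):
        m1 = mask & np.roll(mask, -1, axis=axis)
        m1[tuple(slice(-1, None) if ax == axis else slice(None)
                 for ax in range(3))] = False
        if np.any(m1):
            pairs_a.append(r4d[m1].ravel())
            pairs_b.append(np.roll(r4d, -1, axis=axis)[m1].ravel())
    if pairs_a:
        a = np.concatenate(pairs_a)
        b = np.concatenate(pairs_b)
        ok = np.isfinite(a) & np.isfinite(b)
        lag1 = float(np.corrcoef(a[ok], b[ok])[0, 1]) if ok.sum() > 2 else 0.0
    else:
        lag1 = 0.0
    return ResidualDiagnostics(mean=mean, sd=sd, skewness=skew,
                               excess_kurtosis=kurt, lag1_autocorr=lag1,
                               n=r.size)


def sigma_trend_report(runs: Sequence) -> pd.DataFrame:
    """Tabulate per-slice noise-sd estimates across denoising runs.

    ``runs`` are slice-wise denoising results; the table holds one row per
    (strategy, block, slice) with the estimated sigma and retained P, the
    raw material for checking that noise estimates from different modality
    subsets agree on homoscedastic data.
    """
    frames = []
    for run in runs:
        rec = run.records.copy()
        rec.insert(0, "strategy", run.strategy.name)
        frames.append(rec)
    if not frames:
        return pd.DataFrame(columns=["strategy", "slice", "block",
                                     "M", "N", "P", "sigma_hat"])
    return pd.concat(frames, ignore_index=True)
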