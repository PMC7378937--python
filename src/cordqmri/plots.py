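"""Optional figure rendering for study outputs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .protocol import MODALITIES  # noqa: E402

__all__ = ["plot_error_panels", "plot_sv_spectra"]


def plot_error_panels(error_stats: pd.DataFrame,
                      path: Optional[str | Path] = None,
                      noise_model: str = "gaussian"):
    """Accuracy (median) and precision (IQR) of the percentage relative
    error versus SNR, one column per modality, one line per strategy."""
    table = error_stats[error_stats["noise_model"] == noise_model]
    fig, axes = plt.subplots(2, len(MODALITIES), figsize=(14, 6),
                             sharex=True)
    for j, mod in enumerate(MODALITIES):
        sub = table[table["modality"] == mod]
        for strategy, grp in sub.groupby("strategy"):
            grp = grp.sort_values("snr")
            axes[0, j].plot(grp["snr"], grp["median_eps"], "o-",
                            label=strategy)
            axes[1, j].plot(grp["snr"], grp["iqr_eps"], "o-", label=strategy)
        axes[0, j].set_title(f"{mod} imaging")
        axes[1, j].set_xlabel("SNR")
    axes[0, 0].set_ylabel("error median [%]")
    axes[1, 0].set_ylabel("error IQR [%]")
    axes[0, -1].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_sv_spectra(sv_spectra: pd.DataFrame,
                    path: Optional[str | Path] = None):
    """Squared singular values (descending) of the noise-free, noisy and
    denoised matrices of the representative slice."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in sv_spectra.groupby("matrix"):
        grp = grp.sort_values("rank")
        positive = grp[grp["sv_squared"] > 0]
        ax.semilogy(positive["rank"], positive["sv_squared"], "o-",
                    label=label, markersize=3)
    ax.set_xlabel("component")
    ax.set_ylabel("squared singular value")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
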