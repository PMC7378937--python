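"""Shared Results container for the quantitative fitters."""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd


class FitResults:
    """Parametric maps from one model fit.

    ``maps`` holds one 3D array per metric (NaN outside the fitted mask);
    ``valid`` flags voxels whose fit succeeded. ``summary()`` tabulates
    median and IQR per metric, optionally within named tissue masks.
    """

    metric_names: tuple[str, ...] = ()

    def __init__(self, maps: Mapping[str, np.ndarray], valid: np.ndarray,
                 model=None):
        self.maps = dict(maps)
        self.valid = valid
        self.model = model

    def __getattr__(self, name: str):
        maps = self.__dict__.get("maps", {})
        if name in maps:
            return maps[name]
        raise AttributeError(name)

    def summary(self, tissue_masks: Optional[Mapping[str, np.ndarray]] = None
                ) -> pd.DataFrame:
        masks = dict(tissue_masks) if tissue_masks else {"all": self.valid}
        rows = []
        for metric, vol in self.maps.items():
            for tissue, mask in masks.items():
                vals = vol[mask & self.valid]
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    continue
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                rows.append(dict(metric=metric, tissue=tissue, n=vals.size,
                                 median=med, iqr=q3 - q1))
        return pd.DataFrame(rows, columns=["metric", "tissue", "n",
                                           "median", "iqr"])

    def __repr__(self) -> str:
        return (f"<{type(self).__name__}: metrics={list(self.maps)}, "
                f"n_valid={int(self.valid.sum())}>")
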