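"""Relaxometry: mono-exponential T2 and magnitude inversion-recovery T1.

Both are voxel-wise nonlinear least-squares fits. The IR fit uses the
magnitude signal model A |1 - 2 exp(-TI/T1)|, whose null point creates a
local minimum; a small multi-start around the zero-crossing TI guards
against it.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .base import FitResults

__all__ = ["MonoExpT2Model", "MonoExpT2Results", "fit_t2",
           "IRT1Model", "IRT1Results", "fit_t1_ir"]

T2_BOUNDS = (1.0, 3000.0)   # ms
T1_BOUNDS = (10.0, 10000.0)  # ms


class MonoExpT2Results(FitResults):
    """T2 [ms] and amplitude maps."""


class MonoExpT2Model:
    """Per-voxel fit of A exp(-TE/T2) to a multi-echo series."""

    def __init__(self, data: np.ndarray, tes: np.ndarray, mask: np.ndarray):
        tes = np.asarray(tes, dtype=float)
        if tes.size < 3:
            raise ValueError("need at least 3 echo times")
        if data.shape[-1] != tes.size:
            raise ValueError("data/TE length mismatch")
        self.data = np.asarray(data, dtype=float)
        self.tes = tes
        self.mask = np.asarray(mask, dtype=bool)

    def fit(self) -> MonoExpT2Results:
        tes = self.tes
        vox_signals = self.data[self.mask]
        n = len(vox_signals)
        t2 = np.full(n, np.nan)
        amp = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)
        for v in range(n):
            s = vox_signals[v]
            if np.all(s <= 0):
                continue
            # log-linear initialisation on the positive samples
            pos = s > 0
            slope, intercept = np.polyfit(tes[pos], np.log(s[pos]), 1)
            if slope >= 0:  # not a decaying signal: flag, don't fit
                continue
            t2_0 = float(np.clip(-1.0 / slope, *T2_BOUNDS))
            a_0 = float(np.exp(intercept))

            def resid(theta):
                return theta[0] * np.exp(-tes / theta[1]) - s

            sol = least_squares(resid, x0=[a_0, t2_0],
                                bounds=([0.0, T2_BOUNDS[0]],
                                        [np.inf, T2_BOUNDS[1]]))
            amp[v], t2[v] = sol.x
            valid[v] = sol.success
        return self._package(t2, amp, valid)

    def _package(self, t2, amp, valid_flat) -> MonoExpT2Results:
        shape = self.mask.shape
        maps = {}
        for name, vals in (("T2", t2), ("A", amp)):
            vol = np.full(shape, np.nan)
            vol[self.mask] = vals
            maps[name] = vol
        valid = np.zeros(shape, dtype=bool)
        valid[self.mask] = valid_flat
        return MonoExpT2Results(maps, valid, model=self)


class IRT1Results(FitResults):
    """T1 [ms] and amplitude maps."""


class IRT1Model:
    """Per-voxel magnitude IR fit A |1 - 2 exp(-TI/T1)| with multi-start."""

    #: multiplicative factors applied to the null-point T1 guess
    STARTS = (0.5, 1.0, 2.0)

    def __init__(self, data: np.ndarray, tis: np.ndarray, mask: np.ndarray):
        tis = np.asarray(tis, dtype=float)
        if tis.size < 3:
            raise ValueError("need at least 3 inversion times")
        if data.shape[-1] != tis.size:
            raise ValueError("data/TI length mismatch")
        self.data = np.asarray(data, dtype=float)
        self.tis = tis
        self.mask = np.asarray(mask, dtype=bool)

    def fit(self) -> IRT1Results:
        tis = self.tis
        vox_signals = self.data[self.mask]
        n = len(vox_signals)
        t1 = np.full(n, np.nan)
        amp = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)
        for v in range(n):
            s = vox_signals[v]
            if np.all(s == 0):
                continue
            # the signal minimum approximates the null point TI = T1 ln 2
            t1_null = tis[np.argmin(s)] / np.log(2.0)
            a_0 = float(s.max())
            best = None
            for factor in self.STARTS:
                t1_0 = float(np.clip(factor * t1_null, *T1_BOUNDS))

                def resid(theta):
                    return (theta[0] * np.abs(1.0 - 2.0 * np.exp(-tis / theta[1]))
                            - s)

                sol = least_squares(resid, x0=[a_0, t1_0],
                                    bounds=([0.0, T1_BOUNDS[0]],
                                            [np.inf, T1_BOUNDS[1]]))
                if best is None or sol.cost < best.cost:
                    best = sol
            amp[v], t1[v] = best.x
            valid[v] = best.success
        shape = self.mask.shape
        maps = {}
        for name, vals in (("T1", t1), ("A", amp)):
            vol = np.full(shape, np.nan)
            vol[self.mask] = vals
            maps[name] = vol
        valid_map = np.zeros(shape, dtype=bool)
        valid_map[self.mask] = valid
        return IRT1Results(maps, valid_map, model=self)


def fit_t2(mte: np.ndarray, tes: np.ndarray, mask: np.ndarray) -> MonoExpT2Results:
    return MonoExpT2Model(mte, tes, mask).fit()


def fit_t1_ir(ir: np.ndarray, tis: np.ndarray, mask: np.ndarray) -> IRT1Results:
    return IRT1Model(ir, tis, mask).fit()
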