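"""Two-pool quantitative magnetisation transfer fitting.

Each voxel's MT-weighted signals are normalised by the no-saturation
reference of the same repetition (same post-train delay), which cancels the
proton density and echo-time decay and leaves the MT weighting factor w.
The bound pool fraction BPF, exchange rate k and bound-pool T2B are then
recovered by bounded nonlinear least squares with the two-pool Bloch
simulator as forward model (coarse grid search followed by a batched
Levenberg-Marquardt refinement), holding T1 and T2F at the values fitted
from the IR and multi-echo data. Optional per-voxel B1 scale and B0 offset
maps correct the nominal flip angles and offset frequencies.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .. import bloch
from ..protocol import Protocol
from .base import FitResults

__all__ = ["QMTModel", "QMTResults", "fit_qmt"]

BPF_BOUNDS = (0.0, 0.5)
K_BOUNDS = (0.1, 10.0)    # 1/s
T2B_BOUNDS = (5.0, 20.0)  # us

_GRID_BPF = (0.05, 0.12, 0.25)
_GRID_K = (0.8, 2.0, 5.0)
_GRID_T2B = (7.0, 11.0, 16.0)


class QMTResults(FitResults):
    """BPF, k [1/s] and T2B [us] maps."""


class QMTModel:
    """Two-pool qMT fit over a voxel mask.

    ``data`` may cover the full protocol (qMT rows are extracted) or just
    the qMT block in protocol order. ``t1_map``/``t2_map`` supply the
    per-voxel relaxation times that the fit holds fixed (T2F = fitted T2).
    """

    def __init__(self, data: np.ndarray, protocol: Protocol,
                 t1_map: np.ndarray, t2_map: np.ndarray, mask: np.ndarray,
                 b1_scale_map: Optional[np.ndarray] = None,
                 b0_offset_map: Optional[np.ndarray] = None,
                 n_segments: int = 64):
        qmt_rows = protocol.modality_rows.get("qMT")
        if qmt_rows is None:
            raise ValueError("protocol has no qMT block")
        trains = [protocol[i].mt_train for i in qmt_rows]
        data = np.asarray(data, dtype=float)
        if data.shape[-1] == len(protocol):
            data = data[..., qmt_rows]
        elif data.shape[-1] != len(qmt_rows):
            raise ValueError("data does not match the protocol's qMT block")

        # group measurements by post-train delay; theta=0 is the reference
        ref_of_train: dict[float, int] = {}
        for j, train in enumerate(trains):
            if train.flip_angle_deg == 0:
                ref_of_train[train.post_train_delay_ms] = j
        if not ref_of_train:
            raise ValueError("qMT block lacks a theta=0 reference measurement")
        self._mt_cols, self._ref_cols, self._trains = [], [], []
        for j, train in enumerate(trains):
            if train.flip_angle_deg == 0:
                continue
            if train.post_train_delay_ms not in ref_of_train:
                raise ValueError("no theta=0 reference for delay "
                                 f"{train.post_train_delay_ms} ms")
            self._mt_cols.append(j)
            self._ref_cols.append(ref_of_train[train.post_train_delay_ms])
            self._trains.append(train)

        self.data = data
        self.mask = np.asarray(mask, dtype=bool)
        self.t1_map, self.t2_map = t1_map, t2_map
        self.b1_scale_map = b1_scale_map
        self.b0_offset_map = b0_offset_map
        self.n_segments = n_segments

    # -- forward model ----------------------------------------------------

    def _predict(self, bpf, k, t2b, t1, t2f, b1, b0) -> np.ndarray:
        params = {"T1": t1, "T2F": t2f, "k": k, "T2B": t2b, "BPF": bpf,
                  "b1_scale": b1, "b0_offset_khz": b0}
        return bloch.mt_weighting(self._trains, params,
                                  n_segments=self.n_segments)

    def fit(self, max_iter: int = 15, ftol: float = 1e-8) -> QMTResults:
        mask = self.mask
        ratios = (self.data[mask][:, self._mt_cols]
                  / np.maximum(self.data[mask][:, self._ref_cols], 1e-12))
        B = ratios.shape[0]
        t1 = np.asarray(self.t1_map, dtype=float)[mask]
        t2f = np.asarray(self.t2_map, dtype=float)[mask]
        b1 = (np.ones(B) if self.b1_scale_map is None
              else np.asarray(self.b1_scale_map, dtype=float)[mask])
        b0 = (np.zeros(B) if self.b0_offset_map is None
              else np.asarray(self.b0_offset_map, dtype=float)[mask])

        # coarse grid search
        best_cost = np.full(B, np.inf)
        theta = np.zeros((B, 3))
        for gb in _GRID_BPF:
            for gk in _GRID_K:
                for gt in _GRID_T2B:
                    pred = self._predict(np.full(B, gb), np.full(B, gk),
                                         np.full(B, gt), t1, t2f, b1, b0)
                    cost = np.sum((pred - ratios) ** 2, axis=1)
                    better = cost < best_cost
                    best_cost[better] = cost[better]
                    theta[better] = (gb, gk, gt)

        # batched projected Levenberg-Marquardt
        lo = np.array([BPF_BOUNDS[0], K_BOUNDS[0], T2B_BOUNDS[0]])
        hi = np.array([BPF_BOUNDS[1], K_BOUNDS[1], T2B_BOUNDS[1]])
        steps = np.array([1e-4, 1e-3, 1e-3])  # forward-difference steps
        lam = np.full(B, 1e-3)

        def eval_resid(th):
            pred = self._predict(th[:, 0], th[:, 1], th[:, 2], t1, t2f, b1, b0)
            return pred - ratios

        resid = eval_resid(theta)
        cost = np.sum(resid ** 2, axis=1)
        for _ in range(max_iter):
            J = np.empty((B, resid.shape[1], 3))
            for p in range(3):
                th_p = theta.copy()
                th_p[:, p] = np.minimum(th_p[:, p] + steps[p], hi[p])
                dp = th_p[:, p] - theta[:, p]
                J[:, :, p] = (eval_resid(th_p) - resid) / np.where(dp == 0, 1, dp)[:, None]
            JtJ = np.einsum("bmi,bmj->bij", J, J)
            Jtf = np.einsum("bmi,bm->bi", J, resid)
            A = JtJ + lam[:, None, None] * np.eye(3)
            try:
                delta = np.linalg.solve(A, -Jtf[..., None])[..., 0]
            except np.linalg.LinAlgError:
                A = A + 1e-10 * np.eye(3)
                delta = np.linalg.solve(A, -Jtf[..., None])[..., 0]
            trial = np.clip(theta + delta, lo, hi)
            resid_trial = eval_resid(trial)
            cost_trial = np.sum(resid_trial ** 2, axis=1)
            improved = cost_trial < cost
            theta[improved] = trial[improved]
            resid[improved] = resid_trial[improved]
            rel_drop = np.where(cost > 0, (cost - cost_trial) / np.maximum(cost, 1e-30), 0)
            cost = np.where(improved, cost_trial, cost)
            lam = np.where(improved, lam * 0.3, lam * 5.0)
            if np.all((rel_drop < ftol) | ~improved) and np.all(lam > 1e3):
                break

        shape = mask.shape
        maps = {}
        for name, vals in (("BPF", theta[:, 0]), ("k", theta[:, 1]),
                           ("T2B", theta[:, 2])):
            vol = np.full(shape, np.nan)
            vol[mask] = vals
            maps[name] = vol
        valid = np.zeros(shape, dtype=bool)
        valid[mask] = np.isfinite(cost)
        return QMTResults(maps, valid, model=self)


def fit_qmt(qmt: np.ndarray, protocol: Protocol, t1_map: np.ndarray,
            t2_map: np.ndarray, mask: np.ndarray,
            b1_scale_map: Optional[np.ndarray] = None,
            b0_offset_map: Optional[np.ndarray] = None) -> QMTResults:
    """Convenience wrapper: build a :class:`QMTModel` and fit it."""
    return QMTModel(qmt, protocol, t1_map, t2_map, mask,
                    b1_scale_map=b1_scale_map,
                    b0_offset_map=b0_offset_map).fit()
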