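"""Diffusion kurtosis imaging: weighted-least-squares tensor fit.

The log-signal representation

    ln S(b, g) = ln S0 - b g'Dg + (b^2/6) (MD^2) g:W:g

is linear in the 22 unknowns (ln S0, the 6 diffusion tensor elements, and
the 15 elements of U = MD^2 W), and is fitted by two-pass weighted least
squares on log-signals with weights equal to the squared predicted signals.
FA and MD derive from the diffusion tensor eigenvalues; MK is the mean of
the directional apparent kurtosis over the acquired diffusion directions,
clamped to a physically sensible range before averaging.
"""

from __future__ import annotations

import numpy as np

from .base import FitResults

__all__ = ["DKIModel", "DKIResults", "fit_dki"]

#: Clamp for directional apparent kurtosis before averaging into MK.
KURTOSIS_CLAMP = (-3.0 / 7.0, 10.0)

# quartic monomial exponents and multinomial multiplicities (15 W elements)
_W_EXP = [(4, 0, 0), (0, 4, 0), (0, 0, 4),
          (3, 1, 0), (3, 0, 1), (1, 3, 0), (0, 3, 1), (1, 0, 3), (0, 1, 3),
          (2, 2, 0), (2, 0, 2), (0, 2, 2),
          (2, 1, 1), (1, 2, 1), (1, 1, 2)]
_W_MULT = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)

_D_EXP = [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
_D_MULT = np.array([1, 1, 1, 2, 2, 2], dtype=float)


def _design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """(n_meas, 22) design matrix; b scaled to ms/um^2."""
    b = bvals * 1e-3
    g = bvecs
    cols = [np.ones_like(b)]
    for (i, j, k), mult in zip(_D_EXP, _D_MULT):
        cols.append(-b * mult * g[:, 0] ** i * g[:, 1] ** j * g[:, 2] ** k)
    for (i, j, k), mult in zip(_W_EXP, _W_MULT):
        cols.append(b ** 2 / 6.0 * mult
                    * g[:, 0] ** i * g[:, 1] ** j * g[:, 2] ** k)
    return np.stack(cols, axis=1)


def _quadratic_form(coeffs: np.ndarray, g: np.ndarray) -> np.ndarray:
    """g'Dg for D packed as (dxx, dyy, dzz, dxy, dxz, dyz); batched."""
    out = 0.0
    for idx, ((i, j, k), mult) in enumerate(zip(_D_EXP, _D_MULT)):
        out = out + coeffs[..., idx, None] * mult * (
            g[:, 0] ** i * g[:, 1] ** j * g[:, 2] ** k)
    return out


def _quartic_form(coeffs: np.ndarray, g: np.ndarray) -> np.ndarray:
    out = 0.0
    for idx, ((i, j, k), mult) in enumerate(zip(_W_EXP, _W_MULT)):
        out = out + coeffs[..., idx, None] * mult * (
            g[:, 0] ** i * g[:, 1] ** j * g[:, 2] ** k)
    return out


class DKIResults(FitResults):
    """FA, MD [um^2/ms] and MK maps plus S0 and the raw tensor elements."""


class DKIModel:
    """WLS diffusion kurtosis fit over a voxel mask.

    Parameters
    ----------
    data : 4D array, last axis matching ``bvals``/``bvecs``.
    bvals : (n,) b-values [s/mm^2] spanning at least two nonzero shells.
    bvecs : (n, 3) unit gradient directions (rows at b=0 ignored).
    mask : 3D boolean array of voxels to fit.
    """

    def __init__(self, data: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray,
                 mask: np.ndarray):
        data = np.asarray(data, dtype=float)
        bvals = np.asarray(bvals, dtype=float)
        bvecs = np.asarray(bvecs, dtype=float)
        if data.shape[-1] != bvals.size:
            raise ValueError("data/bval length mismatch")
        if bvals.size < 22:
            raise ValueError("DKI needs at least 22 measurements")
        shells = np.unique(bvals[bvals > 0])
        if shells.size < 2:
            raise ValueError("DKI needs at least two nonzero shells")
        self.data, self.bvals, self.bvecs = data, bvals, bvecs
        self.mask = np.asarray(mask, dtype=bool)
        self._X = _design(bvals, bvecs)
        self._dirs = np.unique(np.round(bvecs[bvals > 0], 12), axis=0)

    def fit(self) -> DKIResults:
        X = self._X
        vox = np.argwhere(self.mask)
        S = self.data[self.mask]  # (V, n)
        S = np.maximum(S, 1e-12)
        y = np.log(S)
        # pass 1: OLS
        beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        beta = beta.T  # (V, 22)
        # pass 2: weights = squared predicted signals
        w = np.exp(X @ beta.T).T ** 2  # (V, n)
        XtWX = np.einsum("mi,vm,mj->vij", X, w, X)
        XtWy = np.einsum("mi,vm,vm->vi", X, w, y)
        valid_flat = np.ones(len(vox), dtype=bool)
        try:
            beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for v in range(len(vox)):
                try:
                    beta[v] = np.linalg.solve(XtWX[v], XtWy[v])
                except np.linalg.LinAlgError:
                    valid_flat[v] = False

        s0 = np.exp(beta[:, 0])
        d6 = beta[:, 1:7]
        u15 = beta[:, 7:22]

        # tensor eigen-metrics
        D = np.zeros((len(vox), 3, 3))
        D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = d6[:, 0], d6[:, 1], d6[:, 2]
        D[:, 0, 1] = D[:, 1, 0] = d6[:, 3]
        D[:, 0, 2] = D[:, 2, 0] = d6[:, 4]
        D[:, 1, 2] = D[:, 2, 1] = d6[:, 5]
        evals = np.linalg.eigvalsh(D)
        md = evals.mean(axis=1)
        num = ((evals - md[:, None]) ** 2).sum(axis=1)
        den = (evals ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5 * num / den)
        fa = np.clip(np.nan_to_num(fa), 0.0, 1.0)

        # directional apparent kurtosis, averaged over acquired directions
        g = self._dirs
        d_app = _quadratic_form(d6, g)
        u_app = _quartic_form(u15, g)
        with np.errstate(invalid="ignore", divide="ignore"):
            k_app = u_app / d_app ** 2
        k_app = np.clip(np.nan_to_num(k_app), *KURTOSIS_CLAMP)
        mk = k_app.mean(axis=1)

        valid_flat &= np.isfinite(md) & (md > 0)
        shape = self.mask.shape

        def scatter(vals):
            vol = np.full(shape, np.nan)
            vol[self.mask] = vals
            return vol

        valid = np.zeros(shape, dtype=bool)
        valid[self.mask] = valid_flat
        maps = {"FA": scatter(fa), "MD": scatter(md), "MK": scatter(mk),
                "S0": scatter(s0)}
        return DKIResults(maps, valid, model=self)


def fit_dki(dwi: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray,
            mask: np.ndarray) -> DKIResults:
    """Convenience wrapper: build a :class:`DKIModel` and fit it."""
    return DKIModel(dwi, bvals, bvecs, mask).fit()
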