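"""Synthetic spinal cord phantom.

A parametric stand-in for a template-derived cord: an elliptical cord
cross-section containing a butterfly-shaped grey-matter region, embedded in
CSF, rendered at low resolution (1 x 1 x 5 mm) with supersampled partial
volume. Per-voxel tissue parameters are drawn from tissue-specific Gaussian
distributions (sd = 10% of the mean) so that every tissue voxel carries a
unique noise-free signal profile; CSF parameters are fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TISSUE_PARAMS_MEAN",
    "TissueParams",
    "VolumeFractions",
    "Phantom",
    "generate_geometry",
    "sample_tissue_params",
    "build_phantom",
]

#: Tissue parameter means: relative proton density rho [-], T1 [ms], T2 [ms],
#: axial/radial diffusivity AD/RD [um^2/ms], free-to-bound exchange rate k
#: [1/s], bound-pool T2B [us], bound pool fraction BPF [-]. T2F is fixed
#: equal to T2. CSF has no bound pool (BPF = 0, k and T2B inert).
TISSUE_PARAMS_MEAN: dict[str, dict[str, float]] = {
    "WM": dict(rho=0.70, T1=1000.0, T2=70.0, AD=2.10, RD=0.40,
               k=2.3, T2B=12.0, BPF=0.14),
    "GM": dict(rho=0.80, T1=1200.0, T2=80.0, AD=1.60, RD=0.55,
               k=1.7, T2B=12.0, BPF=0.08),
    "CSF": dict(rho=1.00, T1=4000.0, T2=800.0, AD=3.00, RD=3.00,
                k=0.0, T2B=0.0, BPF=0.0),
}

#: Relative sd of the within-tissue Gaussians (WM/GM only).
RELATIVE_SD = 0.10

_PARAM_NAMES = ("rho", "T1", "T2", "AD", "RD", "k", "T2B", "BPF")


@dataclass
class TissueParams:
    """Tissue parameter set; fields may be scalars or aligned arrays of draws."""

    rho: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    AD: np.ndarray
    RD: np.ndarray
    k: np.ndarray
    T2B: np.ndarray
    BPF: np.ndarray

    @property
    def T2F(self) -> np.ndarray:
        """Free-pool T2, fixed equal to the macroscopic T2."""
        return self.T2

    def __len__(self) -> int:
        return int(np.size(self.rho))

    def __getitem__(self, idx) -> "TissueParams":
        return TissueParams(**{f.name: np.asarray(getattr(self, f.name))[idx]
                               for f in fields(self)})

    def validate(self) -> None:
        for name in ("rho", "T1", "T2", "AD", "RD"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(np.asarray(self.k) < 0) or np.any(np.asarray(self.BPF) < 0):
            raise ValueError("k and BPF must be >= 0")
        if np.any(np.asarray(self.BPF) >= 1):
            raise ValueError("BPF must be < 1")


@dataclass
class VolumeFractions:
    """Per-voxel WM/GM/CSF volume fractions on a regular grid.

    Fractions sum to one everywhere; the cord mask is exactly the set of
    voxels with any WM or GM content.
    """

    vWM: np.ndarray
    vGM: np.ndarray
    vCSF: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 5.0)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.vWM.shape)

    @property
    def cord_mask(self) -> np.ndarray:
        return (self.vWM + self.vGM) > 0

    def validate(self, tol: float = 1e-9) -> None:
        total = self.vWM + self.vGM + self.vCSF
        if np.max(np.abs(total - 1.0)) > tol:
            raise ValueError("volume fractions must sum to 1")
        for v in (self.vWM, self.vGM, self.vCSF):
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError("fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

# Cord cross-section semi-axes [mm] (left-right, anterior-posterior) and the
# grey-matter butterfly envelope, sized so one slice holds ~44 cord voxels
# (pure + partial-volume) at 1 x 1 mm in-plane resolution and a 40-slice
# volume holds ~1700.
_CORD_SEMI_AXES = (3.65, 2.60)
_GM_RADIUS_SCALE = 0.72
_GM_SHAPE_MIN = 0.30
_SLICE_RADIUS_MOD = 0.05  # sinusoidal radius modulation along the cord
_CENTER_JITTER_MM = 0.3


def _gm_radius(phi: np.ndarray) -> np.ndarray:
    """Normalised butterfly envelope: two lateral lobes joined centrally."""
    return _GM_RADIUS_SCALE * (_GM_SHAPE_MIN + (1 - _GM_SHAPE_MIN)
                               * np.abs(np.cos(phi)))


def generate_geometry(nx: int = 16, ny: int = 16, nslices: int = 40,
                      seed: int = 0,
                      voxel_size: tuple[float, float, float] = (1.0, 1.0, 5.0),
                      supersample: int = 8) -> VolumeFractions:
    """Render the parametric cord geometry with partial-volume fractions.

    Each voxel is supersampled ``supersample`` times per in-plane axis; the
    WM/GM/CSF fractions are sub-voxel occupancy counts. The cord radius and
    centre drift slightly from slice to slice (deterministic given seed) so
    slices are not identical copies.
    """
    if nx < 8 or ny < 8 or nslices < 1:
        raise ValueError("grid must have nx, ny >= 8 and nslices >= 1")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    jitter = rng.uniform(-_CENTER_JITTER_MM, _CENTER_JITTER_MM, size=(nslices, 2))

    dx, dy = voxel_size[0], voxel_size[1]
    # subvoxel centre offsets within one voxel, in mm
    sub = (np.arange(supersample) + 0.5) / supersample
    ox = (sub - 0.5) * dx
    oy = (sub - 0.5) * dy
    # voxel centres, cord centred in the FOV
    xc = (np.arange(nx) - (nx - 1) / 2.0) * dx
    yc = (np.arange(ny) - (ny - 1) / 2.0) * dy
    X = xc[:, None, None, None] + ox[None, None, :, None]
    Y = yc[None, :, None, None] + oy[None, None, None, :]

    a0, b0 = _CORD_SEMI_AXES
    vWM = np.zeros((nx, ny, nslices))
    vGM = np.zeros((nx, ny, nslices))
    for z in range(nslices):
        scale = 1.0 + _SLICE_RADIUS_MOD * np.sin(2 * np.pi * z / max(nslices, 2) + phase)
        cx, cy = jitter[z]
        u = (X - cx) / (a0 * scale)
        v = (Y - cy) / (b0 * scale)
        r = np.sqrt(u ** 2 + v ** 2)
        in_cord = r <= 1.0
        phi = np.arctan2(v, u)
        in_gm = in_cord & (r <= _gm_radius(phi))
        n_sub = supersample ** 2
        vGM[:, :, z] = in_gm.sum(axis=(2, 3)) / n_sub
        vWM[:, :, z] = (in_cord & ~in_gm).sum(axis=(2, 3)) / n_sub
    vCSF = 1.0 - vWM - vGM
    out = VolumeFractions(vWM=vWM, vGM=vGM, vCSF=vCSF, voxel_size=voxel_size)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def sample_tissue_params(tissue: str, n: int, seed: int) -> TissueParams:
    """Draw ``n`` parameter sets for one tissue.

    WM/GM parameters are drawn independently from Gaussian(mean, 0.1*mean);
    non-positive draws (vanishingly rare) are redrawn. CSF parameters are
    fixed, replicated ``n`` times.
    """
    if tissue not in TISSUE_PARAMS_MEAN:
        raise ValueError(f"unknown tissue {tissue!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    means = TISSUE_PARAMS_MEAN[tissue]
    if tissue == "CSF":
        return TissueParams(**{p: np.full(n, means[p]) for p in _PARAM_NAMES})
    rng = np.random.default_rng(seed)
    out = {}
    for p in _PARAM_NAMES:
        mu = means[p]
        draws = rng.normal(mu, RELATIVE_SD * mu, size=n)
        bad = draws <= 0
        while np.any(bad):  # keep draws physically valid
            draws[bad] = rng.normal(mu, RELATIVE_SD * mu, size=int(bad.sum()))
            bad = draws <= 0
        out[p] = draws
    params = TissueParams(**out)
    params.validate()
    return params


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    """Ground-truth phantom: geometry plus per-voxel tissue parameter draws.

    ``wm_index``/``gm_index`` list the grid coordinates of voxels with any
    WM (resp. GM) content, aligned with the rows of ``wm_params`` /
    ``gm_params``. CSF shares one fixed parameter set.
    """

    fractions: VolumeFractions
    wm_index: np.ndarray
    wm_params: TissueParams
    gm_index: np.ndarray
    gm_params: TissueParams
    csf_params: TissueParams
    seed: int

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.fractions.grid_shape

    def pure_tissue_mask(self, tissue: str, threshold: float = 0.99) -> np.ndarray:
        frac = {"WM": self.fractions.vWM, "GM": self.fractions.vGM,
                "CSF": self.fractions.vCSF}[tissue]
        return frac >= threshold

    # -- serialization (NIfTI maps + JSON sidecar) ------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag(list(self.fractions.voxel_size) + [1.0])
        frac4d = np.stack([self.fractions.vWM, self.fractions.vGM,
                           self.fractions.vCSF], axis=-1)
        nib.save(nib.Nifti1Image(frac4d.astype(np.float32), affine),
                 directory / "fractions.nii.gz")
        for tissue, index, params in (("wm", self.wm_index, self.wm_params),
                                      ("gm", self.gm_index, self.gm_params)):
            for p in _PARAM_NAMES:
                vol = np.full(self.grid_shape, np.nan, dtype=np.float64)
                vol[tuple(index.T)] = getattr(params, p)
                nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                         directory / f"{tissue}_{p}.nii.gz")
        sidecar = {
            "seed": self.seed,
            "voxel_size_mm": list(self.fractions.voxel_size),
            "tissue_params_mean": TISSUE_PARAMS_MEAN,
            "relative_sd": RELATIVE_SD,
            "csf_params": {p: float(np.asarray(getattr(self.csf_params, p)).flat[0])
                           for p in _PARAM_NAMES},
        }
        (directory / "phantom.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "Phantom":
        directory = Path(directory)
        sidecar = json.loads((directory / "phantom.json").read_text())
        frac4d = np.asarray(nib.load(directory / "fractions.nii.gz").dataobj,
                            dtype=np.float64)
        fractions = VolumeFractions(
            vWM=frac4d[..., 0], vGM=frac4d[..., 1], vCSF=frac4d[..., 2],
            voxel_size=tuple(sidecar["voxel_size_mm"]))
        # renormalise float32 round-off so the sum-to-one invariant holds
        total = fractions.vWM + fractions.vGM + fractions.vCSF
        fractions.vWM /= total
        fractions.vGM /= total
        fractions.vCSF /= total
        out = {}
        for tissue in ("wm", "gm"):
            vols = {p: np.asarray(nib.load(directory / f"{tissue}_{p}.nii.gz").dataobj,
                                  dtype=np.float64) for p in _PARAM_NAMES}
            mask = np.isfinite(vols["rho"])
            index = np.argwhere(mask)
            out[tissue] = (index,
                           TissueParams(**{p: vols[p][mask] for p in _PARAM_NAMES}))
        csf = TissueParams(**{p: np.asarray(sidecar["csf_params"][p])
                              for p in _PARAM_NAMES})
        return cls(fractions=fractions,
                   wm_index=out["wm"][0], wm_params=out["wm"][1],
                   gm_index=out["gm"][0], gm_params=out["gm"][1],
                   csf_params=csf, seed=int(sidecar["seed"]))


def build_phantom(fractions: VolumeFractions, seed: int = 0) -> Phantom:
    """Assign one WM draw to every voxel with vWM > 0 and one GM draw to
    every voxel with vGM > 0; CSF parameters are shared and fixed."""
    fractions.validate()
    wm_index = np.argwhere(fractions.vWM > 0)
    gm_index = np.argwhere(fractions.vGM > 0)
    wm_params = sample_tissue_params("WM", max(len(wm_index), 1), seed=seed)
    gm_params = sample_tissue_params("GM", max(len(gm_index), 1),
                                     seed=seed + 1)
    csf_params = sample_tissue_params("CSF", 1, seed=seed + 2)
    return Phantom(fractions=fractions,
                   wm_index=wm_index, wm_params=wm_params[: len(wm_index)],
                   gm_index=gm_index, gm_params=gm_params[: len(gm_index)],
                   csf_params=csf_params[0], seed=seed)
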