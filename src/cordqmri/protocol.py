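"""Unified multi-contrast acquisition protocol.

The default protocol bundles four spin-echo EPI contrasts sharing one
readout: diffusion-weighted (DW) imaging, off-resonance pulsed quantitative
magnetisation transfer (qMT), inversion recovery (IR) and multi-echo-time
(mTE) imaging — 131 measurements in total (68 DW + 44 qMT + 12 IR + 7 mTE).
This module is the single source of truth for which rows of a stacked
signal matrix belong to which modality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PulseTrainSpec",
    "Measurement",
    "Protocol",
    "default_protocol",
    "gradient_directions",
    "MODALITIES",
]

MODALITIES = ("DW", "qMT", "IR", "mTE")

#: qMT off-resonance pulse flip angles [deg] (first entry: no saturation).
QMT_FLIP_ANGLES = (0.0, 426.0, 433.0, 524.0, 1429.0, 1438.0,
                   1440.0, 1459.0, 1460.0, 1462.0, 1465.0)
#: Matching off-resonance offsets [kHz].
QMT_OFFSETS = (0.00, 1.07, 1.00, 2.70, 14.13, 3.78,
               13.60, 1.05, 1.01, 3.76, 8.39)
#: Per-repetition delay between end of the pulse train and readout [ms].
QMT_POST_TRAIN_DELAYS = (17.0, 95.0, 173.0, 251.0)

DW_TE = 72.0
QMT_TE = 24.0
IR_TE = 24.0
DW_SHELLS = (300.0, 1000.0, 2000.0, 2800.0)
DW_DIRS_PER_SHELL = (4, 10, 18, 28)
DW_N_B0 = 8
IR_TI_RANGE = (200.0, 2300.0)
IR_N_TI = 12
MTE_TES = (25.0, 40.0, 55.0, 70.0, 85.0, 100.0, 200.0)

_DEFAULT_DIRECTION_SEED = 20201117


@dataclass(frozen=True)
class PulseTrainSpec:
    """Off-resonance saturation train: 25 sinc-Gaussian pulses of 15 ms
    (122 Hz bandwidth) separated by 15 ms gaps, followed by a delay before
    the readout."""

    flip_angle_deg: float
    offset_khz: float
    post_train_delay_ms: float
    n_pulses: int = 25
    pulse_duration_ms: float = 15.0
    interpulse_delay_ms: float = 15.0
    bandwidth_hz: float = 122.0

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.pulse_duration_ms < 0 or self.interpulse_delay_ms < 0:
            raise ValueError("durations must be >= 0")
        if self.flip_angle_deg < 0:
            raise ValueError("flip angle must be >= 0")


@dataclass(frozen=True)
class Measurement:
    """One acquisition of the unified protocol.

    Only the fields relevant to the modality are set: DW carries (b, g),
    qMT an off-resonance pulse train, IR an inversion time; every
    measurement has an echo time.
    """

    modality: str
    te_ms: float
    ti_ms: Optional[float] = None
    b_s_mm2: float = 0.0
    g: Optional[tuple[float, float, float]] = None
    mt_train: Optional[PulseTrainSpec] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.te_ms <= 0:
            raise ValueError("TE must be > 0")
        if self.b_s_mm2 < 0:
            raise ValueError("b-value must be >= 0")
        if self.g is not None and self.b_s_mm2 > 0:
            norm = float(np.linalg.norm(self.g))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError("gradient direction must have unit norm")


@dataclass
class Protocol:
    """Ordered measurement list with per-modality row bookkeeping."""

    measurements: list[Measurement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def __getitem__(self, i):
        return self.measurements[i]

    @property
    def modality_rows(self) -> dict[str, np.ndarray]:
        """Row indices per modality, in acquisition order."""
        out: dict[str, np.ndarray] = {}
        for mod in MODALITIES:
            idx = [i for i, m in enumerate(self.measurements) if m.modality == mod]
            if idx:
                out[mod] = np.asarray(idx, dtype=int)
        return out

    # -- DW helpers -------------------------------------------------------

    def bvals(self) -> np.ndarray:
        """b-values [s/mm^2] of the DW block, in order."""
        return np.asarray([m.b_s_mm2 for m in self.measurements
                           if m.modality == "DW"], dtype=float)

    def bvecs(self) -> np.ndarray:
        """(n_dw, 3) gradient directions of the DW block; zero rows at b=0."""
        rows = []
        for m in self.measurements:
            if m.modality != "DW":
                continue
            rows.append(m.g if (m.g is not None and m.b_s_mm2 > 0) else (0.0, 0.0, 0.0))
        return np.asarray(rows, dtype=float)

    def ti_list(self) -> np.ndarray:
        return np.asarray([m.ti_ms for m in self.measurements
                           if m.modality == "IR"], dtype=float)

    def te_list(self, modality: str = "mTE") -> np.ndarray:
        return np.asarray([m.te_ms for m in self.measurements
                           if m.modality == modality], dtype=float)

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = []
        for m in self.measurements:
            d = asdict(m)
            payload.append(d)
        Path(path).write_text(json.dumps({"measurements": payload}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Protocol":
        raw = json.loads(Path(path).read_text())
        meas = []
        for d in raw["measurements"]:
            train = d.pop("mt_train", None)
            g = d.pop("g", None)
            meas.append(Measurement(
                **d,
                g=tuple(g) if g is not None else None,
                mt_train=PulseTrainSpec(**train) if train is not None else None,
            ))
        return cls(meas)

    def write_bval_bvec(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        """FSL dialect: one whitespace-separated row of b-values; bvecs as
        three rows (x, y, z components)."""
        bvals = self.bvals()
        bvecs = self.bvecs()
        Path(bval_path).write_text(" ".join(f"{b:g}" for b in bvals) + "\n")
        lines = [" ".join(f"{v:.6f}" for v in bvecs[:, ax]) for ax in range(3)]
        Path(bvec_path).write_text("\n".join(lines) + "\n")

    @staticmethod
    def read_bval_bvec(bval_path: str | Path, bvec_path: str | Path,
                       tol: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
        bvals = np.loadtxt(bval_path, ndmin=1, dtype=float)
        bvecs = np.loadtxt(bvec_path, ndmin=2, dtype=float)
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        elif bvecs.shape == (3, 3):
            pass  # ambiguous; FSL convention is rows-per-axis, so transpose
        if bvecs.shape[0] != bvals.size:
            raise ValueError("bval/bvec length mismatch")
        norms = np.linalg.norm(bvecs, axis=1)
        bad = (bvals > 0) & (np.abs(norms - 1.0) > tol)
        if np.any(bad):
            raise ValueError("non-unit bvec rows at nonzero b")
        return bvals, bvecs


def gradient_directions(n: int, seed: int = _DEFAULT_DIRECTION_SEED) -> np.ndarray:
    """Approximately uniform unit vectors by electrostatic repulsion.

    Antipodally-symmetric Coulomb energy is minimised from a seeded random
    start; deterministic given (n, seed). Returns an (n, 3) array with rows
    of unit norm (to 1e-12).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    v0 = rng.normal(size=(n, 3))
    v0 /= np.linalg.norm(v0, axis=1, keepdims=True)
    if n == 1:
        return v0

    iu = np.triu_indices(n, k=1)

    def energy(flat: np.ndarray) -> float:
        v = flat.reshape(n, 3)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        d = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=-1)[iu]
        da = np.linalg.norm(v[:, None, :] + v[None, :, :], axis=-1)[iu]
        eps = 1e-12
        return float(np.sum(1.0 / (d + eps) + 1.0 / (da + eps)))

    from scipy.optimize import minimize
    res = minimize(energy, v0.ravel(), method="L-BFGS-B",
                   options=dict(maxiter=2000, ftol=1e-14, gtol=1e-10))
    v = res.x.reshape(n, 3)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def default_protocol(direction_seed: int = _DEFAULT_DIRECTION_SEED) -> Protocol:
    """The 131-measurement unified simulation protocol.

    DW: TE 72 ms, 8 b=0 plus shells {300, 1000, 2000, 2800} s/mm^2 with
    {4, 10, 18, 28} directions. qMT: TE 24 ms, 4 repetitions of 11
    (flip angle, offset) pairs, each repetition with its own post-train
    delay. IR: TE 24 ms, 12 TIs linearly spaced in [200, 2300] ms.
    mTE: TEs {25, 40, 55, 70, 85, 100, 200} ms. TR is treated as infinite.
    """
    meas: list[Measurement] = []
    for _ in range(DW_N_B0):
        meas.append(Measurement("DW", te_ms=DW_TE, b_s_mm2=0.0))
    for shell, ndir in zip(DW_SHELLS, DW_DIRS_PER_SHELL):
        dirs = gradient_directions(ndir, seed=direction_seed + int(shell))
        for g in dirs:
            meas.append(Measurement("DW", te_ms=DW_TE, b_s_mm2=shell,
                                    g=tuple(float(x) for x in g)))
    for delay in QMT_POST_TRAIN_DELAYS:
        for theta, dfc in zip(QMT_FLIP_ANGLES, QMT_OFFSETS):
            train = PulseTrainSpec(flip_angle_deg=theta, offset_khz=dfc,
                                   post_train_delay_ms=delay)
            meas.append(Measurement("qMT", te_ms=QMT_TE, mt_train=train))
    for ti in np.linspace(IR_TI_RANGE[0], IR_TI_RANGE[1], IR_N_TI):
        meas.append(Measurement("IR", te_ms=IR_TE, ti_ms=float(ti)))
    for te in MTE_TES:
        meas.append(Measurement("mTE", te_ms=te))
    return Protocol(meas)
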