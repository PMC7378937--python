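# cordqmri

Multi-parametric quantitative MRI (qMRI) of the spinal cord with a
*unified readout* — diffusion-weighted (DW), quantitative magnetisation
transfer (qMT), inversion recovery (IR) and multi-echo (mTE) imaging
acquired with matched spatial encoding — makes every contrast share the
same resolution, distortions and thermal-noise statistics. That opens the
door to *joint multi-contrast denoising*: modalities with few measurements
(a 7-echo T2 series, a 12-point IR series) can be denoised together with
redundant ones (a 68-measurement DW scan) inside one Marchenko–Pastur PCA
(MP-PCA) matrix.

`cordqmri` is an in-silico laboratory for that idea, aimed at qMRI
methods researchers. It provides:

- a **synthetic spinal cord phantom** — an elliptical cord with a butterfly
  GM region in CSF, 1 × 1 × 5 mm voxels with supersampled partial-volume
  fractions, and per-voxel tissue parameters drawn from per-tissue
  Gaussians (sd = 10% of mean), ≈1700 cord voxels over 40 slices;
- a **forward signal model** for a 131-measurement unified protocol
  (68 DW + 44 qMT + 12 IR + 7 mTE),

  S = ρ e^(−TE/T2) |1−2e^(−TI/T1)| e^(−b gᵀ[(AD−RD)zzᵀ+RD·I]g) · w(θ,Δfc),

  where the MT weighting *w* comes from direct numerical integration of the
  two-pool Bloch equations with a super-Lorentzian bound-pool lineshape
  over 25-pulse sinc-Gaussian saturation trains;
- **Gaussian/Rician corruption** at an SNR referenced to the WM b=0 signal,
  and the method-of-moments Rician floor correction;
- **slice-wise MP-PCA denoising**: singular values consistent with a
  Marchenko–Pastur noise bulk are nullified, yielding the denoised matrix,
  a noise estimate σ̂ and the retained component count P, under five
  strategies (per-modality, all-modalities joint, DW + one partner);
- **model fitting** in a statsmodels-like Model → `fit()` → Results shape:
  DKI (FA, MD, MK), mono-exponential T2, magnitude IR T1, and two-pool qMT
  (BPF, k, T2B) with the Bloch simulator as forward model;
- **study statistics**: relative-error accuracy/precision, CoV, scan-rescan
  variability, WM/GM CNR, residual and σ̂ diagnostics, and a reproducible
  (SNR × noise model × realization) study runner with checkpointing.

## Worked example

```python
import numpy as np
from cordqmri import (default_protocol, generate_geometry, build_phantom,
                      synthesize_dataset, denoise_slicewise, noise)
from cordqmri.evaluation import relative_error_stats

protocol = default_protocol()                      # 131 measurements
phantom = build_phantom(generate_geometry(seed=1), seed=1)
clean = synthesize_dataset(phantom, protocol)      # (16, 16, 40, 131)
mask = phantom.fractions.cord_mask
print(f"{int(mask.sum())} cord voxels")

sigma = noise.sigma_from_snr(phantom, protocol, snr=10, clean=clean)
noisy = noise.add_gaussian_noise(clean, sigma, seed=42)

rows = protocol.modality_rows["mTE"]
for name in ("individual", "joint_all"):
    run = denoise_slicewise(noisy, mask, protocol, name)
    s = relative_error_stats(run.denoised, clean, mask, rows)
    print(f"{name:11s} mTE error median {s.median_eps:+.2f}%  "
          f"IQR {s.iqr_eps:.2f}%")
```

prints

```
1676 cord voxels
individual  mTE error median +0.06%  IQR 4.19%
joint_all   mTE error median -0.02%  IQR 3.38%
```

The mTE series is short (7 echoes), so denoised alone it keeps limited
precision; concatenating it with the other 124 measurements of the unified
protocol lets MP-PCA separate signal from noise better — the error IQR
(precision) drops, while the median (accuracy) stays at zero. A
command-line interface wraps the same steps
(`cordqmri simulate|corrupt|denoise|fit|evaluate|study`; see
`cordqmri --help`).

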