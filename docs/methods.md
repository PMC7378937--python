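# Methods

`cordqmri` simulates a unified-readout multi-parametric quantitative MRI
(qMRI) experiment of the cervical spinal cord entirely in silico, applies
Marchenko–Pastur principal component analysis (MP-PCA) denoising under
single- and multi-contrast strategies, fits the four standard quantitative
models, and quantifies accuracy, precision, variability and contrast. This
note records the models, the numerical choices, and what the synthetic
study does and does not demonstrate.

## Synthetic spinal cord phantom

**Geometry.** The phantom is a parametric stand-in for a template-derived
cord: an elliptical cord cross-section (semi-axes 3.65 × 2.60 mm) containing
a butterfly-shaped grey-matter (GM) region, embedded in cerebrospinal fluid
(CSF), rendered on a 16 × 16 × 40 grid of 1 × 1 × 5 mm voxels (200 mm
foot–head coverage). Each voxel is supersampled 8× per in-plane axis, so
boundary voxels carry realistic partial-volume fractions vWM + vGM + vCSF = 1.
The cord radius and centre drift slightly from slice to slice (5% sinusoidal
modulation plus ±0.3 mm seeded jitter) so slices are not identical. The
defaults yield ≈42 cord voxels per slice and ≈1700 cord voxels in total —
the matrix sizes the slice-wise denoiser actually sees. The GM butterfly is
sized to leave enough near-pure voxels of both tissues (≈220 WM, ≈150 GM at
95% purity) for tissue-wise map statistics.

**Tissue parameters.** Every voxel with any WM content receives its own WM
parameter draw, and likewise for GM, from per-tissue Gaussians with sd equal
to 10% of the mean (WM: ρ=0.70, T1=1000 ms, T2=70 ms, AD=2.10, RD=0.40
μm²/ms, k=2.3 s⁻¹, T2B=12 μs, BPF=0.14; GM: ρ=0.80, T1=1200 ms, T2=80 ms,
AD=1.60, RD=0.55 μm²/ms, k=1.7 s⁻¹, T2B=12 μs, BPF=0.08). T2F is fixed equal
to T2. CSF parameters are fixed across voxels (ρ=1, T1=4000 ms, T2=800 ms,
AD=RD=3.0 μm²/ms, no bound pool). Non-positive draws (probability ~10⁻²³
per draw) are redrawn, which leaves the distribution unchanged to any
measurable degree. Unique per-voxel draws matter: identical columns in the
signal matrix would overstate what MP-PCA can remove.

## Signal model

For a measurement with echo time TE, inversion time TI, diffusion weighting
(b, g) and off-resonance saturation (θ, Δfc), each tissue contributes

    S = ρ · e^(−TE/T2) · |1 − 2 e^(−TI/T1)| · e^(−b gᵀ[(AD−RD)zzᵀ + RD·I]g)
        · w(θ, Δfc; T1, T2F, k, T2B, BPF)

with the diffusion tensor axially symmetric about the cord axis z = (0,0,1),
and the voxel signal is the volume-fraction-weighted sum of the WM, GM and
CSF contributions. Each factor defaults to 1 when its mechanism is absent.
TR is treated as infinite (TR ≫ T1). b is in s/mm² and diffusivities in
μm²/ms, so the exponent carries a 10⁻³ factor.

**Default protocol (131 measurements).** DW: TE 72 ms, 8 b=0 plus shells
{300, 1000, 2000, 2800} s/mm² with {4, 10, 18, 28} directions; qMT: TE 24
ms, 4 repetitions of 11 (θ, Δfc) pairs, repetitions distinguished by
post-train delays {17, 95, 173, 251} ms, the θ=0 entry serving as the
no-saturation reference; IR: TE 24 ms, 12 TIs linearly spaced in [200,
2300] ms; mTE: TEs {25, 40, 55, 70, 85, 100, 200} ms. Gradient direction
sets are generated by minimising an antipodally symmetric Coulomb energy on
the sphere (L-BFGS from a seeded start, fixed seed per shell), since no
published table is part of the protocol definition.

**Two-pool MT weighting.** w is obtained by direct numerical integration of
the coupled two-pool system over the 25-pulse train. The free pool evolves
under full 3D Bloch dynamics (off-resonance precession during pulses,
relaxation, exchange); the bound pool carries only longitudinal
magnetisation, saturated at rate W(t) = π ω₁(t)² G(Δfc) with a
super-Lorentzian absorption lineshape G — the standard treatment when
T2B (~μs) is far below the pulse duration (15 ms), so bound-pool transverse
coherence is never appreciable. Exchange uses kf = k (free→bound) and
kb = k·(1−BPF)/BPF, which satisfies detailed balance with pool sizes
(1−BPF, BPF); at BPF = 0 the pools decouple and only direct (free-pool)
saturation remains, giving w ≈ 1 at the offsets used — this is how CSF is
handled. The bound-pool T1 is not identifiable from these data and is fixed
at the conventional 1 s.

Numerics: each sinc-Gaussian pulse (122 Hz bandwidth, Gaussian window with
FWHM equal to the 15 ms pulse duration, amplitude scaled so the on-resonance
flip integral equals θ) is discretised into 96 piecewise-constant segments;
within a segment the system is linear time-invariant and is propagated
exactly by a batched 5×5 matrix exponential. Doubling the segment count
changes w by < 1e−4 for every (θ, Δfc) pair of the default protocol at WM
parameters, which is the convergence criterion that fixed the default.
Pulse propagators are reused across the 25 pulses and across the four
repetition delays, and whole-phantom weightings are cached (optionally on
disk), so synthesis of the full phantom takes ~1 minute and repeated noise
realizations are essentially free.

**Super-Lorentzian lineshape.** G(Δ, T2B) = T2B·F(Δ·T2B) is evaluated by
adaptive quadrature of the scaled integrand (singular point at the magic
angle handled by the quadrature); batched evaluations use a log-log cubic
spline of F accurate to ~1e−8. Below |Δ| = 1 kHz, where the on-resonance
singularity looms, G is cubically extrapolated from values at 1–2.5 kHz;
all protocol offsets with θ > 0 are ≥ 1 kHz, so this path only matters for
fitting with B0 offsets.

## Noise model

σ is referenced to the modality with the lowest baseline signal level:
σ = (mean noise-free b=0 DW signal over voxels with vWM ≥ 0.99)/SNR.
Gaussian corruption adds i.i.d. N(0, σ²); Rician corruption takes
√((S+n₁)² + n₂²). After denoising magnitude (Rician) data, the residual
noise floor is mitigated voxel-wise by the second-moment method-of-moments
inversion Ŝ = √(max(m² − 2σ̂², 0)) with the per-slice MP-PCA σ̂ — the
simplest moments-based correction; the study grid stores a deterministic
seed per (SNR, model, realization) cell so any cell reproduces in
isolation.

## MP-PCA denoising

All cord voxels of one slice form one matrix (measurements × voxels;
columns in fixed first-axis-major mask order, so runs are bit-reproducible).
Let λ₁ ≥ … ≥ λ_R be the squared singular values divided by the larger
matrix dimension, R the smaller. The retained component count P is the
smallest p for which the range-based noise estimate
(λ_{p+1} − λ_R)/(4√((R−p)/N_large)) does not exceed the tail mean of
λ_{p+1..R} — i.e. the smallest tail consistent with a Marchenko–Pastur
bulk; σ̂² is that tail mean, and components beyond P are nullified. No mean
centering is applied. If no p qualifies, the matrix is returned unchanged
with σ̂ = 0 (noise-free input). On pure-noise matrices of the study shape
(131 × 44) the estimator recovers σ within ~1% in median with P ≤ 1–3.

Three strategies mirror the study design: *individual* (each modality's
block denoised separately), *joint_all* (all 131 rows as one matrix), and
*dwi+{mte,ir,qmt}* (the DW block concatenated with one partner; other rows
pass through). The rough SNR gain is reported as M/P, following the
description the study uses (the random-matrix literature often quotes
√(M/P); the operation returns the former).

## Quantitative fitting

All fitters follow a Model → fit() → Results pattern; Results carry the
parametric maps, a validity flag and a `summary()` table.

- **DKI** (diffusion kurtosis): two-pass weighted least squares on
  log-signals in the 22-parameter linearisation (ln S0, 6 tensor elements,
  15 elements of U = MD²·W), weights equal to squared predicted signals.
  MD and FA come from the tensor eigenvalues; MK is the mean directional
  apparent kurtosis K(g) = g:U:g / (gᵀDg)² over the protocol's 60 unique
  directions, clamped to [−3/7, 10] before averaging. The directional mean
  (rather than analytic integration) is adequate here because MK serves
  variability analysis, not absolute benchmarking.
- **Mono-exponential T2**: per-voxel nonlinear least squares of
  A·e^(−TE/T2), initialised from a log-linear fit, T2 bounded to (1, 3000]
  ms; voxels whose log-signal slope is non-negative are flagged invalid.
- **IR T1**: magnitude model A·|1 − 2e^(−TI/T1)|, T1 bounded to
  (10, 10000] ms. The signal minimum estimates the null point TI ≈ T1·ln 2;
  three starts (0.5×, 1×, 2× that guess) guard against the null-point local
  minimum.
- **Two-pool qMT**: MT-weighted signals are normalised by the θ=0 reference
  of the same repetition, which cancels ρ·e^(−TE/T2) and leaves w. (BPF, k,
  T2B) are then fitted per voxel with the same Bloch simulator as forward
  model, holding T1 and T2F at the IR/mTE-fitted values: a 3×3×3 coarse
  grid (BPF {0.05, 0.12, 0.25} × k {0.8, 2, 5} s⁻¹ × T2B {7, 11, 16} μs)
  followed by a batched projected Levenberg–Marquardt refinement with
  bounds BPF ∈ [0, 0.5], k ∈ [0.1, 10] s⁻¹, T2B ∈ [5, 20] μs; the fitter
  uses 64 Bloch segments per pulse (|Δw| ~1e−4 versus the synthesis
  default, negligible against the fit tolerances). Optional per-voxel B1
  scale and B0 offset maps correct nominal θ and Δfc; in simulation they
  default to ideal. Noise-free self-recovery is better than 0.1% for all
  three parameters.

## Study statistics

Percentage relative error ε = 100·(denoised − truth)/truth is pooled over
cord voxels × measurements of a modality × realizations (default; a
per-realization aggregation is available behind a flag). Median ε measures
accuracy, IQR(ε) precision. Map quality uses CoV = 100·IQR/median,
scan-rescan variability = 100·IQR(m₁−m₂)/median((m₁+m₂)/2), and WM/GM
CNR = |median_WM − median_GM| / √((IQR_WM/1.349)² + (IQR_GM/1.349)²),
1.349 being the IQR of a standard normal. All quantiles use linear
interpolation ("type 7"); IQR-based statistics are convention-sensitive, so
this is fixed project-wide. Denoising diagnostics: normalised residuals
(noisy − denoised)/σ̂ should be near-Gaussian with sd slightly below 1, and
the σ̂ trend table compares per-slice noise estimates across modality
subsets (the 7-measurement mTE estimate is expectedly the least stable).

## What the synthetic study shows — and what it does not

The phantom reproduces the statistical structure that matters for MP-PCA —
mixed pure/partial-volume voxels, per-voxel parameter diversity, ~44-voxel
slice matrices, a squared-singular-value spectrum spanning > 10⁸ — and the
pipeline reproduces the central qualitative findings: joint multi-contrast
denoising improves the precision of low-redundancy modalities (mTE, IR)
while leaving their accuracy unchanged, noise estimates from different
modality subsets agree on homoscedastic data, and denoised residuals are
noise-like.

Quantitatively, the parametric geometry yields slice matrices whose signal
spectrum is somewhat lower-rank than a template-derived phantom's: MP-PCA
retains fewer components (P ≈ 3–5 at SNR 10) and therefore removes *more*
noise in single-modality denoising than a template-derived phantom would
allow (mTE-alone error IQR ≈ 4% here versus ≈ 8% reported for
template-derived geometry), and the DW error IQR is
mildly sensitive to the denoising strategy (~20–30% relative) rather than
flat. Directional conclusions are unaffected. Similarly, comparing fitted
maps with versus without denoising on *pure-tissue* voxels makes the
relative MK difference explode, because ground-truth MK of a single
Gaussian compartment is ≈ 0 and the raw arm's Rician floor inflates it —
the denoised arm is *closer to ground truth*, but relative differences on a
near-zero metric are ill-conditioned; in vivo, where MK ≈ 0.75, the same
absolute shift is well under 5%.

The simulation does not model EPI readout physics (distortions, blurring),
eddy currents, motion or physiological noise, spatially varying or
coil-correlated noise, cord curvature or pathology; passing tests therefore
certify the algorithmic pipeline, not robustness to those real-data
effects.

## Problem sizes

Default scales were chosen so a full run completes in minutes on one core:
the 40-slice phantom (~1700 cord voxels) and 131-measurement synthesis take
~1 minute (dominated by the Bloch integration, cached thereafter); error
statistics use 50–100 noise realizations per grid cell (denoising itself is
seconds per realization); the map-bias comparison fits 220 near-pure voxels
per arm (~3 minutes per arm, dominated by the qMT fit).
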