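# uteqmt

Digital-phantom simulation, voxel-wise fitting and denoising for
**ultrashort-echo-time quantitative magnetization transfer (UTE-qMT)**
imaging of cortical bone.

Cortical bone holds most of the body's collagen-bound proton pool, but its
sub-millisecond T2* makes it invisible to conventional MRI. UTE readouts
recover that signal, and pulsed magnetization-transfer (MT) preparation
turns it into quantitative estimates of the **macromolecular fraction
(MMF)** and the free↔bound **exchange rates** (k<sub>ab</sub>,
k<sub>ba</sub>) — candidate imaging markers of bone matrix quality and
fracture risk. Because bone images are intrinsically noisy, the central
practical question is *how reliable are these voxel-wise estimates at a
given SNR, and how much does denoising buy you?* This package answers that
with fully synthetic digital phantoms whose ground truth is known exactly.

It is written for MR physicists and image-analysis researchers who want to

* simulate MT-weighted image stacks of bone-like tissue with a known
  two-pool ground truth,
* inject Rician noise calibrated to a target reference-image SNR,
* fit the two-pool model voxel-by-voxel (trust-region least squares) and
  map MMF / exchange rates with the standard instability exclusions,
* denoise stacks with tensor Marchenko–Pastur PCA (tMPPCA) or a Gaussian
  baseline and quantify the downstream accuracy gain.

## The model

Tissue is a binary spin bath: a free-water pool *a* and a macromolecular
pool *b* with longitudinal magnetizations M<sub>za</sub>, M<sub>zb</sub>,
relaxation rates R<sub>1a</sub>, R<sub>1b</sub>, sizes M<sub>0a</sub>,
M<sub>0b</sub>, exchange rates k<sub>ab</sub>, k<sub>ba</sub> =
k<sub>ab</sub>(1−MMF)/MMF, and MMF = M<sub>0b</sub>/(M<sub>0a</sub>+M<sub>0b</sub>).
R<sub>1a</sub> is not fitted; it is derived from the observed relaxation
rate R<sub>1obs</sub> (the slow eigenvalue of the relaxation–exchange
matrix):

```
R1a = R1obs − kab (R1b − R1obs) / (R1b − R1obs + kba)
```

Off-resonance saturation follows the rectangular-pulse approximation: the
shaped MT pulse (flip angle θ, offset Δ, duration τ) acts as constant
saturation rates W = π ω₁ᵣₘₛ² g(Δ) on each pool, with a Gaussian
lineshape at T<sub>2b</sub> = 15 µs for the bound pool and a Lorentzian at
T<sub>2a</sub> for direct free-pool saturation. Each MT cycle —
saturation, a 13-spoke UTE readout train (cos FA losses), recovery to fill
the 86 ms TR — is a piecewise-constant affine ODE solved by closed-form
2×2 matrix exponentials, and the reported signal is the periodic
steady-state free-pool magnetization (sin FA × spoke-train average).

Five parameters are free per voxel (M<sub>0a</sub>, MMF, k<sub>ab</sub>,
R<sub>1obs</sub>, T<sub>2a</sub>); R<sub>1b</sub> = 1 s⁻¹ and
T<sub>2b</sub> = 15 µs are fixed. Voxels with k<sub>ab</sub> > 10³ s⁻¹ or
k<sub>ba</sub> > 5×10³ s⁻¹ are flagged as unstable fits and excluded from
exchange-rate statistics.

## Worked example

```python
import numpy as np
from uteqmt import (PhantomSpec, NoiseSpec, FitConfig, MIDPOINT_PARAMS,
                    generate_phantom, add_rician_noise, measure_snr, fit_image)

chip  = generate_phantom(PhantomSpec(chips=(MIDPOINT_PARAMS,), layout=(1, 1)))
noisy = add_rician_noise(chip, NoiseSpec(target_snr=200, seed=0))
maps  = fit_image(noisy, FitConfig(init_mode="ground_truth"))
print(f"measured SNR : {measure_snr(noisy):.1f}")
print(f"MMF  mean/sd : {100*np.nanmean(maps['mmf']):.1f} / "
      f"{100*np.nanstd(maps['mmf']):.1f} %  (truth 50.0)")
print(f"kab  mean/sd : {np.nanmean(maps['k_ab']):.1f} / "
      f"{np.nanstd(maps['k_ab']):.1f} s^-1  (truth 25.0)")
```

prints

```
measured SNR : 200.1
MMF  mean/sd : 48.2 / 11.5 %  (truth 50.0)
kab  mean/sd : 26.1 / 11.7 s^-1  (truth 25.0)
```

i.e. at reference SNR 200 the across-voxel mean MMF of an 18×18 midpoint
chip (truth 50%) is recovered to within ~2 percentage points, with the
voxel-wise scatter and the MMF↔k<sub>ab</sub> coupling that motivate
ROI averaging or denoising at lower SNR.

A CLI wraps the same pipeline for NIfTI stacks with JSON sidecars:

```bash
uteqmt simulate --out phantom.nii --snr 50 --seed 0
uteqmt denoise  --input phantom.nii --sidecar phantom.json --method tmppca --out dn.nii
uteqmt fit      --input dn.nii --sidecar dn.json --init fixed --outdir maps/
uteqmt reproduce denoising --seed 0 --outdir results/
```

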