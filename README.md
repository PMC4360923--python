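# psnlm — pre-smoothed non-local means denoising for Rician MRI noise

Magnitude MR images from single-coil acquisitions carry **Rician**
noise: the measured magnitude is |z| = √((r + n₁)² + n₂²) with the true
signal r and two independent Gaussian fields n₁, n₂ ~ N(0, σ²).  The
noise is signal-dependent and biased (E|z|² = r² + 2σ²), which breaks
denoisers designed for additive Gaussian noise and skews downstream
quantitative analysis (registration, segmentation, morphometry).

`psnlm` implements a denoising framework for 3D MR volumes that

1. **transforms** the noisy volume into a domain where the noise is
   (approximately) additive — either the *squared magnitude* (bias is
   the constant 2σ²) or a numerically constructed *variance-stabilizing
   transform* (VST) with unit stabilized noise std and an
   exact-unbiased inverse;
2. **pre-smooths** the transformed volume with a traditional filter
   (Gaussian, median, or Perona–Malik anisotropic diffusion);
3. runs a 3D **non-local means** (NLM) filter whose weights
   w(p,q) = exp(−‖patch(p) − patch(q)‖²_{G_a} / h²) / Z(p)
   are computed from the *pre-smoothed* guide while averaging the
   intensities of the *transformed* volume (default patch 5×5×5, search
   window 11×11×11);
4. **inverts** the transform with bias compensation: subtract 2σ² and
   take the square root (squared-magnitude path, "PSNLM1"), or apply
   the exact-unbiased inverse VST ("PSNLM2").

σ is estimated from the image background as σ = √(μ/2), with μ the mean
of the squared magnitude over the background mask, extracted
automatically by median filtering → Otsu thresholding → morphological
closing → hole filling (or supplied externally).  Setting the
pre-smoother to `identity` reduces PSNLM to the unbiased-NLM baselines
(UNLM1/UNLM2); a plain NLM baseline on the raw magnitude is included.

A synthetic-phantom module generates brain-like piecewise-constant
multi-tissue volumes (brightest tissue t = 150/250/255 for T1/T2/PD
contrast) and injects Rician noise at a percent level p with
σ = (p/100)·t, so the whole pipeline is testable without any data
downloads.

## Worked example

```python
import numpy as np
from psnlm import (PhantomSpec, NoiseSpec, PipelineConfig, PresmoothConfig,
                   NLMParams, generate_phantom, add_rician_noise, denoise, evaluate)

clean = generate_phantom(PhantomSpec(shape=(48, 48, 48), modality="T1", geometry_seed=3))
noisy = add_rician_noise(clean, NoiseSpec(percent=17, t=150.0, seed=7))
print("noisy PSNR: %.2f dB" % evaluate(noisy, clean)[1])

cfg = PipelineConfig(variant="PSNLM2", presmooth=PresmoothConfig(method="gaussian"),
                     nlm=NLMParams(h=0.2))          # h in stabilized-noise units
out = denoise(noisy, cfg)                           # sigma auto-estimated
print("PSNLM2 PSNR: %.2f dB" % evaluate(out, clean)[1])
```

prints

```
noisy PSNR: 13.11 dB
PSNLM2 PSNR: 26.04 dB
```

i.e. at 17% Rician noise the VST + Gaussian-pre-smoothed NLM pipeline
recovers ~13 dB of peak signal-to-noise ratio
(PSNR = 10·log₁₀(C²/MSE), C the maximum representable intensity)
against the known ground truth.

The same pipelines are scriptable from the shell:

```sh
psnlm simulate --modality t1 --shape 64 --percent 17 --seed 1 \
       --out-clean clean.nii.gz --out-noisy noisy.nii.gz
psnlm denoise  --input noisy.nii.gz --output out.nii.gz \
       --variant psnlm2 --presmooth gaussian --sigma auto --h 0.2
psnlm evaluate --result out.nii.gz --reference clean.nii.gz --cmax 150
```

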