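# ctrestore

Restoration of blurred, noisy CT image *sequences* by sparse + low-rank
decomposition and Wiener filtering.

CT slice stacks are degraded by the scanner's finite resolution and by
acquisition noise — `g = h * f + n`, a convolutional blur plus additive
noise — which weakens contrast and smears organ boundaries. Classic
deblurring treats each slice independently and ignores that adjacent
slices are highly correlated. `ctrestore` instead stacks the sequence
into a data matrix `D` (one vectorized frame per column) and splits it
into a shared low-rank background and per-frame sparse structure, then
restores each part with the degradation model that fits it.

## Method

Three decomposition models are implemented:

- **RPCA** (robust PCA): `min ‖A‖* + λ‖E‖₁ s.t. D = A + E`, solved by
  the inexact augmented Lagrange multiplier method — singular-value
  thresholding for the low-rank part `A`, elementwise soft shrinkage for
  the sparse part `E`.
- **LADMAP**: the same convex program solved by the linearized
  alternating direction method with adaptive penalty (faster penalty
  schedule, two-part stopping rule).
- **GoDec**: the approximate model `X = L + S + G` with hard constraints
  `rank(L) ≤ r`, `card(S) ≤ k`, alternating a bilateral-random-projection
  rank-r step with a keep-k-largest projection; the residual `G` absorbs
  dense noise, which suits heavily noisy stacks.

The restored sequence is

    f̂ᵢ = f₁(Sᵢ) + f₂(L̄),      L̄ = mean of the low-rank frames,

where `f₂` is Wiener deconvolution of the averaged background under an
isotropic Gaussian PSF `h(x,y) ∝ exp(−(x²+y²)/2σ²)` and `f₁` is Wiener
deconvolution of each sparse frame under a turbulence-style transfer
function `H(u,v) = exp(−k(u²+v²)^{5/6})`. Both use the constant-NSR
Wiener form `F̂ = conj(H)/(|H|² + K) · G`. Any noise component `G` is
discarded, never added back.

Quality is scored per frame by standard deviation (SD, population
normalization), information entropy (IE, bits over 256 gray levels) and
the image-quality measurement function value (IQMFV, the variance =
SD²); for all three, higher means more contrast/detail.

## Worked example

```python
import numpy as np
from ctrestore import (PhantomSpec, make_phantom, RestorationConfig,
                       SolverOptions, restore_sequence)
from ctrestore.psf_wiener import matched_turbulence_k

# ground-truthed phantom: 10 correlated 64x64 frames,
# Gaussian blur sigma=2 px, noise std 5 (0-255 scale)
spec = PhantomSpec(n_frames=10, height=64, width=64,
                   blur={"kind": "gaussian", "sigma": 2.0},
                   noise_std=5.0, seed=0)
truth = make_phantom(spec)

clean = np.stack(truth.clean.frames)
cfg = RestorationConfig(
    model="godec",
    solver_opts=SolverOptions(r=2, k=int(0.10 * clean.size), seed=1),
    gauss_sigma=2.0,
    gauss_nsr=spec.noise_std**2 / np.var(clean),   # matched NSR
    turb_k=matched_turbulence_k(2.0, 64),          # matched turbulence strength
    turb_nsr=0.05,
)
result = restore_sequence(truth.degraded, cfg)
```

Output (mean over the 10 frames; RMSE is to the clean ground truth):

```
degraded:  SD=26.3713  IE=6.6715  IQMFV=  697.9  RMSE=9.917
restored:  SD=27.6431  IE=6.7327  IQMFV=  764.5  RMSE=8.120
solver: 65 iterations, rank 2, 4096 sparse entries
```

Restoration raises contrast (SD, IQMFV) and entropy while moving the
frames closer to the truth (RMSE down 18%). The same pipeline runs from
the shell:

```bash
ctrestore simulate --output work/phantom
ctrestore restore --input work/phantom/degraded --output work/out \
                  --model rpca --gauss-sigma 2.0
ctrestore metrics --input work/out/restored
```

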