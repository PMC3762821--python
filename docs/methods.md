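# Methods

## Degradation model

A frame reaching the viewer is modelled as `g = h * f + n`: circular
convolution of the latent frame `f` with a blur kernel `h`, plus
additive zero-mean noise `n`. Two kernels are supported. The system
blur is an isotropic 2-D Gaussian PSF of standard deviation `sigma`
pixels, normalized to unit sum (support `ceil(6 sigma)` rounded up to
odd, so the truncated tails are negligible). A second, turbulence-style
degradation `H(u,v) = exp(-k (u^2+v^2)^(5/6))` is defined directly in
the frequency domain on centered integer frequency coordinates (then
rotated so zero frequency sits at index (0,0)); it models refraction-like
blur and is the transfer function applied to the sparse component.

All convolutions and deconvolutions use plain 2-D FFTs, i.e. circular
boundary conditions. No edge tapering is applied by default; for frames
whose content touches the border, wrap-around artifacts are possible and
a windowing step would have to be added upstream.

## Wiener restoration

Restoration uses the constant noise-to-signal-ratio approximation of
the Wiener filter, `F_hat = conj(H) / (|H|^2 + K) * G`, with `K = nsr`
the reciprocal signal-to-noise ratio. This form is algebraically the
classic `(1/H) |H|^2/(|H|^2+K)` wherever `H != 0` but stays finite at
zeros of `H`. With `nsr = 0` the filter is exact inverse filtering;
frequencies with `|H| < epsilon` (default 1e-12) are then zeroed rather
than amplified without bound. The filter gain is bounded by
`1/(2 sqrt(nsr))` for positive `nsr`, which caps noise amplification.

Choosing the constants: `gauss_sigma` should match the believed system
blur; `nsr` is ideally the true noise-to-signal power ratio (the worked
example uses `noise_var / signal_var` of the known phantom). The
turbulence constant `k` has no canonical value; `matched_turbulence_k`
sets it so the turbulence MTF equals the Gaussian system MTF at the
half-power frequency, which is the recommended choice when the blur
width is roughly known. The library defaults (`sigma = 2.5`,
`k = 0.0025`, `nsr = 0.01`) are plain configuration defaults, not
calibrated values.

## Decomposition solvers

All three solvers operate on the `(H*W) x n` matrix whose column `i` is
frame `i` flattened row-major (the scan order is arbitrary but fixed).

**RPCA (inexact ALM).** `min ||A||_* + lam ||E||_1 s.t. D = A + E`.
Defaults: `lam = 1/sqrt(max(m,n))`, `mu0 = 1.25/||D||_2`, `rho = 1.5`,
`mu_max = 1e7 mu0`, stopping at relative constraint residual `1e-7`,
at most 500 iterations — the conventional inexact-ALM settings. The
dual variable is initialized at `D / max(||D||_2, ||D||_inf/lam)`.
Non-convergence within the iteration cap is flagged in the diagnostics,
not fatal. For sequences whose per-frame features are compact and
all-positive (bright structures rather than symmetric corruption), the
default weight is marginal for exact separation and `lam = 2/sqrt(m)`
separates cleanly; the relevant test uses that weight.

**LADMAP.** Same convex program. Specialized to the identity constraint
maps of `D = A + E`, the linearization constant is 1, so each proximal
step matches ALM's but the updates are Gauss–Seidel and the penalty
grows (factor `rho`) only when the scaled iterate change
`mu * max(dA, dE)/||D||` falls below `eps2 = 1e-4`; stopping requires
both the constraint residual (`tol`) and that change (`tol2 = 1e-5`) to
be small. The penalty sequence is therefore non-decreasing and capped
by `mu_max`.

**GoDec.** `X = L + S + G` with `rank(L) <= r`, `card(S) <= k`.
The L-step is a bilateral-random-projection rank-r approximation
(`Y1 = X A1`, `Y2 = X' Y1`, `q = 2` power refinements, QR
re-orthogonalization of both bases, `L = Q1 (Q1' X Q2) Q2'`); the
S-step keeps the `k` largest-magnitude entries of `X - L`, ties at the
k-th magnitude broken by scan order (first kept). Because the
randomized L-step is approximate, it can occasionally raise the
residual; whenever a BRP iterate would do so, the step falls back to
the exact truncated SVD of `X - S`, so the objective
`||X - L - S||_F^2` is non-increasing at every iteration by
construction. Iteration stops when the objective's relative change
drops below `tol`. All randomness flows through an explicit seed
(default 0).

## Restoration pipeline

Stack, decompose, then: (a) average the low-rank columns into one
background frame `L_bar` and Wiener-restore it once under the Gaussian
OTF; (b) Wiener-restore each sparse frame under the turbulence OTF —
sparse frames may be negative-valued, which is well-defined since the
filter is linear; (c) output frame `i` = restored sparse `i` + restored
`L_bar`, clipped to `[0, 255]` (clipping is the only nonlinearity; the
pre-clip recombination is exact). GoDec's noise component is discarded.
Single-frame input is allowed with a warning: the frame's own low-rank
part replaces the sequence average, which forgoes the inter-slice
information the method is built to exploit.

A convenience `select_model` picks GoDec when a Laplacian-MAD noise
estimate exceeds a configurable threshold (default 4 intensity units)
and RPCA otherwise; it is a rule of thumb, not a calibrated classifier,
and explicit model choice is the default interface.

## Quality metrics

SD is the population standard deviation (1/MN). IE is Shannon entropy
in bits over the 256-level histogram after rounding intensities to
integer levels; it is bounded by 8 bits. IQMFV is defined as the
population variance, i.e. SD². That definition is adopted because it
reproduces every published (SD, IQMFV) pair in the reference
comparisons to the last printed decimal (within one unit in that
decimal; a few entries are truncated rather than rounded), e.g.
49.2172² = 2422.3. Reports are computed on clipped, non-renormalized
outputs.

## Synthetic phantoms

`make_phantom` emulates the statistical structure the method assumes.
The background is `background_rank` basis images — a constant image
plus smooth random fields (Gaussian-filtered white noise, smoothing
std 6 px) — combined with per-frame coefficients. The global level is
fixed across frames because CT intensities are calibrated; small
per-frame drift (`coeff_variation`, default 5%) multiplies the
structural components only. Keeping the constant image inside the basis
lets the affine intensity remap (into [40, 180]) preserve the rank
bound exactly. Sparse features are randomly placed bright disks
covering `sparse_fraction` (default 2%) of the pixels per frame,
redrawn each frame — compact structures mimicking per-slice anatomy,
deliberately not salt-and-pepper. Degradation applies the configured
OTF and i.i.d. Gaussian noise on the 0–255 scale (the noise law is a
modelling choice; scanner physics is out of scope). Default geometry is
64×64×10 with blur sigma 2 and noise std 5, which keeps the full test
suite under a minute while leaving the blur and noise clearly visible
at the phantom's contrast.

What the phantom does *not* emulate: anatomical texture, streak and
beam-hardening artifacts, spatially varying or non-Gaussian noise, and
inter-slice motion. Passing tests therefore demonstrate correctness of
the decomposition/restoration machinery under the model's own
assumptions, not clinical performance.

## Known limitations

- The method degrades when the background genuinely varies from frame
  to frame: everything the mean low-rank frame cannot represent must
  either migrate to the sparse component or be lost.
- Circular convolution implies wrap-around boundary handling.
- The turbulence constant, blur width and NSR are user-supplied; no
  blind estimation is provided.
- With the default sparsity weight, RPCA's separation of all-positive
  compact features is approximate (relative error ~1e-3 rather than
  exact); raise `lam` toward `2/sqrt(m)` for such content.
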