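"""Ground-truthed phantom sequences for testing and benchmarking.

Real CT studies have a shared, slowly varying anatomical background across
adjacent slices (a low-rank stack) plus per-slice structures (sparse in
each frame), and reach the viewer degraded by convolutional blur and
additive noise.  ``make_phantom`` emulates exactly that statistical
structure with full ground truth:

* background = ``background_rank`` smooth random basis images combined
  with per-frame coefficients whose first component dominates, mimicking
  the strong inter-frame correlation of a slice stack;
* sparse features = randomly placed bright disks covering a stated pixel
  fraction per frame (compact structures, not salt-and-pepper);
* degradation = circular convolution with a Gaussian or turbulence
  transfer function plus i.i.d. zero-mean Gaussian noise (0-255 scale).

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .psf_wiener import (
    OpticalTransferFunction,
    apply_otf,
    gaussian_psf,
    psf_to_otf,
    turbulence_otf,
)
from .sequence_io import DataMatrix, ImageSequence, stack_sequence

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "degrade"]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic CT-like sequence.

    ``coeff_variation`` sets the relative spread of the per-frame
    background coefficients (0 = identical frames); blur is either
    {"kind": "gaussian", "sigma": s}, {"kind": "turbulence", "k": k}, or
    None for no blur.
    """

    n_frames: int = 10
    height: int = 64
    width: int = 64
    background_rank: int = 2
    sparse_fraction: float = 0.02
    sparse_amplitude: float = 100.0
    coeff_variation: float = 0.05
    blur: dict | None = field(default_factory=lambda: {"kind": "gaussian",
                                                       "sigma": 2.0})
    noise_std: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rank > self.n_frames:
            raise ValueError("background_rank cannot exceed n_frames")
        if not 0 <= self.sparse_fraction <= 0.2:
            raise ValueError("sparse_fraction must lie in [0, 0.2]")
        if self.noise_std < 0:
            raise ValueError("noise_std must be nonnegative")


@dataclass
class PhantomTruth:
    """A phantom with every ground-truth component retained."""

    clean: ImageSequence
    degraded: ImageSequence
    true_lowrank: DataMatrix
    true_sparse: DataMatrix
    true_noise: DataMatrix
    spec: PhantomSpec


def _smooth_basis(rng: np.random.Generator, h: int, w: int, n: int,
                  smooth_sigma: float = 6.0) -> np.ndarray:
    """Constant column + n-1 smooth random fields (unit max magnitude).

    Keeping the constant image inside the basis span lets the overall
    intensity level/offset vary without raising the background rank.
    """
    basis = np.empty((h * w, n))
    basis[:, 0] = 1.0
    for j in range(1, n):
        field_ = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                         smooth_sigma, mode="wrap")
        field_ /= np.abs(field_).max()
        basis[:, j] = field_.reshape(-1)
    return basis


def _disk_mask(h: int, w: int, cy: float, cx: float, radius: float) -> np.ndarray:
    y, x = np.ogrid[:h, :w]
    return (y - cy) ** 2 + (x - cx) ** 2 <= radius**2


def _sparse_frame(rng: np.random.Generator, h: int, w: int,
                  fraction: float, amplitude: float) -> np.ndarray:
    """Random bright disks covering roughly `fraction` of the pixels."""
    out = np.zeros((h, w))
    target = fraction * h * w
    covered = 0
    while covered < target:
        radius = rng.uniform(1.5, max(2.0, 0.04 * min(h, w)))
        cy = rng.uniform(radius, h - radius)
        cx = rng.uniform(radius, w - radius)
        mask = _disk_mask(h, w, cy, cx, radius)
        out[mask] = amplitude * rng.uniform(0.5, 1.0)
        covered = np.count_nonzero(out)
    return out


def degrade(frame: np.ndarray, otf: OpticalTransferFunction | None,
            noise_std: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Blur a frame through an OTF and add i.i.d. Gaussian noise."""
    frame = np.asarray(frame, dtype=np.float64)
    if otf is not None:
        if frame.shape != otf.shape:
            raise ValueError(f"frame shape {frame.shape} != OTF {otf.shape}")
        frame = apply_otf(frame, otf)
    if noise_std > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        frame = frame + rng.normal(0.0, noise_std, size=frame.shape)
    return frame


def blur_otf_for_spec(spec: PhantomSpec) -> OpticalTransferFunction | None:
    """The OTF a spec's blur dict describes (None for no blur)."""
    shape = (spec.height, spec.width)
    if spec.blur is None:
        return None
    kind = spec.blur.get("kind", "gaussian")
    if kind == "gaussian":
        sigma = float(spec.blur.get("sigma", 2.0))
        if sigma <= 0:
            return None
        return psf_to_otf(gaussian_psf(sigma=sigma), shape)
    if kind == "turbulence":
        k = float(spec.blur.get("k", 0.0025))
        if k == 0:
            return None
        return turbulence_otf(shape, k)
    raise ValueError(f"unknown blur kind {kind!r}")


def make_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Generate a ground-truthed phantom sequence from a spec.

    The clean stack satisfies ``stack(clean) = true_lowrank + true_sparse``
    exactly, with rank(true_lowrank) <= background_rank; degraded frames
    are ``blur(clean) + noise`` with the noise realization retained.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    h, w, n = spec.height, spec.width, spec.n_frames

    basis = _smooth_basis(rng, h, w, spec.background_rank)
    # CT intensities are calibrated, so the global level is fixed; the
    # per-frame drift lives on the structural (spatial) components
    coeffs = np.empty((spec.background_rank, n))
    coeffs[0] = 110.0
    if spec.background_rank > 1:
        coeffs[1] = 60.0 * (1.0 + spec.coeff_variation * rng.standard_normal(n))
    if spec.background_rank > 2:
        coeffs[2:] = 15.0 * rng.standard_normal((spec.background_rank - 2, n))
    lowrank = basis @ coeffs
    # affine remap into [40, 180]; the constant basis column keeps rank intact
    lo, hi = lowrank.min(), lowrank.max()
    scale = 140.0 / max(hi - lo, 1e-12)
    lowrank = 40.0 + (lowrank - lo) * scale

    sparse = np.zeros((h * w, n))
    if spec.sparse_fraction > 0 and spec.sparse_amplitude != 0:
        for i in range(n):
            sparse[:, i] = _sparse_frame(
                rng, h, w, spec.sparse_fraction, spec.sparse_amplitude
            ).reshape(-1)

    clean_mat = lowrank + sparse
    clean = ImageSequence(
        frames=[clean_mat[:, i].reshape(h, w) for i in range(n)],
        source_ids=[f"clean_{i:03d}" for i in range(n)],
    )

    otf = blur_otf_for_spec(spec)
    degraded_frames = [
        degrade(clean.frames[i], otf, spec.noise_std, seed=rng)
        for i in range(n)
    ]
    degraded = ImageSequence(
        frames=degraded_frames,
        source_ids=[f"degraded_{i:03d}" for i in range(n)],
    )

    blurred = np.column_stack([
        apply_otf(f, otf).reshape(-1) if otf is not None else f.reshape(-1)
        for f in clean.frames
    ])
    noise = stack_sequence(degraded).values - blurred

    return PhantomTruth(
        clean=clean,
        degraded=degraded,
        true_lowrank=DataMatrix(lowrank, h, w),
        true_sparse=DataMatrix(sparse, h, w),
        true_noise=DataMatrix(noise, h, w),
        spec=spec,
    )
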