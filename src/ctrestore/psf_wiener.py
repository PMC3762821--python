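"""Degradation models and frequency-domain Wiener restoration.

Two degradations are modelled.  The imaging system's finite resolution is
an isotropic 2-D Gaussian point-spread function (PSF),
``h(x, y) ~ exp(-(x^2 + y^2) / (2 sigma^2))``, defined in the spatial
domain and carried to the frequency domain by :func:`psf_to_otf`.  The
second, a turbulence-style optical transfer function
``H(u, v) = exp(-k (u^2 + v^2)^(5/6))``, models refraction-like blur and
is defined directly in the frequency domain; it is applied to the sparse
component of a decomposed sequence while the Gaussian acts on the shared
low-rank background.

Restoration uses the constant noise-to-signal-ratio (NSR) approximation
of the Wiener filter,

    F_hat = conj(H) / (|H|^2 + nsr) * G,

algebraically the classic (1/H) |H|^2 / (|H|^2 + K) form wherever H != 0
but finite at zeros of H.  All transforms are plain (circular) 2-D FFTs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PointSpreadKernel",
    "OpticalTransferFunction",
    "WienerConfig",
    "gaussian_psf",
    "turbulence_otf",
    "psf_to_otf",
    "wiener_restore",
]


@dataclass
class PointSpreadKernel:
    """Normalized nonnegative spatial blur kernel with a declared center."""

    values: np.ndarray
    center: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("kernel must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("kernel taps must be nonnegative")
        s = self.values.sum()
        if not np.isclose(s, 1.0, atol=1e-12):
            raise ValueError(f"kernel taps must sum to 1, got {s!r}")

    @property
    def normalization(self) -> float:
        return float(self.values.sum())


@dataclass
class OpticalTransferFunction:
    """Frequency-domain degradation H(u, v), zero frequency at index (0, 0)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("OTF must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("OTF contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class WienerConfig:
    """Constant-NSR Wiener settings.

    ``nsr`` is the reciprocal signal-to-noise ratio K; ``epsilon`` guards
    near-zero |H| when nsr = 0 (those frequencies are zeroed rather than
    amplified without bound).
    """

    nsr: float = 0.01
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.nsr < 0:
            raise ValueError("nsr must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def default_gaussian_size(sigma: float) -> int:
    """Kernel support covering +-3 sigma, rounded up to odd."""
    size = int(np.ceil(6 * sigma))
    return size + 1 if size % 2 == 0 else max(size, 1)


def gaussian_psf(size: int | None = None, sigma: float = 2.5) -> PointSpreadKernel:
    """Isotropic 2-D Gaussian blur kernel, unit sum.

    ``size`` must be odd (default: ceil(6 sigma) rounded up to odd).  The
    normalization to unit sum fixes the leading constant of the Gaussian.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if size is None:
        size = default_gaussian_size(sigma)
    if size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {size}")
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1]
    taps = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    taps /= taps.sum()
    return PointSpreadKernel(values=taps, center=(half, half))


def turbulence_otf(shape: tuple[int, int], k: float) -> OpticalTransferFunction:
    """Turbulence-style transfer function exp(-k (u^2 + v^2)^(5/6)).

    Evaluated on centered integer frequency coordinates (isotropic about
    zero frequency), then rotated so the zero frequency sits at (0, 0).
    k = 0 gives the identity degradation.
    """
    if k < 0:
        raise ValueError("turbulence strength k must be nonnegative")
    h, w = shape
    v = np.arange(h) - h // 2
    u = np.arange(w) - w // 2
    r2 = v[:, None] ** 2.0 + u[None, :] ** 2.0
    H = np.exp(-k * r2 ** (5.0 / 6.0))
    return OpticalTransferFunction(values=np.fft.ifftshift(H))


def matched_turbulence_k(sigma: float, n: int) -> float:
    """Turbulence strength whose MTF matches a Gaussian blur at half power.

    The Gaussian PSF of std ``sigma`` (pixels) on an n-pixel grid has MTF
    exp(-2 pi^2 sigma^2 r^2 / n^2); the turbulence MTF is
    exp(-k r^(5/3)).  Equating the two at the Gaussian's half-power
    radius gives a k that deblurs comparably — the usual way the
    empirical constant is set when the system blur is roughly known.
    """
    if sigma <= 0 or n <= 0:
        raise ValueError("sigma and n must be positive")
    r_half = n * np.sqrt(np.log(2.0) / (2.0 * np.pi**2 * sigma**2))
    return float(np.log(2.0) / r_half ** (5.0 / 3.0))


def psf_to_otf(kernel: PointSpreadKernel,
               shape: tuple[int, int]) -> OpticalTransferFunction:
    """Zero-pad a spatial kernel to the frame shape and transform it.

    The kernel's center tap is circularly shifted to index (0, 0) first,
    so the resulting OTF applies the blur without spatial offset; its
    zero-frequency value equals the tap sum (1 for a normalized kernel).
    """
    kh, kw = kernel.values.shape
    h, w = shape
    if kh > h or kw > w:
        raise ValueError(f"kernel {kh}x{kw} larger than frame {h}x{w}")
    padded = np.zeros(shape, dtype=np.float64)
    padded[:kh, :kw] = kernel.values
    cy, cx = kernel.center
    padded = np.roll(padded, (-cy, -cx), axis=(0, 1))
    return OpticalTransferFunction(values=np.fft.fft2(padded))


def wiener_filter_gain(otf: OpticalTransferFunction,
                       cfg: WienerConfig) -> np.ndarray:
    """The frequency-domain gain conj(H) / (|H|^2 + nsr)."""
    H = otf.values
    mag2 = np.abs(H) ** 2
    if cfg.nsr == 0:
        gain = np.zeros_like(H)
        ok = np.abs(H) >= cfg.epsilon
        gain[ok] = np.conj(H[ok]) / mag2[ok]
        return gain
    return np.conj(H) / (mag2 + cfg.nsr)


def wiener_restore(g: np.ndarray, otf: OpticalTransferFunction,
                   cfg: WienerConfig | None = None) -> np.ndarray:
    """Constant-NSR Wiener deconvolution of one frame.

    Multiplies the image spectrum by conj(H)/(|H|^2 + nsr) and inverts;
    the output is the real part of the inverse transform.  With nsr = 0
    and |H| bounded away from zero this is exact inverse filtering.
    """
    cfg = cfg or WienerConfig()
    g = np.asarray(g, dtype=np.float64)
    if g.shape != otf.shape:
        raise ValueError(f"image shape {g.shape} != OTF shape {otf.shape}")
    gain = wiener_filter_gain(otf, cfg)
    return np.real(np.fft.ifft2(gain * np.fft.fft2(g)))


def apply_otf(f: np.ndarray, otf: OpticalTransferFunction) -> np.ndarray:
    """Circular convolution of a frame with the degradation H."""
    f = np.asarray(f, dtype=np.float64)
    if f.shape != otf.shape:
        raise ValueError(f"image shape {f.shape} != OTF shape {otf.shape}")
    return np.real(np.fft.ifft2(otf.values * np.fft.fft2(f)))
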