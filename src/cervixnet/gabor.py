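"""Gabor angle-sweep texture fusion (GMT).

The denoised image is correlated with a bank of complex Gabor kernels whose
orientation runs over the 180 integer angles -90..+89 degrees at scale 1
(+90 is omitted because its response magnitude duplicates -90).  Taking the
per-pixel maximum magnitude across the 180 response images fuses the sweep
into a single orientation-agnostic texture-energy map, the Gabor cervigram
image (GCI).

The kernel is the standard complex Gabor

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * exp(i(2 pi x'/lambda + psi))

with x' = x cos(theta) + y sin(theta), y' = -x sin(theta) + y cos(theta),
x increasing along columns and y along rows; ``scale`` multiplies both
sigma and lambda.  Kernels are DC-adjusted (an envelope-weighted mean is
subtracted) so that constant regions respond zero and brightness cannot
masquerade as texture; this can be switched off via ``zero_mean=False``.
Image borders are mirror padded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as sfft

from .core import as_gray


@dataclass(frozen=True)
class GaborParams:
    theta: float = 0.0          # orientation, degrees in [-90, 90)
    wavelength: float = 8.0     # carrier wavelength, pixels
    sigma: float = 4.0          # envelope width, pixels
    gamma: float = 0.5          # envelope aspect ratio
    psi: float = 0.0            # phase offset, radians
    ksize: int = 31             # odd kernel side, pixels
    scale: float = 1.0          # multiplies sigma and lambda
    zero_mean: bool = True

    def validate(self) -> None:
        if self.ksize % 2 == 0 or self.ksize < 3:
            raise ValueError("ksize must be odd and >= 3")
        if self.wavelength <= 0 or self.sigma <= 0 or self.scale <= 0:
            raise ValueError("wavelength, sigma and scale must be > 0")


@dataclass
class GaborResponseStack:
    """180 magnitude images, one per integer orientation in [-90, 89]."""

    responses: np.ndarray  # (n_theta, H, W), all >= 0
    thetas: np.ndarray     # (n_theta,) degrees


@dataclass
class GaborCervigramImage:
    pixels: np.ndarray         # per-pixel max magnitude over the stack
    winning_theta: np.ndarray  # per-pixel orientation (deg) achieving the max


def _envelope(p: GaborParams) -> np.ndarray:
    half = p.ksize // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    th = np.deg2rad(p.theta)
    xp = x * np.cos(th) + y * np.sin(th)
    yp = -x * np.sin(th) + y * np.cos(th)
    s = p.sigma * p.scale
    return np.exp(-(xp**2 + (p.gamma**2) * yp**2) / (2.0 * s * s)), xp


def make_kernel(p: GaborParams) -> np.ndarray:
    """Complex Gabor kernel of shape (ksize, ksize)."""
    p.validate()
    env, xp = _envelope(p)
    lam = p.wavelength * p.scale
    kernel = env * np.exp(1j * (2.0 * np.pi * xp / lam + p.psi))
    if p.zero_mean:
        kernel = kernel - env * (kernel.sum() / env.sum())
    return kernel


def matched_gain(p: GaborParams) -> float:
    """Response magnitude per unit amplitude of a frequency/orientation
    matched sinusoidal grating (half the envelope mass).  Used to express a
    GCI in equivalent grating-amplitude units on the 0-255 scale."""
    env, _ = _envelope(p)
    return float(env.sum() / 2.0)


def _fft_correlate(img: np.ndarray, kernels: np.ndarray, fker: np.ndarray | None = None) -> np.ndarray:
    """|correlation| of a mirror-padded image with one or more kernels.

    ``kernels`` has shape (..., k, k); the result is (..., H, W).  ``fker``
    may carry precomputed kernel spectra for the implied FFT shape.
    """
    k = kernels.shape[-1]
    pad = k // 2
    padded = np.pad(img, pad, mode="reflect")
    fshape = [sfft.next_fast_len(s + k - 1) for s in padded.shape]
    fimg = sfft.fft2(padded, fshape)
    if fker is None:
        # correlation == convolution with the spatially flipped kernel
        fker = sfft.fft2(kernels[..., ::-1, ::-1], fshape)
    full = sfft.ifft2(fimg * fker)
    h, w = img.shape
    return np.abs(full[..., k - 1 : k - 1 + h, k - 1 : k - 1 + w])


def respond(img: np.ndarray, p: GaborParams) -> np.ndarray:
    """Same-shape magnitude response of the image to one Gabor kernel."""
    img = as_gray(img)
    return _fft_correlate(img, make_kernel(p))


_SWEEP_CACHE: dict = {}


def sweep_thetas() -> np.ndarray:
    return np.arange(-90, 90, dtype=np.float64)


def sweep(img: np.ndarray, base: GaborParams) -> GaborResponseStack:
    """Run the 180-orientation sweep (theta = -90..+89 deg, step 1)."""
    base.validate()
    img = as_gray(img)
    thetas = sweep_thetas()
    k = base.ksize
    fshape = tuple(sfft.next_fast_len(s + 2 * (k // 2) + k - 1) for s in img.shape)
    key = (replace(base, theta=0.0), fshape)
    cached = _SWEEP_CACHE.get(key)
    if cached is None:
        kernels = np.stack([make_kernel(replace(base, theta=float(t))) for t in thetas])
        fker = sfft.fft2(kernels[..., ::-1, ::-1], fshape)
        _SWEEP_CACHE.clear()  # keep at most one bank resident
        _SWEEP_CACHE[key] = cached = (kernels, fker)
    kernels, fker = cached
    responses = _fft_correlate(img, kernels, fker=fker)
    return GaborResponseStack(responses=responses, thetas=thetas)


def fuse_max(stack: GaborResponseStack) -> GaborCervigramImage:
    """Per-pixel maximum magnitude across the stack."""
    if stack.responses.size == 0:
        raise ValueError("empty response stack")
    arg = stack.responses.argmax(axis=0)
    return GaborCervigramImage(
        pixels=stack.responses.max(axis=0),
        winning_theta=stack.thetas[arg],
    )


def gci(img: np.ndarray, base: GaborParams) -> GaborCervigramImage:
    """Convenience: sweep + max fusion."""
    return fuse_max(sweep(img, base))


def equivalent_amplitude(gci_pixels: np.ndarray, base: GaborParams) -> np.ndarray:
    """Rescale raw GCI magnitudes to matched-grating amplitude units
    (0-255 scale), clipped; float32 so disk round-trips are exact."""
    out = np.clip(gci_pixels / matched_gain(base), 0.0, 255.0)
    return out.astype(np.float32)
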