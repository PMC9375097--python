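"""Coherent confocal scanning laser microscope (CSLM) image formation.

With a point detector the CSLM is a coherent system whose effective
amplitude PSF is the pointwise product of the illumination and detection
amplitude PSFs, h_eff = h1 * h2. Scanning an object of transmitted
amplitude g produces the complex amplitude C = h_eff (x) g (convolution),
and the detector records the intensity I = |C|^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .aperture_models import ApertureSpec, PupilMask, make_circular, make_spiky
from .numeric_psf import diffract

__all__ = ["ObjectImage", "ConfocalImage", "effective_psf", "form_image", "simulate_cslm"]


@dataclass(frozen=True)
class ObjectImage:
    """Object transmitted amplitude g(x, y), values in [0, 1]."""

    amplitude: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitude)
        if a.size == 0:
            raise ValueError("degenerate input: empty object")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("object amplitude must be finite and non-negative")


@dataclass(frozen=True)
class ConfocalImage:
    """Scanned-image complex amplitude C(x, y) and detected intensity |C|^2
    (max-normalized)."""

    complex_amplitude: np.ndarray
    intensity: np.ndarray


def effective_psf(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Pointwise product h1 * h2 of the two lens amplitude PSFs."""
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    if h1.shape != h2.shape:
        raise ValueError(f"shape mismatch: {h1.shape} vs {h2.shape}")
    return h1 * h2


def form_image(obj: ObjectImage, h_eff: np.ndarray) -> ConfocalImage:
    """Coherent convolution of the object amplitude with h_eff.

    Full zero-padded linear convolution, cropped to the object size with the
    kernel centre pixel (N//2 for an even kernel) aligned: a centred unit
    impulse object reproduces h_eff exactly, pixel for pixel.
    """
    g = np.asarray(obj.amplitude, dtype=np.complex128)
    k = np.asarray(h_eff, dtype=np.complex128)
    full = signal.fftconvolve(g, k, mode="full")
    r0, c0 = k.shape[0] // 2, k.shape[1] // 2
    c = full[r0 : r0 + g.shape[0], c0 : c0 + g.shape[1]]
    intensity = np.abs(c) ** 2
    peak = intensity.max()
    if peak > 0:
        intensity = intensity / peak
    return ConfocalImage(complex_amplitude=c, intensity=intensity)


def _pupil_from_spec(spec: ApertureSpec) -> PupilMask:
    if spec.spike_mode == "none":
        return make_circular(spec.grid_size, spec.inner_radius)
    return make_spiky(spec)


def simulate_cslm(
    obj: ObjectImage, illum_spec: ApertureSpec, detect_spec: ApertureSpec
) -> ConfocalImage:
    """End-to-end CSLM simulation from two pupil specifications.

    Builds both pupils, computes their complex amplitude PSFs by centred
    FFT, forms h_eff as their pointwise product, convolves with the object
    amplitude and returns the detected intensity. The reference microscope
    configuration pairs a spiky illumination pupil with a uniform circular
    detection pupil of the same radius (512^2 frame, radius 128, 8 spikes).
    """
    if illum_spec.grid_size != detect_spec.grid_size:
        raise ValueError("illumination and detection pupils must share a grid size")
    h1 = diffract(_pupil_from_spec(illum_spec)).amplitude
    h2 = diffract(_pupil_from_spec(detect_spec)).amplitude
    h_eff = effective_psf(h1, h2)
    h_eff = h_eff / np.abs(h_eff).max()
    return form_image(obj, h_eff)
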