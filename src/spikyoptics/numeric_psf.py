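"""FFT diffraction of pupil masks, windowed line profiles, autocorrelation.

The far-field amplitude impulse response of a pupil is its centred 2-D
discrete Fourier transform: a pupil centred at 0-based pixel (N/2, N/2)
yields a PSF whose zero-frequency peak lands on the same pixel, so 1-based
reporting places the N = 2048 peak at pixel 1025, i.e. position 36 of the
window [990, 1058]. The pupil autocorrelation (proportional to the support
of the incoherent optical transfer function) is computed transform-based on
the doubled support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .aperture_models import ApertureSpec, PupilMask

__all__ = [
    "PSFImage",
    "WindowProfile",
    "diffract",
    "line_profile",
    "peak_position",
    "pupil_autocorrelation",
]


@dataclass(frozen=True)
class PSFImage:
    """Diffraction intensity (max-normalized) with optional complex field.

    ``intensity`` is N x N in [0, 1] with peak exactly 1, centred at 0-based
    (N/2, N/2). ``amplitude`` retains the complex transform for coherent
    imaging chains.
    """

    intensity: np.ndarray
    spec: Optional[ApertureSpec] = None
    amplitude: Optional[np.ndarray] = None

    @property
    def center(self) -> tuple[int, int]:
        n = self.intensity.shape[0]
        return (n // 2, n // 2)


@dataclass(frozen=True)
class WindowProfile:
    """1-D windowed intensity samples; indices are 1-based inclusive."""

    values: np.ndarray
    window_start: int
    window_end: int
    fixed_axis_index: int

    def __post_init__(self) -> None:
        if len(self.values) != self.window_end - self.window_start + 1:
            raise ValueError("profile length inconsistent with window bounds")


def diffract(mask: PupilMask, pad: int = 1) -> PSFImage:
    """Centred FFT diffraction of a pupil mask.

    The amplitude grid is shifted so the pupil centre sits at the DFT origin,
    transformed, and shifted back so the zero-frequency peak lands at
    (N/2, N/2). ``pad`` >= 1 zero-pads the frame by that factor for finer
    PSF sampling (default none: the full frame is transformed as-is).
    """
    a = np.asarray(mask.amplitude, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("mask contains non-finite values")
    if not np.any(a):
        raise ValueError("degenerate input: all-zero mask")
    if pad > 1:
        n = a.shape[0]
        big = np.zeros((n * pad, n * pad), dtype=np.float64)
        o = (n * pad) // 2 - n // 2
        big[o : o + n, o : o + n] = a
        a = big
    field = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a)))
    intensity = np.abs(field) ** 2
    intensity /= intensity.max()
    return PSFImage(intensity=intensity, spec=mask.spec, amplitude=field)


def line_profile(
    image: PSFImage,
    axis: str,
    fixed_index: int,
    window_start: int,
    window_end: int,
) -> WindowProfile:
    """Extract a windowed row/column profile with 1-based pixel indices.

    ``axis="row"`` samples along a row (``fixed_index`` selects the row);
    ``axis="column"`` samples along a column. Values are re-normalized to
    the window maximum, matching normalized-PSF line plots.
    """
    n_rows, n_cols = image.intensity.shape
    if axis not in ("row", "column"):
        raise ValueError(f"axis must be 'row' or 'column', got {axis!r}")
    along = n_cols if axis == "row" else n_rows
    across = n_rows if axis == "row" else n_cols
    if not (1 <= window_start <= window_end <= along):
        raise IndexError(f"window [{window_start}, {window_end}] outside image of size {along}")
    if not (1 <= fixed_index <= across):
        raise IndexError(f"fixed_index {fixed_index} outside image of size {across}")
    if axis == "row":
        vals = image.intensity[fixed_index - 1, window_start - 1 : window_end]
    else:
        vals = image.intensity[window_start - 1 : window_end, fixed_index - 1]
    vals = np.array(vals, dtype=np.float64)
    m = vals.max()
    if m > 0:
        vals = vals / m
    return WindowProfile(
        values=vals,
        window_start=window_start,
        window_end=window_end,
        fixed_axis_index=fixed_index,
    )


def peak_position(profile: WindowProfile) -> int:
    """1-based position of the profile maximum within its window.

    Ties break toward the smallest index (argmax convention).
    """
    if len(profile.values) == 0:
        raise ValueError("empty profile")
    return int(np.argmax(profile.values)) + 1


def pupil_autocorrelation(mask: PupilMask, normalized: bool = True) -> np.ndarray:
    """Transform-based 2-D autocorrelation of the pupil amplitude.

    Returns the full (2N-1) x (2N-1) correlation, real and non-negative for
    non-negative masks, with the zero-lag peak at the array centre. With
    ``normalized`` the peak is scaled to 1; otherwise the zero-lag value of
    a binary mask equals its on-pixel count.
    """
    a = np.asarray(mask.amplitude, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("mask contains non-finite values")
    if not np.any(a):
        raise ValueError("degenerate input: all-zero mask")
    corr = signal.fftconvolve(a, a[::-1, ::-1], mode="full")
    corr = np.maximum(corr, 0.0)  # clip FFT round-off below zero
    if normalized:
        corr = corr / corr.max()
    return corr
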