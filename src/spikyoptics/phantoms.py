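"""Synthetic spiky virus-like phantom objects and grayscale conversion.

The phantom is a synthetic stand-in for a grayscale coronavirus micrograph:
a textured body disc fringed by stalk-and-knob protrusions (the peplomer
morphology), deterministic for a given seed. Default geometry: 512 x 512
frame with a 340-pixel body diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .confocal_imaging import ObjectImage

__all__ = ["VirusPhantomSpec", "make_virus_phantom", "to_grayscale"]

GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class VirusPhantomSpec:
    """Geometry and texture of the synthetic virus phantom."""

    grid_size: int = 512
    body_diameter: float = 340.0
    n_spikes: int = 24
    spike_length: float = 40.0
    texture_contrast: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size <= 0 or self.body_diameter <= 0 or self.spike_length <= 0:
            raise ValueError("grid_size, body_diameter and spike_length must be positive")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be non-negative")
        if not 0.0 <= self.texture_contrast <= 1.0:
            raise ValueError("texture_contrast must lie in [0, 1]")
        if self.body_diameter + 2 * self.spike_length >= self.grid_size:
            raise ValueError("phantom does not fit: body_diameter + 2*spike_length >= grid_size")


def make_virus_phantom(spec: VirusPhantomSpec) -> ObjectImage:
    """Deterministic grayscale phantom in [0, 1].

    Body: disc of the requested diameter carrying a smooth seeded speckle
    texture of the requested contrast (contrast 0 gives a flat disc).
    Spikes: radial stalks capped by knobs at seeded angles, amplitude 1.
    Everything lies within body radius + spike_length of the centre.
    """
    n = spec.grid_size
    c = n // 2
    rng = np.random.default_rng(spec.seed)
    v, u = np.ogrid[:n, :n]
    x = u - c
    y = v - c
    rho = np.hypot(x, y)
    r_body = spec.body_diameter / 2.0

    body = rho <= r_body
    img = np.zeros((n, n), dtype=np.float64)
    if spec.texture_contrast > 0:
        noise = rng.standard_normal((n, n))
        smooth = ndimage.gaussian_filter(noise, sigma=max(2.0, r_body / 20.0))
        lo, hi = smooth.min(), smooth.max()
        speckle = (smooth - lo) / (hi - lo) if hi > lo else np.zeros_like(smooth)
        img[body] = (1.0 - spec.texture_contrast) + spec.texture_contrast * speckle[body]
    else:
        img[body] = 1.0

    # stalk-and-knob protrusions: stalk 60% of the spike length, knob 40%
    stalk_len = 0.6 * spec.spike_length
    knob_r = 0.2 * spec.spike_length
    angles = np.sort(rng.uniform(0.0, 360.0, spec.n_spikes))
    theta = np.degrees(np.arctan2(y, x))
    for ang in angles:
        d_ang = np.abs((theta - ang + 180.0) % 360.0 - 180.0)
        stalk = (rho > r_body) & (rho <= r_body + stalk_len) & (rho * np.sin(np.radians(d_ang)) <= 2.0) & (d_ang < 90.0)
        kc = r_body + stalk_len + knob_r
        kx = kc * np.cos(np.radians(ang))
        ky = kc * np.sin(np.radians(ang))
        knob = np.hypot(x - kx, y - ky) <= knob_r
        img[stalk | knob] = 1.0
    return ObjectImage(amplitude=img)


def to_grayscale(color_image: np.ndarray) -> ObjectImage:
    """Luminance conversion of a 3-channel image with weights
    0.299 / 0.587 / 0.114, rescaled to [0, 1].

    Integer input is assumed to span [0, 255]; floating input is taken as
    already on [0, 1].
    """
    arr = np.asarray(color_image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / 255.0
    lum = arr[..., 0] * GRAY_WEIGHTS[0] + arr[..., 1] * GRAY_WEIGHTS[1] + arr[..., 2] * GRAY_WEIGHTS[2]
    return ObjectImage(amplitude=np.clip(lum, 0.0, 1.0))
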