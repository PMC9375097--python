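"""Pupil-mask generators for circular, spiky and radially modulated apertures.

A pupil is a square amplitude-transmission grid. The spiky apertures model a
coronavirus-like pupil: a disc of internal radius ``rho0`` fringed by wedge
shaped protrusions of mean radial extent ``eps_r``, with the internal/external
radius ratio ``alpha = rho0 / (rho0 + eps_r)``. Spikes may be placed at
regular angles or drawn (length and angle) from a seeded RNG; radially
modulated pupils carry a rim-weighted linear or quadratic transmission.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ApertureSpec",
    "PupilMask",
    "make_circular",
    "make_spiky",
    "make_modulated",
    "alpha_ratio",
]

SPIKE_MODES = ("none", "regular", "irregular")
MODULATIONS = ("uniform", "linear", "quadratic")

#: cap on irregular spike length as a multiple of the mean extent eps_r
IRREGULAR_LENGTH_CAP = 1.5


@dataclass(frozen=True)
class ApertureSpec:
    """Parameters defining a pupil mask.

    Parameters
    ----------
    grid_size
        Pixels per side of the (square, even-sized) grid.
    inner_radius
        Internal radius ``rho0`` in pixels: the radius of the solid disc.
    spike_length
        Mean radial extent ``eps_r`` of the spikes beyond ``rho0``, pixels.
    n_spikes
        Number of spikes; zero if and only if ``spike_mode == "none"``.
    spike_mode
        ``"none"``, ``"regular"`` (equal angles, fixed length) or
        ``"irregular"`` (seeded random lengths and jittered angles).
    spike_halfwidth_deg
        Angular half-width of each wedge-shaped spike, degrees.
    modulation
        Radial transmission profile of the disc interior: ``"uniform"``
        (binary), ``"linear"`` (t = rho/rho0) or ``"quadratic"``
        (t = (rho/rho0)**2).
    seed
        RNG seed used by ``"irregular"`` mode.
    """

    grid_size: int
    inner_radius: float
    spike_length: float = 0.0
    n_spikes: int = 0
    spike_mode: str = "none"
    spike_halfwidth_deg: float = 6.0
    modulation: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size <= 0 or self.grid_size % 2 != 0:
            raise ValueError(f"grid_size must be a positive even integer, got {self.grid_size}")
        if self.inner_radius <= 0:
            raise ValueError(f"inner_radius must be positive, got {self.inner_radius}")
        if self.spike_length < 0:
            raise ValueError(f"spike_length must be non-negative, got {self.spike_length}")
        if self.spike_mode not in SPIKE_MODES:
            raise ValueError(f"spike_mode must be one of {SPIKE_MODES}, got {self.spike_mode!r}")
        if self.modulation not in MODULATIONS:
            raise ValueError(f"modulation must be one of {MODULATIONS}, got {self.modulation!r}")
        if (self.n_spikes == 0) != (self.spike_mode == "none"):
            raise ValueError("n_spikes must be 0 exactly when spike_mode is 'none'")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be non-negative")
        if self.inner_radius + self.max_spike_extent >= self.grid_size / 2:
            raise ValueError(
                "aperture does not fit: inner_radius + maximum spike extent "
                f"({self.inner_radius + self.max_spike_extent}) >= grid_size/2 "
                f"({self.grid_size / 2})"
            )

    @property
    def max_spike_extent(self) -> float:
        """Largest radial extent any spike may reach beyond ``inner_radius``."""
        if self.spike_mode == "irregular":
            return IRREGULAR_LENGTH_CAP * self.spike_length
        return self.spike_length if self.spike_mode == "regular" else 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ApertureSpec":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class PupilMask:
    """Amplitude transmission grid with its generating spec.

    ``amplitude`` is a ``grid_size x grid_size`` array of values in [0, 1];
    the aperture is centred at 0-based pixel ``(N/2, N/2)``.
    """

    amplitude: np.ndarray
    spec: ApertureSpec

    @property
    def center(self) -> tuple[int, int]:
        n = self.amplitude.shape[0]
        return (n // 2, n // 2)


def _grids(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Radial and angular coordinate grids about the centre pixel (N/2, N/2)."""
    c = grid_size // 2
    v, u = np.ogrid[:grid_size, :grid_size]
    du = u - c
    dv = v - c
    rho = np.hypot(du, dv)
    theta = np.degrees(np.arctan2(dv, du))  # in (-180, 180]
    return rho, theta


def alpha_ratio(inner_radius: float, spike_length: float) -> float:
    """Internal/external radius ratio ``alpha = rho0 / (rho0 + eps_r)``."""
    if inner_radius <= 0:
        raise ValueError(f"inner_radius must be positive, got {inner_radius}")
    if spike_length < 0:
        raise ValueError(f"spike_length must be non-negative, got {spike_length}")
    return inner_radius / (inner_radius + spike_length)


def make_circular(grid_size: int, inner_radius: float) -> PupilMask:
    """Binary disc pupil: pixel on iff its centre lies within ``inner_radius``.

    Pixel membership uses the closed inequality ``rho <= inner_radius`` on
    integer pixel centres, so masks are bit-reproducible.
    """
    spec = ApertureSpec(grid_size=grid_size, inner_radius=inner_radius)
    if inner_radius >= grid_size / 2:
        raise ValueError("inner_radius must be < grid_size/2")
    rho, _ = _grids(grid_size)
    amplitude = (rho <= inner_radius).astype(np.float64)
    return PupilMask(amplitude=amplitude, spec=spec)


def _angular_distance(theta: np.ndarray, angle: float) -> np.ndarray:
    d = np.abs((theta - angle + 180.0) % 360.0 - 180.0)
    return d


def _spike_geometry(spec: ApertureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-spike (angle_deg, length_px) for regular or irregular placement.

    Regular: equally spaced angles starting at 0 deg, all lengths eps_r.
    Irregular: lengths ~ U(0.5 eps_r, 1.5 eps_r); angles jittered around the
    regular positions by U(-pitch/4, +pitch/4), from the seeded generator.
    """
    n = spec.n_spikes
    pitch = 360.0 / n
    base = np.arange(n) * pitch
    if spec.spike_mode == "regular":
        return base, np.full(n, float(spec.spike_length))
    rng = np.random.default_rng(spec.seed)
    lengths = rng.uniform(0.5 * spec.spike_length, IRREGULAR_LENGTH_CAP * spec.spike_length, n)
    angles = base + rng.uniform(-pitch / 4.0, pitch / 4.0, n)
    return angles, lengths


def make_spiky(spec: ApertureSpec) -> PupilMask:
    """Disc of radius ``rho0`` united with ``n_spikes`` wedge protrusions."""
    if spec.spike_mode not in ("regular", "irregular") or spec.n_spikes < 1:
        raise ValueError("make_spiky requires spike_mode 'regular' or 'irregular' with n_spikes >= 1")
    rho, theta = _grids(spec.grid_size)
    mask = rho <= spec.inner_radius
    angles, lengths = _spike_geometry(spec)
    for angle, length in zip(angles, lengths):
        wedge = (
            (_angular_distance(theta, angle) <= spec.spike_halfwidth_deg)
            & (rho > spec.inner_radius)
            & (rho <= spec.inner_radius + length)
        )
        mask |= wedge
    return PupilMask(amplitude=mask.astype(np.float64), spec=spec)


def make_modulated(
    grid_size: int,
    inner_radius: float,
    modulation: str,
    spec_for_spikes: Optional[ApertureSpec] = None,
) -> PupilMask:
    """Radially modulated pupil, rim-weighted: t = rho/rho0 or (rho/rho0)**2.

    Transmission is zero outside the disc. If ``spec_for_spikes`` is given,
    its spikes are added at full amplitude 1 (the modulated disc of Fig.-5
    type geometry, a linear-distribution aperture fringed with spikes).
    """
    if modulation not in ("linear", "quadratic"):
        raise ValueError(f"modulation must be 'linear' or 'quadratic', got {modulation!r}")
    if not 0 < inner_radius < grid_size / 2:
        raise ValueError("inner_radius must satisfy 0 < inner_radius < grid_size/2")
    rho, _ = _grids(grid_size)
    t = np.clip(rho / inner_radius, 0.0, 1.0)
    if modulation == "quadratic":
        t = t * t
    amplitude = np.where(rho <= inner_radius, t, 0.0)
    spec = ApertureSpec(grid_size=grid_size, inner_radius=inner_radius, modulation=modulation)
    if spec_for_spikes is not None:
        spikes = make_spiky(spec_for_spikes).amplitude
        disc = make_circular(spec_for_spikes.grid_size, spec_for_spikes.inner_radius).amplitude
        amplitude = np.maximum(amplitude, spikes - disc)
        spec = dataclasses.replace(
            spec_for_spikes, modulation=modulation, inner_radius=inner_radius, grid_size=grid_size
        )
    return PupilMask(amplitude=amplitude, spec=spec)
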