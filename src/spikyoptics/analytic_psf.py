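"""Closed-form and quadrature radial amplitude PSFs, and the cutoff metric.

The radial amplitude point spread function of a circularly symmetric pupil
with transmission t(s), s = rho/rho0 in [0, 1], is the Hankel-type integral

    h(w)  proportional to  integral_0^1 t(s) J0(w s) s ds,

with the reduced image-plane coordinate w = 2 pi rho0 r / (f lambda).
Special cases in closed form:

* uniform disc (Airy amplitude)          h(w) = 2 J1(w)/w
* spiky pupil, thin-annulus approximation h(w) = 2 J1(w)/w + beta J0(w)
* confocal effective profile              h(w) = [2 J1(w)/w]^2 + beta J0(w) 2 J1(w)/w

The resolution figure of merit W_c is the reduced coordinate of the first
local minimum of the normalized amplitude profile after the central lobe
(for the Airy amplitude this is the first positive root of J2, 5.1356).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "OpticalConfig",
    "AmplitudeProfile",
    "CutoffResult",
    "CutoffNotFoundError",
    "airy",
    "airy_derivative",
    "spiky_approx",
    "spiky_approx_derivative",
    "annular_exact",
    "confocal_heff",
    "radial_hankel_psf",
    "normalize",
    "find_cutoff",
    "cutoff",
]

_SMALL_W = 1e-8
DEFAULT_BETA = 0.5


class CutoffNotFoundError(RuntimeError):
    """No post-lobe local minimum exists on the sampled grid."""


@dataclass(frozen=True)
class OpticalConfig:
    """Focal length and wavelength; they enter only through the reduced
    coordinate w = 2 pi rho0 r / (f lambda)."""

    focal_length: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.focal_length <= 0 or self.wavelength <= 0:
            raise ValueError("focal_length and wavelength must be positive")

    def reduced_coordinate(self, r: np.ndarray, rho0: float) -> np.ndarray:
        return 2.0 * np.pi * rho0 * np.asarray(r) / (self.focal_length * self.wavelength)


@dataclass(frozen=True)
class AmplitudeProfile:
    """1-D amplitude PSF h(w) sampled on a strictly increasing w grid."""

    w_grid: np.ndarray
    h_values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.w_grid, dtype=float)
        h = np.asarray(self.h_values, dtype=float)
        if w.shape != h.shape or w.ndim != 1:
            raise ValueError("w_grid and h_values must be 1-D arrays of equal length")
        if w.size >= 2 and not np.all(np.diff(w) > 0):
            raise ValueError("w_grid must be strictly increasing")


@dataclass(frozen=True)
class CutoffResult:
    """First post-lobe local minimum W_c of a normalized amplitude profile."""

    W_c: float
    bracket: tuple[float, float]
    tolerance: float


def airy(w):
    """Airy amplitude 2 J1(w)/w of the uniform circular pupil; airy(0) = 1."""
    w = np.asarray(w, dtype=float)
    small = np.abs(w) < _SMALL_W
    safe = np.where(small, 1.0, w)
    out = np.where(small, 1.0 - w * w / 8.0, 2.0 * special.jv(1, safe) / safe)
    return out if out.ndim else float(out)


def airy_derivative(w):
    """d/dw [2 J1(w)/w] = -2 J2(w)/w (odd, zero at w = 0)."""
    w = np.asarray(w, dtype=float)
    small = np.abs(w) < _SMALL_W
    safe = np.where(small, 1.0, w)
    out = np.where(small, -w / 4.0, -2.0 * special.jv(2, safe) / safe)
    return out if out.ndim else float(out)


def _check_beta(beta: float) -> None:
    if not 0.0 <= beta < 1.0:
        raise ValueError(f"beta must be in [0, 1), got {beta}")


def spiky_approx(w, beta: float = DEFAULT_BETA):
    """Spiky-pupil amplitude in the thin-annulus approximation.

    h(w) = 2 J1(w)/w + beta J0(w), un-normalized (value 1 + beta at w = 0).
    The beta-weighted J0 term is the contribution of the spiky fringe,
    modelled as a thin annulus of random surface.
    """
    _check_beta(beta)
    out = airy(w) + beta * special.jv(0, w)
    return out if np.ndim(out) else float(out)


def spiky_approx_derivative(w, beta: float = DEFAULT_BETA):
    """d/dw of :func:`spiky_approx`, using d/dw J0 = -J1."""
    _check_beta(beta)
    out = airy_derivative(w) - beta * special.jv(1, w)
    return out if np.ndim(out) else float(out)


def annular_exact(w, alpha: float, eps_over_rho: float):
    """Exact spiky-pupil amplitude with the annular fringe term as printed:

    h(w) = 2 J1(w)/w + 2/(1 - alpha^2) [ J1(w1)/w1 - alpha J1(w)/w ],

    with w1 = w (1 + eps_r/rho0) and alpha = rho0/(rho0 + eps_r). The two
    parameters are redundant and must agree to 1e-9.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if eps_over_rho <= 0:
        raise ValueError(f"eps_over_rho must be positive, got {eps_over_rho}")
    if abs(alpha - 1.0 / (1.0 + eps_over_rho)) > 1e-9:
        raise ValueError(
            f"inconsistent parameters: alpha={alpha} but 1/(1+eps_over_rho)="
            f"{1.0 / (1.0 + eps_over_rho)}"
        )
    w = np.asarray(w, dtype=float)
    w1 = w * (1.0 + eps_over_rho)
    a = np.asarray(airy(w))
    a1 = np.asarray(airy(w1))
    out = a + (2.0 / (1.0 - alpha**2)) * (0.5 * a1 - alpha * 0.5 * a)
    return out if out.ndim else float(out)


def confocal_heff(w, beta: float = DEFAULT_BETA):
    """Effective confocal amplitude profile for spiky illumination and
    circular detection pupils:

    h_eff(w) = [2 J1(w)/w]^2 + beta J0(w) 2 J1(w)/w  (1 + beta at w = 0).
    """
    _check_beta(beta)
    a = airy(w)
    out = a * a + beta * special.jv(0, w) * a
    return out if np.ndim(out) else float(out)


def confocal_heff_derivative(w, beta: float = DEFAULT_BETA):
    _check_beta(beta)
    a, da = airy(w), airy_derivative(w)
    j0, j1 = special.jv(0, w), special.jv(1, w)
    out = 2.0 * a * da + beta * (-j1 * a + j0 * da)
    return out if np.ndim(out) else float(out)


def radial_hankel_psf(
    transmission: Callable[[float], float],
    w_grid: np.ndarray,
    *,
    quad_tol: float = 1e-10,
) -> AmplitudeProfile:
    """Amplitude PSF of an arbitrary radial transmission by quadrature.

    Evaluates h(w) = 2 * integral_0^1 t(s) J0(w s) s ds at every grid point
    with adaptive quadrature and normalizes so h(0) = 1. The factor 2 makes
    t == 1 reduce to the Airy amplitude 2 J1(w)/w exactly.
    """
    w_grid = np.asarray(w_grid, dtype=float)

    def integrand_at(w: float) -> float:
        val, err = integrate.quad(
            lambda s: transmission(s) * special.jv(0, w * s) * s,
            0.0,
            1.0,
            epsabs=quad_tol,
            epsrel=quad_tol,
            limit=200,
        )
        if not np.isfinite(val) or err > max(1e-6, 1e-4 * abs(val)):
            raise ArithmeticError(
                f"quadrature failed at w={w}: value={val}, error estimate={err}"
            )
        return 2.0 * val

    h0 = integrand_at(0.0)
    if h0 == 0.0:
        raise ArithmeticError("degenerate transmission: h(0) = 0, cannot normalize")
    h = np.array([integrand_at(w) for w in w_grid]) / h0
    return AmplitudeProfile(w_grid=w_grid, h_values=h, normalized=True)


def normalize(profile: AmplitudeProfile) -> AmplitudeProfile:
    """Scale a profile so its value at w = 0 is 1 (idempotent).

    If the grid does not contain w = 0 exactly, the sample closest to zero
    is used; profiles in scope peak at the origin.
    """
    if profile.normalized:
        return profile
    idx = int(np.argmin(np.abs(profile.w_grid)))
    h0 = profile.h_values[idx]
    if h0 == 0.0:
        raise ZeroDivisionError("degenerate profile: h(0) = 0")
    return AmplitudeProfile(
        w_grid=profile.w_grid, h_values=profile.h_values / h0, normalized=True
    )


def _refine_parabolic(w: np.ndarray, h: np.ndarray, i: int) -> float:
    """Vertex of the parabola through the three samples around index i."""
    x0, x1, x2 = w[i - 1], w[i], w[i + 1]
    y0, y1, y2 = h[i - 1], h[i], h[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a <= 0:
        return float(x1)
    return float(-b / (2.0 * a))


def find_cutoff(
    profile: AmplitudeProfile,
    derivative: Optional[Callable[[float], float]] = None,
    h_func: Optional[Callable[[float], float]] = None,
    tol: float = 1e-6,
) -> CutoffResult:
    """Locate W_c, the first local minimum of h(w) after the central lobe.

    Scans the normalized profile for w > 0 for the first sign change of the
    discrete derivative from negative to non-negative, then refines inside
    the bracketing interval: with the analytic ``derivative`` (or a central
    difference of ``h_func``, step 1e-4) by Brent root-finding to ``tol``;
    otherwise by the parabola through the three bracketing samples.
    """
    prof = normalize(profile)
    w, h = prof.w_grid, prof.h_values
    pos = w > 0
    w, h = w[pos], h[pos]
    if w.size < 3:
        raise CutoffNotFoundError("profile too short to contain a local minimum")
    dh = np.diff(h)
    idx = np.nonzero((dh[:-1] < 0) & (dh[1:] >= 0))[0]
    if idx.size == 0:
        raise CutoffNotFoundError("no local minimum found on the sampled grid")
    i = int(idx[0]) + 1  # h[i] is the discrete minimum; bracket (w[i-1], w[i+1])
    lo, hi = float(w[i - 1]), float(w[i + 1])
    if derivative is None and h_func is not None:
        step = 1e-4
        derivative = lambda x: (h_func(x + step) - h_func(x - step)) / (2 * step)
    if derivative is not None and derivative(lo) < 0 and derivative(hi) > 0:
        wc = float(optimize.brentq(derivative, lo, hi, xtol=tol))
    else:
        wc = _refine_parabolic(w, h, i)
    return CutoffResult(W_c=wc, bracket=(lo, hi), tolerance=tol)


_MODEL_TRANSMISSION = {"linear": lambda s: s, "quadratic": lambda s: s * s}


def cutoff(
    model: str,
    beta: float = DEFAULT_BETA,
    w_max: float = 4.0 * np.pi,
    step: float = 0.005,
    tol: float = 1e-6,
) -> CutoffResult:
    """Cutoff W_c for a named pupil model.

    ``model`` is one of ``"circular"`` (or ``"airy"``), ``"spiky"`` (uses
    ``beta``), ``"linear"`` or ``"quadratic"`` (rim-weighted modulated
    pupils, evaluated by quadrature).
    """
    w = np.arange(step, w_max + step / 2, step)
    if model in ("circular", "airy"):
        prof = AmplitudeProfile(w, airy(w), normalized=True)
        return find_cutoff(prof, derivative=airy_derivative, tol=tol)
    if model == "spiky":
        prof = normalize(AmplitudeProfile(np.concatenate(([0.0], w)),
                                          spiky_approx(np.concatenate(([0.0], w)), beta)))
        return find_cutoff(prof, derivative=lambda x: spiky_approx_derivative(x, beta), tol=tol)
    if model in _MODEL_TRANSMISSION:
        t = _MODEL_TRANSMISSION[model]
        prof = radial_hankel_psf(t, w)

        def h_func(x: float) -> float:
            val, _ = integrate.quad(lambda s: t(s) * special.jv(0, x * s) * s, 0.0, 1.0,
                                    epsabs=1e-12, epsrel=1e-12, limit=200)
            return val

        return find_cutoff(prof, h_func=h_func, tol=tol)
    raise ValueError(f"unknown model {model!r}; expected circular/airy, spiky, linear, quadratic")
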