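"""Deterministic mathematics of the cusp catastrophe.

The cusp is the simplest catastrophe with two control parameters: an
*asymmetry* parameter ``alpha`` that tilts the system smoothly toward high
or low states, and a *bifurcation* parameter ``beta`` that, past a critical
value, splits a single stable state into two coexisting attractors.  The
potential is

    f(y; alpha, beta) = alpha*y + (1/2)*beta*y**2 - (1/4)*y**4

whose stationary points solve ``-y**3 + beta*y + alpha = 0``.  The
stochastic counterpart is the quartic-exponential density

    p(y) = exp(f(y; alpha, beta)) / Z(alpha, beta)

with ``Z`` obtained by numerical quadrature; its modes coincide with the
stable equilibria of the deterministic system, so bimodality of the density
and multistability of the dynamics are the same statement.

This module is pure in-memory numerics: potential, equilibria with
stability labels, the Cardan discriminant delineating the bifurcation set,
the normalized density, its quadrature moments, and mode finding.  A
vectorized fixed-order Gauss-Legendre path is provided for likelihood code
that must evaluate thousands of (alpha, beta) pairs per iteration; it is
tested against the adaptive-quadrature path.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "CuspControlPoint",
    "EquilibriumSet",
    "QuadratureError",
    "potential",
    "cardan_discriminant",
    "equilibria",
    "log_norm_const",
    "cusp_pdf",
    "cusp_moments",
    "density_modes",
    "batch_log_norm_and_moments",
]

#: Boundary tolerance on the Cardan discriminant below which the control
#: point is treated as lying on a fold line (root multiplicity collapsed).
DISCRIMINANT_TOL = 1e-9


class QuadratureError(RuntimeError):
    """Raised when the normalizing-constant quadrature fails to converge."""


@dataclass(frozen=True)
class CuspControlPoint:
    """A point (alpha, beta) in the control plane."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("control parameters must be finite")


@dataclass(frozen=True)
class EquilibriumSet:
    """Real stationary points of the cusp potential, ascending, with labels.

    One root (outside the bifurcation set) is stable; three roots (inside)
    bracket an unstable middle state between two attractors.  On the fold
    lines the degenerate double root is labelled unstable.
    """

    roots: tuple[float, ...]
    stability: tuple[Literal["stable", "unstable"], ...]

    @property
    def stable_roots(self) -> tuple[float, ...]:
        return tuple(r for r, s in zip(self.roots, self.stability) if s == "stable")


def potential(y, alpha, beta):
    """Cusp potential f(y) = alpha*y + beta*y^2/2 - y^4/4 (vectorized)."""
    y = np.asarray(y, dtype=float)
    return alpha * y + 0.5 * beta * y * y - 0.25 * y ** 4


def cardan_discriminant(alpha: float, beta: float) -> float:
    """Cardan discriminant delta = 27*alpha^2 - 4*beta^3.

    delta < 0: three real equilibria (inside the bifurcation set, bimodal);
    delta > 0: one; delta = 0: fold boundary.
    """
    return 27.0 * alpha ** 2 - 4.0 * beta ** 3


def _polish_root(y: float, alpha: float, beta: float) -> float:
    # Newton steps on g(y) = y^3 - beta*y - alpha; safeguarded derivative.
    for _ in range(50):
        g = y ** 3 - beta * y - alpha
        dg = 3.0 * y * y - beta
        if abs(dg) < 1e-14:
            break
        step = g / dg
        y -= step
        if abs(step) < 1e-13 * max(1.0, abs(y)):
            break
    return y


def equilibria(alpha: float, beta: float) -> EquilibriumSet:
    """All real roots of -y^3 + beta*y + alpha = 0 with stability labels.

    Stability is read from the curvature of the potential: a root is stable
    when f''(y) = beta - 3*y^2 < 0 (a local maximum of f, hence a density
    mode), which for three distinct roots singles out the outer pair.
    """
    delta = cardan_discriminant(alpha, beta)
    raw = np.roots([1.0, 0.0, -beta, -alpha])
    scale = max(1.0, float(np.max(np.abs(raw))))
    real = sorted(_polish_root(float(r.real), alpha, beta)
                  for r in raw if abs(r.imag) < 1e-7 * scale)
    # collapse numerically coincident roots (fold-line degeneracy)
    merged: list[float] = []
    for r in real:
        if merged and abs(r - merged[-1]) < 1e-6 * max(1.0, abs(r)):
            continue
        merged.append(r)
    if abs(delta) >= DISCRIMINANT_TOL and len(merged) == 2:
        # roots distinct analytically but nearly merged numerically
        merged = real[:1] + real[-1:]

    if len(merged) == 3:
        stability = ("stable", "unstable", "stable")
    elif len(merged) == 1:
        stability = ("stable",)
    else:  # fold boundary: simple root stable, double root degenerate
        stability = tuple(
            "stable" if (beta - 3.0 * r * r) < -1e-9 else "unstable" for r in merged
        )
    return EquilibriumSet(roots=tuple(merged), stability=stability)


def _tail_bound(alpha: float, beta: float) -> float:
    # smallest L (>= 10) with f(±L) - f(peak) < -700, so the tails are
    # numerically zero in double precision
    L = 10.0
    fpeak = max(potential(r, alpha, beta) for r in equilibria(alpha, beta).roots)
    while L < 1e4:
        if max(potential(L, alpha, beta), potential(-L, alpha, beta)) - fpeak < -700:
            return L
        L *= 1.5
    raise QuadratureError(f"no integrable tail bound for alpha={alpha}, beta={beta}")


@functools.lru_cache(maxsize=100_000)
def log_norm_const(alpha: float, beta: float) -> float:
    """log of Z(alpha, beta) = integral exp(f(y)) dy over the real line.

    Adaptive quadrature on [-L, L] with L chosen so the discarded tails are
    below double-precision resolution; the integrand is shifted by the peak
    potential for overflow safety and the equilibria are passed as
    break-points.  Results are cached per control point.
    """
    eq = equilibria(alpha, beta)
    fpeak = max(potential(r, alpha, beta) for r in eq.roots)
    L = _tail_bound(alpha, beta)
    pts = [r for r in eq.roots if -L < r < L]
    val, err = integrate.quad(
        lambda y: math.exp(potential(y, alpha, beta) - fpeak),
        -L, L, points=pts, limit=200, epsabs=1e-12, epsrel=1e-11,
    )
    if not np.isfinite(val) or val <= 0 or err > 1e-7 * val:
        raise QuadratureError(
            f"normalization quadrature failed at alpha={alpha}, beta={beta}: "
            f"value={val}, abs err={err}"
        )
    return fpeak + math.log(val)


def cusp_pdf(y, alpha: float, beta: float):
    """Normalized quartic-exponential density exp(f(y))/Z (vectorized in y)."""
    return np.exp(potential(y, alpha, beta) - log_norm_const(alpha, beta))


def cusp_moments(alpha: float, beta: float) -> tuple[float, float]:
    """Mean and variance of the cusp density by adaptive quadrature."""
    L = _tail_bound(alpha, beta)
    pts = [r for r in equilibria(alpha, beta).roots if -L < r < L]
    logz = log_norm_const(alpha, beta)

    def moment(k: int) -> float:
        val, _ = integrate.quad(
            lambda y: y ** k * math.exp(potential(y, alpha, beta) - logz),
            -L, L, points=pts, limit=200,
        )
        return val

    mean = moment(1)
    var = moment(2) - mean * mean
    if var <= 0:
        raise QuadratureError(f"non-positive variance at alpha={alpha}, beta={beta}")
    return mean, var


def density_modes(alpha: float, beta: float) -> list[float]:
    """Locations of the local maxima of the cusp density, ascending.

    The density modes are exactly the stable equilibria of the potential
    (the density is a monotone transform exp(f) of f), so this returns the
    stable-labelled roots: one mode outside the bifurcation set, two inside.
    """
    return list(equilibria(alpha, beta).stable_roots)


# ---------------------------------------------------------------------------
# Vectorized fixed-order quadrature for likelihood evaluation.
# ---------------------------------------------------------------------------

_GL_ORDER = 512
_GL_HALF_WIDTH = 13.0  # |y| beyond which exp(f) underflows for |alpha|,|beta| <~ 30


@functools.lru_cache(maxsize=4)
def _gl_rule(order: int = _GL_ORDER, half_width: float = _GL_HALF_WIDTH):
    x, w = np.polynomial.legendre.leggauss(order)
    return x * half_width, w * half_width


def batch_log_norm_and_moments(alpha, beta):
    """Vectorized (log Z, E[Y], E[Y^2]) for arrays of control points.

    Fixed-order Gauss-Legendre on [-13, 13]; accurate to better than 1e-8
    relative for |alpha|, |beta| <= 20 (checked against the adaptive path).
    Intended for likelihood code that revisits many (alpha, beta) pairs.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    y, w = _gl_rule()
    f = alpha[:, None] * y + 0.5 * beta[:, None] * y ** 2 - 0.25 * y ** 4
    fmax = f.max(axis=1)
    e = np.exp(f - fmax[:, None])
    z0 = e @ w
    logz = fmax + np.log(z0)
    ey = (e @ (w * y)) / z0
    ey2 = (e @ (w * y * y)) / z0
    return logz, ey, ey2
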