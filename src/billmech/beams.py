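"""Closed-form performance metrics for solid elliptical beams.

A bird maxilla scaled to a common length is idealised as a solid
elliptical cantilever of half-width ``a`` (x axis) and half-depth ``b``
(y axis).  Two scalar metrics summarise excavation performance:

* **critical buckling stress** ``sigma_cr`` — the Euler buckling load of
  a column fixed at one end and free at the other (effective length
  factor K = 2) divided by the section area; the impact-performance
  analogue (higher is better);
* **maximum surface shear stress** ``tau_max`` — the peak shear on the
  surface of the elliptical shaft twisted by a fixed small angle theta;
  the torsion-performance analogue (higher is worse).

Note on the torsion formula: combining ``tau_max = 2T/(pi a b^2)`` with
the elliptical-shaft torque ``T = pi G theta a^3 b^3 / ((a^2+b^2) L)``
cancels the factor pi, giving ``tau_max = 2 G theta a^2 b /((a^2+b^2) L)``.
This self-consistent form is used throughout; it reduces to the circular
shaft ``G theta r / L`` at a = b = r.  Any fixed multiplicative constant
is irrelevant for the rank-based comparative statistics downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeamGeometry",
    "BeamMetrics",
    "second_moment",
    "euler_critical_load",
    "critical_buckling_stress",
    "shear_modulus",
    "resultant_torque",
    "max_shear_stress",
    "beam_metrics",
    "performance_grid",
]


@dataclass(frozen=True)
class BeamGeometry:
    """Solid elliptical section: half-width ``a``, half-depth ``b``, length ``L`` (m)."""

    a: float
    b: float
    L: float = 0.05
    K: float = 2.0  # effective length factor; 2 = fixed-free column

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.L > 0):
            raise ValueError("a, b and L must all be positive")
        if self.K <= 0:
            raise ValueError("effective length factor K must be positive")

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    @property
    def second_moment_x(self) -> float:
        return second_moment(self.a, self.b)


@dataclass(frozen=True)
class BeamMetrics:
    """Performance metrics for one beam (SI units)."""

    P_cr: float  # Euler critical load, N
    sigma_cr: float  # critical buckling stress, Pa
    T: float  # resultant internal torque at twist theta, N m
    tau_max: float  # maximum surface shear stress, Pa
    G: float  # shear modulus used, Pa


def second_moment(a, b):
    """Second moment of area about the x axis, ``I_x = pi a b^3 / 4``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("half-axes must be positive")
    return np.pi * a * b**3 / 4.0


def euler_critical_load(E, a, b, L, K=2.0):
    """Euler critical load ``P_cr = pi^2 E I_x / (K L)^2`` of the elliptical column."""
    if np.any(np.asarray(E) <= 0) or np.any(np.asarray(L) <= 0) or K <= 0:
        raise ValueError("E, L and K must be positive")
    return np.pi**2 * E * second_moment(a, b) / (K * np.asarray(L, dtype=float)) ** 2


def critical_buckling_stress(E, b, L):
    """Critical buckling stress ``sigma_cr = pi^2 E b^2 / (16 L^2)``.

    Equals ``P_cr / (pi a b)`` for K = 2 — independent of the half-width
    ``a``: only section depth protects a fixed-free column from buckling.
    """
    b = np.asarray(b, dtype=float)
    if np.any(np.asarray(E) <= 0) or np.any(np.asarray(L) <= 0) or np.any(b < 0):
        raise ValueError("E and L must be positive, b non-negative")
    return np.pi**2 * E * b**2 / (16.0 * np.asarray(L, dtype=float) ** 2)


def shear_modulus(E, nu):
    """Isotropic shear modulus ``G = E / (2 (1 + nu))``."""
    return np.asarray(E, dtype=float) / (2.0 * (1.0 + np.asarray(nu, dtype=float)))


def resultant_torque(G, theta, a, b, L):
    """Internal torque of an elliptical shaft at twist ``theta``:
    ``T = pi G theta a^3 b^3 / ((a^2 + b^2) L)``."""
    G = np.asarray(G, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(G <= 0) or np.any(a <= 0) or np.any(b <= 0) or np.any(np.asarray(L) <= 0):
        raise ValueError("G, a, b, L must be positive")
    return np.pi * G * theta * a**3 * b**3 / ((a**2 + b**2) * np.asarray(L, dtype=float))


def max_shear_stress(E, nu, theta, a, b, L):
    """Maximum surface shear of the twisted elliptical shaft.

    ``tau_max = 2 T / (pi a b^2) = 2 G theta a^2 b / ((a^2 + b^2) L)``
    with ``G = E / (2 (1 + nu))``.  The classical maximum sits at
    (x, y) = (0, b) for b < a; the formula is evaluated regardless of the
    aspect ratio, which is the convention adopted for bills whose depth
    may exceed their width.
    """
    G = shear_modulus(E, nu)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return 2.0 * G * theta * a**2 * b / ((a**2 + b**2) * np.asarray(L, dtype=float))


def beam_metrics(E: float, nu: float, theta: float, geom: BeamGeometry) -> BeamMetrics:
    """All metrics for one beam under material (E, nu) and twist theta."""
    G = float(shear_modulus(E, nu))
    P = float(euler_critical_load(E, geom.a, geom.b, geom.L, geom.K))
    return BeamMetrics(
        P_cr=P,
        sigma_cr=P / geom.area,
        T=float(resultant_torque(G, theta, geom.a, geom.b, geom.L)),
        tau_max=float(max_shear_stress(E, nu, theta, geom.a, geom.b, geom.L)),
        G=G,
    )


def performance_grid(a_range, b_range, E, nu, theta, L, n_grid):
    """Theoretical performance space over a (half-width, half-depth) grid.

    Returns ``(a_grid, b_grid, sigma_cr, tau_max)`` where the matrices are
    ``n_grid x n_grid`` with rows indexed by b and columns by a.  sigma_cr
    is constant along each row (it does not depend on a).
    """
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    a_lo, a_hi = a_range
    b_lo, b_hi = b_range
    if a_lo <= 0 or b_lo <= 0 or a_hi <= a_lo or b_hi <= b_lo:
        raise ValueError("ranges must be positive and increasing")
    a = np.linspace(a_lo, a_hi, n_grid)
    b = np.linspace(b_lo, b_hi, n_grid)
    A, B = np.meshgrid(a, b)
    sigma = critical_buckling_stress(E, B, L)
    tau = max_shear_stress(E, nu, theta, A, B, L)
    return A, B, sigma, tau


def grid_to_frame(A, B, sigma, tau):
    """Long-format table (width, depth, sigma_cr, tau_max) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "width": 2.0 * A.ravel(),
            "depth": 2.0 * B.ravel(),
            "sigma_cr": np.asarray(sigma).ravel(),
            "tau_max": np.asarray(tau).ravel(),
        }
    )
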