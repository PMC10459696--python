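"""Closed-form groundwater transport of an instantaneous line-source spill.

An accidental spill forms a vertical line source (length ``b``) at the
origin of a homogeneous aquifer.  The plume advects with the linear
groundwater velocity ``V_fx = k*g/n`` (Darcy), disperses longitudinally
and laterally (no vertical dispersion: the source spans the saturated
thickness), and is retarded by a factor ``F >= 1`` representing weak
particle-medium interaction.  The 2-D Gaussian solution gives the full
concentration field; the peak concentration at a receptor distance ``L``
and its arrival time follow in closed form.

Unit convention (fixed package-wide): mass in µg, lengths in m, time in
days.  Concentration is then µg/m³, numerically identical to ng/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SourceSpec",
    "AquiferDraw",
    "TransportSolution",
    "dispersivity_x",
    "dispersivity_y",
    "linear_velocity",
    "darcy_velocity",
    "arrival_time",
    "peak_concentration",
    "concentration_field",
    "solve_transport",
]

#: ratio of lateral to longitudinal dispersivity
LATERAL_RATIO = 0.1


@dataclass(frozen=True)
class SourceSpec:
    """Spill source: total mass (µg), vertical source length b (m) and
    along-flow distance L (m) to the receptor."""

    mass: float
    source_length_b: float
    distance_L: float

    def __post_init__(self) -> None:
        for fname in ("mass", "source_length_b", "distance_L"):
            if not getattr(self, fname) > 0:
                raise ValueError(f"SourceSpec.{fname} must be > 0, got {getattr(self, fname)}")


@dataclass(frozen=True)
class AquiferDraw:
    """One realization of the aquifer parameters."""

    porosity_n: float
    gradient_g: float
    conductivity_k: float
    retardation_F: float

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity_n < 1.0:
            raise ValueError(f"porosity must lie in (0, 1), got {self.porosity_n}")
        if not self.gradient_g > 0:
            raise ValueError(f"hydraulic gradient must be > 0, got {self.gradient_g}")
        if not self.conductivity_k > 0:
            raise ValueError(f"hydraulic conductivity must be > 0, got {self.conductivity_k}")
        if not self.retardation_F >= 1.0:
            raise ValueError(f"retardation factor must be >= 1, got {self.retardation_F}")


@dataclass(frozen=True)
class TransportSolution:
    """Deterministic transport outputs for one draw."""

    alpha_x: float  # longitudinal dispersivity, m
    alpha_y: float  # lateral dispersivity, m
    velocity_Vfx: float  # linear groundwater velocity, m/day
    darcy_q: float  # Darcy velocity, m/day
    Dx: float  # longitudinal dispersion coefficient, m²/day
    Dy: float  # lateral dispersion coefficient, m²/day
    c_max: float  # peak concentration at L, µg/m³ == ng/L
    t_max: float  # arrival time of the peak, days


def dispersivity_x(x) -> float:
    """Longitudinal dispersivity from the scale-dependent field
    correlation ``alpha_x = 0.83 * (log10 x)**2.414`` (x in metres).

    Only defined for travel distances beyond 1 m, where the correlation
    is positive.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 1.0):
        raise ValueError("dispersivity correlation requires distance x > 1 m")
    out = 0.83 * np.log10(x) ** 2.414
    return float(out) if out.ndim == 0 else out


def dispersivity_y(x) -> float:
    """Lateral dispersivity: one tenth of the longitudinal value."""
    return dispersivity_x(x) * LATERAL_RATIO


def darcy_velocity(k, g):
    """Darcy velocity q = k*g (m/day)."""
    return np.asarray(k, dtype=float) * np.asarray(g, dtype=float)


def linear_velocity(k, g, n):
    """Linear (seepage) groundwater velocity V_fx = k*g/n (m/day)."""
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0) or np.any(n >= 1):
        raise ValueError("porosity must lie in (0, 1)")
    return darcy_velocity(k, g) / n


def arrival_time(L, F, Vfx):
    """Arrival time of the retarded plume centre at distance L:
    t_max = L*F/V_fx (days)."""
    Vfx = np.asarray(Vfx, dtype=float)
    if np.any(Vfx <= 0):
        raise ValueError("linear velocity must be > 0")
    return np.asarray(L, dtype=float) * np.asarray(F, dtype=float) / Vfx


def peak_concentration(src: SourceSpec, aq: AquiferDraw | None = None, *,
                       n=None, F=None) -> float:
    """Peak concentration (ng/L) at the receptor distance L.

    Evaluates ``C_max = m / (4*pi*b*n*F*L*sqrt(alpha_x*alpha_y))``, the
    plume-centre concentration at the moment the retarded centre passes
    x = L.  ``aq`` may be replaced by vectorized ``n`` and ``F`` keyword
    arrays for ensemble use (C_max depends on no other aquifer field).
    """
    if aq is not None:
        n, F = aq.porosity_n, aq.retardation_F
    if n is None or F is None:
        raise TypeError("peak_concentration needs an AquiferDraw or n= and F=")
    n = np.asarray(n, dtype=float)
    F = np.asarray(F, dtype=float)
    L = src.distance_L
    ax = dispersivity_x(L)
    ay = ax * LATERAL_RATIO
    out = src.mass / (4.0 * np.pi * src.source_length_b * n * F * L * np.sqrt(ax * ay))
    return float(out) if out.ndim == 0 else out


def concentration_field(x, y, t, src: SourceSpec, aq: AquiferDraw):
    """Concentration C(x, y, t) in µg/m³ at time t (days) after the spill.

    2-D Gaussian plume of an instantaneous vertical line source, uniform
    in z:

        C = m / (4*pi*b*n*t*sqrt(Dx*Dy))
            * exp(-(x - Vfx*t/F)²/(4*Dx*t/F) - y²/(4*Dy*t/F))
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time since spill must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ax = dispersivity_x(src.distance_L)
    ay = ax * LATERAL_RATIO
    Vfx = linear_velocity(aq.conductivity_k, aq.gradient_g, aq.porosity_n)
    Dx = ax * Vfx
    Dy = ay * Vfx
    F = aq.retardation_F
    prefactor = src.mass / (4.0 * np.pi * src.source_length_b * aq.porosity_n * t * np.sqrt(Dx * Dy))
    expo = -((x - Vfx * t / F) ** 2) / (4.0 * Dx * t / F) - y ** 2 / (4.0 * Dy * t / F)
    out = prefactor * np.exp(expo)
    return float(out) if out.ndim == 0 else out


def solve_transport(src: SourceSpec, aq: AquiferDraw) -> TransportSolution:
    """Full deterministic transport solution for one aquifer draw."""
    ax = dispersivity_x(src.distance_L)
    ay = ax * LATERAL_RATIO
    q = darcy_velocity(aq.conductivity_k, aq.gradient_g)
    Vfx = q / aq.porosity_n
    t_max = arrival_time(src.distance_L, aq.retardation_F, Vfx)
    c_max = peak_concentration(src, aq)
    return TransportSolution(
        alpha_x=float(ax),
        alpha_y=float(ay),
        velocity_Vfx=float(Vfx),
        darcy_q=float(q),
        Dx=float(ax * Vfx),
        Dy=float(ay * Vfx),
        c_max=float(c_max),
        t_max=float(t_max),
    )
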