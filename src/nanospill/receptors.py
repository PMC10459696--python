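"""Receptor mixing: from the groundwater peak to a river or wetland C0.

River path: the lateral Gaussian profile at the discharge point is
averaged over the plume width W = 4*sqrt(2*alpha_y*L) (95% of the
Gaussian mass), giving the section-average concentration
C_D = sqrt(pi/8)*erf(sqrt(2))*C_max ≈ 0.5981*C_max.  The aquifer
discharges Q_D = q*W*b into the river; an in-stream mass balance with
the river flow Q_R yields the mixed concentration C0.

Wetland path: contaminated groundwater pumped at q_w for a time t_m into
a perfectly mixed wetland of volume V dilutes the peak by the dilution
factor DF = q_w*t_m/V, so C0 = C_max*DF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .distributions import DistributionSpec

__all__ = [
    "SECTION_AVERAGE_COEFF",
    "section_average_coefficient",
    "RiverReceptor",
    "WetlandReceptor",
    "RiverMixingSolution",
    "plume_width",
    "section_average_concentration",
    "discharge_flow",
    "river_mixing",
    "dilution_factor",
    "wetland_concentration",
    "evapo_supply",
    "SECONDS_PER_DAY",
]

SECONDS_PER_DAY = 86_400.0


def section_average_coefficient() -> float:
    """Exact C_D/C_max ratio: sqrt(pi/8)*erf(sqrt(2)) = 0.5981..."""
    return float(np.sqrt(np.pi / 8.0) * erf(np.sqrt(2.0)))


#: section-average concentration as a fraction of the plume peak
SECTION_AVERAGE_COEFF = section_average_coefficient()


@dataclass(frozen=True)
class RiverReceptor:
    """River mixing parameters (all flows in m³/day).

    ``flow_QR`` may also be supplied as a DistributionSpec at the
    scenario level; this dataclass holds one realized value.  Upstream
    concentration defaults to zero (no nanoparticles upstream of the
    discharge point) and the upstream flow defaults to the downstream
    flow.
    """

    flow_QR: float
    upstream_concentration: float = 0.0
    upstream_flow_QR_prime: float | None = None

    def __post_init__(self) -> None:
        if not self.flow_QR > 0:
            raise ValueError(f"river flow must be > 0, got {self.flow_QR}")
        if self.upstream_concentration < 0:
            raise ValueError("upstream concentration must be >= 0")


@dataclass(frozen=True)
class WetlandReceptor:
    """Wetland dilution parameters.

    Either the (volume, supply flow, mixing time) triple or a direct
    dilution-factor DistributionSpec may be given; the triple route must
    satisfy q_w*t_m <= V so the pumped pulse fits the mixed volume.
    """

    volume_V: float | None = None
    supply_qw: float | None = None
    mixing_time_tm: float | None = None
    dilution_spec: DistributionSpec | None = None

    def __post_init__(self) -> None:
        if self.dilution_spec is None:
            if None in (self.volume_V, self.supply_qw, self.mixing_time_tm):
                raise ValueError(
                    "WetlandReceptor needs either dilution_spec or all of "
                    "volume_V, supply_qw, mixing_time_tm"
                )
            if not self.volume_V > 0:
                raise ValueError("wetland volume must be > 0")
            if self.supply_qw < 0 or self.mixing_time_tm < 0:
                raise ValueError("supply flow and mixing time must be >= 0")
            if self.supply_qw * self.mixing_time_tm > self.volume_V:
                raise ValueError("q_w * t_m exceeds the wetland volume (DF > 1)")


@dataclass(frozen=True)
class RiverMixingSolution:
    plume_width_W: float  # m
    section_area_A: float  # m²
    section_avg_CD: float  # ng/L
    discharge_QD: float  # m³/day
    receptor_C0: float  # ng/L


def plume_width(alpha_y, L):
    """Plume width W = 4*sqrt(2*alpha_y*L) covering 95% of the lateral
    Gaussian (two standard deviations each side)."""
    alpha_y = np.asarray(alpha_y, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(alpha_y <= 0) or np.any(L <= 0):
        raise ValueError("plume_width requires positive alpha_y and L")
    out = 4.0 * np.sqrt(2.0 * alpha_y * L)
    return float(out) if out.ndim == 0 else out


def section_average_concentration(c_max):
    """Average of the lateral Gaussian over the plume width:
    C_D = 0.5981*C_max."""
    c_max = np.asarray(c_max, dtype=float)
    if np.any(c_max < 0):
        raise ValueError("c_max must be >= 0")
    out = SECTION_AVERAGE_COEFF * c_max
    return float(out) if out.ndim == 0 else out


def discharge_flow(k, g, b, alpha_y, L):
    """Steady-state aquifer-to-river discharge Q_D = q*W*b (m³/day)."""
    k = np.asarray(k, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(k <= 0) or np.any(g <= 0) or b <= 0:
        raise ValueError("discharge_flow requires positive k, g, b")
    out = k * g * plume_width(alpha_y, L) * b
    return float(out) if out.ndim == 0 else out


def river_mixing(QD, CD, river: RiverReceptor | None = None, *, QR=None):
    """In-stream mass balance at the discharge point.

    C0 = (CR' * QR' + CD * QD) / QR; with the default clean upstream
    river this reduces to C0 = QD*CD/QR.  Emits a warning when QD > QR,
    where the dilution picture breaks down.
    """
    if river is not None:
        QR = river.flow_QR
        CRp = river.upstream_concentration
        QRp = river.upstream_flow_QR_prime if river.upstream_flow_QR_prime is not None else QR
    else:
        CRp, QRp = 0.0, None
    QD = np.asarray(QD, dtype=float)
    CD = np.asarray(CD, dtype=float)
    QR = np.asarray(QR, dtype=float)
    if np.any(QR <= 0):
        raise ValueError("river flow QR must be > 0")
    if np.any(QD > QR):
        warnings.warn(
            "discharge flow QD exceeds river flow QR; dilution assumption breached",
            RuntimeWarning,
            stacklevel=2,
        )
    upstream = CRp * (QRp if QRp is not None else QR)
    out = (upstream + CD * QD) / QR
    return float(out) if out.ndim == 0 else out


def dilution_factor(qw, tm, V):
    """Wetland dilution factor DF = q_w*t_m/V, in [0, 1]."""
    qw = np.asarray(qw, dtype=float)
    tm = np.asarray(tm, dtype=float)
    if not V > 0:
        raise ValueError("wetland volume must be > 0")
    if np.any(qw < 0) or np.any(tm < 0):
        raise ValueError("supply flow and mixing time must be >= 0")
    out = qw * tm / V
    if np.any(out > 1.0):
        raise ValueError("q_w * t_m exceeds the wetland volume (DF > 1 violates perfect mixing)")
    return float(out) if out.ndim == 0 else out


def wetland_concentration(c_max, DF):
    """Wetland concentration C0 = C_max * DF (ng/L); never exceeds C_max."""
    c_max = np.asarray(c_max, dtype=float)
    DF = np.asarray(DF, dtype=float)
    if np.any(c_max < 0):
        raise ValueError("c_max must be >= 0")
    if np.any((DF < 0) | (DF > 1)):
        raise ValueError("dilution factor must lie in [0, 1]")
    out = c_max * DF
    return float(out) if out.ndim == 0 else out


def evapo_supply(et_rate, area):
    """Minimum groundwater supply balancing evapotranspiration:
    q_w = et_rate (m³/ha·day) × area (ha), in m³/day."""
    if et_rate < 0 or area < 0:
        raise ValueError("evapo_supply requires non-negative inputs")
    return float(et_rate * area)
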