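"""Input-influence analysis: Spearman ranks for concentration and
elasticity-style sensitivity ratios for risk.

Concentration sensitivity is a one-dimensional Monte Carlo analysis:
the Spearman rank correlation r_s between each sampled input and the
receptor concentration C0, ranked by |r_s|.  Risk sensitivity uses the
sensitivity ratio SR = (dR/dC)·(C0/R0) evaluated along the fuzzy
risk-vs-concentration curve with a central finite difference; SR is the
local elasticity, so SR = b everywhere on a power law R = a·C^b and 0 on
the flat plateaus of the risk curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SensitivityReport",
    "spearman_rank",
    "rank_inputs",
    "sensitivity_ratio",
    "sr_table",
    "TABLE_INTERVALS",
]

#: default concentration intervals (ng/L) for the SR report
TABLE_INTERVALS = (
    (3.0, 8.0),
    (8.0, 12.0),
    (12.0, 19.0),
    (19.0, 21.9),
    (21.9, 21.99),
    (22.0, 300.0),
    (300.0, 370.0),
    (370.0, 400.0),
    (400.0, 430.0),
    (430.0, 475.0),
    (475.0, 490.0),
    (490.0, 550.0),
)

#: default half-width of the central difference, relative to C0
SR_REL_HALF_WIDTH = 0.01


@dataclass
class SensitivityReport:
    """Spearman coefficients per input plus the SR-vs-interval table."""

    spearman: dict[str, tuple[float, float]]  # name -> (r_s, p-value)
    ranked_inputs: list[str]
    output_name: str = "C0"
    sr_curve: list[tuple[tuple[float, float], float, float]] = field(default_factory=list)
    sr_half_width_rel: float = SR_REL_HALF_WIDTH

    def spearman_frame(self) -> pd.DataFrame:
        rows = [
            {"input": name, "r_s": self.spearman[name][0], "p_value": self.spearman[name][1]}
            for name in self.ranked_inputs
        ]
        return pd.DataFrame(rows)

    def sr_frame(self) -> pd.DataFrame:
        rows = [
            {"C0_low_ng_L": lohi[0], "C0_high_ng_L": lohi[1], "SR_min": lo, "SR_max": hi}
            for lohi, lo, hi in self.sr_curve
        ]
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = [
            f"# Sensitivity report ({self.output_name})",
            "",
            "## Spearman rank correlation of inputs vs " + self.output_name,
            "",
            "| input | r_s | p-value |",
            "| --- | --- | --- |",
        ]
        for name in self.ranked_inputs:
            r, p = self.spearman[name]
            lines.append(f"| {name} | {r:+.4f} | {p:.3g} |")
        if self.sr_curve:
            lines += [
                "",
                "## Sensitivity ratio of risk vs concentration",
                "",
                f"Central finite difference, half-width {self.sr_half_width_rel:.0%} of C0.",
                "",
                "| C0 interval (ng/L) | SR range |",
                "| --- | --- |",
            ]
            for (lo, hi), smin, smax in self.sr_curve:
                if abs(smax) < 5e-3 and abs(smin) < 5e-3:
                    sr_txt = "0"
                else:
                    sr_txt = f"{smin:.2g}–{smax:.2g}"
                lines.append(f"| {lo:g}–{hi:g} | {sr_txt} |")
        return "\n".join(lines) + "\n"


def spearman_rank(y, z) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on average ranks) and p-value."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.shape != z.shape or y.ndim != 1:
        raise ValueError(f"vectors must be 1-D with equal length, got {y.shape} vs {z.shape}")
    if y.size < 3:
        raise ValueError("Spearman correlation needs at least 3 observations")
    if np.all(y == y[0]) or np.all(z == z[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    r, p = stats.spearmanr(y, z)
    return float(r), float(p)


def rank_inputs(ens, output: str = "C0") -> SensitivityReport:
    """Spearman r_s of the ensemble output against every sampled input,
    ordered by decreasing |r_s| (constant inputs are skipped)."""
    yvals = ens.outputs[output]
    spearman: dict[str, tuple[float, float]] = {}
    for name, vec in ens.inputs.items():
        if np.all(vec.values == vec.values[0]):
            continue
        spearman[name] = spearman_rank(yvals, vec.values)
    if len(spearman) < 2:
        raise ValueError("sensitivity ranking needs at least 2 varying inputs")
    ranked = sorted(spearman, key=lambda n: abs(spearman[n][0]), reverse=True)
    return SensitivityReport(spearman=spearman, ranked_inputs=ranked, output_name=output)


def _as_risk_function(curve):
    """Accept a callable R(C) or a (C, R) curve pair (interpolated).

    Returns (f, domain, resolution); resolution is the coarsest grid
    spacing of a tabulated curve (None for callables) and is used to
    keep finite differences clear of interpolation kinks.
    """
    if callable(curve):
        return curve, None, None
    C, R = curve
    C = np.asarray(C, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(np.diff(C) <= 0):
        raise ValueError("curve concentrations must be strictly increasing")

    def f(x):
        return np.interp(x, C, R)

    return f, (float(C[0]), float(C[-1])), float(np.max(np.diff(C)))


def sensitivity_ratio(curve, C0: float, rel_half_width: float = SR_REL_HALF_WIDTH) -> float:
    """SR = (ΔR/ΔC)·(C0/R0) with a central difference of half-width
    ``rel_half_width * C0`` around C0.

    ``curve`` is either a callable R(C) or a ``(C, R)`` pair as returned
    by :func:`nanospill.fuzzy_risk.risk_curve`.
    """
    f, domain, _ = _as_risk_function(curve)
    if C0 <= 0:
        raise ValueError("SR needs C0 > 0")
    h = rel_half_width * C0
    if domain is not None:
        lo, hi = domain
        if not (lo <= C0 - h and C0 + h <= hi):
            raise ValueError(
                f"C0 ± h = [{C0 - h:g}, {C0 + h:g}] outside curve domain [{lo:g}, {hi:g}]"
            )
    R0 = float(f(C0))
    if R0 == 0:
        raise ValueError("SR undefined where R0 = 0")
    slope = (float(f(C0 + h)) - float(f(C0 - h))) / (2.0 * h)
    return slope * C0 / R0


def sr_table(
    curve,
    intervals=TABLE_INTERVALS,
    rel_half_width: float = SR_REL_HALF_WIDTH,
    points_per_interval: int = 50,
) -> list[tuple[tuple[float, float], float, float]]:
    """(interval, SR_min, SR_max) rows over the risk curve.

    SR is evaluated on an even grid strictly inside each interval; the
    interval presentation mirrors how elasticity bands are reported for
    stepwise risk curves.
    """
    f, domain, resolution = _as_risk_function(curve)
    rows = []
    for lo, hi in intervals:
        pad = rel_half_width * hi + (resolution or 0.0)
        xs = np.linspace(lo + pad, hi - pad, points_per_interval)
        xs = xs[xs > 0]
        if domain is not None:
            dlo, dhi = domain
            xs = xs[(xs * (1 - rel_half_width) >= dlo) & (xs * (1 + rel_half_width) <= dhi)]
        if xs.size == 0:
            continue
        srs = np.array([sensitivity_ratio(f, float(x), rel_half_width) for x in xs])
        rows.append(((lo, hi), float(srs.min()), float(srs.max())))
    return rows
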