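"""Monte Carlo propagation of the transport + receptor chain.

For each of N draws, the uncertain inputs (porosity n, gradient g,
conductivity k, retardation F, and river flow Q_R or wetland dilution
factor DF) are sampled from their configured distributions using
independent per-variable streams; the deterministic chain then yields
the groundwater peak c_max, its arrival time t_max, and the receptor
concentration C0.  Dispersivities depend only on the fixed receptor
distance L and are computed once per scenario.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import receptors, transport
from .distributions import (
    SampleVector,
    empirical_percentile,
    fraction_below,
    sample,
    stream_seed,
)

__all__ = ["MonteCarloEnsemble", "run_case", "summarize", "MAC_NG_L"]

#: proposed EU maximum allowable concentration for silver in surface water
MAC_NG_L = 22.0

#: fixed stream order so per-variable seeds are stable across runs
_STREAM_ORDER = ("n", "g", "k", "F", "QR", "DF", "tm")

_PERCENTILES = (5.0, 50.0, 90.0, 95.0)


@dataclass
class MonteCarloEnsemble:
    """Column-aligned sampled inputs and computed outputs across N draws."""

    scenario_id: str
    n_draws: int
    inputs: dict[str, SampleVector]
    outputs: dict[str, np.ndarray]
    seeds: dict[str, int]
    receptor_type: str
    transport_constants: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, vec in self.inputs.items():
            if len(vec) != self.n_draws:
                raise ValueError(f"input {name!r} has length {len(vec)} != N={self.n_draws}")
        for name, arr in self.outputs.items():
            if len(arr) != self.n_draws:
                raise ValueError(f"output {name!r} has length {len(arr)} != N={self.n_draws}")

    def input_values(self, name: str) -> np.ndarray:
        return self.inputs[name].values

    def percentile(self, output: str, p: float) -> float:
        return empirical_percentile(self.outputs[output], p)

    def to_frame(self) -> pd.DataFrame:
        cols = {name: vec.values for name, vec in self.inputs.items()}
        cols.update(self.outputs)
        df = pd.DataFrame(cols)
        df.index.name = "draw"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def run_case(config) -> MonteCarloEnsemble:
    """Run the full Monte Carlo chain for a validated ScenarioConfig."""
    src = config.source
    N = config.n_draws
    seeds = {
        name: stream_seed(config.seed, i) for i, name in enumerate(_STREAM_ORDER)
    }

    inputs: dict[str, SampleVector] = {}
    for name in ("n", "g", "k", "F"):
        inputs[name] = sample(config.aquifer[name], N, seeds[name], name=name)

    # porosity: defensively clip normal draws to the physical support
    n_vals = np.clip(inputs["n"].values, 1e-9, 1.0 - 1e-9)
    g_vals = inputs["g"].values
    k_vals = inputs["k"].values
    F_vals = inputs["F"].values
    _check_positive("g", g_vals)
    _check_positive("k", k_vals)
    if np.any(F_vals < 1.0):
        bad = int(np.argmax(F_vals < 1.0))
        raise ValueError(f"draw {bad}: retardation factor {F_vals[bad]} < 1")

    ax = transport.dispersivity_x(src.distance_L)
    ay = ax * transport.LATERAL_RATIO

    Vfx = transport.linear_velocity(k_vals, g_vals, n_vals)
    t_max = transport.arrival_time(src.distance_L, F_vals, Vfx)
    c_max = transport.peak_concentration(src, n=n_vals, F=F_vals)

    outputs = {"c_max": c_max, "t_max": t_max}

    if config.receptor_type == "river":
        QR_spec = config.receptor["flow_QR_m3_s"]
        inputs["QR"] = sample(QR_spec, N, seeds["QR"], name="QR")
        # river flow configured in m³/s (gauge convention), converted to
        # m³/day for the mixing balance
        QR_day = inputs["QR"].values * receptors.SECONDS_PER_DAY
        QD = receptors.discharge_flow(k_vals, g_vals, src.source_length_b, ay, src.distance_L)
        CD = receptors.section_average_concentration(c_max)
        C0 = receptors.river_mixing(QD, CD, QR=QR_day)
        outputs.update({"QD": QD, "CD": CD, "C0": C0})
    elif config.receptor_type == "wetland":
        if "dilution_factor" in config.receptor:
            inputs["DF"] = sample(config.receptor["dilution_factor"], N, seeds["DF"], name="DF")
            DF = inputs["DF"].values
        else:
            tm = sample(config.receptor["mixing_time_tm_days"], N, seeds["tm"], name="tm")
            inputs["tm"] = tm
            DF = receptors.dilution_factor(
                config.receptor["supply_qw_m3_day"],
                tm.values,
                config.receptor["volume_V_m3"],
            )
        C0 = receptors.wetland_concentration(c_max, DF)
        outputs.update({"DF": DF, "C0": C0})
    else:
        raise ValueError(f"unknown receptor type {config.receptor_type!r}")

    _check_positive("C0", outputs["C0"])
    return MonteCarloEnsemble(
        scenario_id=config.scenario_id,
        n_draws=N,
        inputs=inputs,
        outputs=outputs,
        seeds=seeds,
        receptor_type=config.receptor_type,
        transport_constants={"alpha_x_m": float(ax), "alpha_y_m": float(ay)},
    )


def summarize(ens: MonteCarloEnsemble, thresholds=(MAC_NG_L,)) -> dict:
    """Percentiles and threshold-compliance fractions of the ensemble.

    Percentile convention: linear interpolation between order
    statistics (stated here once; report writers echo it).
    """
    if ens.n_draws == 0:
        raise ValueError("empty ensemble")
    out: dict = {
        "scenario_id": ens.scenario_id,
        "n_draws": ens.n_draws,
        "seeds": dict(ens.seeds),
        "receptor_type": ens.receptor_type,
        "percentile_convention": "linear interpolation between order statistics",
        "outputs": {},
        "compliance": {},
    }
    for name in ("c_max", "t_max", "C0"):
        v = ens.outputs[name]
        out["outputs"][name] = {
            "min": float(np.min(v)),
            **{f"p{int(p)}": empirical_percentile(v, p) for p in _PERCENTILES},
            "max": float(np.max(v)),
        }
    for thr in thresholds:
        out["compliance"][str(thr)] = fraction_below(ens.outputs["C0"], thr)
    return out


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def _check_positive(name: str, values: np.ndarray) -> None:
    if np.any(values <= 0):
        bad = int(np.argmax(values <= 0))
        raise ValueError(f"draw {bad}: {name} = {values[bad]} is not positive")
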