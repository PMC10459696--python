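"""Scenario configuration, packaged case studies and the pipeline glue.

A scenario bundles the spill source, the aquifer parameter
distributions, the receptor (river or wetland), the released particle
and the Monte Carlo settings.  Configs are YAML with units spelled out
in field names (``flow_QR_m3_s``, ``conductivity_k_m_day``) to keep the
m³/s-vs-m³/day conversion explicit.  Two presets ship with the package:

``case1_river``
    2 kg of 10 nm citrate-coated AgNP spheres spilled 200 m upgradient
    of a river; groundwater discharge and in-stream mixing.
``case2_wetland``
    the same spill 600 m from a supply well whose pumped water recharges
    a 20,000 m³ wetland.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib.resources import files
from pathlib import Path

import numpy as np
import yaml

from . import ensemble as ens_mod
from . import fuzzy_risk as fz
from . import sensitivity as sens_mod
from .distributions import ConfigurationError, DistributionSpec
from .transport import SourceSpec

__all__ = [
    "ScenarioConfig",
    "PRESETS",
    "load_scenario",
    "run_pipeline",
    "generate_synthetic_scenario",
]

log = logging.getLogger("nanospill")

PRESETS = ("case1_river", "case2_wetland")

_AQUIFER_KEYS = ("n", "g", "k", "F")
# config spellings carrying units, mapped to short stream names
_AQUIFER_FIELDS = {
    "porosity_n": "n",
    "gradient_g": "g",
    "conductivity_k_m_day": "k",
    "retardation_F": "F",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated description of one spill case."""

    scenario_id: str
    source: SourceSpec
    aquifer: dict[str, DistributionSpec]  # keys: n, g, k, F
    receptor_type: str  # "river" | "wetland"
    receptor: dict  # DistributionSpecs / constants, see module docstring
    nanoparticle: fz.NanoparticleSpec
    n_draws: int = 10_000
    seed: int = 1234
    thresholds_ng_L: tuple[float, ...] = (ens_mod.MAC_NG_L,)

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ConfigurationError(f"n_draws must be >= 1, got {self.n_draws}")
        missing = [k for k in _AQUIFER_KEYS if k not in self.aquifer]
        if missing:
            raise ConfigurationError(f"aquifer config missing distribution(s) {missing}")
        if self.receptor_type not in ("river", "wetland"):
            raise ConfigurationError(
                f"receptor type must be 'river' or 'wetland', got {self.receptor_type!r}"
            )
        if self.receptor_type == "river":
            if "flow_QR_m3_s" not in self.receptor:
                raise ConfigurationError("river receptor missing 'flow_QR_m3_s' distribution")
        else:
            direct = "dilution_factor" in self.receptor
            triple = all(
                k in self.receptor
                for k in ("volume_V_m3", "supply_qw_m3_day", "mixing_time_tm_days")
            )
            if not (direct or triple):
                raise ConfigurationError(
                    "wetland receptor needs 'dilution_factor' or the "
                    "(volume_V_m3, supply_qw_m3_day, mixing_time_tm_days) triple"
                )

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        receptor = {"type": self.receptor_type}
        for key, val in self.receptor.items():
            receptor[key] = val.to_dict() if isinstance(val, DistributionSpec) else val
        return {
            "scenario_id": self.scenario_id,
            "source": {
                "mass_ug": self.source.mass,
                "source_length_b_m": self.source.source_length_b,
                "distance_L_m": self.source.distance_L,
            },
            "aquifer": {
                cfg_name: self.aquifer[short].to_dict()
                for cfg_name, short in _AQUIFER_FIELDS.items()
            },
            "receptor": receptor,
            "nanoparticle": {
                "size_nm": self.nanoparticle.size_nm,
                "shape": self.nanoparticle.shape,
                "coating": self.nanoparticle.coating,
            },
            "n_draws": self.n_draws,
            "seed": self.seed,
            "thresholds_ng_L": list(self.thresholds_ng_L),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ScenarioConfig":
        try:
            src = doc["source"]
            source = SourceSpec(
                mass=float(src["mass_ug"]),
                source_length_b=float(src["source_length_b_m"]),
                distance_L=float(src["distance_L_m"]),
            )
        except KeyError as e:
            raise ConfigurationError(f"source config missing field {e}") from None
        aquifer = {}
        for cfg_name, short in _AQUIFER_FIELDS.items():
            if cfg_name not in doc.get("aquifer", {}):
                raise ConfigurationError(f"aquifer config missing field {cfg_name!r}")
            aquifer[short] = DistributionSpec.from_dict(doc["aquifer"][cfg_name])
        rec = dict(doc.get("receptor", {}))
        rtype = rec.pop("type", None)
        if rtype is None:
            raise ConfigurationError("receptor config missing 'type'")
        receptor = {
            k: DistributionSpec.from_dict(v) if isinstance(v, dict) else float(v)
            for k, v in rec.items()
        }
        np_doc = doc.get("nanoparticle", {})
        try:
            nanoparticle = fz.NanoparticleSpec(
                size_nm=float(np_doc["size_nm"]),
                shape=str(np_doc["shape"]),
                coating=str(np_doc["coating"]),
            )
        except KeyError as e:
            raise ConfigurationError(f"nanoparticle config missing field {e}") from None
        return cls(
            scenario_id=str(doc.get("scenario_id", "scenario")),
            source=source,
            aquifer=aquifer,
            receptor_type=str(rtype),
            receptor=receptor,
            nanoparticle=nanoparticle,
            n_draws=int(doc.get("n_draws", 10_000)),
            seed=int(doc.get("seed", 1234)),
            thresholds_ng_L=tuple(float(t) for t in doc.get("thresholds_ng_L", [ens_mod.MAC_NG_L])),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def with_overrides(self, n_draws=None, seed=None, thresholds=None) -> "ScenarioConfig":
        cfg = self
        if n_draws is not None:
            cfg = replace(cfg, n_draws=int(n_draws))
        if seed is not None:
            cfg = replace(cfg, seed=int(seed))
        if thresholds:
            cfg = replace(cfg, thresholds_ng_L=tuple(float(t) for t in thresholds))
        return cfg


def load_scenario(path_or_preset) -> ScenarioConfig:
    """Load a scenario from a YAML path or a packaged preset name."""
    name = str(path_or_preset)
    if name in PRESETS:
        path = files("nanospill.data") / f"{name}.yaml"
    else:
        path = Path(name)
        if not path.exists():
            raise ConfigurationError(
                f"no such scenario file or preset {name!r}; presets: {list(PRESETS)}"
            )
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg = ScenarioConfig.from_dict(doc)
    log.info("loaded scenario %s: %s", cfg.scenario_id, cfg.to_dict())
    return cfg


def run_pipeline(
    config: ScenarioConfig,
    out_dir,
    fuzzy_model: fz.FuzzyRiskModel | None = None,
    plots: bool = False,
) -> dict[str, Path]:
    """Ensemble → fuzzy risk distribution → sensitivity; artifacts on disk.

    Writes the per-draw ensemble CSV, a JSON percentile/compliance
    summary, the risk-category frequency CSV and a sensitivity report
    (CSV + Markdown).  A ``.incomplete`` marker is present while the run
    is in flight and removed on success.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / f"{config.scenario_id}.incomplete"
    marker.write_text("run in progress\n")
    model = fuzzy_model or fz.FuzzyRiskModel.default()
    paths: dict[str, Path] = {}
    try:
        ens = ens_mod.run_case(config)

        paths["ensemble"] = out_dir / f"{config.scenario_id}_ensemble.csv"
        ens.to_csv(paths["ensemble"])

        summary = ens_mod.summarize(ens, thresholds=config.thresholds_ng_L)
        summary["scenario"] = config.to_dict()
        paths["summary"] = out_dir / f"{config.scenario_id}_summary.json"
        ens_mod.write_summary(summary, paths["summary"])

        freq = fz.risk_distribution(ens.outputs["C0"], config.nanoparticle, model)
        paths["risk_frequency"] = out_dir / f"{config.scenario_id}_risk_frequency.csv"
        with open(paths["risk_frequency"], "w") as fh:
            fh.write("category,fraction\n")
            for cat in model.categories:
                fh.write(f"{cat},{freq[cat]:.6f}\n")

        report = sens_mod.rank_inputs(ens)
        grid = np.linspace(1.0, 550.0, 1100)
        curve = fz.risk_curve(model, config.nanoparticle, grid)
        report.sr_curve = sens_mod.sr_table(curve)
        paths["sensitivity_csv"] = out_dir / f"{config.scenario_id}_sensitivity.csv"
        report.spearman_frame().to_csv(paths["sensitivity_csv"], index=False)
        paths["sensitivity_md"] = out_dir / f"{config.scenario_id}_sensitivity.md"
        paths["sensitivity_md"].write_text(report.to_markdown())

        if plots:
            paths.update(_write_plots(config, ens, curve, out_dir))
    except Exception:
        for p in paths.values():
            p.unlink(missing_ok=True)
        raise
    finally:
        marker.unlink(missing_ok=True)
    log.info("pipeline %s complete: %s", config.scenario_id, sorted(paths))
    return paths


def _write_plots(config, ens, curve, out_dir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    for key, label in (("C0", "C0 (ng/L)"), ("t_max", "t_max (days)")):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        v = np.sort(ens.outputs[key])
        ax.plot(v, np.arange(1, v.size + 1) / v.size)
        ax.set_xlabel(label)
        ax.set_ylabel("F(x)")
        ax.set_title(f"{config.scenario_id}: CDF of {key}")
        fig.tight_layout()
        p = out_dir / f"{config.scenario_id}_cdf_{key}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[f"cdf_{key}"] = p
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve[0], curve[1])
    ax.set_xlabel("C0 (ng/L)")
    ax.set_ylabel("risk score")
    ax.set_title("Fuzzy risk vs concentration")
    fig.tight_layout()
    p = out_dir / f"{config.scenario_id}_risk_curve.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["risk_curve"] = p
    return paths


def generate_synthetic_scenario(seed: int) -> ScenarioConfig:
    """Random but physically sensible scenario for property testing.

    River scenarios draw the river-flow distribution large enough that
    the aquifer discharge QD stays far below QR with overwhelming
    probability, keeping the dilution assumption intact.
    """
    rng = np.random.default_rng(int(seed))
    L = float(rng.uniform(50.0, 1000.0))
    b = float(rng.uniform(1.0, 10.0))
    mass = float(rng.uniform(1e8, 1e10))
    n_mean = float(rng.uniform(0.10, 0.35))
    g_lo = float(rng.uniform(1e-4, 1e-3))
    g_hi = g_lo * float(rng.uniform(1.5, 4.0))
    k_log_mean = float(rng.uniform(4.0, 7.0))
    k_log_sd = float(rng.uniform(0.2, 0.5))
    F_hi = 1.0 + float(rng.uniform(0.02, 0.3))
    aquifer = {
        "n": DistributionSpec("normal", {"mean": n_mean, "sd": 0.1 * n_mean}),
        "g": DistributionSpec("uniform", {"min": g_lo, "max": g_hi}),
        "k": DistributionSpec("lognormal", {"log_mean": k_log_mean, "log_sd": k_log_sd}, "m/day"),
        "F": DistributionSpec("uniform", {"min": 1.0, "max": F_hi}),
    }
    if rng.random() < 0.5:
        # QD upper bound at ~+4 sigma of k and max g
        from .receptors import SECONDS_PER_DAY, discharge_flow
        from .transport import dispersivity_y

        k_hi = np.exp(k_log_mean + 4.0 * k_log_sd)
        qd_hi = discharge_flow(k_hi, g_hi, b, dispersivity_y(L), L)
        qr_log_mean = float(np.log(100.0 * qd_hi / SECONDS_PER_DAY))
        receptor_type = "river"
        receptor = {
            "flow_QR_m3_s": DistributionSpec(
                "lognormal", {"log_mean": qr_log_mean, "log_sd": 0.25}, "m3/s"
            )
        }
    else:
        df_lo = float(rng.uniform(1e-4, 1e-3))
        df_hi = df_lo * float(rng.uniform(5.0, 50.0))
        receptor_type = "wetland"
        receptor = {
            "dilution_factor": DistributionSpec("uniform", {"min": df_lo, "max": df_hi})
        }
    return ScenarioConfig(
        scenario_id=f"synthetic_{int(seed)}",
        source=SourceSpec(mass=mass, source_length_b=b, distance_L=L),
        aquifer=aquifer,
        receptor_type=receptor_type,
        receptor=receptor,
        nanoparticle=fz.NanoparticleSpec(size_nm=10.0, shape="sphere", coating="citrate"),
        n_draws=1000,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
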