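"""Scenario configs, presets, synthetic generator, pipeline and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import nanospill as ns
from nanospill.cli import main as cli_main
from nanospill.distributions import ConfigurationError


def test_preset_case1_matches_published_parameterization(case1_config):
    cfg = case1_config
    assert cfg.source.mass == 2e9
    assert cfg.source.source_length_b == 3.0
    assert cfg.source.distance_L == 200.0
    assert cfg.receptor_type == "river"
    assert cfg.aquifer["n"].kind == "normal"
    assert cfg.aquifer["n"].params == {"mean": 0.15, "sd": 0.02}
    assert cfg.aquifer["g"].kind == "uniform"
    assert cfg.aquifer["g"].params == {"min": 5e-4, "max": 1.5e-3}
    assert cfg.aquifer["k"].kind == "lognormal"
    assert cfg.aquifer["k"].params == {"log_mean": 5.5, "log_sd": 0.4}
    assert cfg.aquifer["F"].kind == "uniform"
    assert cfg.aquifer["F"].params == {"min": 1.0, "max": 1.1}
    qr = cfg.receptor["flow_QR_m3_s"]
    assert qr.kind == "lognormal"
    assert qr.params == {"log_mean": 1.887, "log_sd": 0.248}
    assert cfg.n_draws == 10_000
    assert cfg.thresholds_ng_L == (22.0,)


def test_preset_case2_matches_published_parameterization(case2_config):
    cfg = case2_config
    assert cfg.source.distance_L == 600.0
    assert cfg.receptor_type == "wetland"
    assert cfg.aquifer["n"].params == {"mean": 0.25, "sd": 0.02}
    assert cfg.aquifer["k"].params == {"log_mean": 6.1, "log_sd": 0.4}
    df = cfg.receptor["dilution_factor"]
    assert df.kind == "uniform"
    assert df.params == {"min": 4.2e-4, "max": 2.7e-2}
    assert cfg.nanoparticle == ns.NanoparticleSpec(10.0, "sphere", "citrate")


def test_unknown_preset_lists_presets(tmp_path):
    with pytest.raises(ConfigurationError, match="case1_river"):
        ns.load_scenario("no_such_case")


def test_config_roundtrip_is_identity(case1_config, case2_config, tmp_path):
    for cfg in (case1_config, case2_config):
        path = tmp_path / f"{cfg.scenario_id}.yaml"
        cfg.to_yaml(path)
        again = ns.load_scenario(path)
        assert again.to_dict() == cfg.to_dict()


def test_missing_porosity_is_a_validation_error(case1_config, tmp_path):
    doc = case1_config.to_dict()
    del doc["aquifer"]["porosity_n"]
    import yaml

    path = tmp_path / "broken.yaml"
    path.write_text(yaml.safe_dump(doc))
    with pytest.raises(ConfigurationError, match="porosity_n"):
        ns.load_scenario(path)


@pytest.mark.parametrize("seed", [0, 7, 1234])
def test_synthetic_scenarios_valid_and_reproducible(seed):
    a = ns.generate_synthetic_scenario(seed)
    b = ns.generate_synthetic_scenario(seed)
    assert a.to_dict() == b.to_dict()
    # valid enough to run end to end at small N
    ens = ns.run_case(a.with_overrides(n_draws=200))
    assert np.all(ens.outputs["C0"] > 0)


def test_synthetic_river_scenarios_respect_dilution_assumption():
    """Generated river scenarios keep QD below QR essentially always."""
    from nanospill.receptors import SECONDS_PER_DAY, discharge_flow
    from nanospill.transport import dispersivity_y

    checked = 0
    for seed in range(40):
        cfg = ns.generate_synthetic_scenario(seed)
        if cfg.receptor_type != "river":
            continue
        checked += 1
        ens = ns.run_case(cfg.with_overrides(n_draws=1000))
        QD = discharge_flow(
            ens.input_values("k"),
            ens.input_values("g"),
            cfg.source.source_length_b,
            dispersivity_y(cfg.source.distance_L),
            cfg.source.distance_L,
        )
        QR = ens.input_values("QR") * SECONDS_PER_DAY
        assert np.mean(QD > QR) == 0.0
        if checked >= 5:
            break
    assert checked > 0


def test_pipeline_writes_all_artifacts(tmp_path, case1_config):
    cfg = case1_config.with_overrides(n_draws=10)
    paths = ns.run_pipeline(cfg, tmp_path)
    for key in ("ensemble", "summary", "risk_frequency", "sensitivity_csv", "sensitivity_md"):
        assert paths[key].exists(), key
    assert not (tmp_path / f"{cfg.scenario_id}.incomplete").exists()
    summary = json.loads(paths["summary"].read_text())
    assert summary["n_draws"] == 10
    assert "22.0" in summary["compliance"]
    freq_lines = paths["risk_frequency"].read_text().strip().splitlines()
    assert freq_lines[0] == "category,fraction"
    fracs = [float(line.split(",")[1]) for line in freq_lines[1:]]
    assert sum(fracs) == pytest.approx(1.0, abs=1e-9)


def test_cli_run_and_validate(tmp_path):
    runner = CliRunner()
    res = runner.invoke(
        cli_main,
        ["run", "case1_river", "-N", "10", "--seed", "5", "-o", str(tmp_path / "out")],
    )
    assert res.exit_code == 0, res.output
    assert "summary" in res.output
    res = runner.invoke(cli_main, ["validate-config", "case2_wetland"])
    assert res.exit_code == 0
    assert "wetland" in res.output


def test_cli_summarize_and_risk_curve():
    runner = CliRunner()
    res = runner.invoke(cli_main, ["summarize", "case2_wetland", "-N", "50", "--seed", "2"])
    assert res.exit_code == 0, res.output
    doc = json.loads(res.output)
    assert doc["compliance"]["22.0"] == 0.0
    res = runner.invoke(cli_main, ["risk-curve", "--points", "12"])
    assert res.exit_code == 0
    assert "C0_ng_L,risk_score,category" in res.output


def test_cli_sensitivity_smoke():
    runner = CliRunner()
    res = runner.invoke(cli_main, ["sensitivity", "case1_river", "-N", "300", "--seed", "3"])
    assert res.exit_code == 0, res.output
    assert "Spearman" in res.output


def test_pipeline_plots(tmp_path, case1_config):
    cfg = case1_config.with_overrides(n_draws=10)
    paths = ns.run_pipeline(cfg, tmp_path, plots=True)
    for key in ("cdf_C0", "cdf_t_max", "risk_curve"):
        assert paths[key].exists()
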