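import numpy as np
import pytest
from click.testing import CliRunner

from pararep import experiments as ex
from pararep.chemostat import ChemostatConfig
from pararep.cli import main as cli_main
from pararep.constant_population import ConstantPopulationConfig
from pararep.kinetics import KineticParams


def test_scale_down_proportional():
    cfg = ConstantPopulationConfig()  # 1e7 events, cadence 2000, window 1e4
    red = ex.scale_down(cfg, 10)
    assert red.max_repl_events == 1_000_000
    assert red.survival_cadence == 200
    assert red.survival_window == 1000
    assert red.survival_window == 5 * red.survival_cadence
    assert red.kinetics == cfg.kinetics


def test_scale_down_identity_and_error():
    cfg = ConstantPopulationConfig()
    same = ex.scale_down(cfg, 1)
    assert same.max_repl_events == cfg.max_repl_events
    with pytest.raises(ValueError):
        ex.scale_down(cfg, 10_000)  # cadence would drop below one event
    with pytest.raises(ValueError):
        ex.scale_down(cfg, 0.5)


def test_set_param_targets_config_or_kinetics():
    cfg = ConstantPopulationConfig()
    assert ex.set_param(cfg, "n0", 500).n0 == 500
    assert ex.set_param(cfg, "delta", 0.01).kinetics.delta == 0.01
    with pytest.raises(ValueError):
        ex.set_param(cfg, "nonsense", 1)


def test_replicate_seeds_are_31bit_and_deterministic():
    a = ex.replicate_seeds(1, 5)
    b = ex.replicate_seeds(1, 5)
    assert a == b
    assert all(0 <= s < 2**31 for s in a)
    assert ex.replicate_seeds(2, 5) != a


def _tiny_config():
    return ConstantPopulationConfig(
        n0=100, max_repl_events=400, survival_cadence=4, survival_window=20)


def test_sweep_rerun_is_byte_identical(tmp_path):
    cfg = _tiny_config()
    grid = {"delta": [0.001, 0.01]}
    out1, out2 = tmp_path / "a", tmp_path / "b"
    ex.sweep(cfg, grid, replicates=2, master_seed=3, out_dir=out1)
    ex.sweep(cfg, grid, replicates=2, master_seed=3, out_dir=out2)
    for name in ("runs.csv", "aggregate.csv"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


def test_sweep_shapes_and_single_replicate_sd():
    runs, agg = ex.sweep(_tiny_config(), {"delta": [0.001, 0.01]},
                         replicates=1, master_seed=4)
    assert len(runs) == 2 and len(agg) == 2
    assert agg["sd_survivors"].isna().all()
    assert not runs["failed"].any()
    assert set(agg.columns) >= {"mean_survivors", "mean_pct", "mean_N"}


def test_sweep_records_failures_and_continues():
    cfg = _tiny_config()
    runs, agg = ex.sweep(cfg, {"n0": [100, 1]},  # n0=1 is invalid
                         replicates=2, master_seed=5)
    bad = runs[runs["n0"] == 1]
    assert bad["failed"].all()
    good = runs[runs["n0"] == 100]
    assert not good["failed"].any()
    assert agg.loc[agg["n0"] == 100, "any_failed"].iloc[0] == False  # noqa: E712


def test_config_yaml_roundtrip(tmp_path):
    cfg = ConstantPopulationConfig(
        n0=1234, kinetics=KineticParams(delta=0.01, p_mut=0.05))
    path = tmp_path / "run.yaml"
    ex.save_config(cfg, path)
    back = ex.load_config(path)
    assert isinstance(back, ConstantPopulationConfig)
    assert back.n0 == 1234
    assert back.kinetics.delta == 0.01
    chem = ChemostatConfig(c_in=0.1, kinetics=KineticParams(f=0.5))
    ex.save_config(chem, path)
    back = ex.load_config(path)
    assert isinstance(back, ChemostatConfig)
    assert back.c_in == 0.1 and back.kinetics.f == 0.5


def test_fit_growth_laws_recovers_quadratic():
    t = np.linspace(0, 100, 50)
    n = (0.05 * t / 2 + np.sqrt(9.0)) ** 2
    fits = ex.fit_growth_laws(t, n, 9.0)
    assert fits["k"] == pytest.approx(0.05, rel=1e-3)
    assert fits["rmse_sqrt"] < 1e-6
    assert fits["rmse_sqrt"] < fits["rmse_exp"]


def test_cli_generate_masters_and_ode(tmp_path):
    runner = CliRunner()
    fasta = tmp_path / "m.fasta"
    res = runner.invoke(cli_main, ["generate-masters", "--seed", "1",
                                   "--out", str(fasta)])
    assert res.exit_code == 0, res.output
    assert fasta.read_text().count(">") == 10

    res = runner.invoke(cli_main, ["run-ode", "--model", "both",
                                   "-A", "2", "-Q", "0.75"])
    assert res.exit_code == 0, res.output
    assert '"x_exponential": 0.5' in res.output


def test_cli_run_constant_and_scale_down(tmp_path):
    runner = CliRunner()
    cfg_path = tmp_path / "cfg.yaml"
    ex.save_config(_tiny_config(), cfg_path)
    out = tmp_path / "out"
    res = runner.invoke(cli_main, ["run-constant", "--config", str(cfg_path),
                                   "--seed", "1", "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert (out / "trajectory.csv").exists()
    assert (out / "summary.json").exists()

    red = tmp_path / "red.yaml"
    res = runner.invoke(cli_main, ["scale-down", "--config", str(cfg_path),
                                   "--factor", "2", "--out", str(red)])
    assert res.exit_code == 0, res.output
    back = ex.load_config(red)
    assert back.max_repl_events == 200
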