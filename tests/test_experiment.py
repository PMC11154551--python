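import json

import numpy as np
import pytest

from ncie.cli import main
from ncie.experiment import RunConfig, child_seed, run_experiment


BOOL_CONFIG = {
    "seed": 5,
    "stages": ["simulate", "extract", "evalmi"],
    "simulate": {"system": "boolean", "n": 400},
    "spec": {"target": "Y", "causes": ["X:1"], "k": 1},
    "ncie": {"epochs": 10, "hidden_dim": 8, "disc_hidden": [16]},
    "evalmi": {"method": "binning", "bins": 2},
}


def test_child_seed_is_deterministic_and_bounded():
    assert child_seed(3, "simulate") == child_seed(3, "simulate")
    assert child_seed(3, "simulate") != child_seed(3, "extract")
    assert 0 <= child_seed(2 ** 20, "x") < 2 ** 31


def test_end_to_end_boolean_run_writes_manifest(tmp_path):
    out = run_experiment(RunConfig(BOOL_CONFIG), out_dir=tmp_path / "run")
    manifest = json.loads((out / "manifest.json").read_text())
    assert [s["stage"] for s in manifest["stages"]] == \
        ["simulate", "extract", "evalmi"]
    assert (out / "panel.csv").exists()
    assert (out / "implicit.csv").exists()


def test_same_config_same_seed_identical_outputs(tmp_path):
    out1 = run_experiment(RunConfig(BOOL_CONFIG), out_dir=tmp_path / "a")
    out2 = run_experiment(RunConfig(BOOL_CONFIG), out_dir=tmp_path / "b")
    m1 = json.loads((out1 / "manifest.json").read_text())
    m2 = json.loads((out2 / "manifest.json").read_text())
    assert m1 == m2
    assert (out1 / "implicit.csv").read_text() == \
        (out2 / "implicit.csv").read_text()


def test_unknown_config_keys_rejected():
    with pytest.raises(ValueError, match="unknown config keys"):
        RunConfig({"stages": [], "tyop": 1})


def test_failing_stage_is_named_and_artifacts_retained(tmp_path):
    config = dict(BOOL_CONFIG)
    config["spec"] = {"target": "NOPE", "causes": [], "k": 1}
    with pytest.raises(RuntimeError, match="extract"):
        run_experiment(RunConfig(config), out_dir=tmp_path / "run")
    manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
    assert manifest["failed_stage"] == "extract"
    assert (tmp_path / "run" / "panel.csv").exists()


def test_yaml_round_trip(tmp_path):
    cfg = RunConfig(BOOL_CONFIG)
    cfg.to_yaml(tmp_path / "c.yaml")
    back = RunConfig.from_yaml(tmp_path / "c.yaml")
    assert back.mapping == cfg.mapping
    assert back.digest() == cfg.digest()


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_simulate_and_evalmi(tmp_path, capsys):
    panel_path = tmp_path / "bool.csv"
    assert main(["simulate", "--system", "boolean", "--n", "2000",
                 "--seed", "1", "--out", str(panel_path)]) == 0
    assert panel_path.exists()
    assert main(["evalmi", "--panel", str(panel_path), "--target", "Y",
                 "--causes", "X:1,W:1", "--k", "1", "--bins", "2"]) == 0
    record = json.loads(capsys.readouterr().out.strip().splitlines()[-1])
    assert record["units"] == "bits"
    assert record["value"] > 0.5  # X, W and Y_{t-1} nearly cover H(Y)


def test_cli_extract_writes_z_panel(tmp_path):
    panel_path = tmp_path / "bool.csv"
    main(["simulate", "--system", "boolean", "--n", "300", "--out",
          str(panel_path)])
    z_path = tmp_path / "z.csv"
    assert main(["extract", "--panel", str(panel_path), "--target", "Y",
                 "--causes", "X:1", "--k", "1", "--epochs", "5",
                 "--out-z", str(z_path)]) == 0
    assert z_path.exists()
    assert z_path.with_suffix(".json").exists()


def test_cli_run_subcommand(tmp_path):
    cfg_path = tmp_path / "cfg.yaml"
    RunConfig(BOOL_CONFIG).to_yaml(cfg_path)
    assert main(["run", "--config", str(cfg_path),
                 "--out-dir", str(tmp_path / "out")]) == 0
    assert (tmp_path / "out" / "manifest.json").exists()
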