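"""Config-driven experiment runner: simulate -> extract/evalmi -> predict.

A run is described by a YAML (or dict) :class:`RunConfig`; stages execute in
order, each reading only the artifacts of the previous one, and every stage
writes its outputs plus a manifest sufficient to re-run into the output
directory.  A single global seed fans out deterministically to per-stage
seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .design import CausalSpec
from .information import BinningSpec, DVConfig, SamplePairBatch, mi_binned, \
    train_dv_estimator
from .model import NCIEConfig, mi_gap_report, train_ncie
from .panel import PanelTable, read_panel, write_panel
from .pipeline import (PredictorConfig, PretrainConfig,
                       compare_with_without_z, select_causes)
from .systems import LVParams, simulate_boolean, simulate_case, simulate_lv

__all__ = ["RunConfig", "run_experiment", "child_seed", "simulate_system"]

log = logging.getLogger("ncie")

_KNOWN_KEYS = {"seed", "out_dir", "stages", "simulate", "spec", "ncie",
               "pretrain", "predictor", "evalmi", "panel"}


def child_seed(seed: int, tag: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from a global seed."""
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def simulate_system(system: str, seed: int, n: int | None = None,
                    t_start: float | None = None, t_end: float | None = None,
                    lv_params: dict | None = None) -> PanelTable:
    """Dispatch to one of the synthetic generators by name."""
    if system == "boolean":
        return simulate_boolean(n or 5000, seed=seed)
    if system in ("case1", "case2", "case3"):
        return simulate_case(int(system[-1]), t_start=t_start, t_end=t_end,
                             n=n)
    if system == "lv":
        params = LVParams(**(lv_params or {}))
        return simulate_lv(params, seed=seed)
    raise ValueError(f"unknown system {system!r}")


@dataclass(frozen=True)
class RunConfig:
    """Nested mapping of all stage configs; round-trips through YAML."""

    mapping: dict

    def __post_init__(self) -> None:
        unknown = set(self.mapping) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" not in self.mapping:
            raise ValueError("config must list 'stages'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.mapping, fh, sort_keys=True)

    @property
    def seed(self) -> int:
        return int(self.mapping.get("seed", 0))

    def digest(self) -> str:
        blob = json.dumps(self.mapping, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_spec(panel: PanelTable, cfg: dict) -> CausalSpec:
    return select_causes(panel, cfg["target"],
                         max_lag=int(cfg.get("max_lag", 8)),
                         causes=cfg.get("causes", []),
                         k=int(cfg.get("k", 1)))


def run_experiment(config: RunConfig | dict, out_dir: str | Path | None = None
                   ) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage error aborts the run with the stage named; artifacts of the
    completed stages are retained and the manifest records the failure.
    """
    if isinstance(config, dict):
        config = RunConfig(config)
    out = Path(out_dir or config.mapping.get("out_dir", "ncie_run"))
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"seed": config.seed, "config_hash": config.digest(),
                      "stages": []}
    panel: PanelTable | None = None
    current_stage = None
    try:
        for stage in config.mapping["stages"]:
            current_stage = stage
            log.info("stage %s starting", stage)
            if stage == "simulate":
                sim = dict(config.mapping.get("simulate", {}))
                system = sim.pop("system")
                panel = simulate_system(
                    system, seed=child_seed(config.seed, "simulate"), **sim)
                path = write_panel(panel, out / "panel.csv")
                manifest["stages"].append(
                    {"stage": stage, "system": system, "panel": path.name,
                     "rows": panel.n_rows})
            elif stage == "extract":
                panel = _require_panel(panel, config, out)
                spec = _build_spec(panel, config.mapping["spec"])
                opts = {k: v for k, v in config.mapping.get(
                    "ncie", {}).items() if k != "seed"}
                ncfg = NCIEConfig(**opts,
                                  seed=child_seed(config.seed, "extract"))
                model, z_series, estimate = train_ncie(panel, spec, ncfg)
                zpanel = PanelTable.from_columns(
                    {f"Z{j + 1}": z_series.z[:, j]
                     for j in range(z_series.z.shape[1])},
                    time=z_series.rows)
                zpath = write_panel(zpanel, out / "implicit.csv")
                record = {"stage": stage, "z_panel": zpath.name,
                          "mi_estimate_nats": estimate.value,
                          "method": estimate.method,
                          "n_samples": estimate.n_samples}
                (out / "mi_estimate.json").write_text(
                    json.dumps(record, indent=2))
                manifest["stages"].append(record)
            elif stage == "evalmi":
                panel = _require_panel(panel, config, out)
                cfg = config.mapping.get("evalmi", {})
                spec = _build_spec(panel, config.mapping["spec"])
                record = _evalmi(panel, spec, cfg,
                                 seed=child_seed(config.seed, "evalmi"))
                (out / "evalmi.json").write_text(json.dumps(record, indent=2))
                manifest["stages"].append({"stage": stage, **record})
            elif stage == "predict":
                panel = _require_panel(panel, config, out)
                spec = _build_spec(panel, config.mapping["spec"])
                fams = tuple(config.mapping.get(
                    "predictor", {}).get("families", ["NN", "RNN", "LSTM"]))
                report = compare_with_without_z(
                    panel, spec, families=fams,
                    pre_config=PretrainConfig(
                        **config.mapping.get("pretrain", {})),
                    ncie_config=NCIEConfig(**config.mapping.get("ncie", {})),
                    predictor_config=PredictorConfig(
                        **{k: v for k, v in config.mapping.get(
                            "predictor", {}).items() if k != "families"}),
                    seed=child_seed(config.seed, "predict"))
                (out / "prediction_report.json").write_text(
                    json.dumps(report.as_dict(), indent=2))
                manifest["stages"].append({"stage": stage,
                                           **report.as_dict()})
            else:
                raise ValueError(f"unknown stage {stage!r}")
            log.info("stage %s done", stage)
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"stage {current_stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _require_panel(panel: PanelTable | None, config: RunConfig,
                   out: Path) -> PanelTable:
    if panel is not None:
        return panel
    path = config.mapping.get("panel") or (out / "panel.csv")
    return read_panel(path)


def _evalmi(panel: PanelTable, spec: CausalSpec, cfg: dict,
            seed: int) -> dict:
    """One MI evaluation between the target and its explicit causes."""
    from .design import build_lagged_design
    design = build_lagged_design(panel, spec)
    method = cfg.get("method", "binning")
    base = cfg.get("base", 2)
    if method == "binning":
        table = {"__y__": design.y_now}
        table.update({lab: design.explicit[:, j]
                      for j, lab in enumerate(design.labels)})
        est = mi_binned(table, ["__y__"], list(design.labels),
                        BinningSpec(n_bins=int(cfg.get("bins", 16))), base)
        diag = None
    elif method == "dv":
        est = train_dv_estimator(
            SamplePairBatch(design.y_now.reshape(-1, 1), design.explicit),
            DVConfig(seed=seed, epochs=int(cfg.get("epochs", 200))))
        diag = est.diagnostics["bound_curve"][-5:]
    else:
        raise ValueError(f"unknown evalmi method {method!r}")
    value = est.in_units("bits" if base == 2 else "nats")
    return {"value": value, "units": "bits" if base == 2 else "nats",
            "method": est.method, "n_samples": design.n_rows,
            "tail_curve": diag}
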