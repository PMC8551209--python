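"""Run configuration: YAML schema, validation, defaults.

The empty config reproduces the nominal experimental setup: four populations
of ten neurons, 1000 ms horizon at dt = 0.01 ms, healthy reference vs PD
plant, the frozen tuned controller gains.  Unknown keys are rejected so typos
cannot silently fall back to defaults.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .controller import ControllerConfig
from .experiments import Scenario
from .params import (ConfigurationError, NetworkParams, SmcInputParams,
                     apply_condition)

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    network: NetworkParams = field(default_factory=NetworkParams)
    smc: SmcInputParams = field(default_factory=SmcInputParams)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    scenario: Scenario = None
    seed: int = 0
    output_dir: str = "out"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.scenario is None:
            self.scenario = Scenario(mode=self.controller.mode,
                                     controller=self.controller,
                                     network=self.network, smc=self.smc)


_SIMPLE_NETWORK_KEYS = {"c_m", "n_per_pop", "condition"}
_SCENARIO_KEYS = {"mode", "uncertainty", "disturbance", "duration", "dt",
                  "n_trials"}


def _update_dataclass(obj, section: Dict[str, Any], where: str):
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in section.items():
        if key not in names:
            raise ConfigurationError(f"unknown key {where}.{key!r}")
        setattr(obj, key, value)
    # re-run validation
    post = getattr(obj, "__post_init__", None)
    if post is not None:
        post()
    return obj


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[Dict[str, Any]] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty/missing file yields the all-defaults configuration.  Validation
    errors name the offending key; range checks of the underlying dataclasses
    (e.g. eta outside (1, 2)) propagate as configuration errors.
    """
    raw: Dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config root must be a mapping, "
                                     f"got {type(raw).__name__}")
    if overrides:
        for k, v in overrides.items():
            raw.setdefault(k, {}).update(v)

    cfg = RunConfig.__new__(RunConfig)
    cfg.seed = 0
    cfg.output_dir = "out"
    cfg.log_level = "INFO"

    known = {"network", "smc", "controller", "scenario", "seed",
             "output_dir", "log_level"}
    for key in raw:
        if key not in known:
            raise ConfigurationError(f"unknown section {key!r}")

    net = NetworkParams()
    net_raw = dict(raw.get("network") or {})
    condition = net_raw.pop("condition", None)
    for key in net_raw:
        if key not in _SIMPLE_NETWORK_KEYS:
            raise ConfigurationError(f"unknown key network.{key!r}")
    if net_raw:
        net = dataclasses.replace(net, **net_raw)
    if condition is not None:
        net = apply_condition(net, condition)
    cfg.network = net

    cfg.smc = _update_dataclass(SmcInputParams(), dict(raw.get("smc") or {}),
                                "smc")
    cfg.controller = _update_dataclass(
        ControllerConfig(), dict(raw.get("controller") or {}), "controller")

    scen_raw = dict(raw.get("scenario") or {})
    for key in scen_raw:
        if key not in _SCENARIO_KEYS:
            raise ConfigurationError(f"unknown key scenario.{key!r}")
    mode = scen_raw.pop("mode", cfg.controller.mode)
    if mode != cfg.controller.mode:
        cfg.controller = dataclasses.replace(cfg.controller, mode=mode)
    cfg.scenario = Scenario(mode=mode, controller=cfg.controller,
                            network=cfg.network, smc=cfg.smc, **scen_raw)

    cfg.seed = int(raw.get("seed", 0))
    cfg.output_dir = str(raw.get("output_dir", "out"))
    cfg.log_level = str(raw.get("log_level", "INFO"))
    return cfg


def dump_config(cfg: RunConfig) -> str:
    """Serialize the effective configuration (echoed alongside outputs)."""
    doc = {
        "network": {"c_m": cfg.network.c_m, "n_per_pop": cfg.network.n_per_pop,
                    "condition": cfg.network.condition},
        "smc": dataclasses.asdict(cfg.smc),
        "controller": dataclasses.asdict(cfg.controller),
        "scenario": {k: getattr(cfg.scenario, k) for k in _SCENARIO_KEYS},
        "seed": cfg.seed,
        "output_dir": cfg.output_dir,
        "log_level": cfg.log_level,
    }
    return yaml.safe_dump(doc, sort_keys=False)
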