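"""Configuration parsing and validation.

Configs are flat YAML (or JSON) documents with up to six sections —
``model``, ``drive``, ``solver``, ``sweep``, ``sampling``, plus top-level
``seed`` and ``out_dir``.  Unknown keys are rejected at every level and every
default that fills a missing key is logged, so a run's effective settings are
always auditable.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional, Sequence

import yaml

from .drive import DriveProtocol
from .errors import ConfigError
from .model import MicrocircuitParams, SigmoidConstants, SolverConfig
from .search import derive_dependent_weights

__all__ = ["RunConfig", "SweepSettings", "SamplingSettings", "parse_phase",
           "load_config", "save_config"]

logger = logging.getLogger(__name__)

_PHASE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)?\s*\*?\s*pi\s*(?:/\s*"
                       r"(\d+(?:\.\d+)?))?\s*$", re.IGNORECASE)


def parse_phase(value: Any) -> float:
    """Phase in radians from a number or a multiple-of-pi string.

    Accepts e.g. ``0``, ``1.57``, ``"pi"``, ``"pi/2"``, ``"3pi/2"``,
    ``"0.5pi"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        m = _PHASE_RE.match(value)
        if m:
            coef = float(m.group(1)) if m.group(1) else 1.0
            den = float(m.group(2)) if m.group(2) else 1.0
            return coef * math.pi / den
        try:
            return float(value)
        except ValueError:
            pass
    raise ConfigError(f"cannot parse phase value {value!r}")


@dataclass(frozen=True)
class SweepSettings:
    """Grid axes for the entrainment / convergence / phase sweeps."""

    f_in_min: float = 1.0
    f_in_max: float = 14.0
    f_in_step: float = 0.25
    lambda_min: float = 0.05
    lambda_max: float = 0.70
    lambda_step: float = 0.05
    q_values: Sequence[float] = (0.0, 0.5, 1.0)
    delta_phi: float = 0.0

    def f_in_grid(self):
        import numpy as np
        return np.arange(self.f_in_min, self.f_in_max + 1e-9, self.f_in_step)

    def lambda_grid(self):
        import numpy as np
        return np.arange(self.lambda_min, self.lambda_max + 1e-9,
                         self.lambda_step)


@dataclass(frozen=True)
class SamplingSettings:
    """Scale of the sample -> screen -> optimize -> dedupe pipeline."""

    n_draws: int = 2000
    target_valid: int = 10
    batch_size: int = 2000
    max_draws: int = 100_000


@dataclass
class RunConfig:
    """Validated, fully defaulted settings for one CLI invocation."""

    model: MicrocircuitParams
    drive: Optional[DriveProtocol] = None
    solver: SolverConfig = field(default_factory=SolverConfig)
    sweep: SweepSettings = field(default_factory=SweepSettings)
    sampling: SamplingSettings = field(default_factory=SamplingSettings)
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> Dict[str, Any]:
        sg = self.model.sigmoid
        d: Dict[str, Any] = {
            "model": {"P": self.model.P, "w1": self.model.w1,
                      "w2": self.model.w2, "w3": self.model.w3,
                      "w4": self.model.w4, "w5": self.model.w5,
                      "w6": self.model.w6, "w7": self.model.w7,
                      "q": self.model.q, "tau": self.model.tau,
                      "theta_e": sg.theta_e, "theta_i": sg.theta_i,
                      "alpha_e": sg.alpha_e, "alpha_i": sg.alpha_i,
                      "derive_ratio_weights": False},
            "solver": asdict(self.solver),
            "sweep": {**asdict(self.sweep),
                      "q_values": list(self.sweep.q_values)},
            "sampling": asdict(self.sampling),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        if self.drive is not None:
            d["drive"] = {"Lambda": self.drive.Lambda,
                          "f_in": self.drive.f_in,
                          "delta_phi": self.drive.delta_phi,
                          "settle": self.drive.settle,
                          "total": self.drive.total}
        return d


def _take(section: Dict[str, Any], allowed: Dict[str, Any],
          name: str) -> Dict[str, Any]:
    """Validate a config section against its defaults, logging fills."""
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{name}': {sorted(unknown)}")
    out = {}
    for key, default in allowed.items():
        if key in section:
            out[key] = section[key]
        else:
            out[key] = default
            if default is not None:
                logger.info("config: %s.%s defaulted to %r", name, key,
                            default)
    return out


_MODEL_DEFAULTS: Dict[str, Any] = {
    "P": None, "w1": None, "w2": None, "w3": None, "w4": None, "w5": None,
    "w6": None, "w7": None, "q": None, "tau": 0.05,
    "theta_e": 4.0, "theta_i": 3.7, "alpha_e": 1.3, "alpha_i": 2.0,
    "derive_ratio_weights": True,
}

_DRIVE_DEFAULTS: Dict[str, Any] = {
    "Lambda": None, "f_in": None, "delta_phi": 0.0, "settle": 10.0,
    "total": 20.0, "P": None,
}


def _build_model(section: Dict[str, Any]) -> MicrocircuitParams:
    vals = _take(section, _MODEL_DEFAULTS, "model")
    for key in ("P", "w1", "w3", "w4", "w5", "q"):
        if vals[key] is None:
            raise ConfigError(f"model.{key} is required")
    sigmoid = SigmoidConstants(theta_e=vals["theta_e"],
                               theta_i=vals["theta_i"],
                               alpha_e=vals["alpha_e"],
                               alpha_i=vals["alpha_i"])
    if vals["derive_ratio_weights"]:
        for key in ("w2", "w6", "w7"):
            if vals[key] is not None:
                raise ConfigError(
                    f"model.{key} conflicts with derive_ratio_weights")
        w2, w6, w7 = derive_dependent_weights(vals["w3"])
    else:
        for key in ("w2", "w6", "w7"):
            if vals[key] is None:
                raise ConfigError(
                    f"model.{key} is required when derive_ratio_weights "
                    "is false")
        w2, w6, w7 = vals["w2"], vals["w6"], vals["w7"]
    return MicrocircuitParams(P=vals["P"], w1=vals["w1"], w2=w2,
                              w3=vals["w3"], w4=vals["w4"], w5=vals["w5"],
                              w6=w6, w7=w7, q=vals["q"], tau=vals["tau"],
                              sigmoid=sigmoid)


def _from_mapping(data: Dict[str, Any]) -> RunConfig:
    top_allowed = {"model", "drive", "solver", "sweep", "sampling", "seed",
                   "out_dir"}
    unknown = set(data) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "model" not in data:
        raise ConfigError("a 'model' section is required")
    model = _build_model(dict(data["model"]))
    drive = None
    if "drive" in data:
        dv = _take(dict(data["drive"]), _DRIVE_DEFAULTS, "drive")
        if dv["Lambda"] is None or dv["f_in"] is None:
            raise ConfigError("drive.Lambda and drive.f_in are required")
        drive = DriveProtocol(Lambda=dv["Lambda"], f_in=dv["f_in"],
                              delta_phi=parse_phase(dv["delta_phi"]),
                              settle=dv["settle"], total=dv["total"],
                              P=dv["P"])
    solver = SolverConfig(**_take(dict(data.get("solver", {})),
                                  asdict(SolverConfig()), "solver"))
    sweep_defaults = {**asdict(SweepSettings()),
                      "q_values": list(SweepSettings().q_values)}
    sw = _take(dict(data.get("sweep", {})), sweep_defaults, "sweep")
    sw["delta_phi"] = parse_phase(sw["delta_phi"])
    sw["q_values"] = tuple(float(q) for q in sw["q_values"])
    sweep = SweepSettings(**sw)
    sampling = SamplingSettings(**_take(dict(data.get("sampling", {})),
                                        asdict(SamplingSettings()),
                                        "sampling"))
    seed = int(data.get("seed", 0))
    out_dir = str(data.get("out_dir", "results"))
    return RunConfig(model=model, drive=drive, solver=solver, sweep=sweep,
                     sampling=sampling, seed=seed, out_dir=out_dir)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config file.

    Raises
    ------
    ConfigError
        Naming the offending key on any schema violation.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    try:
        return _from_mapping(data)
    except TypeError as exc:  # wrong value type reaching a dataclass
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    """Serialize a config so that load_config round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
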