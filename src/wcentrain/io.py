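"""CSV / JSON readers and writers.

Every results CSV starts with comment lines recording the config hash and
seed that produced it, so outputs remain traceable to their inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd

from .model import Trajectory

__all__ = ["config_hash", "write_results_csv", "read_results_csv",
           "trajectory_to_csv", "trajectory_from_csv", "write_manifest"]


def config_hash(config_dict: Dict[str, Any]) -> str:
    """Short stable hash of a canonicalized config mapping."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_results_csv(frame: pd.DataFrame, path, *, seed: Optional[int],
                      cfg_hash: Optional[str] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash or 'none'}\n")
        fh.write(f"# seed={seed if seed is not None else 'none'}\n")
        frame.to_csv(fh, index=False)


def read_results_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def trajectory_to_csv(trajectory: Trajectory, path) -> None:
    """Full-precision export with header ``t,E,I_dend,I_soma,input``."""
    frame = pd.DataFrame({
        "t": trajectory.t,
        "E": trajectory.E,
        "I_dend": trajectory.I_dend,
        "I_soma": trajectory.I_soma,
        "input": trajectory.input,
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.17g")


def trajectory_from_csv(path) -> Trajectory:
    frame = pd.read_csv(path, comment="#")
    states = np.column_stack([frame["E"], frame["I_dend"], frame["I_soma"]])
    return Trajectory(t=frame["t"].to_numpy(), states=states,
                      input=frame["input"].to_numpy())


def write_manifest(path, *, seed: int, cfg_hash: str,
                   extra: Optional[Dict[str, Any]] = None) -> None:
    """JSON run manifest next to the result files."""
    payload = {"seed": seed, "config_hash": cfg_hash}
    if extra:
        payload.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
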