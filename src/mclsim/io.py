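"""Configuration loading/validation, result serialization, run manifests.

Preset files are JSON documents with a ``params`` object (one key per
CircuitParams field, validated strictly: unknown keys are rejected) and an
optional ``initial_state`` object holding the committed steady-state start
point. Time series are written as plain CSV; experiment results as
canonically ordered JSON with an embedded run manifest.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import List, Optional, Tuple

from pydantic import ValidationError

from . import __version__ as _pkg_version
from .circuit import Trajectory
from .errors import ConfigFileError
from .parameters import CircuitParams, StateVector, default_initial_state

TIMESERIES_COLUMNS = [
    "time_s", "p_lv", "p_rv", "p_la", "p_ra", "p_ao", "p_pa", "p_pv",
    "q_systemic", "q_ecmo", "q_aortic_valve",
    "v_lv", "v_rv", "v_la", "v_ra",
    "water_aoc", "water_svc", "water_pac", "water_pvc",
]


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    experiment_name: str
    timestamp: str
    seed: Optional[int] = None
    output_files: List[str] = field(default_factory=list)

    @classmethod
    def create(cls, params: CircuitParams, experiment_name: str,
               seed: Optional[int] = None,
               output_files: Optional[List[str]] = None) -> "RunManifest":
        return cls(tool_version=_pkg_version,
                   config_hash=params.config_hash(),
                   experiment_name=experiment_name,
                   timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
                   seed=seed, output_files=output_files or [])

    def as_dict(self) -> dict:
        return {"tool_version": self.tool_version,
                "config_hash": self.config_hash,
                "experiment_name": self.experiment_name,
                "timestamp": self.timestamp, "seed": self.seed,
                "output_files": self.output_files}


def _validate_params(obj: dict, source: str) -> CircuitParams:
    try:
        return CircuitParams.model_validate(obj)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigFileError(
            f"{source}: invalid configuration at '{loc}': {first['msg']}"
        ) from exc


def load_config(path: str | Path) -> CircuitParams:
    """Load and schema-validate a parameter file (unknown keys rejected)."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except FileNotFoundError:
        raise ConfigFileError(f"config file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise ConfigFileError(f"{path}: not valid JSON: {exc}") from exc
    params_obj = doc.get("params", doc) if isinstance(doc, dict) else doc
    return _validate_params(params_obj, str(path))


def load_preset(path_or_name: str | Path) -> Tuple[CircuitParams, StateVector]:
    """Load a preset (by shipped name like 'normal' or by path); returns the
    parameters and the committed (or default) initial state."""
    path = Path(path_or_name)
    if not path.exists() and not str(path_or_name).endswith(".json"):
        path = preset_path(str(path_or_name))
    try:
        doc = json.loads(Path(path).read_text())
    except FileNotFoundError:
        raise ConfigFileError(f"preset not found: {path_or_name}") from None
    except json.JSONDecodeError as exc:
        raise ConfigFileError(f"{path}: not valid JSON: {exc}") from exc
    params = _validate_params(doc.get("params", doc), str(path))
    if "initial_state" in doc:
        try:
            initial = StateVector(**doc["initial_state"])
        except TypeError as exc:
            raise ConfigFileError(f"{path}: malformed initial_state: {exc}") from exc
    else:
        initial = default_initial_state(params)
    return params, initial


def preset_path(name: str) -> Path:
    p = resources.files("mclsim") / "presets" / f"{name}.json"
    return Path(str(p))


def list_presets() -> List[str]:
    folder = resources.files("mclsim") / "presets"
    return sorted(f.name[:-5] for f in folder.iterdir() if f.name.endswith(".json"))


def save_preset(params: CircuitParams, initial: StateVector,
                path: str | Path) -> None:
    doc = {"params": params.model_dump(mode="json"),
           "initial_state": {f: getattr(initial, f) for f in StateVector.FIELDS}}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def write_timeseries_csv(trajectory: Trajectory, path: str | Path) -> Path:
    """Fixed-column CSV, one row per integration sample, 6 significant digits."""
    if len(trajectory) == 0:
        raise ConfigFileError("refusing to write an empty trajectory")
    df = trajectory.to_dataframe()[TIMESERIES_COLUMNS]
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def write_summary_json(result, path: str | Path,
                       params: Optional[CircuitParams] = None,
                       seed: Optional[int] = None) -> Path:
    """Serialize an experiment result with its run manifest; canonical key
    order so identical runs produce byte-identical files (timestamp is
    outside the hash scope)."""
    doc = result.as_dict() if hasattr(result, "as_dict") else dict(result)
    missing = [k for k in ("experiment_name", "configuration") if k not in doc]
    if "points" in doc and not doc["points"]:
        missing.append("points (empty)")
    if missing:
        raise ConfigFileError(f"malformed result: missing {missing}")
    if params is not None:
        doc["manifest"] = RunManifest.create(
            params, doc.get("experiment_name", "run"), seed=seed,
            output_files=[str(path)]).as_dict()
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True, default=_coerce) + "\n")
    return path


def _coerce(obj):
    try:
        import numpy as np
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
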