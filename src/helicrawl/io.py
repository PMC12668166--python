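"""Structured-text (YAML) config and delimited-text readers/writers."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .hemodynamics import FlowCondition, MagnetModel, StabilityParams
from .helix import RobotSpec
from .localization import FrameCalibration
from .mechanics import MechanicalParams
from .sizing import DEFAULT_CATALOG, VesselProfile


def _load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, (dict, list)):
        raise ConfigurationError(f"config file {path} is empty or malformed")
    return data


def _dump_yaml(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_robot_spec(path: str | Path) -> RobotSpec:
    return RobotSpec(**_load_yaml(path))


def write_robot_spec(spec: RobotSpec, path: str | Path) -> None:
    _dump_yaml(asdict(spec), path)


def read_catalog(path: str | Path) -> list[float]:
    """Catalog file: YAML list of diameters or a mapping with a 'sizes' key."""
    data = _load_yaml(path)
    sizes = data.get("sizes") if isinstance(data, dict) else data
    if not sizes:
        raise ConfigurationError(f"catalog file {path} lists no sizes")
    return sorted(float(s) for s in sizes)


def write_catalog(sizes, path: str | Path) -> None:
    _dump_yaml({"sizes": [float(s) for s in sizes]}, path)


def read_mechanical_params(path: str | Path) -> MechanicalParams:
    return MechanicalParams(**_load_yaml(path))


def read_flow_condition(path: str | Path) -> FlowCondition:
    return FlowCondition(**_load_yaml(path))


def read_stability_params(path: str | Path) -> StabilityParams:
    return StabilityParams(**_load_yaml(path))


def read_magnet_model(path: str | Path) -> MagnetModel:
    data = _load_yaml(path)
    for key in ("position", "axis"):
        if key in data:
            data[key] = tuple(data[key])
    return MagnetModel(**data)


def read_calibration(path: str | Path) -> FrameCalibration:
    data = _load_yaml(path)
    if "translation" in data:
        data["translation"] = tuple(data["translation"])
    return FrameCalibration(**data)


def write_calibration(cal: FrameCalibration, path: str | Path) -> None:
    _dump_yaml(
        {
            "scale": cal.scale,
            "rotation_deg": cal.rotation_deg,
            "translation": list(cal.translation),
            "projection_axis": cal.projection_axis,
        },
        path,
    )


def read_vessel(path: str | Path) -> VesselProfile:
    return VesselProfile.from_csv(path)


def default_catalog() -> list[float]:
    return list(DEFAULT_CATALOG)
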