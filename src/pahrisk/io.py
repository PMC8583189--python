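"""File formats, configuration and run manifests.

CSV schemas
-----------
sites
    ``site_id, district, area, x, y`` plus either ``bap_eq`` (ng·m⁻³,
    annual total) or one column per congener.
participants
    ``id, age, sex, area, height_cm, bw_kg`` plus ``ir_lpm`` (optional)
    and either ``x, y`` coordinates or a pre-assigned ``site_id``.
quantiles
    ``stratum, parameter, p, value`` (handbook-style).

Scenario and simulation configurations are YAML mappings; numbers in
emitted JSON are serialized to 6 significant digits and every command
records a :class:`RunManifest` with a stable configuration hash.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import LogNormalParams, PowerLawModel
from .mcs import MCSConfig, StratumParams
from .risk_core import ExposureConstants
from .synth import AgeStratumSpec, ScenarioSpec

__all__ = [
    "SITE_COLUMNS",
    "PARTICIPANT_COLUMNS",
    "RunManifest",
    "read_sites",
    "read_participants",
    "write_table",
    "read_quantiles",
    "jsonable",
    "write_json",
    "config_hash",
    "write_manifest",
    "load_yaml",
    "scenario_from_mapping",
    "mcs_config_from_mapping",
]

SITE_COLUMNS = ("site_id", "area", "x", "y")
PARTICIPANT_COLUMNS = ("id", "age", "sex", "height_cm", "bw_kg")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    for column in required:
        if column not in df.columns:
            raise ValueError(f"{what} table is missing required column {column!r}")


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SITE_COLUMNS, "site")
    if "bap_eq" not in df.columns:
        from .risk_core import PRIORITY_CONGENERS

        if not any(c in df.columns for c in PRIORITY_CONGENERS):
            raise ValueError(
                "site table is missing required column 'bap_eq' "
                "(or per-congener concentration columns)"
            )
    if df.empty:
        raise ValueError("site table is empty")
    return df


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PARTICIPANT_COLUMNS, "participant")
    if "site_id" not in df.columns and not {"x", "y"}.issubset(df.columns):
        raise ValueError(
            "participant table is missing required column 'site_id' (or 'x'/'y')"
        )
    if df.empty:
        raise ValueError("participant table is empty")
    return df


def read_quantiles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("stratum", "parameter", "p", "value"), "quantile")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _round_sig(x: float, digits: int = 6) -> float:
    if not np.isfinite(x):
        return float(x)
    return float(f"{x:.{digits}g}")


def jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses/numpy/enums to JSON-safe values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(k): jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer, int, str, bool)) or obj is None:
        return int(obj) if isinstance(obj, np.integer) else obj
    return str(obj)


def write_json(obj: Any, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


def config_hash(config: Any) -> str:
    """Stable sha256 of a configuration object's canonical JSON form."""
    canonical = json.dumps(jsonable(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every command's artifacts."""

    command: str
    seed: int | None
    config_hash: str
    version: str
    created: str
    artifacts: tuple[str, ...]


def write_manifest(out_dir, command: str, seed, config, artifacts) -> RunManifest:
    out_dir = Path(out_dir)
    manifest = RunManifest(
        command=command,
        seed=seed,
        config_hash=config_hash(config),
        version=__version__,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        artifacts=tuple(str(Path(a).name) for a in artifacts),
    )
    write_json(manifest, out_dir / "manifest.json")
    return manifest


def load_yaml(path) -> dict:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def _lognormal(entry, what: str) -> LogNormalParams:
    if entry is None:
        raise ValueError(f"missing lognormal parameters for {what}")
    if isinstance(entry, LogNormalParams):
        return entry
    return LogNormalParams(a=float(entry["a"]), b=float(entry["b"]))


def _power_law(entry) -> PowerLawModel | None:
    if entry is None:
        return None
    if isinstance(entry, PowerLawModel):
        return entry
    return PowerLawModel(
        slope=float(entry["slope"]),
        intercept=float(entry["intercept"]),
        residual_sd=float(entry.get("residual_sd", 0.0)),
    )


def _constants(entry) -> ExposureConstants:
    if entry is None:
        return ExposureConstants()
    if isinstance(entry, ExposureConstants):
        return entry
    return ExposureConstants(**{k: float(v) for k, v in entry.items()})


def scenario_from_mapping(data: Mapping) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a YAML-style mapping."""
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for key in (
        "n_sites",
        "n_participants",
        "ir_mode",
        "sex_bw_log_offset",
        "male_fraction",
        "site_cluster_sigma",
        "participant_cluster_sigma",
    ):
        if key in data:
            kwargs[key] = data[key]
    for key in ("site_concentration", "whole_bw", "whole_ir", "participant_exposure"):
        if key in data and data[key] is not None:
            kwargs[key] = _lognormal(data[key], key)
    if "ir_power_law" in data:
        kwargs["ir_power_law"] = _power_law(data["ir_power_law"])
    if "strata" in data:
        kwargs["strata"] = tuple(
            AgeStratumSpec(
                label=str(s["label"]),
                age_lo=int(s["age_lo"]),
                age_hi=int(s["age_hi"]),
                weight=float(s["weight"]),
                bw=_lognormal(s["bw"], "stratum bw"),
                ir=_lognormal(s["ir"], "stratum ir"),
            )
            for s in data["strata"]
        )
    for key in (
        "cluster_centers",
        "cluster_log_offsets",
        "cluster_participant_weights",
        "cluster_areas",
    ):
        if key in data:
            value = data[key]
            if value is not None:
                value = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v for v in value
                )
            kwargs[key] = value
    spec = ScenarioSpec(**kwargs)
    spec.validate()
    return spec


def mcs_config_from_mapping(data: Mapping, **overrides) -> MCSConfig:
    """Build an :class:`MCSConfig` from a YAML-style mapping.

    Accepts the simulation block either at the top level or nested under
    a ``simulation`` key; keyword overrides (variant, seed, iterations)
    win over file values.
    """
    data = dict(data)
    block = dict(data.get("simulation", data))
    block.update({k: v for k, v in overrides.items() if v is not None})
    strata = None
    if block.get("strata"):
        strata = tuple(
            StratumParams(
                label=str(s["label"]),
                weight=float(s["weight"]),
                bw=_lognormal(s["bw"], "stratum bw"),
                ir=_lognormal(s["ir"], "stratum ir"),
            )
            for s in block["strata"]
        )
    return MCSConfig(
        variant=block["variant"],
        concentration=_lognormal(block.get("concentration"), "concentration"),
        iterations=int(block.get("iterations", 30_000)),
        seed=int(block.get("seed", 0)),
        bw=_lognormal(block["bw"], "bw") if block.get("bw") else None,
        ir=_lognormal(block["ir"], "ir") if block.get("ir") else None,
        strata=strata,
        ir_model=_power_law(block.get("ir_model")),
        ir_residual_sd=float(block.get("ir_residual_sd", 0.0)),
        constants=_constants(data.get("constants")),
    )
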