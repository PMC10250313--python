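"""File formats and run configuration.

Tube laws travel as CSV with unit-bearing headers (``time_s``,
``p_intr_pa`` and either ``area_norm`` or ``area_m2`` — files must
self-describe whether areas are normalized) plus a JSON sidecar carrying
geometry, material, ground truth and seed.  Run configurations are
YAML/JSON mappings validated strictly: unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ShuffledDataWarning
from .models import Material, TubeGeometry
from .synthetic import RampSpec, TubeLawCurve

__all__ = [
    "write_tubelaw_csv",
    "read_tubelaw_csv",
    "write_trace_csv",
    "read_trace_csv",
    "RunConfig",
    "load_run_config",
    "config_hash",
    "write_result_json",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _geometry_dict(g: TubeGeometry | None):
    return None if g is None else {"d": g.d, "gamma": g.gamma, "l": g.l, "r": g.r}


def _material_dict(m: Material | None):
    return None if m is None else {"E": m.E, "nu": m.nu, "rho": m.rho}


def write_tubelaw_csv(curve: TubeLawCurve, path) -> Path:
    """Write a tube law as CSV plus a JSON metadata sidecar.

    The area column is named ``area_norm`` or ``area_m2`` according to the
    curve's normalization flag; the sidecar holds geometry, material and
    the curve metadata (ground truth, seed).  Returns the CSV path.
    """
    path = Path(path)
    area_col = "area_norm" if curve.normalized else "area_m2"
    df = pd.DataFrame(
        {
            "time_s": curve.time,
            "p_intr_pa": curve.p_intr,
            area_col: curve.area,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "geometry": _geometry_dict(curve.geometry),
        "material": _material_dict(curve.material),
        "meta": curve.meta,
    }
    _sidecar_path(path).write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
    )
    return path


def read_tubelaw_csv(path) -> TubeLawCurve:
    """Read a tube law CSV (and its sidecar, if present) back into a
    :class:`TubeLawCurve`.

    Rows are sorted by time (with a :class:`ShuffledDataWarning` if they
    were out of order); schema violations — missing columns, an all-zero
    area column, pressures that increase over time — raise
    :class:`SchemaError` with the offending row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path)
    required = {"time_s", "p_intr_pa"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if "area_norm" in df.columns:
        area_col, normalized = "area_norm", True
    elif "area_m2" in df.columns:
        area_col, normalized = "area_m2", False
    else:
        raise SchemaError(f"{path}: need an 'area_norm' or 'area_m2' column")
    if not np.any(df[area_col].to_numpy() != 0):
        raise SchemaError(f"{path}: area column is identically zero")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        warnings.warn(
            f"{path}: rows were not time-ordered; sorted on read",
            ShuffledDataWarning,
            stacklevel=2,
        )
        df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    p = df["p_intr_pa"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(p) > 1e-9)[0]
    if bad.size:
        raise SchemaError(
            f"{path}: p_intr increases over time at rows {list(bad[:10] + 1)}",
            rows=list(bad + 1),
        )

    geometry = material = None
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        if info.get("geometry"):
            geometry = TubeGeometry(**info["geometry"])
        if info.get("material"):
            material = Material(**info["material"])
        meta = info.get("meta", {})
    return TubeLawCurve(
        time=df["time_s"].to_numpy(dtype=float),
        p_intr=p,
        area=df[area_col].to_numpy(dtype=float),
        normalized=normalized,
        geometry=geometry,
        material=material,
        meta=meta,
    )


def write_trace_csv(trace, path) -> Path:
    """Write a perimeter trace as CSV with columns theta_rad, r_m."""
    path = Path(path)
    pd.DataFrame({"theta_rad": trace.theta, "r_m": trace.r}).to_csv(
        path, index=False, float_format="%.12g"
    )
    return path


def read_trace_csv(path):
    """Read a perimeter trace CSV (columns theta_rad, r_m)."""
    from .cross_section import PerimeterTrace

    path = Path(path)
    df = pd.read_csv(path)
    if not {"theta_rad", "r_m"}.issubset(df.columns):
        raise SchemaError(f"{path}: need columns theta_rad, r_m")
    return PerimeterTrace(
        theta=df["theta_rad"].to_numpy(dtype=float),
        r=df["r_m"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class EstimatorConfig:
    contact_area_threshold: float = 0.35
    n_grid: int = 25


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    geometry: TubeGeometry = field(
        default_factory=lambda: TubeGeometry(d=3.0, gamma=0.06, l=1.1)
    )
    material: Material = field(default_factory=Material)
    ramp: RampSpec = field(default_factory=RampSpec)
    generator: dict = field(default_factory=dict)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    sweeps: dict = field(default_factory=dict)
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"


def _strict_build(cls, mapping, context):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise SchemaError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**mapping)


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Component invariants are enforced by the domain types themselves;
    unknown keys anywhere raise :class:`SchemaError`.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    if "geometry" in raw:
        kwargs["geometry"] = _strict_build(TubeGeometry, raw["geometry"], "geometry")
    if "material" in raw:
        kwargs["material"] = _strict_build(Material, raw["material"], "material")
    if "ramp" in raw:
        kwargs["ramp"] = _strict_build(RampSpec, raw["ramp"], "ramp")
    if "estimator" in raw:
        kwargs["estimator"] = _strict_build(
            EstimatorConfig, raw["estimator"], "estimator"
        )
    for key in ("generator", "sweeps", "output_dir", "seed", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def config_hash(cfg) -> str:
    """Short stable hash of a configuration (dataclass or mapping), for
    embedding in outputs so runs are auditable."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        cfg = dataclasses.asdict(cfg)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_result_json(payload: dict, path, *, seed=None, config=None) -> Path:
    """Write a result JSON, embedding seed and config hash provenance."""
    path = Path(path)
    out = dict(payload)
    out["provenance"] = {
        "seed": None if seed is None else int(seed),
        "config_sha256": None if config is None else config_hash(config),
    }
    path.write_text(json.dumps(out, indent=1, sort_keys=True, default=float) + "\n")
    return path
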