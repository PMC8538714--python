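"""Dataset and configuration I/O.

One canonical dataset dialect: long-format CSV (comma, dot decimal,
UTF-8, header required) with columns ``id, time_h, stream, conc_mg_L``
(optionally ``group``), times in hours from the first monitored dose,
streams "pre" / "post" / "effluent".  A sidecar YAML manifest carries the
dosing design, RRT settings, parameters and per-subject weights needed to
regenerate or analyze the data.

Flows may be given as numbers (L/h) or strings with an explicit unit
suffix: ``"6 L/h"``, ``"100 mL/min"``, ``"30 mL/kg/h"`` (the latter needs
a body weight).
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .cohort import STREAMS, StudyDesign
from .model import PopulationParameters
from .rrt import RRTSettings

__all__ = [
    "parse_flow",
    "read_dataset",
    "write_dataset",
    "load_config",
    "config_hash",
    "rrt_from_config",
    "params_from_config",
    "design_from_config",
]

REQUIRED_COLUMNS = ("id", "time_h", "stream", "conc_mg_L")

_FLOW_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(L/h|mL/min|mL/kg/h)\s*$")


class DatasetError(ValueError):
    """The dataset violates the canonical schema."""


def parse_flow(value, weight_kg: float | None = None) -> float:
    """Convert a flow specification to L/h.

    Numbers pass through as L/h.  Strings need a unit suffix; mL/min is
    multiplied by 0.06, mL/kg/h by weight/1000.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _FLOW_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse flow {value!r}; use e.g. '6 L/h', '100 mL/min', '30 mL/kg/h'")
    x, unit = float(m.group(1)), m.group(2)
    if unit == "L/h":
        return x
    if unit == "mL/min":
        return x * 0.06
    if weight_kg is None:
        raise ValueError(f"flow {value!r} is weight-based but no weight was given")
    return x * weight_kg / 1000.0


def write_dataset(table: pd.DataFrame, manifest: dict, base: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.csv`` and ``<base>.manifest.yaml``."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    man_path = base.with_suffix(".manifest.yaml")
    table.to_csv(csv_path, index=False)
    man_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return csv_path, man_path


def read_dataset(csv_path: str | Path, manifest_path: str | Path | None = None):
    """Read and validate a dataset; returns (table, manifest-or-None).

    Schema violations are reported with offending row numbers (1-based,
    excluding the header).
    """
    csv_path = Path(csv_path)
    try:
        table = pd.read_csv(csv_path)
    except pd.errors.EmptyDataError:
        raise DatasetError(f"{csv_path}: no records (empty file)") from None
    if table.empty:
        raise DatasetError(f"{csv_path}: no records")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DatasetError(f"{csv_path}: missing column(s) {missing}")
    bad = ~table["stream"].isin(STREAMS)
    if bad.any():
        rows = (table.index[bad] + 1).tolist()[:5]
        raise DatasetError(
            f"{csv_path}: unknown stream label(s) {sorted(table.loc[bad, 'stream'].unique())} "
            f"at row(s) {rows}; expected {STREAMS}"
        )
    if (table["time_h"] < 0).any():
        rows = (table.index[table["time_h"] < 0] + 1).tolist()[:5]
        raise DatasetError(f"{csv_path}: negative time_h at row(s) {rows}")
    if (table["conc_mg_L"] < 0).any():
        rows = (table.index[table["conc_mg_L"] < 0] + 1).tolist()[:5]
        raise DatasetError(f"{csv_path}: negative concentration at row(s) {rows}")
    for (sid, stream), grp in table.groupby(["id", "stream"], sort=False):
        t = grp["time_h"].to_numpy()
        if (t[1:] < t[:-1]).any():
            j = int(grp.index[1:][t[1:] < t[:-1]][0]) + 1
            raise DatasetError(
                f"{csv_path}: non-monotone times for id={sid} stream={stream} near row {j}"
            )
    manifest = None
    if manifest_path is None:
        candidate = csv_path.with_suffix(".manifest.yaml")
        manifest_path = candidate if candidate.exists() else None
    if manifest_path is not None:
        manifest = yaml.safe_load(Path(manifest_path).read_text())
    return table, manifest


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    cfg = yaml.safe_load(Path(path).read_text())
    return cfg or {}


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def rrt_from_config(config: Mapping, weight_kg: float | None = None) -> RRTSettings:
    block = dict(config.get("rrt", {}))
    kwargs = {}
    for key in ("q_blood", "q_dial", "q_rf_pre", "q_frr"):
        if key in block:
            kwargs[key] = parse_flow(block[key], weight_kg)
    for key in ("hct", "modality"):
        if key in block:
            kwargs[key] = block[key]
    return RRTSettings(**kwargs)


def params_from_config(config: Mapping) -> PopulationParameters:
    block = dict(config.get("parameters", {}))
    base = PopulationParameters()
    merged = {}
    for key in ("cl_body", "v1", "q", "v2", "cl_rrt", "f_ads", "ads_max", "rbctp",
                "iov_cv_cl_body"):
        if key in block:
            merged[key] = float(block[key])
    if "iiv_cv" in block:
        merged["iiv_cv"] = {**base.iiv_cv, **{k: float(v) for k, v in block["iiv_cv"].items()}}
    if "ruv_prop" in block:
        merged["ruv_prop"] = {**base.ruv_prop, **{k: float(v) for k, v in block["ruv_prop"].items()}}
    return base.with_(**merged) if merged else base


def design_from_config(config: Mapping) -> StudyDesign:
    block = dict(config.get("design", {}))
    if "sampling_times" in block:
        block["sampling_times"] = tuple(float(t) for t in block["sampling_times"])
    return StudyDesign(**block) if block else StudyDesign()
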