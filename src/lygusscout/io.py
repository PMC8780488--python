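"""Plain-CSV and JSON readers/writers for every table the pipeline uses.

All files are UTF-8 CSV with '.' decimal and a fixed header; the readers
validate the schema so user-supplied tables can replace synthetic ones
anywhere in the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    LANDSCAPE_CLASSES,
    RETENTION_COLUMNS,
    UNIT_COLUMNS,
    SpatialDataset,
    retention_to_frame,
    units_to_frame,
    validate_landscape,
)
from .synthetic import HierarchySpec

SPATIAL_COLUMNS = ("field_id", "x_km", "y_km", "growth_stage", "q", "adults",
                   *LANDSCAPE_CLASSES)


def write_units_csv(frame: pd.DataFrame, path) -> None:
    units_to_frame(frame)[list(UNIT_COLUMNS)].to_csv(path, index=False)


def read_units_csv(path) -> pd.DataFrame:
    return units_to_frame(pd.read_csv(path))


def write_retention_csv(frame: pd.DataFrame, path) -> None:
    retention_to_frame(frame)[list(RETENTION_COLUMNS)].to_csv(path, index=False)


def read_retention_csv(path) -> pd.DataFrame:
    return retention_to_frame(pd.read_csv(path))


def write_landscape_csv(frame: pd.DataFrame, path) -> None:
    validate_landscape(frame).to_csv(path, index=False)


def read_landscape_csv(path) -> pd.DataFrame:
    return validate_landscape(pd.read_csv(path))


def write_spatial_csv(dataset: SpatialDataset, path) -> None:
    frame = pd.DataFrame({
        "field_id": dataset.field_id,
        "x_km": dataset.coords_km[:, 0],
        "y_km": dataset.coords_km[:, 1],
        "growth_stage": dataset.growth_stage,
        "q": dataset.q,
        "adults": dataset.y,
    })
    for cls in LANDSCAPE_CLASSES:
        frame[cls] = dataset.covariates[cls].to_numpy()
    frame[list(SPATIAL_COLUMNS)].to_csv(path, index=False)


def read_spatial_csv(path) -> SpatialDataset:
    frame = pd.read_csv(path)
    missing = set(SPATIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing spatial columns: {sorted(missing)}")
    return SpatialDataset(
        field_id=frame["field_id"].to_numpy(),
        coords_km=frame[["x_km", "y_km"]].to_numpy(float),
        covariates=frame[list(LANDSCAPE_CLASSES)].copy(),
        q=frame["q"].to_numpy(int),
        growth_stage=frame["growth_stage"].to_numpy(),
        y=frame["adults"].to_numpy(int),
    )


def write_hierarchy_spec(spec: HierarchySpec, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(spec), indent=2))


def read_hierarchy_spec(path) -> HierarchySpec:
    return HierarchySpec(**json.loads(Path(path).read_text()))


def write_json(obj, path) -> None:
    """JSON writer that understands dataclasses and numpy scalars/arrays."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict("list")
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
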