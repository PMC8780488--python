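"""Row schemas and container helpers for scouting data.

The canonical in-memory container throughout the package is a
:class:`pandas.DataFrame` with a fixed column set; the dataclasses here
describe one row each and provide list-of-records <-> frame conversion for
callers that prefer plain Python objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Land-cover classes tabulated inside the 0.5 km buffer around each field.
#: ``agriculture`` is the superset of all cultivated classes.
LANDSCAPE_CLASSES = (
    "agriculture",
    "corn",
    "cotton",
    "forest",
    "peanuts",
    "soybeans",
    "doublecrop_wheat_soy",
    "wheat",
)

#: Cultivated classes contained in ``agriculture``.
CULTIVATED_CLASSES = (
    "corn",
    "cotton",
    "peanuts",
    "soybeans",
    "doublecrop_wheat_soy",
    "wheat",
)

UNIT_COLUMNS = (
    "year",
    "state",
    "district",
    "field_id",
    "quadrant",
    "unit",
    "method",
    "growth_stage",
    "unit_size",
    "adults",
    "nymphs",
    "total",
)

RETENTION_COLUMNS = (
    "field_id",
    "quadrant",
    "growth_stage",
    "positions_checked",
    "retained",
    "density",
)


@dataclass(frozen=True)
class SamplingUnitRecord:
    """One insect count observation with its full nesting labels.

    ``unit_size`` is the physical size of the sampling unit: 100 sweeps for
    sweep-net samples taken at squaring, 1.5 row-m for drop-cloth samples
    taken at bloom.
    """

    year: int
    state: str
    district: str
    field_id: str
    quadrant: int
    unit: int
    method: str
    growth_stage: str
    unit_size: float
    adults: int
    nymphs: int
    total: int

    def __post_init__(self) -> None:
        if self.total != self.adults + self.nymphs:
            raise ValueError("total must equal adults + nymphs")
        if self.quadrant not in (1, 2, 3, 4):
            raise ValueError("quadrant must be in 1..4")
        if min(self.adults, self.nymphs) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class RetentionRecord:
    """Square-retention inspection for one field quadrant.

    25 first-position squares (5 plants x 5 nodes) are checked per quadrant;
    ``retained`` of them have not abscised. ``density`` is the paired insect
    density on the per-sampling-unit scale.
    """

    field_id: str
    quadrant: int
    growth_stage: str
    positions_checked: int
    retained: int
    density: float

    def __post_init__(self) -> None:
        if not (0 <= self.retained <= self.positions_checked):
            raise ValueError("retained must lie in 0..positions_checked")
        if self.density < 0:
            raise ValueError("density must be non-negative")


def units_to_frame(records: Iterable[SamplingUnitRecord] | pd.DataFrame) -> pd.DataFrame:
    """Coerce sampling-unit records to the canonical DataFrame."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame([vars(r) for r in records])
    missing = set(UNIT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing sampling-unit columns: {sorted(missing)}")
    return frame


def frame_to_units(frame: pd.DataFrame) -> list[SamplingUnitRecord]:
    return [
        SamplingUnitRecord(**{f.name: row[f.name] for f in dc_fields(SamplingUnitRecord)})
        for row in frame.to_dict("records")
    ]


def retention_to_frame(records: Iterable[RetentionRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame([vars(r) for r in records])
    missing = set(RETENTION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing retention columns: {sorted(missing)}")
    return frame


def validate_landscape(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a landscape covariate table (one row per field)."""
    required = ("field_id", "x_km", "y_km", *LANDSCAPE_CLASSES)
    missing = set(required) - set(table.columns)
    if missing:
        raise ValueError(f"missing landscape columns: {sorted(missing)}")
    props = table[list(LANDSCAPE_CLASSES)].to_numpy(float)
    if (props < -1e-12).any() or (props > 1 + 1e-12).any():
        raise ValueError("class proportions must lie in [0, 1]")
    cult = table[list(CULTIVATED_CLASSES)].to_numpy(float)
    if (table["agriculture"].to_numpy(float)[:, None] + 1e-9 < cult).any():
        raise ValueError("agriculture must dominate every cultivated subclass")
    return table


@dataclass
class SpatialDataset:
    """Inputs for the hierarchical spatial Poisson model.

    One row per field visit: planar coordinates (km), a covariate row of
    land-cover proportions, the number of quadrants sampled (``q``, the
    Poisson offset is ``log q``), the growth stage at the visit and the
    adult count response. Rows from the same ``field_id`` share one spatial
    random effect.
    """

    field_id: np.ndarray
    coords_km: np.ndarray  # (n_rows, 2); repeated for repeat visits
    covariates: pd.DataFrame  # (n_rows, classes)
    q: np.ndarray
    growth_stage: np.ndarray
    y: np.ndarray
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.y)
        self.field_id = np.asarray(self.field_id)
        self.coords_km = np.asarray(self.coords_km, float)
        self.q = np.asarray(self.q)
        self.growth_stage = np.asarray(self.growth_stage)
        self.y = np.asarray(self.y)
        shapes = (len(self.field_id), len(self.coords_km), len(self.covariates),
                  len(self.q), len(self.growth_stage))
        if any(s != n for s in shapes):
            raise ValueError("all SpatialDataset fields must share one length")
        if (self.q < 1).any():
            raise ValueError("offsets q must be >= 1")
        if not np.isfinite(self.coords_km).all():
            raise ValueError("coordinates must be finite")
        if (self.y < 0).any() or not np.issubdtype(self.y.dtype, np.integer):
            raise ValueError("response must be non-negative integers")

    def subset(self, idx: Sequence[int]) -> "SpatialDataset":
        idx = np.asarray(idx)
        return SpatialDataset(
            field_id=self.field_id[idx],
            coords_km=self.coords_km[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            q=self.q[idx],
            growth_stage=self.growth_stage[idx],
            y=self.y[idx],
            truth=self.truth,
        )

    def __len__(self) -> int:
        return len(self.y)
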