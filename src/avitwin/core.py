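"""Shared domain types and numerical primitives.

The digital twin predicts, for every citizen-science recording, the probability
that a given bird species is detected as the product of three components:
migration presence, spatial occurrence and vocal detection.  This module holds
the vocabulary shared by all model components: timestamps, the planar raster
grids on which occurrence surfaces live, recording metadata, the detection
matrix, calendar scaling conventions and the standard-normal CDF/quantile used
by the probit-scale models.

Grid conventions
----------------
Grids are planar, in projected kilometre coordinates, 0-based, row-major, with
the origin at the north-west corner (row 0 is the northernmost).  The fine grid
(0.1 km = 1 ha cells) nests exactly 10x10 inside the coarse grid (1 km^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "Timestamp",
    "GridSpec",
    "CellIndex",
    "RecordingMeta",
    "DetectionMatrix",
    "RasterLayer",
    "std_normal_cdf",
    "std_normal_quantile",
    "cell_distance_km",
    "scale_to_unit",
    "day_fraction",
    "minute_fraction",
    "read_recording_csv",
    "write_recording_csv",
    "read_ascii_grid",
    "write_ascii_grid",
]

REC_TYPES = ("direct", "interval", "point")

DAYS_PER_YEAR = 365
MINUTES_PER_DAY = 1440


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


@dataclass(frozen=True)
class Timestamp:
    """Calendar time of a recording: year, day of year (1-based), minute of day."""

    year: int
    day_of_year: int
    minute_of_day: int

    def __post_init__(self) -> None:
        max_day = 366 if _is_leap(self.year) else 365
        if not 1 <= self.day_of_year <= max_day:
            raise ValueError(
                f"day_of_year {self.day_of_year} out of range 1..{max_day} for {self.year}"
            )
        if not 0 <= self.minute_of_day < MINUTES_PER_DAY:
            raise ValueError(f"minute_of_day {self.minute_of_day} out of range")


@dataclass(frozen=True)
class GridSpec:
    """A regular planar raster grid in projected km coordinates.

    ``origin_easting_km``/``origin_northing_km`` locate the north-west corner;
    cells are ``cell_size_km`` squares, indexed (row, col) from that corner.
    """

    origin_easting_km: float
    origin_northing_km: float
    cell_size_km: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def contains(self, cell: "CellIndex") -> bool:
        return 0 <= cell.row < self.n_rows and 0 <= cell.col < self.n_cols

    def cell_center_km(self, cell: "CellIndex") -> tuple[float, float]:
        """(easting, northing) of the cell center, in km."""
        e = self.origin_easting_km + (cell.col + 0.5) * self.cell_size_km
        n = self.origin_northing_km - (cell.row + 0.5) * self.cell_size_km
        return (e, n)

    def coarsen(self, factor: int = 10) -> "GridSpec":
        """The coarse grid into which this grid nests ``factor`` x ``factor``."""
        if self.n_rows % factor or self.n_cols % factor:
            raise ValueError("grid dimensions must be divisible by the coarsening factor")
        return GridSpec(
            origin_easting_km=self.origin_easting_km,
            origin_northing_km=self.origin_northing_km,
            cell_size_km=self.cell_size_km * factor,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
        )

    def to_coarse(self, cell: "CellIndex", factor: int = 10) -> "CellIndex":
        """Coarse-grid cell containing a fine-grid cell (partition map)."""
        return CellIndex(cell.row // factor, cell.col // factor)


@dataclass(frozen=True, order=True)
class CellIndex:
    row: int
    col: int

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValueError("cell indices are non-negative")


@dataclass(frozen=True)
class RecordingMeta:
    """Metadata for a single recording (sampling-effort covariates).

    ``log_duration`` is the natural log of the duration in minutes, so a
    1-minute recording has log-duration 0 and the probit translation intercept
    aligns with the 1-minute passive-monitoring reference unit.
    """

    recording_id: str
    timestamp: Timestamp
    cell: CellIndex
    latitude_deg: float
    rec_type: str
    duration_min: float

    def __post_init__(self) -> None:
        if self.rec_type not in REC_TYPES:
            raise ValueError(f"rec_type must be one of {REC_TYPES}")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")

    @property
    def log_duration(self) -> float:
        return math.log(self.duration_min)


@dataclass
class DetectionMatrix:
    """The observation stream: recordings x species binary detections.

    A 1 means the upstream classifier flagged the species at >= 0.90
    confidence in that recording.
    """

    recordings: list[RecordingMeta]
    species_ids: list[str]
    values: np.ndarray  # shape (n_recordings, n_species), dtype int8, entries 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.recordings), len(self.species_ids)):
            raise ValueError("values shape must be (n_recordings, n_species)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("detections must be binary")

    def __len__(self) -> int:
        return len(self.recordings)

    def species_column(self, species_id: str) -> np.ndarray:
        return self.values[:, self.species_ids.index(species_id)]

    # --- convenience covariate arrays (derived, cached) ---

    _frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def meta_frame(self) -> pd.DataFrame:
        """Per-recording covariates as a DataFrame (computed once)."""
        if self._frame is None:
            recs = self.recordings
            self._frame = pd.DataFrame(
                {
                    "recording_id": [r.recording_id for r in recs],
                    "year": np.array([r.timestamp.year for r in recs], dtype=int),
                    "day_of_year": np.array([r.timestamp.day_of_year for r in recs], dtype=int),
                    "minute_of_day": np.array([r.timestamp.minute_of_day for r in recs], dtype=int),
                    "row": np.array([r.cell.row for r in recs], dtype=int),
                    "col": np.array([r.cell.col for r in recs], dtype=int),
                    "latitude_deg": np.array([r.latitude_deg for r in recs], dtype=float),
                    "rec_type": pd.Categorical([r.rec_type for r in recs], categories=REC_TYPES),
                    "duration_min": np.array([r.duration_min for r in recs], dtype=float),
                    "log_duration": np.array([r.log_duration for r in recs], dtype=float),
                }
            )
        return self._frame


@dataclass
class RasterLayer:
    """A single-band raster on a :class:`GridSpec`; NaN encodes nodata."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("raster values shape must match grid shape")

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)


# ---------------------------------------------------------------------------
# numerical primitives
# ---------------------------------------------------------------------------


def std_normal_cdf(z):
    """Standard normal CDF Phi(z); vectorized; rejects non-finite input."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("std_normal_cdf requires finite input")
    out = ndtr(z)
    return float(out) if out.ndim == 0 else out


def std_normal_quantile(p):
    """Standard normal quantile Phi^{-1}(p) for p in (0,1); vectorized."""
    p = np.asarray(p, dtype=float)
    if not (np.isfinite(p).all() and (p > 0).all() and (p < 1).all()):
        raise ValueError("std_normal_quantile requires p strictly inside (0,1)")
    out = ndtri(p)
    return float(out) if out.ndim == 0 else out


def cell_distance_km(a: CellIndex, b: CellIndex, grid: GridSpec) -> float:
    """Euclidean distance between cell centers, in km."""
    if not (grid.contains(a) and grid.contains(b)):
        raise ValueError("cells must lie within the grid")
    return math.hypot(a.row - b.row, a.col - b.col) * grid.cell_size_km


def scale_to_unit(value: int, period_length: int) -> float:
    """Map a calendar index to a unit fraction in [0, 1).

    Days (period 365) map as (day-1)/365 with leap day 366 wrapping to 0, so
    the periodic basis is continuous across year boundaries.  Minutes (period
    1440) map as minute/1440.
    """
    if period_length == DAYS_PER_YEAR:
        if not 1 <= value <= 366:
            raise ValueError(f"day {value} out of range 1..366")
        return ((value - 1) % DAYS_PER_YEAR) / DAYS_PER_YEAR
    if not 0 <= value < period_length:
        raise ValueError(f"value {value} out of range 0..{period_length - 1}")
    return value / period_length


def day_fraction(day_of_year) -> np.ndarray | float:
    """Vectorized day -> unit fraction (365-day cycle, day 366 wraps to 0)."""
    d = np.asarray(day_of_year)
    if ((d < 1) | (d > 366)).any():
        raise ValueError("day_of_year out of range 1..366")
    out = ((d - 1) % DAYS_PER_YEAR) / DAYS_PER_YEAR
    return float(out) if out.ndim == 0 else out


def minute_fraction(minute_of_day) -> np.ndarray | float:
    m = np.asarray(minute_of_day)
    if ((m < 0) | (m >= MINUTES_PER_DAY)).any():
        raise ValueError("minute_of_day out of range 0..1439")
    out = m / MINUTES_PER_DAY
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# stream CSV I/O
# ---------------------------------------------------------------------------

_META_COLS = [
    "recording_id",
    "year",
    "day_of_year",
    "minute_of_day",
    "row",
    "col",
    "latitude_deg",
    "rec_type",
    "duration_min",
]


def write_recording_csv(dm: DetectionMatrix, path: str | Path) -> None:
    """Write the recording stream: metadata columns then one 0/1 column per species."""
    frame = dm.meta_frame()[_META_COLS].copy()
    for k, sp in enumerate(dm.species_ids):
        frame[sp] = dm.values[:, k]
    # %.17g keeps the stream lossless under a write/read round trip
    frame.to_csv(path, index=False, float_format="%.17g")


def read_recording_csv(path: str | Path) -> DetectionMatrix:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _META_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"recording CSV missing columns: {missing}")
    species = [c for c in frame.columns if c not in _META_COLS]
    recordings = [
        RecordingMeta(
            recording_id=str(r.recording_id),
            timestamp=Timestamp(int(r.year), int(r.day_of_year), int(r.minute_of_day)),
            cell=CellIndex(int(r.row), int(r.col)),
            latitude_deg=float(r.latitude_deg),
            rec_type=str(r.rec_type),
            duration_min=float(r.duration_min),
        )
        for r in frame.itertuples(index=False)
    ]
    values = frame[species].to_numpy(dtype=np.int8) if species else np.zeros((len(frame), 0), np.int8)
    return DetectionMatrix(recordings=recordings, species_ids=species, values=values)


# ---------------------------------------------------------------------------
# plain-text raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------
#
# Occurrence surfaces are exchanged as ESRI ASCII grids (.asc): a six-line
# header followed by the value matrix, top row first — the plain-text raster
# fallback documented in the package interfaces.  Coordinates are in km.

_NODATA = -1.0


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    g = layer.grid
    vals = np.where(np.isnan(layer.values), _NODATA, layer.values)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_easting_km!r}\n"
        f"yllcorner {g.origin_northing_km - g.n_rows * g.cell_size_km!r}\n"
        f"cellsize {g.cell_size_km!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> RasterLayer:
    with open(path, "r", encoding="utf-8") as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    grid = GridSpec(
        origin_easting_km=header["xllcorner"],
        origin_northing_km=header["yllcorner"] + n_rows * cell,
        cell_size_km=cell,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return RasterLayer(grid=grid, values=vals)
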