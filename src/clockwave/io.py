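"""Reading and writing the formats the pipeline touches.

Traces are exchanged as plain CSV (one time column in minutes, one column
per well/ROI, a single header row); movies as multi-frame single-channel
TIFF; plate layouts as CSV tables. Frame interval and pixel size are always
passed explicitly rather than read from TIFF tags, because tag conventions
differ between acquisition packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TimeSeries",
    "MovieStack",
    "PlateLayout",
    "read_pmt_csv",
    "write_timeseries_csv",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_plate_layout",
]

#: relative tolerance on deviations from a uniform time grid
_GRID_RTOL = 1e-6


@dataclass
class TimeSeries:
    """A single luminescence trace on a uniform time grid.

    Parameters
    ----------
    time_min
        Acquisition times in minutes, strictly increasing, uniformly spaced.
    value
        Intensities in counts per second (cps), same length as ``time_min``.
    label
        Well or ROI identifier.
    """

    time_min: np.ndarray
    value: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_min.ndim != 1 or self.value.ndim != 1:
            raise ValueError("time_min and value must be 1-D")
        if self.time_min.size != self.value.size:
            raise ValueError("time_min and value lengths differ")
        if self.time_min.size < 2:
            raise ValueError("a TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(self.value)) or not np.all(np.isfinite(self.time_min)):
            raise ValueError("non-finite entries in time series")
        steps = np.diff(self.time_min)
        if np.any(steps <= 0):
            bad = int(np.argmax(steps <= 0)) + 2
            raise ValueError(f"time not strictly increasing at row {bad}")
        dt = float(steps[0])  # interval set by the start of the recording
        dev = np.abs(steps - dt)
        if np.any(dev > _GRID_RTOL * dt):
            bad = int(np.argmax(dev > _GRID_RTOL * dt)) + 2
            raise ValueError(f"non-uniform sampling at row {bad}")

    @property
    def interval_min(self) -> float:
        """Sampling interval in minutes."""
        return float(np.median(np.diff(self.time_min)))

    def __len__(self) -> int:
        return int(self.time_min.size)

    def with_values(self, value: np.ndarray, label: str | None = None) -> "TimeSeries":
        """Return a copy on the same time grid with new values."""
        return TimeSeries(self.time_min.copy(), np.asarray(value, dtype=float),
                          self.label if label is None else label)


@dataclass
class MovieStack:
    """A T x H x W luminescence movie with physical calibration.

    ``frames`` holds non-negative intensities (arbitrary luminescence units);
    ``interval_min`` is the frame interval in minutes, ``pixel_um`` the pixel
    edge length in micrometres, ``t0_min`` the time of the first frame.
    Pixel coordinates are row-major ``(y, x)``, 0-based, pixel-center.
    Detrended movies oscillate about zero; they set ``signed=True``, which
    relaxes the non-negativity invariant.
    """

    frames: np.ndarray
    interval_min: float
    pixel_um: float
    t0_min: float = 0.0
    signed: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frames.shape[0] < 2:
            raise ValueError("a MovieStack needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite pixel values")
        if not self.signed and np.any(self.frames < 0):
            raise ValueError("negative pixel values")
        if self.interval_min <= 0 or self.pixel_um <= 0:
            raise ValueError("interval_min and pixel_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def time_min(self) -> np.ndarray:
        """Frame times in minutes."""
        t = self.frames.shape[0]
        return self.t0_min + self.interval_min * np.arange(t)


@dataclass
class PlateLayout:
    """Well -> compound/role mapping for a screening plate."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("well_id", "compound_name", "concentration_uM", "role")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"plate layout missing columns: {missing}")
        if self.table["well_id"].duplicated().any():
            dup = self.table.loc[self.table["well_id"].duplicated(), "well_id"].iloc[0]
            raise ValueError(f"duplicate well_id {dup!r}")
        bad_role = set(self.table["role"]) - {"control", "treated"}
        if bad_role:
            raise ValueError(f"unknown roles: {sorted(bad_role)}")

    def row(self, well_id: str) -> pd.Series:
        hit = self.table[self.table["well_id"] == well_id]
        if hit.empty:
            raise KeyError(f"well {well_id!r} not in layout")
        return hit.iloc[0]

    @property
    def control_wells(self) -> list[str]:
        return list(self.table.loc[self.table["role"] == "control", "well_id"])


def read_pmt_csv(path: str | Path) -> list[TimeSeries]:
    """Read PMT photon-count traces from CSV.

    First column is time in minutes; every remaining column is one trace,
    labelled by its header. The time grid must be uniform; a non-uniform grid
    or a non-numeric cell is a hard error (rows are never silently dropped).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column and at least one trace column")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = int(np.argmax(coerced.isna().to_numpy())) + 2  # 1-based incl. header
            raise ValueError(f"{path}: non-numeric cell in column {col!r}, file row {row}")
        if df[col].isna().any():
            row = int(np.argmax(df[col].isna().to_numpy())) + 2
            raise ValueError(f"{path}: missing cell in column {col!r}, file row {row}")
        df[col] = coerced
    time = df.iloc[:, 0].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        out.append(TimeSeries(time, df[col].to_numpy(dtype=float), label=str(col)))
    return out


def write_timeseries_csv(series: Sequence[TimeSeries], path: str | Path) -> None:
    """Write traces sharing one time grid to CSV (one column per trace)."""
    if len(series) == 0:
        raise ValueError("no series to write")
    t0 = series[0].time_min
    for s in series[1:]:
        if len(s) != len(series[0]) or not np.allclose(s.time_min, t0, atol=1e-9):
            raise ValueError(f"series {s.label!r} is not on the shared time grid")
    data = {"time_min": t0}
    for i, s in enumerate(series):
        data[s.label or f"trace_{i}"] = s.value
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def read_tiff_stack(path: str | Path, interval_min: float, pixel_um: float,
                    t0_min: float = 0.0) -> MovieStack:
    """Read a multi-frame single-channel TIFF as a MovieStack.

    Calibration (frame interval, pixel size) comes from the arguments;
    TIFF tags are ignored. Multi-channel pages are a hard error.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        raise ValueError(f"{path}: single page, need a multi-frame stack")
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected single channel, got shape {arr.shape}")
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError(f"{path}: expected single channel, got shape {arr.shape}")
    return MovieStack(arr.astype(float), interval_min=interval_min,
                      pixel_um=pixel_um, t0_min=t0_min)


def write_tiff_stack(movie: MovieStack, path: str | Path,
                     dtype: str | np.dtype | None = None) -> None:
    """Write a MovieStack as a multi-page grayscale TIFF.

    Integer ``dtype`` round-trips bit-exactly through :func:`read_tiff_stack`
    when the data are integral; default is float32.
    """
    arr = movie.frames
    if dtype is not None:
        arr = arr.astype(dtype)
    else:
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_plate_layout(path: str | Path) -> PlateLayout:
    """Read a plate-layout CSV (columns well_id, compound_name, concentration_uM, role)."""
    return PlateLayout(pd.read_csv(path))
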