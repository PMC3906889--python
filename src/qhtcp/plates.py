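"""Quantification of time-lapse plate images into per-spot density series.

A plate carries a rectangular grid of spot cultures (384 = 16 x 24 by
default).  For every frame and grid cell, the summed pixel intensity inside
a square window centred on the nominal spot position is background
corrected with the frame's inter-spot median, giving the spot's "pixel
density" — the quantity fitted by :mod:`qhtcp.growth`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import TimeSeries

#: fraction of the spot pitch used as the measurement window side
WINDOW_FRACTION = 0.9


class GridError(ValueError):
    """Raised when the spot grid does not fit inside the frames."""


@dataclass(frozen=True)
class PlateGrid:
    """Nominal spot layout: ``rows x cols`` spots, centres at
    ``origin + index * pitch`` pixels (row origin first)."""

    rows: int = 16
    cols: int = 24
    pitch: float = 20.0
    origin_row: float = 10.0
    origin_col: float = 10.0

    def center(self, row: int, col: int) -> tuple[float, float]:
        return (self.origin_row + row * self.pitch, self.origin_col + col * self.pitch)


@dataclass(frozen=True)
class PlateImageStack:
    """Ordered grayscale frames of one plate plus their acquisition times."""

    frames: np.ndarray  # (n_frames, height, width), intensity >= 0
    frame_times: np.ndarray  # hours, strictly increasing
    grid: PlateGrid

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        times = np.asarray(self.frame_times, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_times", times)
        if frames.ndim != 3:
            raise GridError("frames must be a (n_frames, height, width) array")
        if times.ndim != 1 or times.size != frames.shape[0]:
            raise GridError("frame_times must match the number of frames")
        if np.any(np.diff(times) <= 0):
            raise GridError("frame_times must strictly increase")
        h, w = frames.shape[1:]
        half = WINDOW_FRACTION * self.grid.pitch / 2.0
        g = self.grid
        rmax = g.origin_row + (g.rows - 1) * g.pitch + half
        cmax = g.origin_col + (g.cols - 1) * g.pitch + half
        if g.origin_row - half < 0 or g.origin_col - half < 0 or rmax > h or cmax > w:
            raise GridError(
                f"{g.rows}x{g.cols} grid (pitch {g.pitch}) does not fit in "
                f"{h}x{w} frames"
            )


def _window_slices(grid: PlateGrid, row: int, col: int) -> tuple[slice, slice]:
    half = WINDOW_FRACTION * grid.pitch / 2.0
    cr, cc = grid.center(row, col)
    return (
        slice(int(round(cr - half)), int(round(cr + half))),
        slice(int(round(cc - half)), int(round(cc + half))),
    )


def _background_mask(grid: PlateGrid, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of inter-spot pixels (outside every cell window)."""
    mask = np.ones(shape, dtype=bool)
    for row in range(grid.rows):
        for col in range(grid.cols):
            rs, cs = _window_slices(grid, row, col)
            mask[rs, cs] = False
    return mask


def quantify_stack(stack: PlateImageStack) -> pd.DataFrame:
    """Measure every spot in every frame.

    Returns a DataFrame with columns ``row``, ``col``, ``time_h`` and
    ``density`` where density is the window pixel sum minus the frame's
    inter-spot median background times the window area.  Densities can be
    slightly negative under noise; that is expected and left uncorrected.
    """
    grid = stack.grid
    bg_mask = _background_mask(grid, stack.frames.shape[1:])
    records: list[tuple[int, int, float, float]] = []
    for frame, time in zip(stack.frames, stack.frame_times):
        background = float(np.median(frame[bg_mask])) if bg_mask.any() else 0.0
        for row in range(grid.rows):
            for col in range(grid.cols):
                rs, cs = _window_slices(grid, row, col)
                window = frame[rs, cs]
                density = float(window.sum() - background * window.size)
                records.append((row, col, float(time), density))
    return pd.DataFrame(records, columns=["row", "col", "time_h", "density"])


def to_time_series(
    measurements: pd.DataFrame, row: int, col: int, culture_id: str | None = None
) -> TimeSeries:
    """Extract one cell's density-vs-time series, ready for fitting."""
    cell = measurements[(measurements["row"] == row) & (measurements["col"] == col)]
    if cell.empty:
        raise KeyError(f"no measurements for cell ({row}, {col})")
    n_frames = measurements["time_h"].nunique()
    if cell["time_h"].nunique() != n_frames:
        missing = sorted(set(measurements["time_h"]) - set(cell["time_h"]))
        raise ValueError(f"cell ({row}, {col}) missing frames at times {missing}")
    cell = cell.sort_values("time_h")
    return TimeSeries(
        culture_id or f"r{row:02d}c{col:02d}",
        cell["time_h"].to_numpy(),
        cell["density"].to_numpy(),
    )


def read_png_stack(
    paths: Sequence[str], frame_times: Sequence[float], grid: PlateGrid
) -> PlateImageStack:
    """Load grayscale PNG frames from disk into a stack."""
    import imageio.v3 as iio

    frames = np.stack([np.asarray(iio.imread(p), dtype=float) for p in paths])
    return PlateImageStack(frames, np.asarray(frame_times, dtype=float), grid)
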