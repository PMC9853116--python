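"""Shared in-memory containers: profile spectra and pixel-grid MSI datasets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["Spectrum", "MSIDataset"]


@dataclass
class Spectrum:
    """A profile spectrum: strictly increasing m/z axis and intensities >= 0."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size < 2 or np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def slice_indices(self, lo: float, hi: float) -> tuple[int, int]:
        """Index range [i, j) of axis values in the half-open window [lo, hi)."""
        i = int(np.searchsorted(self.mz, lo, side="left"))
        j = int(np.searchsorted(self.mz, hi, side="left"))
        return i, j


@dataclass
class MSIDataset:
    """Continuous-mode MSI dataset: one shared axis, one spectrum per pixel.

    ``coords`` are 0-based (x right, y down) pixel coordinates, unique per
    row of ``intensities``.  Intensities are stored float32 as written to
    imzML; arithmetic downstream promotes to float64.
    """

    mz_axis: np.ndarray
    coords: np.ndarray
    intensities: np.ndarray
    pixel_pitch_um: float = 60.0
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (N, 2) array")
        n = self.coords.shape[0]
        if self.intensities.shape != (n, self.mz_axis.size):
            raise ValueError("intensities must be (n_pixels, n_axis_points)")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("shared m/z axis must be strictly increasing")
        seen = {tuple(c) for c in self.coords}
        if len(seen) != n:
            raise ValueError("duplicate pixel coordinates")
        self._index = {tuple(c): i for i, c in enumerate(map(tuple, self.coords))}

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(height, width) of the pixel grid.

        Uses the acquisition grid recorded in metadata ("grid_height",
        "grid_width") when present, else the minimal enclosing grid.
        """
        meta = self.metadata
        if "grid_height" in meta and "grid_width" in meta:
            return (int(meta["grid_height"]), int(meta["grid_width"]))
        return (int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1)

    def pixel_index(self, x: int, y: int) -> int:
        return self._index[(x, y)]

    def spectrum(self, i: int) -> Spectrum:
        x, y = self.coords[i]
        return Spectrum(
            self.mz_axis,
            self.intensities[i].astype(np.float64),
            label=f"pixel({x},{y})",
        )

    def has_pixel(self, x: int, y: int) -> bool:
        return (x, y) in self._index

    def to_grid(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter one value per pixel onto the (height, width) grid."""
        h, w = self.grid_shape
        grid = np.full((h, w), fill, dtype=np.float64)
        grid[self.coords[:, 1], self.coords[:, 0]] = values
        return grid
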