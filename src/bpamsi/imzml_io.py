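"""imzML 1.1 round-trip for continuous-mode profile datasets (via pyimzml)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

from .dataset import MSIDataset

__all__ = ["write_imzml", "read_imzml"]


def write_imzml(dataset: MSIDataset, path: str | Path) -> Path:
    """Write a dataset as continuous-mode imzML (float64 m/z, float32 I).

    Internal 0-based pixel coordinates are converted to imzML's 1-based
    convention.  Returns the path of the .imzML XML file (the .ibd binary
    sits next to it).
    """
    path = Path(path)
    with ImzMLWriter(
        str(path),
        mode="continuous",
        spec_type="profile",
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
        polarity="positive",
    ) as writer:
        for i in range(dataset.n_pixels):
            x, y = dataset.coords[i]
            writer.addSpectrum(
                dataset.mz_axis, dataset.intensities[i], (int(x) + 1, int(y) + 1, 1)
            )
    return path if path.suffix == ".imzML" else path.with_suffix(".imzML")


def read_imzml(path: str | Path, pixel_pitch_um: float = 60.0) -> MSIDataset:
    """Read a continuous-mode imzML file back into an :class:`MSIDataset`.

    Processed-mode files (per-pixel axes) are rejected; duplicate pixel
    coordinates raise through the dataset invariant.
    """
    parser = ImzMLParser(str(path))
    params = parser.metadata.file_description.param_by_name
    if "continuous" not in params:
        raise ValueError(
            "only continuous-mode imzML is supported (this file is processed-mode "
            "or lacks a binary-data mode declaration)"
        )
    if not parser.coordinates:
        raise ValueError("imzML file contains no spectra")
    mz0, _ = parser.getspectrum(0)
    axis = np.asarray(mz0, dtype=np.float64)
    n = len(parser.coordinates)
    intensities = np.empty((n, axis.size), dtype=np.float32)
    coords = np.empty((n, 2), dtype=np.int64)
    for i, (x, y, _z) in enumerate(parser.coordinates):
        _, inten = parser.getspectrum(i)
        intensities[i] = inten
        coords[i] = (x - 1, y - 1)
    return MSIDataset(
        mz_axis=axis,
        coords=coords,
        intensities=intensities,
        pixel_pitch_um=pixel_pitch_um,
        metadata={"source": str(path)},
    )
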