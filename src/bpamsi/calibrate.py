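"""Internal (lock-mass) recalibration of MSI spectra.

A matrix-derived ion of precisely known m/z — [DHB-H+2K]+ at 230.946 for the
main acquisition range, [DHB+K]+ at 192.990 for the low-mass range — is
located in each spectrum and the mass axis is corrected by the single-point
multiplicative factor theoretical/observed.  One lock per spectrum admits no
richer model; a multiplicative factor is the minimal correction closed under
composition, and with uniform per-pixel drift it commutes with ROI averaging.
Spectra in which the lock cannot be found are left unchanged and flagged,
never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import MSIDataset, Spectrum
from .imaging import ROI, parabolic_centroid, roi_mean_spectrum

__all__ = [
    "LockMass",
    "CalibrationFit",
    "catalog_lock",
    "locate_lock_peak",
    "fit_single_point",
    "recalibrate_dataset",
    "MAX_PLAUSIBLE_PPM",
]

#: Corrections beyond this are treated as a mis-located lock, not a real drift.
MAX_PLAUSIBLE_PPM = 500.0


@dataclass(frozen=True)
class LockMass:
    """A lock-mass ion: name, theoretical m/z and search half-window (Da)."""

    name: str
    mz: float
    half_window: float = 0.2

    def __post_init__(self):
        if not (0.0 < self.half_window < 0.5):
            raise ValueError("half-window must be in (0, 0.5) Da")
        if self.mz <= 0:
            raise ValueError("lock m/z must be positive")


@dataclass(frozen=True)
class CalibrationFit:
    """Single-point fit: multiplicative factor on m/z, residual, found flag."""

    factor: float
    residual_ppm: float | None
    found: bool

    @classmethod
    def not_found(cls) -> "CalibrationFit":
        return cls(factor=1.0, residual_ppm=None, found=False)


def catalog_lock(name: str, half_window: float = 0.2) -> LockMass:
    """Lock mass for a catalog species at its exact theoretical m/z.

    The printed three-decimal value (e.g. 230.946 for [DHB-H+2K]+) would bias
    every correction by its own rounding error (~1.6 ppm there); the exact
    monoisotopic mass avoids that.
    """
    from .chem import default_catalog

    for s in default_catalog():
        if s.name == name:
            return LockMass(name, s.mz, half_window)
    raise KeyError(f"species {name!r} not in catalog")


def locate_lock_peak(spectrum: Spectrum, lock: LockMass) -> float | None:
    """Centroid of the lock peak, or None when no credible maximum exists.

    Searches ± half_window around the theoretical m/z for local maxima above
    the window's noise floor (3 x median |I|); the tallest wins, ties go to
    the candidate nearest the theoretical position.  The returned centroid is
    the three-point log-parabola through the apex.
    """
    lo, hi = lock.mz - lock.half_window, lock.mz + lock.half_window
    if lo < spectrum.mz[0] or hi > spectrum.mz[-1]:
        raise ValueError(
            f"axis does not cover lock window [{lo:.3f}, {hi:.3f}]"
        )
    i, j = spectrum.slice_indices(lo, hi)
    y = spectrum.intensity
    floor = 3.0 * float(np.median(np.abs(y[i:j])))
    k = np.arange(max(i, 1), min(j, y.size - 1))
    cand = k[(y[k] > y[k - 1]) & (y[k] >= y[k + 1]) & (y[k] > floor) & (y[k] > 0)]
    if cand.size == 0:
        return None
    best = np.max(y[cand])
    ties = cand[y[cand] == best]
    apex = int(ties[np.argmin(np.abs(spectrum.mz[ties] - lock.mz))])
    return parabolic_centroid(spectrum.mz, y, apex)


def fit_single_point(observed: float, theoretical: float) -> CalibrationFit:
    """factor = theoretical / observed; residual at the lock is 0 afterwards.

    Raises ``ValueError`` when the implied correction exceeds
    ``MAX_PLAUSIBLE_PPM`` (an implausible fit: the located peak is not the
    lock ion).
    """
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    factor = theoretical / observed
    if abs(1.0 - factor) * 1e6 > MAX_PLAUSIBLE_PPM:
        raise ValueError(
            f"implausible calibration factor {factor:.6f} "
            f"({(factor - 1) * 1e6:+.0f} ppm) for lock at {theoretical}"
        )
    return CalibrationFit(factor=factor, residual_ppm=0.0, found=True)


def _apply_factor(
    axis: np.ndarray, intensity: np.ndarray, factor: float
) -> np.ndarray:
    """Resample intensities from the corrected axis back onto the shared axis.

    Multiplying the axis by ``factor`` and immediately resampling by linear
    interpolation keeps every spectrum on the shared (continuous-mode) axis.
    """
    if factor == 1.0:
        return intensity
    return np.interp(axis, axis * factor, intensity)


def recalibrate_dataset(
    dataset: MSIDataset,
    lock: LockMass,
    scope: str = "pixel",
    rois: Sequence[ROI] | None = None,
) -> tuple[MSIDataset, pd.DataFrame]:
    """Lock-mass correct a dataset per pixel or per ROI.

    Returns the corrected dataset (same shared axis; intensities resampled
    from each unit's corrected axis) and a report table with one row per unit:
    unit id, factor, applied shift in ppm, found flag.  Units whose lock peak
    is not found, or whose fit is implausible, are left unchanged and flagged.
    """
    if scope not in ("pixel", "roi"):
        raise ValueError("scope must be 'pixel' or 'roi'")
    new_intens = dataset.intensities.copy()
    rows = []

    def fit_for(spectrum: Spectrum) -> CalibrationFit:
        observed = locate_lock_peak(spectrum, lock)
        if observed is None:
            return CalibrationFit.not_found()
        try:
            return fit_single_point(observed, lock.mz)
        except ValueError:
            return CalibrationFit.not_found()

    if scope == "pixel":
        for i in range(dataset.n_pixels):
            fit = fit_for(dataset.spectrum(i))
            if fit.found:
                new_intens[i] = _apply_factor(
                    dataset.mz_axis,
                    dataset.intensities[i].astype(np.float64),
                    fit.factor,
                ).astype(np.float32)
            x, y = dataset.coords[i]
            rows.append(
                {
                    "unit": f"pixel({x},{y})",
                    "factor": fit.factor,
                    "ppm_shift": (fit.factor - 1.0) * 1e6,
                    "found": fit.found,
                }
            )
    else:
        if not rois:
            raise ValueError("scope='roi' requires at least one ROI")
        for roi in rois:
            fit = fit_for(roi_mean_spectrum(dataset, roi))
            for x, y in roi.pixels:
                i = dataset.pixel_index(x, y)
                if fit.found:
                    new_intens[i] = _apply_factor(
                        dataset.mz_axis,
                        dataset.intensities[i].astype(np.float64),
                        fit.factor,
                    ).astype(np.float32)
            rows.append(
                {
                    "unit": roi.label,
                    "factor": fit.factor,
                    "ppm_shift": (fit.factor - 1.0) * 1e6,
                    "found": fit.found,
                }
            )

    corrected = MSIDataset(
        mz_axis=dataset.mz_axis,
        coords=dataset.coords,
        intensities=new_intens,
        pixel_pitch_um=dataset.pixel_pitch_um,
        metadata={**dataset.metadata, "recalibrated": lock.name},
    )
    return corrected, pd.DataFrame(rows)
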