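"""Lock-mass location, single-point fitting and dataset recalibration."""

from dataclasses import replace

import numpy as np
import pytest

from bpamsi.calibrate import (
    CalibrationFit,
    LockMass,
    catalog_lock,
    fit_single_point,
    locate_lock_peak,
    recalibrate_dataset,
)
from bpamsi.dataset import Spectrum
from bpamsi.imaging import nearest_peak_centroid, roi_mean_spectrum, ROI
from bpamsi.phantom import (
    ResolutionModel,
    low_mass_config,
    make_axis,
    simulate_dataset,
    synthesize_spectrum,
)

RES = ResolutionModel(20_000.0)
LOCK = LockMass("[DHB-H+2K]+", 230.946)


def render_lock(drift_ppm=0.0, amount=200.0, extra=None):
    axis = make_axis((230.4, 231.5), RES)
    lines = {"lock": ((230.946, 100.0),)}
    amounts = {"lock": amount}
    if extra:
        lines.update(extra[0])
        amounts.update(extra[1])
    return synthesize_spectrum(amounts, lines, RES, axis, drift_ppm=drift_ppm)


def test_locate_lock_recovers_injected_drift():
    for drift in (-25.0, 0.0, 20.0):
        spec = render_lock(drift_ppm=drift)
        c = locate_lock_peak(spec, LOCK)
        assert c == pytest.approx(230.946 * (1 + drift * 1e-6), abs=2e-5)


def test_locate_lock_absent_species_not_found():
    spec = render_lock(amount=0.0)
    # flat (all-zero) spectrum: nothing above the noise floor
    assert locate_lock_peak(spec, LOCK) is None


def test_locate_lock_taller_candidate_wins():
    spec = render_lock(
        extra=({"decoy": ((231.05, 100.0),)}, {"decoy": 500.0})
    )
    c = locate_lock_peak(spec, LOCK)
    assert c == pytest.approx(231.05, abs=1e-4)  # taller wins inside window


def test_locate_lock_axis_must_cover_window():
    spec = render_lock()
    with pytest.raises(ValueError, match="cover"):
        locate_lock_peak(spec, LockMass("x", 231.4, half_window=0.2))


def test_fit_single_point_identity_and_algebra():
    assert fit_single_point(230.946, 230.946).factor == 1.0
    fit = fit_single_point(230.946 * (1 + 30e-6), 230.946)
    assert fit.factor == pytest.approx(1.0 / (1 + 30e-6), rel=1e-12)
    assert fit.residual_ppm == 0.0


def test_fit_single_point_implausible_offset_rejected():
    with pytest.raises(ValueError, match="implausible"):
        fit_single_point(230.946 + 0.5, 230.946)
    assert CalibrationFit.not_found().found is False


def test_recovery_within_half_ppm_noise_off():
    """Fitted factor equals 1/(1+d ppm) within 0.5 ppm for injected drift."""
    for drift in (-30.0, -7.5, 12.0, 30.0):
        spec = render_lock(drift_ppm=drift)
        fit = fit_single_point(locate_lock_peak(spec, LOCK), LOCK.mz)
        expected = 1.0 / (1 + drift * 1e-6)
        assert abs(fit.factor - expected) * 1e6 < 0.5


def test_recalibration_reduces_bpa_error_per_pixel(sim, recal):
    """Parameter recovery: corrected pixels locate the drug peak better."""
    corrected, report = recal
    assert report["found"].all()
    target = sim.truth_position("[BPA+H]+")
    tumor = sim.masks["tumor"]
    better = total = 0
    for i, (x, y) in enumerate(sim.dataset.coords):
        if not tumor[y, x]:
            continue
        pre = nearest_peak_centroid(sim.dataset.spectrum(i), target, 0.012)
        post = nearest_peak_centroid(corrected.spectrum(i), target, 0.012)
        if pre is None or post is None:
            continue
        total += 1
        if abs(post - target) < abs(pre - target):
            better += 1
    assert total > 50
    assert better / total > 0.85  # drift dominates the pre-correction error


def test_zero_drift_dataset_factors_near_one(phantom_cfg, lock):
    cfg = replace(phantom_cfg, drift_ppm_range=(0.0, 0.0), noise_scale=None)
    sim0 = simulate_dataset(cfg)
    _, report = recalibrate_dataset(sim0.dataset, lock)
    assert np.all(np.abs(report["ppm_shift"]) < 1.0)


def test_recalibration_is_idempotent(phantom_cfg, lock):
    """A second pass moves every (noise-free) axis by < 0.5 ppm."""
    cfg = replace(phantom_cfg, noise_scale=None)
    s = simulate_dataset(cfg)
    once, _ = recalibrate_dataset(s.dataset, lock)
    _, report2 = recalibrate_dataset(once, lock)
    found = report2[report2["found"]]
    assert found["found"].all()
    assert np.all(np.abs(found["ppm_shift"]) < 0.5)


def test_roi_scope_matches_pixel_scope_for_uniform_drift(phantom_cfg, lock):
    """Uniform drift: per-ROI and per-pixel corrections agree closely."""
    cfg = replace(phantom_cfg, drift_ppm_range=(18.0, 18.0), noise_scale=None)
    s = simulate_dataset(cfg)
    roi = ROI.from_mask(s.masks["tumor"], "tumor")
    per_pixel, _ = recalibrate_dataset(s.dataset, lock, scope="pixel")
    per_roi, rep = recalibrate_dataset(s.dataset, lock, scope="roi", rois=[roi])
    assert rep.iloc[0]["ppm_shift"] == pytest.approx(-18.0, abs=0.5)
    a = roi_mean_spectrum(per_pixel, roi).intensity
    b = roi_mean_spectrum(per_roi, roi).intensity
    assert np.max(np.abs(a - b)) < 0.01 * a.max()


def test_unfound_units_left_unchanged_and_flagged(lock):
    axis = make_axis((230.4, 231.5), RES)
    flat = np.zeros((1, axis.size), np.float32)
    from bpamsi.dataset import MSIDataset

    ds = MSIDataset(axis, np.array([[0, 0]]), flat)
    corrected, report = recalibrate_dataset(ds, lock)
    assert not report.iloc[0]["found"]
    assert np.array_equal(corrected.intensities, ds.intensities)


def test_low_mass_preset_lock_recovery():
    """[DHB+K]+ at 192.990 supports the same recovery on the low-mass scene."""
    cfg = replace(
        low_mass_config(seed=3),
        mz_range=(150.0, 215.0),
        drift_ppm_range=(22.0, 22.0),
        noise_scale=None,
    )
    s = simulate_dataset(cfg)
    lock = catalog_lock("[DHB+K]+")
    assert lock.mz == pytest.approx(192.990, abs=1e-3)  # printed value, 3 dp
    _, report = recalibrate_dataset(s.dataset, lock)
    assert report["found"].all()
    assert np.allclose(report["ppm_shift"], -22.0, atol=0.5)
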