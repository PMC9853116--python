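"""Phantom geometry, ground-truth maps, forward model and determinism."""

from dataclasses import replace

import numpy as np
import pytest

from bpamsi.phantom import (
    Ellipse,
    ResolutionModel,
    build_phantom,
    default_phantom_config,
    line_sources,
    low_mass_config,
    make_axis,
    region_masks,
    simulate_dataset,
    synthesize_spectrum,
    with_spot,
)


def test_region_masks_are_nested():
    masks = region_masks(default_phantom_config())
    assert np.all(~masks["hotspot"] | masks["tumor"])
    assert np.all(~masks["tumor"] | masks["brain"])
    assert np.all(~masks["cortex"] | masks["brain"])
    assert not np.any(masks["cortex"] & masks["tumor"])


def test_hotspot_outside_tumor_rejected():
    cfg = replace(default_phantom_config(), hotspot=Ellipse(5.0, 5.0, 2.0, 2.0))
    with pytest.raises(ValueError, match="hotspot"):
        region_masks(cfg)


def test_bpa_maps_zero_outside_tumor():
    maps, masks = build_phantom(default_phantom_config())
    for name, m in maps.items():
        if name.startswith("[BPA"):
            assert np.all(m[~masks["tumor"]] == 0)
            assert np.all(m[masks["hotspot"]] > m[masks["tumor"] & ~masks["hotspot"]].max() - 1e-12)


def test_potassium_rich_sources_elevated_in_tumor():
    maps, masks = build_phantom(low_mass_config())
    k = maps["[K]+"]
    assert k[masks["tumor"]].mean() > k[masks["cortex"]].mean()


def test_empty_tumor_gives_zero_bpa_maps():
    cfg = replace(
        default_phantom_config(),
        tumor=Ellipse(27.0, 18.0, 0.0, 0.0),
        hotspot=Ellipse(27.0, 18.0, 0.0, 0.0),
    )
    maps, _ = build_phantom(cfg)
    assert np.all(maps["[BPA+H]+"] == 0)


def test_axis_spacing_keeps_ten_points_per_fwhm():
    for res in (ResolutionModel(20_000.0), ResolutionModel(20_000.0, exponent=1.0)):
        axis = make_axis((205.0, 235.0), res)
        step = axis[1] - axis[0]
        fwhm_min = float(res.fwhm(axis[0]))
        assert fwhm_min / step == pytest.approx(10.0, rel=1e-6)


def test_single_line_apex_at_theoretical_position():
    res = ResolutionModel(20_000.0)
    axis = make_axis((209.5, 210.7), res)
    spec = synthesize_spectrum(
        {"x": 50.0}, {"x": ((210.0932, 100.0),)}, res, axis
    )
    apex = axis[np.argmax(spec.intensity)]
    assert abs(apex - 210.0932) <= (axis[1] - axis[0])


def test_rendered_fwhm_matches_resolving_power():
    from bpamsi.imaging import fwhm_resolving_power, peak_pick

    res = ResolutionModel(20_000.0)
    axis = make_axis((209.5, 210.7), res)
    spec = synthesize_spectrum({"x": 50.0}, {"x": ((210.0932, 100.0),)}, res, axis)
    (peak,) = peak_pick(spec, min_snr=1.0)
    assert peak.fwhm == pytest.approx(210.0932 / 20_000.0, rel=0.05)
    assert fwhm_resolving_power(peak) == pytest.approx(20_000.0, rel=0.05)


def test_two_lines_resolved_at_high_but_not_low_r():
    pair = {"a": ((210.084, 100.0),), "b": ((210.104, 100.0),)}
    amounts = {"a": 100.0, "b": 100.0}
    hi = ResolutionModel(20_000.0)
    axis = make_axis((209.0, 211.2), hi)
    spec = synthesize_spectrum(amounts, pair, hi, axis)
    y = spec.intensity
    n_max = np.sum((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] > 1.0))
    assert n_max == 2
    lo = ResolutionModel(2_000.0)
    axis2 = make_axis((209.0, 211.2), lo)
    spec2 = synthesize_spectrum(amounts, pair, lo, axis2)
    y2 = spec2.intensity
    n_max2 = np.sum((y2[1:-1] > y2[:-2]) & (y2[1:-1] >= y2[2:]) & (y2[1:-1] > 1.0))
    assert n_max2 == 1


def test_unresolved_pair_apex_between_line_positions():
    """At R=2,000 the 210.084/210.098 pair merges; its apex lies between."""
    lo = ResolutionModel(2_000.0)
    axis = make_axis((209.0, 211.2), lo)
    spec = synthesize_spectrum(
        {"bpa": 100.0, "isobar": 300.0},
        {"bpa": ((210.084, 100.0),), "isobar": ((210.098, 100.0),)},
        lo,
        axis,
    )
    apex = axis[np.argmax(spec.intensity)]
    assert 210.084 < apex < 210.098


def test_axis_too_coarse_is_an_error():
    res = ResolutionModel(20_000.0)
    axis = np.arange(209.0, 211.0, 0.005)  # ~2 points per FWHM
    with pytest.raises(ValueError, match="coarse"):
        synthesize_spectrum({"x": 1.0}, {"x": ((210.0, 100.0),)}, res, axis)


def test_line_outside_axis_is_an_error():
    res = ResolutionModel(20_000.0)
    axis = make_axis((209.5, 210.5), res)
    with pytest.raises(ValueError, match="cover"):
        synthesize_spectrum({"x": 1.0}, {"x": ((210.499, 100.0),)}, res, axis)


def test_profile_integral_proportional_to_abundance():
    """Noise-off rendered area tracks the configured abundance within 1%."""
    res = ResolutionModel(20_000.0)
    axis = make_axis((209.5, 210.7), res)
    lines = {"x": ((210.0932, 100.0), (210.1002, 24.0))}
    areas = []
    for amount in (50.0, 175.0):
        spec = synthesize_spectrum({"x": amount}, lines, res, axis)
        areas.append(spec.intensity.sum())
    assert areas[1] / areas[0] == pytest.approx(175.0 / 50.0, rel=0.01)


def test_simulation_is_deterministic_and_in_brain_only(phantom_cfg, sim):
    sim2 = simulate_dataset(phantom_cfg)
    assert np.array_equal(sim.dataset.intensities, sim2.dataset.intensities)
    assert np.array_equal(sim.dataset.coords, sim2.dataset.coords)
    assert sim.dataset.n_pixels <= phantom_cfg.width * phantom_cfg.height
    brain = sim.masks["brain"]
    for x, y in sim.dataset.coords:
        assert brain[y, x]


def test_per_pixel_drift_within_configured_range(phantom_cfg, sim):
    lo, hi = phantom_cfg.drift_ppm_range
    d = sim.drift_ppm[~np.isnan(sim.drift_ppm)]
    assert d.min() >= lo and d.max() <= hi
    assert d.std() > 5.0  # genuinely spread, not constant


def test_bpa_apex_one_third_of_tallest_interference(phantom_cfg):
    levels = phantom_cfg.species_levels["[BPA+H]+"]
    tallest = max(
        lv for _, regions in phantom_cfg.interferences for lv in regions.values()
    )
    assert levels["tumor"] == pytest.approx(tallest / 3.0)


def test_with_spot_raises_only_that_species(phantom_cfg):
    spotted = with_spot(phantom_cfg, "cortex", "[BPA+H]+", 150.0)
    maps0, masks = build_phantom(phantom_cfg)
    maps1, _ = build_phantom(spotted)
    assert np.all(
        maps1["[BPA+H]+"][masks["cortex"]]
        == maps0["[BPA+H]+"][masks["cortex"]] + 150.0
    )
    assert np.array_equal(maps1["bio@209.914"], maps0["bio@209.914"])


def test_line_sources_shift_bpa_to_observed_position(phantom_cfg):
    src = line_sources(phantom_cfg)
    base = max(src["[BPA+H]+"], key=lambda t: t[1])[0]
    # pooled base-cluster centroid (10B+13C merged in) minus the -9.2 mDa
    # observed tissue displacement
    assert base == pytest.approx(210.0932 - 0.0092, abs=3e-4)
    # interference lines are single and unshifted
    assert src["bio@209.914"] == ((209.914, 100.0),)
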