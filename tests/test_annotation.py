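"""Catalog assignment, isotope-ratio verification and MS/MS annotation."""

import numpy as np
import pytest

from bpamsi.annotate import (
    NAMED_FRAGMENTS,
    NEUTRAL_LOSSES,
    assign_peaks,
    isotope_ratio_check,
    neutral_loss_annotate,
)
from bpamsi.phantom import ResolutionModel, make_axis, synthesize_spectrum

RES = ResolutionModel(20_000.0)


def render_species(species, amount=100.0, lo=None, hi=None, shift=0.0):
    pat = species.pattern()
    lines = tuple((m + shift, r) for m, r in pat.lines)
    lo = lo if lo is not None else lines[0][0] - 0.5
    hi = hi if hi is not None else lines[-1][0] + 0.5
    lines = tuple((m, r) for m, r in lines if lo + 0.1 < m < hi - 0.1)
    axis = make_axis((lo, hi), RES)
    return synthesize_spectrum({species.name: amount}, {species.name: lines}, RES, axis)


# Observed tissue centroids and their published assignments (Δm in mDa).
TISSUE_ASSIGNMENTS = [
    (210.084, "[BPA+H]+", -9),
    (214.058, "[BPA-H2O+Na]+", -7),
    (350.087, "[BPA+DHB-2H2O+Na]+", 6),
    (366.059, "[BPA+DHB-2H2O+K]+", 4),
]


@pytest.mark.parametrize("observed, species, delta", TISSUE_ASSIGNMENTS)
def test_tissue_centroids_assigned_with_published_delta(
    catalog, observed, species, delta
):
    (a,) = assign_peaks([observed], catalog, tol_mda=10.0)
    assert a.status == "assigned"
    assert a.species == species
    assert round(a.delta_mda) == delta


def test_far_centroid_unassigned(catalog):
    (a,) = assign_peaks([500.0], catalog, tol_mda=10.0)
    assert a.status == "unassigned" and a.species is None


def test_tolerance_monotonicity(catalog):
    """Raising tol never changes a match, only upgrades unassigned."""
    centroids = [210.084, 214.058, 366.059, 210.12, 500.0]
    for tight, loose in [(5.0, 10.0), (10.0, 30.0)]:
        a_tight = assign_peaks(centroids, catalog, tol_mda=tight)
        a_loose = assign_peaks(centroids, catalog, tol_mda=loose)
        for t, l in zip(a_tight, a_loose):
            if t.status == "assigned":
                assert l.species == t.species


def test_single_species_self_consistency(catalog):
    """Noiseless single-species spectra assign back with |Δm| < 1 mDa."""
    for species in catalog:
        if species.flag != "ok" or species.formula.n_atoms < 3:
            continue
        spec = render_species(species)
        apex = int(np.argmax(spec.intensity))
        from bpamsi.imaging import parabolic_centroid

        centroid = parabolic_centroid(spec.mz, spec.intensity, apex)
        (a,) = assign_peaks([centroid], [species], tol_mda=10.0, spectrum=spec)
        assert a.status == "assigned"
        assert abs(a.delta_mda) < 1.0


def test_isotope_check_noiseless_deviation_below_one_point(by_name):
    for name in ("[BPA+H]+", "[BPA+DHB-2H2O+K]+"):
        species = by_name[name]
        spec = render_species(species)
        res = isotope_ratio_check(spec, species)
        assert res.max_deviation < 1.0


def test_isotope_check_requires_full_pattern_coverage(by_name):
    species = by_name["[BPA+H]+"]
    # spectrum missing the M-1 (boron-isotope) region
    spec = render_species(species, lo=209.9, hi=212.2)
    with pytest.raises(ValueError, match="cover"):
        isotope_ratio_check(spec, species)


def test_isotope_check_empty_base_window_errors(by_name):
    species = by_name["[BPA+H]+"]
    axis = make_axis((208.9, 215.5), RES)
    flat = synthesize_spectrum({}, {}, RES, axis)
    with pytest.raises(ValueError, match="empty"):
        isotope_ratio_check(flat, species)


def test_isotope_check_tracks_displaced_species(by_name):
    """A -9 mDa displaced pattern still verifies via the mz_shift argument."""
    species = by_name["[BPA+H]+"]
    spec = render_species(species, shift=-0.0092)
    res = isotope_ratio_check(spec, species, mz_shift=-0.0092)
    assert res.max_deviation < 1.0


def test_msms_sodiated_complex_products(by_name):
    """Products 23/136/214 of the sodiated complex -> Na+, matrix and drug."""
    ann = neutral_loss_annotate(350.081, [23.0, 136.0, 214.0])
    assert ann.matched_names() == ("Na+", "[DHB-H2O]+", "[BPA-H2O+Na]+")


def test_msms_potassiated_complex_products():
    ann = neutral_loss_annotate(366.055, [39.0, 136.0, 175.0, 230.0])
    assert ann.matched_names() == (
        "K+",
        "[DHB-H2O]+",
        "[DHB-H2O+K]+",
        "[BPA-H2O+K]+",
    )


def test_msms_neutral_loss_of_dehydrated_matrix_from_dimer():
    """Matrix-dimer precursor loses DHB-H2O (nominal 136)."""
    precursor = 273.039
    product = precursor - NEUTRAL_LOSSES["DHB-H2O"]
    ann = neutral_loss_annotate(precursor, [product])
    assert ann.matched_names() == ("loss:DHB-H2O",)


def test_msms_neutral_loss_of_dehydrated_drug():
    """Loss 191 (dehydrated BPA) from the protonated complex precursor."""
    precursor = 328.099
    product = precursor - NEUTRAL_LOSSES["BPA-H2O"]
    ann = neutral_loss_annotate(precursor, [product])
    assert ann.matched_names() == ("loss:BPA-H2O",)
    assert NEUTRAL_LOSSES["BPA-H2O"] == pytest.approx(191.075, abs=1e-3)
    assert NEUTRAL_LOSSES["DHB-H2O"] == pytest.approx(136.016, abs=1e-3)


def test_msms_product_above_precursor_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        neutral_loss_annotate(350.081, [360.0])


def test_msms_fragment_masses():
    assert NAMED_FRAGMENTS["[DHB-H2O]+"] == pytest.approx(136.0155, abs=1e-3)
    assert NAMED_FRAGMENTS["[BPA-H2O+K]+"] == pytest.approx(230.038, abs=1e-3)
    assert NAMED_FRAGMENTS["Na+"] == pytest.approx(22.990, abs=1e-3)


def test_ambiguous_when_two_species_within_tolerance(by_name):
    """Two catalog entries inside tol with near-equal evidence -> ambiguous."""
    a_species = by_name["[BPA+H]+"]
    # a decoy 4 mDa above the drug ion
    from dataclasses import replace

    decoy = replace(a_species, recipe=replace(a_species.recipe, name="decoy"),
                    mz=a_species.mz + 0.004)
    # an exact |Δm| tie with no spectrum to arbitrate is ambiguous
    (a,) = assign_peaks([a_species.mz + 0.002], [a_species, decoy], tol_mda=10.0)
    assert a.status == "ambiguous"
    # off-tie centroid with only the true species in tolerance
    (b,) = assign_peaks([a_species.mz + 0.001], [a_species, decoy], tol_mda=1.9)
    assert b.status == "assigned" and b.species == a_species.name
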