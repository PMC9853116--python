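"""Peak assignment, isotope-ratio verification and MS/MS neutral-loss logic.

Picked centroids are matched to the ion-species catalog by absolute mass
error (default tolerance 10 mDa, covering the 9 mDa worst case observed on
tissue), optionally verified by comparing measured isotope-cluster abundance
ratios with the calculated pattern (< 3 percentage points is the plausibility
envelope for a correct assignment), and MS/MS product-ion lists are annotated
against named fragments and the two characteristic neutral losses of the
BPA-DHB chemistry: dehydrated matrix (DHB - H2O, nominal 136) and dehydrated
drug (BPA - H2O, nominal 191).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import (
    DEFAULT_MOLECULES,
    ELECTRON_MASS,
    IonSpecies,
    monoisotopic_mz,
    parse_formula,
)
from .dataset import Spectrum
from .imaging import PeakCentroid

__all__ = [
    "PeakAssignment",
    "IsotopeRatioResult",
    "MsMsAnnotation",
    "assign_peaks",
    "isotope_ratio_check",
    "neutral_loss_annotate",
    "NAMED_FRAGMENTS",
    "NEUTRAL_LOSSES",
]


@dataclass(frozen=True)
class PeakAssignment:
    """One observed centroid matched (or not) against the species catalog."""

    observed_mz: float
    species: str | None
    delta_mda: float | None
    ppm: float | None
    isotope_deviation: float | None
    status: str  # assigned | ambiguous | unassigned


@dataclass(frozen=True)
class IsotopeRatioResult:
    """Measured isotope-cluster ratios vs the calculated pattern."""

    species: str
    measured: tuple[tuple[float, float], ...]  # (line m/z, measured % of base)
    calculated: tuple[tuple[float, float], ...]
    max_deviation: float  # percentage points, over non-base lines


@dataclass(frozen=True)
class MsMsAnnotation:
    """Product-ion list of one precursor with fragment/neutral-loss matches."""

    precursor_mz: float
    entries: tuple[tuple[float, str | None, float | None], ...]
    # (product m/z, matched name or None, delta in mDa)

    def matched_names(self) -> tuple[str, ...]:
        return tuple(name for _, name, _ in self.entries if name is not None)


def _mz(centroid: PeakCentroid | float) -> float:
    return centroid.mz if isinstance(centroid, PeakCentroid) else float(centroid)


def isotope_ratio_check(
    spectrum: Spectrum,
    species: IonSpecies,
    window: float = 0.02,
    merge_window: float = 0.02,
    mz_shift: float = 0.0,
    min_rel: float = 1.0,
) -> IsotopeRatioResult:
    """Measure isotope-cluster abundance ratios for one species in a spectrum.

    Each calculated pattern line with relative abundance >= ``min_rel`` %
    (the printed-table scale) contributes the intensity sum over the
    half-open window centred on it (optionally displaced by ``mz_shift``, for
    species observed off their calculated position); ratios are per cent of
    the base line's sum.  Raises when the spectrum does not cover a line's
    window or when the base window holds no intensity.
    """
    full = species.pattern(merge_window=merge_window)
    pattern_lines = tuple((m, r) for m, r in full.lines if r >= min_rel)
    sums = []
    for mz, _rel in pattern_lines:
        lo = mz + mz_shift - window / 2.0
        hi = mz + mz_shift + window / 2.0
        if lo < spectrum.mz[0] or hi > spectrum.mz[-1]:
            raise ValueError(
                f"spectrum does not cover the {species.name} line at {mz:.3f}"
            )
        i, j = spectrum.slice_indices(lo, hi)
        sums.append(float(np.sum(spectrum.intensity[i:j])))
    base_idx = int(np.argmax([rel for _, rel in pattern_lines]))
    base_sum = sums[base_idx]
    if base_sum <= 0:
        raise ValueError(f"base-line window for {species.name} is empty")
    measured = tuple(
        (mz, 100.0 * s / base_sum) for (mz, _), s in zip(pattern_lines, sums)
    )
    deviations = [
        abs(m_pct - c_pct)
        for k, ((_, m_pct), (_, c_pct)) in enumerate(zip(measured, pattern_lines))
        if k != base_idx
    ]
    return IsotopeRatioResult(
        species=species.name,
        measured=measured,
        calculated=pattern_lines,
        max_deviation=max(deviations) if deviations else 0.0,
    )


def assign_peaks(
    centroids: Sequence[PeakCentroid | float],
    catalog: Sequence[IonSpecies],
    tol_mda: float = 10.0,
    spectrum: Spectrum | None = None,
    ambiguity_points: float = 1.0,
) -> list[PeakAssignment]:
    """Match each centroid to the nearest catalog species within tolerance.

    Nearest |Δm| wins.  When several species fall inside the tolerance and a
    spectrum is supplied, isotope-ratio agreement breaks the tie; if the two
    best isotope scores differ by less than ``ambiguity_points`` percentage
    points the match is reported as ambiguous rather than silently chosen.
    Without a spectrum, an exact |Δm| tie is ambiguous.  Centroids with no
    species inside the tolerance are unassigned.
    """
    if tol_mda <= 0:
        raise ValueError("tolerance must be positive")
    out = []
    for c in centroids:
        obs = _mz(c)
        within = sorted(
            (abs(obs - s.mz) * 1e3, s) for s in catalog if abs(obs - s.mz) * 1e3 <= tol_mda
        )
        if not within:
            out.append(
                PeakAssignment(obs, None, None, None, None, "unassigned")
            )
            continue
        status = "assigned"
        deviation: float | None = None
        best = within[0][1]
        if len(within) > 1:
            if spectrum is not None:
                scored = []
                for _, s in within:
                    try:
                        res = isotope_ratio_check(
                            spectrum, s, mz_shift=obs - s.mz
                        )
                        scored.append((res.max_deviation, s))
                    except ValueError:
                        continue
                if len(scored) >= 2:
                    scored.sort(key=lambda t: t[0])
                    if scored[1][0] - scored[0][0] < ambiguity_points:
                        status = "ambiguous"
                    best = scored[0][1]
                    deviation = scored[0][0]
                elif len(scored) == 1:
                    best = scored[0][1]
                    deviation = scored[0][0]
            elif len(within) > 1 and np.isclose(within[0][0], within[1][0]):
                status = "ambiguous"
        elif spectrum is not None:
            try:
                deviation = isotope_ratio_check(
                    spectrum, best, mz_shift=obs - best.mz
                ).max_deviation
            except ValueError:
                deviation = None
        delta = (obs - best.mz) * 1e3
        out.append(
            PeakAssignment(
                observed_mz=obs,
                species=best.name,
                delta_mda=delta,
                ppm=1e6 * (obs - best.mz) / best.mz,
                isotope_deviation=deviation,
                status=status,
            )
        )
    return out


# ---------------------------------------------------------------------------
# MS/MS neutral-loss annotation
# ---------------------------------------------------------------------------


_BPA = DEFAULT_MOLECULES["BPA"]
_DHB = DEFAULT_MOLECULES["DHB"]
_H2O = parse_formula("H2O")

#: Named product ions (exact cation m/z).  [DHB-H2O]+ is stored at its exact
#: radical-cation mass 136.0155 (C7H4O3+.), matched at the nominal 136 label.
NAMED_FRAGMENTS: dict[str, float] = {
    "Na+": monoisotopic_mz(parse_formula("Na")),
    "K+": monoisotopic_mz(parse_formula("K")),
    "[DHB-H2O]+": monoisotopic_mz(_DHB - _H2O),
    "[DHB-H2O+K]+": monoisotopic_mz((_DHB - _H2O) + parse_formula("K")),
    "[BPA-H2O+Na]+": monoisotopic_mz((_BPA - _H2O) + parse_formula("Na")),
    "[BPA-H2O+K]+": monoisotopic_mz((_BPA - _H2O) + parse_formula("K")),
}

#: Neutral losses (exact neutral masses): dehydrated matrix and drug.
NEUTRAL_LOSSES: dict[str, float] = {
    "DHB-H2O": monoisotopic_mz(_DHB - _H2O) + ELECTRON_MASS,  # neutral C7H4O3
    "BPA-H2O": monoisotopic_mz(_BPA - _H2O) + ELECTRON_MASS,  # neutral C9H10BNO3
}


def neutral_loss_annotate(
    precursor_mz: float,
    products: Sequence[float],
    tol: float = 0.5,
) -> MsMsAnnotation:
    """Annotate an MS/MS product list by fragment and neutral-loss matching.

    Products are matched (nearest within ``tol``, default 0.5 Da — product
    masses are reported nominally) first against the named fragment ions,
    then as ``precursor - loss`` for the catalog neutral losses; a loss match
    is reported as ``"loss:<name>"``.  A product above the precursor (beyond
    tolerance) is an error.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    entries = []
    for p in products:
        if p > precursor_mz + tol:
            raise ValueError(
                f"product m/z {p} exceeds precursor {precursor_mz} + tolerance"
            )
        candidates: list[tuple[float, str]] = []
        for name, frag in NAMED_FRAGMENTS.items():
            d = p - frag
            if abs(d) <= tol:
                candidates.append((abs(d), name))
        if not candidates:
            for name, loss in NEUTRAL_LOSSES.items():
                d = p - (precursor_mz - loss)
                if abs(d) <= tol:
                    candidates.append((abs(d), f"loss:{name}"))
        if candidates:
            candidates.sort()
            name = candidates[0][1]
            ref = (
                NAMED_FRAGMENTS[name]
                if name in NAMED_FRAGMENTS
                else precursor_mz - NEUTRAL_LOSSES[name.removeprefix("loss:")]
            )
            entries.append((float(p), name, (p - ref) * 1e3))
        else:
            entries.append((float(p), None, None))
    return MsMsAnnotation(precursor_mz=float(precursor_mz), entries=tuple(entries))
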