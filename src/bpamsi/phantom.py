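"""Synthetic MALDI-MSI phantom of a BPA-dosed brain section with a tumor.

The phantom stands in for the tissue measurement: a 60 μm pixel grid holding a
brain outline, a cerebral-cortex band, a tumor ellipse and an intra-tumor
hotspot.  BPA-bearing ion species live only in the tumor (elevated in the
hotspot), matrix (DHB) species cover the whole brain, potassium-dependent
species are enriched in the tumor, and four isobaric interference peaks flank
the protonated-BPA region (m/z 209.914, 210.026, 210.063, 210.098).  Spectra
are rendered as Gaussian profiles at a configurable FWHM resolving power
(default 20,000 at m/z 210), with a per-pixel multiplicative mass-axis drift
and scaled-Poisson shot noise, so that every downstream stage (lock-mass
recalibration, ROI averaging, narrow-window ion images, annotation) can be
tested against known ground truth.

BPA species are rendered at their *apparent* tissue positions — the calculated
m/z plus the small displacement observed on tissue (e.g. the protonated ion at
210.084 instead of 210.093, attributed to overlap with adjacent peaks) — so the
rendered spectrum reproduces the five separated peaks of the m/z 210 region.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .chem import IonSpecies, default_catalog
from .dataset import MSIDataset, Spectrum

__all__ = [
    "ResolutionModel",
    "Ellipse",
    "PhantomConfig",
    "SimulationResult",
    "default_phantom_config",
    "low_mass_config",
    "with_spot",
    "build_phantom",
    "make_axis",
    "synthesize_spectrum",
    "simulate_dataset",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass(frozen=True)
class ResolutionModel:
    """FWHM-based resolving power R(m) = R0 * (m / reference_mz)^exponent.

    ``exponent`` 0 (default) gives constant R over m/z; exponent 1 gives a
    constant absolute FWHM (used for the wide low-mass preset so a uniform
    axis keeps a constant number of points per peak width).
    """

    resolving_power: float = 20_000.0
    reference_mz: float = 210.0
    exponent: float = 0.0

    def __post_init__(self):
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be positive")

    def r_at(self, mz: float) -> float:
        return self.resolving_power * (mz / self.reference_mz) ** self.exponent

    def fwhm(self, mz):
        return np.asarray(mz) / self.r_at(np.asarray(mz))


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates (x right, y down)."""

    cx: float
    cy: float
    rx: float
    ry: float

    def __post_init__(self):
        if self.rx < 0 or self.ry < 0:
            raise ValueError("ellipse radii must be non-negative")

    def mask(self, width: int, height: int) -> np.ndarray:
        if self.rx == 0 or self.ry == 0:
            return np.zeros((height, width), dtype=bool)
        y, x = np.mgrid[0:height, 0:width]
        return ((x - self.cx) / self.rx) ** 2 + ((y - self.cy) / self.ry) ** 2 <= 1.0


# Region precedence from most to least specific; a species level defined for a
# coarser region applies to finer regions unless overridden.
_REGION_ORDER = ("hotspot", "tumor", "cortex", "brain")


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of the synthetic scene, forward model and noise."""

    width: int = 40
    height: int = 30
    pixel_pitch_um: float = 60.0
    brain: Ellipse = Ellipse(19.5, 14.5, 18.0, 13.0)
    tumor: Ellipse = Ellipse(27.0, 18.0, 6.0, 5.0)
    hotspot: Ellipse = Ellipse(28.5, 19.0, 2.5, 2.0)
    cortex_inner_frac: float = 0.75
    mz_range: tuple[float, float] = (205.0, 550.0)
    resolution: ResolutionModel = ResolutionModel()
    #: species name -> {region: apex-height level}; regions inherit outward.
    species_levels: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: isobaric interference lines: (m/z, {region: level})
    interferences: tuple[tuple[float, Mapping[str, float]], ...] = ()
    #: observed-position displacement per species, mDa (tissue overlap effect)
    apparent_shift_mda: Mapping[str, float] = field(default_factory=dict)
    drift_ppm_range: tuple[float, float] = (-30.0, 30.0)
    baseline: float = 1.0
    noise_scale: float | None = 0.04
    merge_window: float = 0.02
    prune: float = 1e-6
    seed: int = 0

    def digest(self) -> str:
        """Stable content digest of the configuration."""
        payload = json.dumps(
            {
                k: (
                    sorted((kk, dict(vv) if isinstance(vv, Mapping) else vv) for kk, vv in v.items())
                    if isinstance(v, Mapping)
                    else v
                )
                for k, v in self.__dict__.items()
            },
            default=lambda o: o.__dict__ if hasattr(o, "__dict__") else str(o),
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_phantom_config(seed: int = 0) -> PhantomConfig:
    """The default scene: acquisition range m/z 205-550, R = 20,000.

    Levels are apex heights in arbitrary intensity units.  The protonated-BPA
    tumor level (100) is about 1/3 of the tallest neighbouring interference
    (300 at 210.098), and the hotspot carries 3x the tumor level.
    """
    return PhantomConfig(
        species_levels={
            "[BPA+H]+": {"tumor": 100.0, "hotspot": 300.0},
            "[BPA-H2O+Na]+": {"tumor": 40.0, "hotspot": 120.0},
            "[BPA-H2O+K]+": {"tumor": 30.0, "hotspot": 90.0},
            "[BPA+DHB-2H2O+Na]+": {"tumor": 50.0, "hotspot": 150.0},
            "[BPA+DHB-2H2O+K]+": {"tumor": 60.0, "hotspot": 180.0},
            "[DHB-H+2K]+": {"brain": 250.0, "tumor": 350.0},
            "[2DHB-2H2O+H]+": {"brain": 150.0},
            "[2DHB-H2O+Na]+": {"brain": 120.0},
            "[2DHB-H2O+K]+": {"brain": 100.0, "tumor": 200.0},
        },
        interferences=(
            (209.914, {"brain": 200.0}),
            (210.026, {"brain": 40.0, "tumor": 100.0}),
            (210.063, {"brain": 60.0, "tumor": 150.0}),
            (210.098, {"brain": 20.0, "tumor": 300.0}),
        ),
        apparent_shift_mda={
            "[BPA+H]+": -9.2,
            "[BPA-H2O+Na]+": -7.0,
            "[BPA+DHB-2H2O+Na]+": 6.0,
            "[BPA+DHB-2H2O+K]+": 4.0,
        },
        seed=seed,
    )


def low_mass_config(seed: int = 0) -> PhantomConfig:
    """The second-measurement preset: m/z 20-215, lock mass [DHB+K]+ 192.990.

    Uses a constant-FWHM resolution model (exponent 1, still R = 20,000 at
    m/z 210) so the uniform axis keeps ten points per peak width across the
    wide range; adds the matrix, Na+ and K+ maps of the low-mass measurement.
    """
    base = default_phantom_config(seed=seed)
    return replace(
        base,
        mz_range=(20.0, 215.0),
        resolution=ResolutionModel(20_000.0, reference_mz=210.0, exponent=1.0),
        species_levels={
            "[BPA+H]+": {"tumor": 100.0, "hotspot": 300.0},
            "[BPA-H2O+Na]+": {"tumor": 40.0, "hotspot": 120.0},
            "[DHB+H]+": {"brain": 200.0},
            "[DHB+K]+": {"brain": 150.0, "tumor": 250.0},
            "[Na]+": {"brain": 120.0},
            "[K]+": {"brain": 100.0, "tumor": 300.0, "hotspot": 500.0},
        },
        interferences=(
            (209.914, {"brain": 200.0}),
            (210.026, {"brain": 40.0, "tumor": 100.0}),
            (210.063, {"brain": 60.0, "tumor": 150.0}),
            (210.098, {"brain": 20.0, "tumor": 300.0}),
        ),
    )


def with_spot(
    config: PhantomConfig,
    region: str | Ellipse,
    species: str = "[BPA+H]+",
    level: float = 150.0,
) -> PhantomConfig:
    """Return a config with a uniform standard spot of ``species`` added.

    Emulates pipetting a drug standard onto the section after the first
    acquisition: the species gains ``level`` uniformly over ``region`` (a mask
    name or an ellipse stored under the synthetic region name "spot").
    """
    levels = {k: dict(v) for k, v in config.species_levels.items()}
    entry = levels.setdefault(species, {})
    if isinstance(region, Ellipse):
        raise NotImplementedError("ellipse spots: pass a region name instead")
    entry[region] = entry.get(region, _inherited_level(config, species, region)) + level
    return replace(config, species_levels=levels)


def _inherited_level(config: PhantomConfig, species: str, region: str) -> float:
    entry = config.species_levels.get(species, {})
    start = _REGION_ORDER.index(region)
    for r in _REGION_ORDER[start:]:
        if r in entry:
            return entry[r]
    return 0.0


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------


def region_masks(config: PhantomConfig) -> dict[str, np.ndarray]:
    """Boolean masks for brain, cortex, tumor and hotspot; nesting enforced."""
    w, h = config.width, config.height
    brain = config.brain.mask(w, h)
    tumor = config.tumor.mask(w, h) & brain
    hotspot = config.hotspot.mask(w, h)
    if np.any(hotspot & ~config.tumor.mask(w, h)):
        raise ValueError("hotspot ellipse extends outside the tumor ellipse")
    if np.any(config.tumor.mask(w, h) & ~brain):
        raise ValueError("tumor ellipse extends outside the brain ellipse")
    inner = Ellipse(
        config.brain.cx,
        config.brain.cy,
        config.brain.rx * config.cortex_inner_frac,
        config.brain.ry * config.cortex_inner_frac,
    ).mask(w, h)
    cortex = brain & ~inner & ~tumor
    return {"brain": brain, "cortex": cortex, "tumor": tumor, "hotspot": hotspot & tumor}


def _level_map(
    levels: Mapping[str, float], masks: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Per-pixel level: most specific region entry wins, inherited outward."""
    out = np.zeros_like(masks["brain"], dtype=np.float64)
    for region in reversed(_REGION_ORDER):  # coarse to fine; fine overwrites
        if region in levels:
            out[masks[region]] = levels[region]
    out[~masks["brain"]] = 0.0
    return out


def build_phantom(
    config: PhantomConfig,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Ground-truth abundance map per signal source, plus the region masks.

    Interference sources are named ``"bio@<m/z>"``.  BPA-bearing maps are
    nonzero only inside the tumor by construction of the default levels.
    """
    masks = region_masks(config)
    maps = {
        name: _level_map(levels, masks)
        for name, levels in config.species_levels.items()
    }
    for mz, levels in config.interferences:
        maps[f"bio@{mz:.3f}"] = _level_map(levels, masks)
    return maps, masks


def line_sources(
    config: PhantomConfig, catalog: Sequence[IonSpecies] | None = None
) -> dict[str, tuple[tuple[float, float], ...]]:
    """(m/z, relative height) lines for every signal source in the scene.

    Catalog species carry their finite-resolution isotope pattern shifted by
    the configured apparent displacement; interferences are single lines.
    Lines outside the configured m/z range (which cannot be rendered) are
    dropped.
    """
    cat = {s.name: s for s in (catalog if catalog is not None else default_catalog())}
    lo, hi = config.mz_range
    out: dict[str, tuple[tuple[float, float], ...]] = {}
    for name in config.species_levels:
        if name not in cat:
            raise KeyError(f"phantom species {name!r} not in catalog")
        pat = cat[name].pattern(config.merge_window, config.prune)
        shift = config.apparent_shift_mda.get(name, 0.0) * 1e-3
        drift_slack = max(abs(d) for d in config.drift_ppm_range) * 1e-6

        def renderable(m: float) -> bool:
            margin = 5.0 * float(config.resolution.fwhm(m)) + drift_slack * m
            return lo + margin <= m <= hi - margin

        lines = tuple(
            (m + shift, r) for m, r in pat.lines if renderable(m + shift)
        )
        if lines:
            out[name] = lines
    for mz, _levels in config.interferences:
        if lo < mz < hi:
            out[f"bio@{mz:.3f}"] = ((mz, 100.0),)
    return out


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def make_axis(
    mz_range: tuple[float, float], resolution: ResolutionModel
) -> np.ndarray:
    """Uniform m/z axis with spacing FWHM(range minimum)/10.

    Anchoring the spacing at the low end keeps at least ten samples per peak
    width everywhere on the axis for any non-negative resolution exponent.
    """
    lo, hi = mz_range
    if hi <= lo:
        raise ValueError("empty m/z range")
    step = float(resolution.fwhm(lo)) / 10.0
    n = int(np.floor((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def synthesize_spectrum(
    species_amounts: Mapping[str, float],
    lines: Mapping[str, Sequence[tuple[float, float]]],
    resolution: ResolutionModel,
    axis: np.ndarray,
    drift_ppm: float = 0.0,
    rng: np.random.Generator | None = None,
    baseline: float = 0.0,
    noise_scale: float | None = None,
) -> Spectrum:
    """Render one profile spectrum from source amounts and line lists.

    Each line becomes a Gaussian centred at ``m/z * (1 + drift_ppm * 1e-6)``
    with height ``amount * relative/100`` and FWHM from the resolution model.
    A flat chemical baseline is added, then scaled-Poisson noise
    (``scale * Poisson(I / scale)``) if ``noise_scale`` is given (requires
    ``rng``).  Raises if a line (± 5 FWHM) falls outside the axis or if the
    axis is coarser than 6 points per FWHM at any rendered line.
    """
    axis = np.asarray(axis, dtype=np.float64)
    step = float(axis[1] - axis[0])
    intens = np.full(axis.size, float(baseline), dtype=np.float64)
    for name, amount in species_amounts.items():
        if amount == 0.0 or name not in lines:
            continue
        for mz, rel in lines[name]:
            center = mz * (1.0 + drift_ppm * 1e-6)
            fwhm = float(resolution.fwhm(center))
            if fwhm / step < 6.0:
                raise ValueError(
                    f"axis too coarse at m/z {center:.3f}: "
                    f"{fwhm / step:.1f} points per FWHM (need >= 6)"
                )
            span = 5.0 * fwhm
            if center - span < axis[0] or center + span > axis[-1]:
                raise ValueError(
                    f"axis does not cover line at m/z {center:.3f} +- 5 FWHM"
                )
            sigma = fwhm / _FWHM_TO_SIGMA
            i, j = np.searchsorted(axis, [center - span, center + span])
            seg = axis[i:j]
            intens[i:j] += (amount * rel / 100.0) * np.exp(
                -0.5 * ((seg - center) / sigma) ** 2
            )
    if noise_scale is not None:
        if rng is None:
            raise ValueError("noise requires a random generator")
        intens = noise_scale * rng.poisson(intens / noise_scale).astype(np.float64)
    return Spectrum(axis, intens)


@dataclass
class SimulationResult:
    """Dataset plus the ground truth it was rendered from."""

    dataset: MSIDataset
    species_maps: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    lines: dict[str, tuple[tuple[float, float], ...]]
    drift_ppm: np.ndarray  # (height, width); NaN outside the brain

    def truth_position(self, species: str) -> float:
        """Ground-truth base-line position (apparent, undrifted) of a source."""
        src = self.lines[species]
        return max(src, key=lambda t: t[1])[0]


def simulate_dataset(
    config: PhantomConfig, catalog: Sequence[IonSpecies] | None = None
) -> SimulationResult:
    """Render the full phantom: one spectrum per in-brain pixel.

    Per-pixel mass-axis drift is drawn uniformly from ``drift_ppm_range``;
    drift, then per-pixel noise, are consumed from a single seeded generator
    in row-major pixel order, so a given config + seed is bit-reproducible.
    """
    maps, masks = build_phantom(config)
    lines = line_sources(config, catalog)
    axis = make_axis(config.mz_range, config.resolution)
    rng = np.random.default_rng(config.seed)

    ys, xs = np.nonzero(masks["brain"])
    order = np.lexsort((xs, ys))  # row-major
    ys, xs = ys[order], xs[order]
    lo_d, hi_d = config.drift_ppm_range
    drifts = rng.uniform(lo_d, hi_d, size=ys.size)

    intensities = np.empty((ys.size, axis.size), dtype=np.float32)
    for k in range(ys.size):
        amounts = {name: maps[name][ys[k], xs[k]] for name in lines}
        spec = synthesize_spectrum(
            amounts,
            lines,
            config.resolution,
            axis,
            drift_ppm=float(drifts[k]),
            rng=rng,
            baseline=config.baseline,
            noise_scale=config.noise_scale,
        )
        intensities[k] = spec.intensity
    drift_map = np.full((config.height, config.width), np.nan)
    drift_map[ys, xs] = drifts
    dataset = MSIDataset(
        mz_axis=axis,
        coords=np.column_stack([xs, ys]),
        intensities=intensities,
        pixel_pitch_um=config.pixel_pitch_um,
        metadata={
            "seed": config.seed,
            "config_digest": config.digest(),
            "grid_width": config.width,
            "grid_height": config.height,
        },
    )
    return SimulationResult(dataset, maps, masks, lines, drift_map)
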