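"""Elemental-formula arithmetic, exact ion masses and isotope fine structure.

This module carries the mass-spectrometric theory used everywhere else in the
package: parsing and combining elemental formulas, resolving adduct/complex
ion recipes (e.g. ``[BPA+DHB-2H2O+K]+``) into a cation formula, computing
monoisotopic m/z with the electron mass accounted for, enumerating the
fine-structure isotopologue distribution (boron's two isotopes give the
characteristic peak ~1 Da below the base peak), and pooling fine-structure
lines that a finite-resolution instrument cannot separate into the familiar
integer-spaced isotope clusters.

Conventions
-----------
* All ions are singly charged positive; m/z equals the summed atomic masses of
  the cation's atoms minus one electron mass.  Protonation therefore adds a
  proton mass (H atom minus electron), which is what makes the protonated
  boronophenylalanine ion come out at 210.093 rather than 210.094.
* Monoisotopic mass uses the most abundant isotope of each element (11B for
  boron, which is heavier than 10B).
* Formula strings are plain Hill-style element runs ("C9H10BNO3"); charge and
  adduct bookkeeping live in :class:`IonRecipe`, never in the string.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "DEFAULT_ISOTOPES",
    "DEFAULT_MOLECULES",
    "ElementalFormula",
    "IsotopeTable",
    "IonRecipe",
    "IsotopePattern",
    "IonSpecies",
    "parse_formula",
    "resolve_recipe",
    "monoisotopic_mz",
    "isotope_fine_pattern",
    "merge_pattern",
    "ppm_error",
    "round_half_up",
    "load_catalog",
    "default_catalog",
]

ELECTRON_MASS = 0.00054858

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ElementalFormula:
    """Element symbol -> non-negative count map with element-wise arithmetic."""

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count ({merged[el]})"
                )
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("multiplicity must be non-negative")
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def hill(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""
        parts = []
        rest = dict(self.counts)
        for el in ("C", "H"):
            if el in rest:
                n = rest.pop(el)
                parts.append(el + (str(n) if n != 1 else ""))
        for el in sorted(rest):
            n = rest[el]
            parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C9H10BNO3"``.

    Raises ``ValueError`` on unknown element symbols or malformed counts.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in DEFAULT_ISOTOPES.elements:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula(counts)


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope masses (Da) and abundances, plus particle masses.

    Invariants: per element, abundances sum to 1 within 1e-9 and masses are
    strictly increasing.
    """

    isotopes: Mapping[str, tuple[tuple[float, float], ...]]
    electron_mass: float = ELECTRON_MASS

    def __post_init__(self):
        for el, iso in self.isotopes.items():
            masses = [m for m, _ in iso]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"isotope masses not strictly increasing for {el}")
            total = sum(a for _, a in iso)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances for {el} sum to {total}, not 1")

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(self.isotopes)

    @property
    def proton_mass(self) -> float:
        h1 = self.isotopes["H"][0][0]
        return h1 - self.electron_mass

    def principal(self, el: str) -> tuple[float, float]:
        """(mass, abundance) of the most abundant isotope of ``el``."""
        try:
            iso = self.isotopes[el]
        except KeyError:
            raise KeyError(f"element {el} missing from isotope table") from None
        return max(iso, key=lambda t: t[1])


# Standard IUPAC/CIAAW atomic data for the elements occurring in the BPA/DHB
# ion catalog.  39K/40K/41K are carried in full so abundances sum to one.
DEFAULT_ISOTOPES = IsotopeTable(
    {
        "H": ((1.00782503, 0.99988), (2.01410178, 0.00012)),
        "B": ((10.01294, 0.199), (11.00931, 0.801)),
        "C": ((12.0, 0.9893), (13.00335, 0.0107)),
        "N": ((14.00307, 0.99636), (15.00011, 0.00364)),
        "O": ((15.99491, 0.99757), (16.99913, 0.00038), (17.99916, 0.00205)),
        "Na": ((22.98977, 1.0),),
        "K": ((38.96371, 0.932581), (39.96400, 0.000117), (40.96182, 0.067302)),
    }
)

PROTON_MASS = DEFAULT_ISOTOPES.proton_mass

#: Neutral molecules the ion recipes are built from.  BPA is
#: L-4-phenylalanineboronic acid (boronophenylalanine), the boron carrier drug;
#: DHB is the 2,5-dihydroxybenzoic acid MALDI matrix.
DEFAULT_MOLECULES: dict[str, ElementalFormula] = {
    "BPA": parse_formula("C9H12BNO4"),
    "DHB": parse_formula("C7H6O4"),
}

_WATER = parse_formula("H2O")

#: Charge-carrier tag -> (formula added, formula removed).  All carriers yield
#: a +1 cation; the electron is subtracted at the mass stage, not here.
CARRIERS: dict[str, tuple[ElementalFormula, ElementalFormula]] = {
    "proton": (parse_formula("H"), ElementalFormula({})),
    "Na": (parse_formula("Na"), ElementalFormula({})),
    "K": (parse_formula("K"), ElementalFormula({})),
    "2K-H": (ElementalFormula({"K": 2}), parse_formula("H")),
    "electron-loss": (ElementalFormula({}), ElementalFormula({})),
}


@dataclass(frozen=True)
class IonRecipe:
    """A named ion recipe: base molecules, water losses and a charge carrier.

    Example: ``[BPA+DHB-2H2O+K]+`` is bases [(BPA,1),(DHB,1)], water_loss 2,
    carrier "K".  Charge is always +1.
    """

    name: str
    bases: tuple[tuple[str, int], ...]
    water_loss: int = 0
    carrier: str = "proton"
    charge: int = 1

    def __post_init__(self):
        if self.charge != 1:
            raise ValueError("only singly charged positive ions are supported")
        if self.carrier not in CARRIERS:
            raise ValueError(f"unknown charge carrier {self.carrier!r}")
        if self.water_loss < 0:
            raise ValueError("water_loss must be non-negative")


def resolve_recipe(
    recipe: IonRecipe,
    molecule_defs: Mapping[str, ElementalFormula] | None = None,
) -> ElementalFormula:
    """Resolve an :class:`IonRecipe` into the elemental formula of the cation.

    formula = sum(bases) - water_loss * H2O + carrier additions - carrier
    removals.  Raises ``KeyError`` for undefined base molecules and
    ``ValueError`` if any subtraction would drive an element count negative.
    """
    defs = DEFAULT_MOLECULES if molecule_defs is None else molecule_defs
    total = ElementalFormula({})
    for name, mult in recipe.bases:
        if name not in defs:
            raise KeyError(f"base molecule {name!r} not defined")
        total = total + mult * defs[name]
    total = total - recipe.water_loss * _WATER
    add, remove = CARRIERS[recipe.carrier]
    return (total + add) - remove


def monoisotopic_mz(
    formula: ElementalFormula,
    table: IsotopeTable = DEFAULT_ISOTOPES,
    charge: int = 1,
) -> float:
    """Monoisotopic m/z of a +1 cation with the given elemental composition.

    Sums the principal-isotope mass of every atom and subtracts one electron
    mass.  The value is returned unrounded; report layers round to 3 decimals.
    """
    if not formula.counts:
        raise ValueError("empty formula")
    if charge != 1:
        raise ValueError("only +1 ions supported")
    mass = sum(n * table.principal(el)[0] for el, n in formula.counts.items())
    return mass - table.electron_mass


def ppm_error(observed: float, calculated: float) -> float:
    """Signed relative mass error in parts per million."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return 1e6 * (observed - calculated) / calculated


# ---------------------------------------------------------------------------
# Fine-structure isotope pattern
# ---------------------------------------------------------------------------


def _compositions(n: int, k: int) -> Iterable[tuple[int, ...]]:
    """All k-tuples of non-negative integers summing to n (stars and bars)."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def _element_pattern(
    el: str, n: int, table: IsotopeTable
) -> list[tuple[float, float]]:
    """Multinomial isotope distribution of n atoms of one element."""
    iso = table.isotopes[el]
    out = []
    for combo in _compositions(n, len(iso)):
        p = math.factorial(n)
        for c, (_, ab) in zip(combo, iso):
            p = p / math.factorial(c) * ab**c
        if p == 0.0:
            continue
        m = sum(c * mass for c, (mass, _) in zip(combo, iso))
        out.append((m, p))
    return out


def isotope_fine_pattern(
    formula: ElementalFormula,
    table: IsotopeTable = DEFAULT_ISOTOPES,
    prune: float = 1e-6,
    charge: int = 1,
) -> list[tuple[float, float]]:
    """Fine-structure isotopologue distribution of a +1 cation.

    Enumerates every isotope composition per element (multinomial) and
    convolves across elements; returns ``(m/z, probability)`` pairs sorted by
    m/z for all isotopologues with probability >= ``prune`` times the most
    probable line.  Probabilities are raw (returned + pruned sum to 1), so the
    pattern can be re-pruned without renormalisation artefacts.
    """
    if not (0.0 < prune <= 1e-3):
        raise ValueError("prune must be in (0, 1e-3]")
    if charge != 1:
        raise ValueError("only +1 ions supported")
    if not formula.counts:
        raise ValueError("empty formula")

    states: dict[float, float] = {0.0: 1.0}
    for el, n in formula.counts.items():
        epat = _element_pattern(el, n, table)
        nxt: dict[float, float] = {}
        for m0, p0 in states.items():
            for dm, dp in epat:
                key = round(m0 + dm, 9)
                nxt[key] = nxt.get(key, 0.0) + p0 * dp
        # Guard against state explosion only; threshold far below the final
        # prune so the returned set is independent of intermediate order.
        if len(nxt) > 500_000:
            floor = max(nxt.values()) * prune * 1e-4
            nxt = {m: p for m, p in nxt.items() if p >= floor}
        states = nxt

    pmax = max(states.values())
    lines = [
        (m - table.electron_mass, p)
        for m, p in states.items()
        if p >= prune * pmax
    ]
    lines.sort()
    return lines


@dataclass(frozen=True)
class IsotopePattern:
    """Finite-resolution isotope pattern: pooled lines, base peak = 100.

    ``lines`` are ``(centroid m/z, relative abundance % of base)`` sorted by
    m/z; any two centroids differ by more than ``merge_window``.
    """

    lines: tuple[tuple[float, float], ...]
    merge_window: float

    def __post_init__(self):
        if not self.lines:
            raise ValueError("pattern has no lines")
        rels = [r for _, r in self.lines]
        if abs(max(rels) - 100.0) > 1e-9:
            raise ValueError("base peak abundance must be exactly 100")
        if any(r <= 0 for r in rels):
            raise ValueError("all abundances must be positive")
        mzs = [m for m, _ in self.lines]
        if any(b - a < self.merge_window for a, b in zip(mzs, mzs[1:])):
            raise ValueError("centroids must differ by at least merge_window")

    @property
    def base_mz(self) -> float:
        return max(self.lines, key=lambda t: t[1])[0]


def merge_pattern(
    fine: Sequence[tuple[float, float]], merge_window: float = 0.02
) -> IsotopePattern:
    """Pool fine-structure lines closer than ``merge_window`` (strict <).

    Consecutive lines whose gap is strictly less than the window are pooled
    into one cluster (probability sum, probability-weighted centroid); the
    pooled pattern is normalised so the most probable cluster reads 100.  With
    the 0.02 Da default this reproduces the printed isotope-abundance-ratio
    arithmetic: the 10B+13C isotopologue (7 mDa above the all-light line)
    pools into the base peak, and 10B+41K pools into M+1.
    """
    if merge_window <= 0:
        raise ValueError("merge_window must be positive")
    if not fine:
        raise ValueError("empty fine pattern")
    pts = sorted(fine)
    clusters: list[list[tuple[float, float]]] = [[pts[0]]]
    for mz, p in pts[1:]:
        if mz - clusters[-1][-1][0] < merge_window:
            clusters[-1].append((mz, p))
        else:
            clusters.append([(mz, p)])
    pooled = []
    for cl in clusters:
        ptot = sum(p for _, p in cl)
        centroid = sum(m * p for m, p in cl) / ptot
        pooled.append((centroid, ptot))
    base = max(p for _, p in pooled)
    lines = tuple((m, 100.0 * (p / base)) for m, p in pooled)
    return IsotopePattern(lines=lines, merge_window=merge_window)


# ---------------------------------------------------------------------------
# Species catalog
# ---------------------------------------------------------------------------

_BASES_RE = re.compile(r"^(\d*)([A-Za-z][A-Za-z0-9]*)$")


def _parse_bases(text: str) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if not text or text == "-":
        return ()
    out = []
    for part in text.split("+"):
        m = _BASES_RE.match(part.strip())
        if not m:
            raise ValueError(f"malformed bases field {text!r}")
        mult = int(m.group(1)) if m.group(1) else 1
        out.append((m.group(2), mult))
    return tuple(out)


@dataclass(frozen=True)
class IonSpecies:
    """A catalog entry: recipe plus derived formula, m/z and isotope pattern.

    ``flag`` is "ok" for species whose printed m/z follows from plain recipe
    arithmetic, "printed" for species kept at their published m/z despite an
    arithmetic inconsistency in their label (the two BPA+2DHB complexes).
    """

    recipe: IonRecipe
    formula: ElementalFormula
    mz: float
    flag: str = "ok"
    printed_mz: float | None = None

    @property
    def name(self) -> str:
        return self.recipe.name

    def pattern(
        self,
        merge_window: float = 0.02,
        prune: float = 1e-6,
        table: IsotopeTable = DEFAULT_ISOTOPES,
    ) -> IsotopePattern:
        fine = isotope_fine_pattern(self.formula, table=table, prune=prune)
        return merge_pattern(fine, merge_window)


def load_catalog(
    path: str | Path,
    molecule_defs: Mapping[str, ElementalFormula] | None = None,
    table: IsotopeTable = DEFAULT_ISOTOPES,
) -> list[IonSpecies]:
    """Load an ion-species catalog from a TSV file.

    Columns: name, bases ("BPA+DHB", "2DHB", "-" for none), water_loss,
    carrier (proton|Na|K|2K-H|electron-loss), flag (ok|printed), printed_mz.
    """
    species: list[IonSpecies] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            row = raw.split("\t")
            recipe = IonRecipe(
                name=row[idx["name"]],
                bases=_parse_bases(row[idx["bases"]]),
                water_loss=int(row[idx["water_loss"]]),
                carrier=row[idx["carrier"]],
            )
            formula = resolve_recipe(recipe, molecule_defs)
            flag = row[idx["flag"]] if "flag" in idx and len(row) > idx["flag"] else "ok"
            printed = None
            if "printed_mz" in idx and len(row) > idx["printed_mz"]:
                cell = row[idx["printed_mz"]].strip()
                printed = float(cell) if cell and cell != "-" else None
            mz = printed if (flag == "printed" and printed is not None) else monoisotopic_mz(
                formula, table
            )
            species.append(
                IonSpecies(
                    recipe=recipe, formula=formula, mz=mz, flag=flag, printed_mz=printed
                )
            )
    return species


def default_catalog() -> list[IonSpecies]:
    """The shipped BPA/DHB adduct catalog."""
    return load_catalog(Path(__file__).parent / "data" / "species_catalog.tsv")
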