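"""Body-mass estimation from dental proxies and size categorization.

Masses come from log-linear allometric regressions,
``log10(mass) = a * log10(x) + b``, applied to a skeletal measurement proxy
``x`` (typically a tooth dimension or area).  Species without measurable
material are placed into a size category from the geometric-mean mass of
their closest measured relatives (genus, then family, then order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AllometricRegression",
    "SpeciesMassRecord",
    "SizeCategoryScheme",
    "ORDER_OF_MAGNITUDE",
    "SIMPLE",
    "estimate_mass",
    "select_regression",
    "assign_category",
    "impute_category_from_relatives",
    "median_mass",
    "read_registry",
    "read_measurements",
    "estimate_species_masses",
]


@dataclass(frozen=True)
class AllometricRegression:
    """One published-style log-linear mass regression.

    ``clade_scope`` names the taxon the fit applies to; ``priority`` breaks
    ties between equally specific scopes (lower wins).
    """

    clade_scope: str
    proxy: str
    slope: float
    intercept: float
    x_units: str = "mm2"
    mass_units: str = "g"
    priority: int = 0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("allometric slope must be positive")
        if self.mass_units not in ("g", "kg"):
            raise ValueError(f"unknown mass units {self.mass_units!r}")


@dataclass(frozen=True)
class SpeciesMassRecord:
    species: str
    mass_kg: float | None
    category: str
    category_source: str  # "measured" | "imputed_from_relatives"


@dataclass(frozen=True)
class SizeCategoryScheme:
    """Ordered mass breakpoints (kg); boundaries belong to the upper category."""

    name: str
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need one more label than boundary")
        if list(self.boundaries) != sorted(self.boundaries):
            raise ValueError("boundaries must be ascending")

    def category_index(self, mass_kg: float) -> int:
        if not mass_kg > 0:
            raise ValueError("mass must be positive")
        # snap masses a rounding error below a breakpoint onto it, so that
        # e.g. a geometric mean of 50 and 200 kg lands in the 100-1000 decade
        return int(np.searchsorted(
            self.boundaries, mass_kg * (1.0 + 1e-9), side="right"
        ))

    def category(self, mass_kg: float) -> str:
        return self.labels[self.category_index(mass_kg)]

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    def log_midpoint(self, index: int) -> float:
        """log10-kg midpoint of a category (end bins extended by one decade)."""
        edges = [math.log10(b) for b in self.boundaries]
        lo = edges[index - 1] if index > 0 else edges[0] - 1.0
        hi = edges[index] if index < len(edges) else edges[-1] + 1.0
        return 0.5 * (lo + hi)


ORDER_OF_MAGNITUDE = SizeCategoryScheme(
    name="order_of_magnitude",
    boundaries=(0.01, 0.1, 1.0, 10.0, 100.0, 1000.0),
    labels=("<0.01", "0.01-0.1", "0.1-1", "1-10", "10-100", "100-1000", "1000+"),
)

SIMPLE = SizeCategoryScheme(
    name="simple",
    boundaries=(1.0, 30.0),
    labels=("small", "medium", "large"),
)


def estimate_mass(
    measurement: float,
    regression: AllometricRegression,
    measurement_units: str | None = None,
) -> float:
    """Mass in kg from ``10**(a*log10(x) + b)``, converted from the
    regression's native mass units."""
    if measurement <= 0:
        raise ValueError("measurement must be positive")
    if measurement_units is not None and measurement_units != regression.x_units:
        raise ValueError(
            f"measurement units {measurement_units!r} do not match "
            f"regression units {regression.x_units!r}"
        )
    mass = 10 ** (regression.slope * math.log10(measurement) + regression.intercept)
    return mass / 1000.0 if regression.mass_units == "g" else mass


def select_regression(
    clade_path: Sequence[str],
    registry: Iterable[AllometricRegression],
    proxy: str | None = None,
) -> AllometricRegression | None:
    """Pick the most clade-specific applicable regression.

    Specificity is depth within ``clade_path`` (ordered root -> genus); ties
    break on ``priority``.  Returns ``None`` when no scope matches — the
    species is then unmeasurable.
    """
    depth = {name: i for i, name in enumerate(clade_path)}
    candidates = [
        r for r in registry
        if r.clade_scope in depth and (proxy is None or r.proxy == proxy)
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda r: (-depth[r.clade_scope], r.priority))


def assign_category(mass_kg: float, scheme: SizeCategoryScheme) -> str:
    return scheme.category(mass_kg)


def impute_category_from_relatives(
    species: str,
    taxonomy: Mapping[str, Sequence[str]],
    measured: Iterable[SpeciesMassRecord],
    scheme: SizeCategoryScheme,
    levels: Sequence[str] = ("genus", "family", "order"),
) -> SpeciesMassRecord | None:
    """Categorize an unmeasured species from the geometric mean mass of its
    closest measured relatives.

    ``taxonomy`` maps each species to its clade path (root -> genus); the
    search widens genus -> family -> order, stopping at the first level with
    any measured relative.  The geometric mean (mean of log10 masses) sets
    the category; ``mass_kg`` stays missing so the species never enters
    median-mass summaries.  Returns ``None`` when no relative is measured at
    any level.
    """
    path = list(taxonomy.get(species, ()))
    if not path:
        return None
    measured = [m for m in measured if m.mass_kg is not None]
    by_species = {m.species: m for m in measured}
    # levels are taken from the tail of the clade path: ... order, family, genus
    for back in range(1, min(len(levels), len(path)) + 1):
        scope = path[-back]
        rel_masses = [
            m.mass_kg
            for name, m in by_species.items()
            if name != species and scope in taxonomy.get(name, ())
        ]
        if rel_masses:
            gm = 10 ** float(np.mean(np.log10(rel_masses)))
            return SpeciesMassRecord(
                species=species,
                mass_kg=None,
                category=scheme.category(gm),
                category_source="imputed_from_relatives",
            )
    return None


def median_mass(records: Iterable[SpeciesMassRecord]) -> float:
    """Median over measured masses only; imputed-category species are
    excluded because they carry no mass estimate."""
    masses = [r.mass_kg for r in records if r.mass_kg is not None]
    if not masses:
        raise ValueError("no measured masses: median undefined")
    return float(np.median(masses))


# ---------------------------------------------------------------------------
# table I/O

def read_registry(path) -> list[AllometricRegression]:
    df = pd.read_csv(path)
    return [
        AllometricRegression(
            clade_scope=row.clade_scope,
            proxy=row.proxy,
            slope=float(row.slope),
            intercept=float(row.intercept),
            x_units=getattr(row, "x_units", "mm2"),
            mass_units=getattr(row, "mass_units", "g"),
            priority=int(getattr(row, "priority", 0)),
        )
        for row in df.itertuples(index=False)
    ]


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "proxy", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"measurements table needs columns {sorted(required)}")
    return df


def estimate_species_masses(
    measurements: pd.DataFrame,
    registry: Sequence[AllometricRegression],
    taxonomy: Mapping[str, Sequence[str]],
    scheme: SizeCategoryScheme = ORDER_OF_MAGNITUDE,
    impute: bool = True,
) -> dict[str, SpeciesMassRecord]:
    """Per-species mass and category for every species in ``taxonomy``.

    Measurements are averaged per (species, proxy) before regression; a
    species with several usable proxies gets the regression selected for its
    most specific scope.  Species without measurements are imputed from
    relatives when ``impute`` is set.
    """
    records: dict[str, SpeciesMassRecord] = {}
    grouped = measurements.groupby(["species", "proxy"])["value"].mean()
    for species in {s for s, _ in grouped.index}:
        path = taxonomy.get(species)
        if path is None:
            continue
        best: tuple[AllometricRegression, float] | None = None
        for (sp, proxy), value in grouped.items():
            if sp != species:
                continue
            reg = select_regression(path, registry, proxy=proxy)
            if reg is None:
                continue
            depth = list(path).index(reg.clade_scope)
            if best is None or depth > list(path).index(best[0].clade_scope):
                best = (reg, float(value))
        if best is None:
            continue
        mass = estimate_mass(best[1], best[0])
        records[species] = SpeciesMassRecord(
            species=species,
            mass_kg=mass,
            category=scheme.category(mass),
            category_source="measured",
        )
    if impute:
        measured_list = list(records.values())
        for species in taxonomy:
            if species in records:
                continue
            rec = impute_category_from_relatives(
                species, taxonomy, measured_list, scheme
            )
            if rec is not None:
                records[species] = rec
    return records
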