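"""Research-time analyses: taxonomic-opinion replay, discovery curves,
sampling-standardized discovery curves, and skew / median-mass trajectories.

"Research time" is the historical time of palaeontological publication
(default window 1840-2024), as opposed to geological time.  Occurrences are
replayed year by year: each carries the identification current in that year
(honouring later re-identifications), and each name is resolved through the
taxonomic opinions — recombinations (valid species moved to another genus)
and synonymizations (names invalidated into another taxon) — published up
to that year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import (
    IncidenceFrequencyTable,
    NotViableError,
    diversity_at_quorum,
)
from .occurrences import OccurrenceRecord

__all__ = [
    "OpinionEvent",
    "OpinionError",
    "OpinionIndex",
    "DiscoveryCurve",
    "name_as_of_year",
    "identification_as_of_year",
    "discovery_curve",
    "standardized_discovery_curve",
    "skew_trajectory",
    "median_mass_trajectory",
    "effort_proxies",
    "read_opinions",
    "moment_skewness",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = (1840, 2024)


class OpinionError(ValueError):
    """Inconsistent opinion set: a cycle or a same-year conflict."""


@dataclass(frozen=True)
class OpinionEvent:
    kind: str  # "recombination" | "synonymization"
    year: int
    from_name: str
    to_name: str

    def __post_init__(self):
        if self.from_name == self.to_name:
            raise ValueError("opinion must change the name")
        if self.kind not in ("recombination", "synonymization"):
            raise ValueError(f"unknown opinion kind {self.kind!r}")


class OpinionIndex:
    """Opinions indexed by superseded name, with per-(name, year) memoized
    resolution."""

    def __init__(self, opinions: Iterable[OpinionEvent]):
        self._by_name: dict[str, list[OpinionEvent]] = {}
        for op in opinions:
            self._by_name.setdefault(op.from_name, []).append(op)
        for name, ops in self._by_name.items():
            ops.sort(key=lambda o: o.year)
            for a, b in zip(ops, ops[1:]):
                if a.year == b.year and a.to_name != b.to_name:
                    raise OpinionError(
                        f"conflicting opinions on {name!r} in {a.year}: "
                        f"{a.to_name!r} vs {b.to_name!r}"
                    )
        self._memo: dict[tuple[str, int], str] = {}

    def resolve(self, name: str, year: int) -> str:
        key = (name, year)
        if key in self._memo:
            return self._memo[key]
        current = name
        seen = {current}
        while True:
            ops = [o for o in self._by_name.get(current, ()) if o.year <= year]
            if not ops:
                break
            nxt = ops[-1].to_name  # most recent applicable opinion
            if nxt in seen:
                raise OpinionError(
                    f"opinion cycle involving {nxt!r} at year {year}"
                )
            seen.add(nxt)
            current = nxt
        self._memo[key] = current
        return current


def name_as_of_year(
    original_name: str,
    opinions: Iterable[OpinionEvent] | OpinionIndex,
    year: int,
) -> str:
    """Resolve a name through every opinion published up to ``year``,
    following synonymization/recombination chains to their fixed point."""
    index = opinions if isinstance(opinions, OpinionIndex) else OpinionIndex(opinions)
    return index.resolve(original_name, year)


def identification_as_of_year(
    record: OccurrenceRecord,
    year: int,
    opinions: OpinionIndex | None = None,
) -> str | None:
    """The species name this occurrence carried in ``year``: the latest
    identification event at or before the year, passed through the opinions
    current in that year.  ``None`` if the occurrence was not yet published."""
    current = None
    for ev_year, ev_name in record.identification_events:
        if ev_year <= year:
            current = ev_name
        else:
            break
    if current is None:
        return None
    return opinions.resolve(current, year) if opinions is not None else current


def _is_species_level(name: str) -> bool:
    parts = name.split()
    return len(parts) >= 2 and not parts[1].rstrip(".").lower() in ("sp", "indet", "cf")


@dataclass(frozen=True)
class DiscoveryCurve:
    axis: str  # "publication_year" | "cumulative_occurrences" | "cumulative_references"
    points: tuple[tuple[float, float], ...]
    size_category: str | None = None
    time_bin: str | None = None
    standardized: bool = False
    q: float | None = None
    ci: tuple[tuple[float | None, float | None], ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["x", "y"])
        df.insert(0, "axis", self.axis)
        df.insert(0, "category", self.size_category)
        df.insert(0, "bin", self.time_bin)
        if self.ci:
            df["ci_low"] = [c[0] for c in self.ci]
            df["ci_high"] = [c[1] for c in self.ci]
        return df


def _ordered(records: Iterable[OccurrenceRecord]) -> list[OccurrenceRecord]:
    # stable intra-year order: publication year, then reference, then id
    return sorted(
        records, key=lambda r: (r.ref_pubyr, str(r.reference_id), str(r.occurrence_id))
    )


def _species_set(
    records: Iterable[OccurrenceRecord], year: int, index: OpinionIndex
) -> set[str]:
    out = set()
    for rec in records:
        name = identification_as_of_year(rec, year, index)
        if name is not None and _is_species_level(name):
            out.add(name)
    return out


def discovery_curve(
    records: Sequence[OccurrenceRecord],
    opinions: Iterable[OpinionEvent],
    axis: str = "publication_year",
    size_category: str | None = None,
    time_bin: str | None = None,
    years: tuple[int, int] = DEFAULT_WINDOW,
) -> DiscoveryCurve:
    """Cumulative distinct-species counts against a research-effort axis.

    Names are resolved as of each point's year, so synonymization can make
    the curve step down.
    """
    index = OpinionIndex(opinions)
    recs = _ordered(records)
    points: list[tuple[float, float]] = []
    if axis == "publication_year":
        for year in range(years[0], years[1] + 1):
            avail = [r for r in recs if r.ref_pubyr <= year]
            points.append((year, len(_species_set(avail, year, index))))
    elif axis == "cumulative_occurrences":
        for k, rec in enumerate(recs, start=1):
            species = _species_set(recs[:k], rec.ref_pubyr, index)
            points.append((k, len(species)))
    elif axis == "cumulative_references":
        seen_refs: set[str] = set()
        for k, rec in enumerate(recs, start=1):
            seen_refs.add(rec.reference_id)
            # one point per reference, emitted after its last record
            # (records of a reference are contiguous in the stable order)
            if k == len(recs) or recs[k].reference_id != rec.reference_id:
                species = _species_set(recs[:k], rec.ref_pubyr, index)
                points.append((len(seen_refs), len(species)))
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return DiscoveryCurve(
        axis=axis, points=tuple(points),
        size_category=size_category, time_bin=time_bin,
    )


def standardized_discovery_curve(
    records: Sequence[OccurrenceRecord],
    opinions: Iterable[OpinionEvent],
    q: float = 0.8,
    min_occurrences: int = 3,
    step: int = 1,
    axis: str = "publication_year",
    years: tuple[int, int] = DEFAULT_WINDOW,
    B: int = 0,
    seed: int | None = None,
    size_category: str | None = None,
    time_bin: str | None = None,
) -> DiscoveryCurve:
    """Coverage-standardized diversity recomputed at each step of research
    time from the occurrences available so far.

    Cells with fewer than ``min_occurrences`` occurrences emit no point
    (coverage estimation is too unstable there).
    """
    index = OpinionIndex(opinions)
    recs = _ordered(records)
    points: list[tuple[float, float]] = []
    cis: list[tuple[float | None, float | None]] = []

    def _emit(x: float, avail: Sequence[OccurrenceRecord], year: int):
        if len(avail) < min_occurrences:
            return
        pairs = []
        for rec in avail:
            name = identification_as_of_year(rec, year, index)
            if name is not None and _is_species_level(name):
                pairs.append((name, rec.collection_id))
        if not pairs:
            return
        table = IncidenceFrequencyTable.from_incidences(pairs)
        try:
            sd = diversity_at_quorum(table, q=q, B=B, seed=seed,
                                     min_incidences=min_occurrences)
        except NotViableError:
            return
        points.append((x, sd.D_q))
        cis.append((sd.ci_low, sd.ci_high))

    if axis == "publication_year":
        for year in range(years[0], years[1] + 1, step):
            avail = [r for r in recs if r.ref_pubyr <= year]
            _emit(year, avail, year)
    elif axis == "cumulative_occurrences":
        for k in range(step, len(recs) + 1, step):
            _emit(k, recs[:k], recs[k - 1].ref_pubyr)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return DiscoveryCurve(
        axis=axis, points=tuple(points), standardized=True, q=q,
        ci=tuple(cis), size_category=size_category, time_bin=time_bin,
    )


def moment_skewness(values: Sequence[float]) -> float | None:
    """Moment skewness g1 = m3 / m2^(3/2) with biased sample moments;
    ``None`` (a gap, never zero) when n < 3 or the variance vanishes."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or np.var(arr) == 0:
        return None
    return float(stats.skew(arr, bias=True))


def _discovered_species(
    records: Sequence[OccurrenceRecord], year: int, index: OpinionIndex,
    present_year: int,
) -> set[str]:
    """Species discovered by ``year`` under presently-accepted names."""
    out = set()
    for rec in records:
        if rec.ref_pubyr > year:
            continue
        name = identification_as_of_year(rec, year)
        if name is None:
            continue
        resolved = index.resolve(name, present_year)
        if _is_species_level(resolved):
            out.add(resolved)
    return out


def skew_trajectory(
    records: Sequence[OccurrenceRecord],
    opinions: Iterable[OpinionEvent],
    species_categories: Mapping[str, int],
    years: tuple[int, int] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Body-size-distribution skew of the species discovered by each year.

    Species lists use presently-accepted names so terminal values agree with
    the final body size distribution; category indices are the skewed
    variable (skewness is invariant to any affine recoding of categories).
    Years with undefined skew appear as NaN gaps.
    """
    index = OpinionIndex(opinions)
    recs = _ordered(records)
    present = years[1]
    rows = []
    for year in range(years[0], years[1] + 1):
        species = _discovered_species(recs, year, index, present)
        vals = [species_categories[s] for s in species if s in species_categories]
        g1 = moment_skewness(vals)
        rows.append((year, np.nan if g1 is None else g1, len(vals)))
    return pd.DataFrame(rows, columns=["year", "skew", "n_species"])


def median_mass_trajectory(
    records: Sequence[OccurrenceRecord],
    opinions: Iterable[OpinionEvent],
    species_masses: Mapping[str, float],
    years: tuple[int, int] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Median measured body mass (kg) of species discovered by each year;
    species lacking mass estimates are necessarily excluded."""
    index = OpinionIndex(opinions)
    recs = _ordered(records)
    present = years[1]
    rows = []
    for year in range(years[0], years[1] + 1):
        species = _discovered_species(recs, year, index, present)
        masses = [species_masses[s] for s in species if s in species_masses]
        med = float(np.median(masses)) if masses else np.nan
        rows.append((year, med, len(masses)))
    return pd.DataFrame(rows, columns=["year", "median_mass_kg", "n_species"])


def effort_proxies(
    records: Sequence[OccurrenceRecord],
    years: tuple[int, int] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Cumulative distinct collections, formations and references published
    by each year — proxies for collector effort and sampling-universe scope.
    Records without a formation are excluded from the formation count."""
    rows = []
    for year in range(years[0], years[1] + 1):
        avail = [r for r in records if r.ref_pubyr <= year]
        rows.append((
            year,
            len({r.collection_id for r in avail}),
            len({r.formation for r in avail if r.formation is not None}),
            len({r.reference_id for r in avail}),
        ))
    return pd.DataFrame(
        rows, columns=["year", "collections", "formations", "references"]
    )


def read_opinions(path) -> list[OpinionEvent]:
    df = pd.read_csv(path)
    return [
        OpinionEvent(
            kind=row.kind, year=int(row.year),
            from_name=row.from_name, to_name=row.to_name,
        )
        for row in df.itertuples(index=False)
    ]
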