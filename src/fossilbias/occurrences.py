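"""Reading, validation, filtering and time-binning of fossil occurrence tables.

Input tables follow the Paleobiology Database (PBDB) download dialect by
default (``identified_name``, ``max_ma``, ``min_ma``, ``lat``, ``lng``,
``collection_no``, ``reference_no``, ``ref_pubyr`` ...); a column-mapping
dict supports other dialects.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "TimeBin",
    "SchemaError",
    "RowValidationError",
    "read_occurrences",
    "filter_occurrences",
    "assign_time_bins",
    "default_time_bins",
    "DEFAULT_EXCLUDED_CLADES",
]

#: Clades removed by default to restrict the dataset to terrestrial mammals.
DEFAULT_EXCLUDED_CLADES = (
    "Chiroptera",
    "Cetacea",
    "Sirenia",
    "Pinnipedimorpha",
    "Desmostylia",
)

_CURRENT_YEAR = datetime.date.today().year


class SchemaError(ValueError):
    """The input table is missing required columns."""


class RowValidationError(ValueError):
    """A row violates a record-level invariant; carries the offending id."""

    def __init__(self, occurrence_id: str, message: str):
        self.occurrence_id = occurrence_id
        super().__init__(f"occurrence {occurrence_id!r}: {message}")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One reported fossil occurrence with its identification history.

    ``identification_events`` is an ascending list of ``(year, binomial)``
    pairs; the first entry is the original publication (year equal to
    ``ref_pubyr``), later entries are museum/literature re-identifications.
    """

    occurrence_id: str
    identified_name: str
    clade_path: tuple[str, ...]
    max_ma: float
    min_ma: float
    lat: float | None
    lon: float | None
    collection_id: str
    reference_id: str
    ref_pubyr: int
    formation: str | None = None
    geo_scale: str = "site"
    strat_scale: str = "bed"
    is_trace: bool = False
    identification_events: tuple[tuple[int, str], ...] = field(default=())

    def __post_init__(self):
        if not self.max_ma >= self.min_ma >= 0:
            raise RowValidationError(
                self.occurrence_id,
                f"require max_ma >= min_ma >= 0, got [{self.max_ma}, {self.min_ma}]",
            )
        if not (1700 <= self.ref_pubyr <= _CURRENT_YEAR):
            raise RowValidationError(
                self.occurrence_id, f"implausible ref_pubyr {self.ref_pubyr}"
            )
        if not self.identification_events:
            object.__setattr__(
                self,
                "identification_events",
                ((self.ref_pubyr, self.identified_name),),
            )
        events = self.identification_events
        if list(events) != sorted(events, key=lambda e: e[0]):
            raise RowValidationError(
                self.occurrence_id, "identification_events not ascending by year"
            )

    @property
    def duration(self) -> float:
        return self.max_ma - self.min_ma

    @property
    def has_coordinates(self) -> bool:
        return self.lat is not None and self.lon is not None


@dataclass(frozen=True)
class TimeBin:
    """A geological time bin, older boundary first (Ma)."""

    name: str
    start_ma: float
    end_ma: float

    def __post_init__(self):
        if not self.start_ma > self.end_ma:
            raise ValueError(f"bin {self.name}: start_ma must exceed end_ma")

    def overlap_fraction(self, max_ma: float, min_ma: float) -> float:
        """Fraction of [min_ma, max_ma] falling inside this bin.

        Zero-duration occurrences return 1.0 when the point lies inside the
        bin; a point on a boundary belongs to the older bin (the bin whose
        end_ma equals the point).
        """
        if max_ma == min_ma:
            # Point ages use half-open [start_ma, end_ma) membership, so a
            # boundary point belongs to the older of the two bins it touches.
            return 1.0 if self.end_ma <= max_ma < self.start_ma else 0.0
        lo = max(min_ma, self.end_ma)
        hi = min(max_ma, self.start_ma)
        return max(0.0, hi - lo) / (max_ma - min_ma)


DEFAULT_COLUMNS: Mapping[str, str] = {
    "occurrence_id": "occurrence_no",
    "identified_name": "identified_name",
    "clade_path": "clade_path",
    "max_ma": "max_ma",
    "min_ma": "min_ma",
    "lat": "lat",
    "lon": "lng",
    "collection_id": "collection_no",
    "formation": "formation",
    "reference_id": "reference_no",
    "ref_pubyr": "ref_pubyr",
    "geo_scale": "geogscale",
    "strat_scale": "stratscale",
    "is_trace": "is_trace",
    "reid_events": "reid_events",
}

_REQUIRED = (
    "occurrence_id",
    "identified_name",
    "max_ma",
    "min_ma",
    "collection_id",
    "reference_id",
    "ref_pubyr",
)


def _parse_reid_events(cell: str) -> tuple[tuple[int, str], ...]:
    # "1990:Canis latrans;2001:Canis lepophagus"
    out = []
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        year, name = part.split(":", 1)
        out.append((int(year), name.strip()))
    return tuple(out)


def read_occurrences(
    path,
    columns: Mapping[str, str] | None = None,
) -> list[OccurrenceRecord]:
    """Parse a PBDB-style occurrence CSV into validated records.

    Missing coordinates stay missing (``None``), never 0.  Rows violating
    record invariants raise :class:`RowValidationError` naming the row.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [cols[k] for k in _REQUIRED if cols[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    def _get(row, key, default=""):
        col = cols[key]
        return row[col] if col in df.columns else default

    records = []
    for _, row in df.iterrows():
        occ_id = str(_get(row, "occurrence_id"))
        try:
            max_ma = float(_get(row, "max_ma"))
            min_ma = float(_get(row, "min_ma"))
        except ValueError as exc:
            raise RowValidationError(occ_id, f"unparseable age: {exc}") from exc
        try:
            pubyr = int(float(_get(row, "ref_pubyr")))
        except ValueError as exc:
            raise RowValidationError(occ_id, f"unparseable ref_pubyr: {exc}") from exc

        lat_s, lon_s = _get(row, "lat"), _get(row, "lon")
        lat = float(lat_s) if lat_s.strip() else None
        lon = float(lon_s) if lon_s.strip() else None
        clade_raw = _get(row, "clade_path")
        clade_path = tuple(p.strip() for p in clade_raw.split("|") if p.strip())
        name = str(_get(row, "identified_name")).strip()
        events = ((pubyr, name),) + _parse_reid_events(_get(row, "reid_events"))
        records.append(
            OccurrenceRecord(
                occurrence_id=occ_id,
                identified_name=name,
                clade_path=clade_path,
                max_ma=max_ma,
                min_ma=min_ma,
                lat=lat,
                lon=lon,
                collection_id=str(_get(row, "collection_id")),
                formation=(_get(row, "formation").strip() or None),
                reference_id=str(_get(row, "reference_id")),
                ref_pubyr=pubyr,
                geo_scale=(_get(row, "geo_scale").strip() or "site"),
                strat_scale=(_get(row, "strat_scale").strip() or "bed"),
                is_trace=str(_get(row, "is_trace")).strip().lower()
                in ("1", "true", "yes"),
                identification_events=events,
            )
        )
    return records


def filter_occurrences(
    records: Iterable[OccurrenceRecord],
    excluded_clades: Sequence[str] = DEFAULT_EXCLUDED_CLADES,
    drop_trace: bool = True,
) -> tuple[list[OccurrenceRecord], dict[str, int]]:
    """Apply the standard terrestrial-mammal cleaning rules.

    Removes trace fossils, occurrences resolved only to a 'basin' geographic
    scale or 'group' stratigraphic scale, occurrences lacking coordinates,
    and members of the excluded clades (exact name match within the clade
    path).  Rules are checked in that order and each record is logged under
    the first rule it trips, so kept + removed counts conserve the input.
    """
    excluded = set(excluded_clades)
    log = {
        "trace": 0,
        "geo_scale_basin": 0,
        "strat_scale_group": 0,
        "no_coordinates": 0,
        "excluded_clade": 0,
    }
    kept: list[OccurrenceRecord] = []
    for rec in records:
        if drop_trace and rec.is_trace:
            log["trace"] += 1
        elif rec.geo_scale == "basin":
            log["geo_scale_basin"] += 1
        elif rec.strat_scale == "group":
            log["strat_scale_group"] += 1
        elif not rec.has_coordinates:
            log["no_coordinates"] += 1
        elif excluded.intersection(rec.clade_path):
            log["excluded_clade"] += 1
        else:
            kept.append(rec)
    return kept, log


def assign_time_bins(
    records: Iterable[OccurrenceRecord],
    bins: Sequence[TimeBin],
) -> dict[str, str | None]:
    """Majority-rule binning: an occurrence joins the unique bin holding
    strictly more than 50% of its age range, else it is dropped (``None``).

    Zero-duration (point-aged) occurrences go to the containing bin, with
    boundary points assigned to the older bin.
    """
    ordered = sorted(bins, key=lambda b: -b.start_ma)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_ma > a.end_ma:
            raise ValueError(f"overlapping bins: {a.name} and {b.name}")
    out: dict[str, str | None] = {}
    for rec in records:
        assigned = None
        for tb in ordered:
            frac = tb.overlap_fraction(rec.max_ma, rec.min_ma)
            if frac > 0.5:
                assigned = tb.name
                break
        out[rec.occurrence_id] = assigned
    return out


def default_time_bins(n_bins: int = 4, oldest_ma: float = 66.0) -> list[TimeBin]:
    """Equal-length Cenozoic bins, oldest first (a configurable stand-in for
    a stage-aggregated bin table)."""
    width = oldest_ma / n_bins
    return [
        TimeBin(name=f"B{i}", start_ma=oldest_ma - i * width,
                end_ma=oldest_ma - (i + 1) * width)
        for i in range(n_bins)
    ]
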