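"""Sampled-area proxy: summed minimum-spanning-tree length over occurrence
coordinates, tracked through research time."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .occurrences import OccurrenceRecord

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_distance",
    "dedupe_coordinates",
    "mst_length",
    "spatial_trajectory",
]

EARTH_RADIUS_KM = 6371.0


def _check(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"invalid coordinates ({lat}, {lon})")


def great_circle_distance(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Haversine distance in km on a sphere of radius 6371 km."""
    _check(*p1)
    _check(*p2)
    lat1, lon1, lat2, lon2 = map(np.radians, (*p1, *p2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def dedupe_coordinates(
    points: Iterable[tuple[float, float]], tol: float = 1e-4
) -> list[tuple[float, float]]:
    """Collapse points identical to within ``tol`` degrees (grid rounding)."""
    seen = set()
    out = []
    for lat, lon in points:
        _check(lat, lon)
        key = (round(lat / tol), round(lon / tol))
        if key not in seen:
            seen.add(key)
            out.append((lat, lon))
    return out


def _distance_matrix(points: Sequence[tuple[float, float]]) -> np.ndarray:
    pts = np.radians(np.asarray(points, dtype=float))
    lat = pts[:, 0][:, None]
    lon = pts[:, 1][:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def mst_length(
    points: Sequence[tuple[float, float]], dedupe_tol: float = 1e-4
) -> float:
    """Total great-circle edge length (km) of a minimum spanning tree over
    the deduplicated point set; 0 for a single point."""
    pts = dedupe_coordinates(points, tol=dedupe_tol)
    if not pts:
        raise ValueError("empty coordinate set")
    if len(pts) == 1:
        return 0.0
    dist = _distance_matrix(pts)
    # scipy treats zero weights as absent edges; keep coincident-on-sphere
    # pairs connected with a negligible positive weight
    dist[dist == 0.0] = 1e-12
    np.fill_diagonal(dist, 0.0)
    tree = minimum_spanning_tree(dist)
    return float(tree.sum())


def spatial_trajectory(
    records: Sequence[OccurrenceRecord],
    years: tuple[int, int] = (1840, 2024),
    dedupe_tol: float = 1e-4,
) -> pd.DataFrame:
    """Cumulative MST length over the unique collection coordinates
    published by each year."""
    coords_by_year: dict[int, list[tuple[float, float]]] = {}
    seen_collections = set()
    for rec in sorted(records, key=lambda r: r.ref_pubyr):
        if not rec.has_coordinates or rec.collection_id in seen_collections:
            continue
        seen_collections.add(rec.collection_id)
        coords_by_year.setdefault(rec.ref_pubyr, []).append((rec.lat, rec.lon))
    rows = []
    acc: list[tuple[float, float]] = []
    for year in range(years[0], years[1] + 1):
        acc.extend(coords_by_year.get(year, ()))
        length = mst_length(acc, dedupe_tol) if acc else 0.0
        rows.append((year, length))
    return pd.DataFrame(rows, columns=["year", "mst_km"])
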