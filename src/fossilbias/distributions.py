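"""Body size distributions per time bin: face-value and coverage-standardized
histograms, skew, and mode geometry.

A body size distribution is the histogram of species richness across ordered
(logarithmic) mass categories.  Its two key geometric descriptors here are
moment skewness and modality — the position of the primary (small-size) mode
and the relative height of any accessory mode at larger size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import (
    IncidenceFrequencyTable,
    NotViableError,
    diversity_at_quorum,
)
from .mass import ORDER_OF_MAGNITUDE, SizeCategoryScheme, SpeciesMassRecord

__all__ = [
    "BodySizeDistribution",
    "build_distribution",
    "standardized_distribution",
    "distribution_skew",
    "weighted_skewness",
    "mode_stats",
    "ModeStats",
]


@dataclass(frozen=True)
class BodySizeDistribution:
    """Species counts (or standardized diversity estimates) per ordered
    mass category for one time bin."""

    bin: str | None
    scheme: SizeCategoryScheme
    counts: tuple[float, ...]
    provenance: str  # "face_value" | "standardized"
    ci_low: tuple[float, ...] | None = None
    ci_high: tuple[float, ...] | None = None
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if len(self.counts) != self.scheme.n_categories:
            raise ValueError("one count per scheme category required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin": self.bin,
                "category": self.scheme.labels,
                "count": self.counts,
                "provenance": self.provenance,
            }
        )
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        return df


def build_distribution(
    species_records: Iterable[SpeciesMassRecord],
    scheme: SizeCategoryScheme = ORDER_OF_MAGNITUDE,
    bin_name: str | None = None,
) -> BodySizeDistribution:
    """Face-value histogram: each categorized species counted once."""
    counts = np.zeros(scheme.n_categories)
    label_ix = {lab: i for i, lab in enumerate(scheme.labels)}
    seen = set()
    for rec in species_records:
        if rec.species in seen:
            continue
        seen.add(rec.species)
        counts[label_ix[rec.category]] += 1
    return BodySizeDistribution(
        bin=bin_name, scheme=scheme, counts=tuple(counts),
        provenance="face_value",
    )


def standardized_distribution(
    incidence_pairs_by_category: Mapping[str, Sequence[tuple[str, str]]],
    scheme: SizeCategoryScheme = ORDER_OF_MAGNITUDE,
    bin_name: str | None = None,
    q: float = 0.8,
    B: int = 0,
    seed: int | None = None,
    min_occurrences: int = 3,
) -> BodySizeDistribution:
    """Coverage-standardized histogram: per-category diversity at quorum q.

    ``incidence_pairs_by_category`` maps a category label to its
    (species, collection) incidence pairs.  Categories below the viability
    threshold are reported as zero and flagged ``not_viable:<label>``;
    extrapolations beyond twice the reference effort are flagged
    ``beyond_double_reference:<label>``.
    """
    counts, lo, hi, flags = [], [], [], []
    for label in scheme.labels:
        pairs = incidence_pairs_by_category.get(label, ())
        if not pairs:
            counts.append(0.0); lo.append(0.0); hi.append(0.0)
            continue
        table = IncidenceFrequencyTable.from_incidences(pairs)
        try:
            sd = diversity_at_quorum(table, q=q, B=B, seed=seed,
                                     min_incidences=min_occurrences)
        except NotViableError:
            counts.append(0.0); lo.append(0.0); hi.append(0.0)
            flags.append(f"not_viable:{label}")
            continue
        counts.append(sd.D_q)
        lo.append(sd.ci_low if sd.ci_low is not None else sd.D_q)
        hi.append(sd.ci_high if sd.ci_high is not None else sd.D_q)
        if sd.beyond_double_reference:
            flags.append(f"beyond_double_reference:{label}")
    return BodySizeDistribution(
        bin=bin_name, scheme=scheme, counts=tuple(counts),
        provenance="standardized", ci_low=tuple(lo), ci_high=tuple(hi),
        flags=tuple(flags),
    )


def weighted_skewness(values: Sequence[float], weights: Sequence[float]) -> float | None:
    """Frequency-weighted moment skewness g1 = m3 / m2^(3/2).

    Weights may be non-integer (standardized diversity estimates); with
    integer weights this equals g1 of the expanded per-species vector.
    ``None`` when total weight < 3 or the variance vanishes.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = w.sum()
    if n < 3:
        return None
    mean = (w * v).sum() / n
    m2 = (w * (v - mean) ** 2).sum() / n
    if m2 == 0:
        return None
    m3 = (w * (v - mean) ** 3).sum() / n
    return float(m3 / m2 ** 1.5)


def distribution_skew(dist: BodySizeDistribution) -> float | None:
    """Moment skewness of the distribution over category indices.

    Affine-invariant in the category coding, so indices and log-midpoints
    give identical values.
    """
    values = np.arange(dist.scheme.n_categories, dtype=float)
    return weighted_skewness(values, dist.counts)


@dataclass(frozen=True)
class ModeStats:
    primary_index: int | None
    accessory_index: int | None
    accessory_to_primary_ratio: float | None


def mode_stats(
    dist: BodySizeDistribution,
    split_index: int | None = None,
) -> ModeStats:
    """Locate the primary (small-size) and accessory (large-size) modes.

    A mode is a category whose count strictly exceeds both neighbours (end
    categories compare to their single neighbour); a plateau collapses to
    its first category.  The primary mode is the highest-count mode at or
    below ``split_index`` (default: the 1-10 kg decade for the
    order-of-magnitude scheme, else the middle category); the accessory is
    the highest-count mode above it.  The ratio is accessory/primary count.
    """
    counts = list(dist.counts)
    k = len(counts)
    if k == 0 or len(set(counts)) == 1:
        return ModeStats(None, None, None)
    if split_index is None:
        try:
            split_index = dist.scheme.labels.index("1-10")
        except ValueError:
            split_index = (k - 1) // 2

    modes = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and counts[j + 1] == counts[i]:
            j += 1  # plateau [i, j]
        left_ok = i == 0 or counts[i - 1] < counts[i]
        right_ok = j == k - 1 or counts[j + 1] < counts[i]
        if left_ok and right_ok and counts[i] > 0:
            modes.append(i)  # plateau collapses to its first category
        i = j + 1

    small = [m for m in modes if m <= split_index]
    large = [m for m in modes if m > split_index]
    primary = max(small, key=lambda m: counts[m]) if small else None
    accessory = max(large, key=lambda m: counts[m]) if large else None
    if primary is None and accessory is not None:
        # no mode at small size: the accessory-side mode is the primary
        primary, accessory = accessory, None
    ratio = (
        counts[accessory] / counts[primary]
        if primary is not None and accessory is not None and counts[primary] > 0
        else None
    )
    return ModeStats(primary, accessory, ratio)
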