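"""Synthetic fossil-record generator with known ground truth.

Emulates the statistical structure of a continental fossil-mammal occurrence
database so that every pipeline stage can be exercised against a known
answer:

* a true species pool drawn from a positively skewed lognormal mixture of
  body masses (a dominant small-size mode plus a lower accessory mode at
  large size);
* per-collection detection probability increasing with body mass (a
  logistic taphonomic/collector filter), with an additional penalty on
  small taxa before a configurable "screen-washing" adoption year;
* a research-time collection process (collections per year ramping up
  through the publication window), references grouping occurrences by
  (year, formation);
* taxonomic churn: some species are first published under oversplit junior
  synonyms that are later synonymized back, and some are recombined into a
  different genus — both emitted as dated opinion events so replay can be
  verified against truth.

All output tables are directly consumable by the occurrence reader and the
research-time analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .mass import ORDER_OF_MAGNITUDE, SizeCategoryScheme
from .occurrences import TimeBin, default_time_bins
from .research_time import OpinionEvent, moment_skewness

__all__ = [
    "SyntheticWorldConfig",
    "SpeciesTruth",
    "SyntheticTruth",
    "GroundTruthReport",
    "simulate_species_pool",
    "simulate_fossil_record",
    "simulate_world",
    "ground_truth_report",
    "write_world",
]


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Full parameterization of the generative fossil-record model.

    Mass mixture components are (weight, mean log10 kg, sd log10 kg).
    Detection probability per eligible species per collection is
    ``base * expit(slope * (log10 mass - midpoint)) * occupancy``, times
    ``small_penalty`` for sub-``small_cutoff_kg`` taxa in years before
    ``screenwash_year``.
    """

    n_species: int = 500
    mixture: tuple[tuple[float, float, float], ...] = (
        (0.88, -0.8, 0.55),
        (0.12, 1.9, 0.45),
    )
    # taphonomic / collector detection filter
    detection_base: float = 0.15
    detection_slope: float = 1.8
    detection_midpoint_log10kg: float = 0.0
    occupancy_alpha: float = 0.8
    occupancy_beta: float = 3.0
    # research-time regime shift
    screenwash_year: int = 1940
    small_penalty: float = 0.12
    small_cutoff_kg: float = 1.0
    # effort curve: collections per year, linear ramp across the window
    years: tuple[int, int] = (1840, 2024)
    collections_per_year_start: float = 2.0
    collections_per_year_end: float = 8.0
    # geological scaffold
    n_bins: int = 4
    oldest_ma: float = 66.0
    n_formations: int = 12
    lat_range: tuple[float, float] = (25.0, 55.0)
    lon_range: tuple[float, float] = (-125.0, -70.0)
    collection_scatter_deg: float = 1.5
    # taxonomic churn
    p_oversplit: float = 0.15
    p_recombination: float = 0.10
    synonymy_delay_mean: float = 30.0
    alias_intro_years: tuple[int, int] = (1860, 1960)
    recombination_years: tuple[int, int] = (1880, 2000)
    # measurement emission for the mass stage
    frac_measured: float = 0.85
    measurement_noise_sd_log10: float = 0.05
    # fractions of records carrying filter-rule defects
    frac_trace: float = 0.02
    frac_basin_scale: float = 0.02
    frac_group_scale: float = 0.02
    frac_missing_coords: float = 0.02
    # taxonomy scaffold
    n_orders: int = 6
    families_per_order: int = 3
    genera_per_family: int = 4
    seed: int = 0

    def __post_init__(self):
        w = sum(c[0] for c in self.mixture)
        if not math.isclose(w, 1.0, rel_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if any(c[2] < 0 for c in self.mixture):
            raise ValueError("mixture sds must be non-negative")
        for p in (self.detection_base, self.small_penalty,
                  self.p_oversplit, self.p_recombination):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def time_bins(self) -> list[TimeBin]:
        return default_time_bins(self.n_bins, self.oldest_ma)


@dataclass(frozen=True)
class SpeciesTruth:
    name: str
    clade_path: tuple[str, ...]
    mass_kg: float
    category: str
    time_bin: str
    occupancy: float
    component: int
    alias: str | None = None           # junior synonym, if oversplit
    alias_intro_year: int | None = None
    synonymized_year: int | None = None
    recombined_name: str | None = None
    recombination_year: int | None = None

    def published_name(self, year: int) -> str:
        """The name under which a new occurrence is published in ``year``."""
        if (
            self.alias is not None
            and self.alias_intro_year <= year < self.synonymized_year
        ):
            return self.alias
        if (
            self.recombined_name is not None
            and year >= self.recombination_year
        ):
            return self.recombined_name
        return self.name

    def current_name(self) -> str:
        """The presently valid name."""
        return self.recombined_name or self.name


@dataclass(frozen=True)
class SyntheticTruth:
    config: SyntheticWorldConfig
    species: tuple[SpeciesTruth, ...]
    opinions: tuple[OpinionEvent, ...]

    @property
    def taxonomy(self) -> dict[str, tuple[str, ...]]:
        tax = {}
        for sp in self.species:
            tax[sp.name] = sp.clade_path
            if sp.recombined_name:
                tax[sp.recombined_name] = sp.clade_path
        return tax


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_species_pool(
    config: SyntheticWorldConfig, seed: int | None = None
) -> SyntheticTruth:
    """Draw the true species pool: masses from the lognormal mixture, a
    random taxonomic scaffold, per-species occupancy, and the churn events
    (junior synonyms and recombinations with their opinion records)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_species
    weights = np.array([c[0] for c in config.mixture])
    comp = rng.choice(len(config.mixture), size=n, p=weights)
    means = np.array([c[1] for c in config.mixture])[comp]
    sds = np.array([c[2] for c in config.mixture])[comp]
    log10_mass = rng.normal(means, sds)
    occupancy = rng.beta(config.occupancy_alpha, config.occupancy_beta, size=n)
    bins = config.time_bins()
    bin_ix = rng.integers(0, len(bins), size=n)

    orders = rng.integers(0, config.n_orders, size=n)
    families = rng.integers(0, config.families_per_order, size=n)
    genera = rng.integers(0, config.genera_per_family, size=n)

    species: list[SpeciesTruth] = []
    opinions: list[OpinionEvent] = []
    y0, y1 = config.years
    for i in range(n):
        order = f"Order{orders[i]}"
        family = f"Family{orders[i]}_{families[i]}"
        genus = f"Genus{orders[i]}_{families[i]}_{genera[i]}"
        name = f"{genus} species{i}"
        mass = float(10.0 ** log10_mass[i])

        recombined_name = None
        recomb_year = None
        if rng.random() < config.p_recombination:
            recomb_year = int(rng.integers(*config.recombination_years))
            recombined_name = f"{genus}oides species{i}"
            opinions.append(OpinionEvent(
                "recombination", recomb_year, name, recombined_name,
            ))

        alias = alias_intro = syn_year = None
        if rng.random() < config.p_oversplit:
            alias_intro = int(rng.integers(*config.alias_intro_years))
            delay = 1 + int(rng.exponential(config.synonymy_delay_mean))
            syn_year = min(alias_intro + delay, y1 - 9)
            if syn_year > alias_intro:
                alias = f"{genus} species{i}b"
                # the synonymization targets the name valid in that year
                target = (
                    recombined_name
                    if recombined_name is not None and syn_year >= recomb_year
                    else name
                )
                opinions.append(OpinionEvent(
                    "synonymization", syn_year, alias, target,
                ))
            else:
                alias_intro = syn_year = None

        species.append(SpeciesTruth(
            name=name,
            clade_path=("Mammalia", order, family, genus),
            mass_kg=mass,
            category=ORDER_OF_MAGNITUDE.category(mass),
            time_bin=bins[bin_ix[i]].name,
            occupancy=float(occupancy[i]),
            component=int(comp[i]),
            alias=alias,
            alias_intro_year=alias_intro,
            synonymized_year=syn_year,
            recombined_name=recombined_name,
            recombination_year=recomb_year,
        ))
    return SyntheticTruth(
        config=config, species=tuple(species), opinions=tuple(opinions)
    )


def _detection_prob(
    truth: SyntheticTruth, year: int
) -> np.ndarray:
    cfg = truth.config
    mass = np.array([sp.mass_kg for sp in truth.species])
    occ = np.array([sp.occupancy for sp in truth.species])
    x = np.log10(mass) - cfg.detection_midpoint_log10kg
    p = cfg.detection_base * _logistic(cfg.detection_slope * x) * occ
    if year < cfg.screenwash_year:
        p = np.where(mass < cfg.small_cutoff_kg, p * cfg.small_penalty, p)
    return p


def simulate_fossil_record(
    truth: SyntheticTruth, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Run the research-time collection process over the publication window.

    Returns a dict of tables: ``occurrences`` (PBDB-dialect columns plus a
    ``true_species`` ground-truth column), ``opinions``, ``references``,
    ``truth``, ``measurements`` and ``registry``.
    """
    cfg = truth.config
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 1])
    )
    bins = {b.name: b for b in cfg.time_bins()}
    bin_names = list(bins)

    # formations: each belongs to one bin and anchors a geographic center
    formations = []
    for f in range(cfg.n_formations):
        formations.append({
            "name": f"Fm{f}",
            "bin": bin_names[f % len(bin_names)],
            "lat": rng.uniform(*cfg.lat_range),
            "lon": rng.uniform(*cfg.lon_range),
        })
    by_bin: dict[str, list[dict]] = {}
    for fm in formations:
        by_bin.setdefault(fm["bin"], []).append(fm)

    species_by_bin: dict[str, np.ndarray] = {
        b: np.array([i for i, sp in enumerate(truth.species) if sp.time_bin == b])
        for b in bin_names
    }

    y0, y1 = cfg.years
    n_years = y1 - y0 + 1
    effort = np.linspace(
        cfg.collections_per_year_start, cfg.collections_per_year_end, n_years
    )

    rows = []
    occ_no = 0
    coll_no = 0
    for yi, year in enumerate(range(y0, y1 + 1)):
        n_coll = int(round(effort[yi]))
        p_all = _detection_prob(truth, year)
        for _ in range(n_coll):
            coll_no += 1
            bin_name = bin_names[int(rng.integers(len(bin_names)))]
            eligible = species_by_bin[bin_name]
            if eligible.size == 0:
                continue
            fm = by_bin[bin_name][int(rng.integers(len(by_bin[bin_name])))]
            lat = float(np.clip(
                rng.normal(fm["lat"], cfg.collection_scatter_deg), -90, 90))
            lon = float(np.clip(
                rng.normal(fm["lon"], cfg.collection_scatter_deg), -180, 180))
            tb = bins[bin_name]
            width = tb.start_ma - tb.end_ma
            center = rng.uniform(tb.end_ma, tb.start_ma)
            half = rng.uniform(0.05, 0.45) * width
            max_ma = min(center + half, cfg.oldest_ma)
            min_ma = max(center - half, 0.0)
            detected = eligible[rng.random(eligible.size) < p_all[eligible]]
            for i in detected:
                sp = truth.species[i]
                occ_no += 1
                u = rng.random()
                trace = u < cfg.frac_trace
                basin = cfg.frac_trace <= u < cfg.frac_trace + cfg.frac_basin_scale
                group = (
                    cfg.frac_trace + cfg.frac_basin_scale
                    <= u
                    < cfg.frac_trace + cfg.frac_basin_scale + cfg.frac_group_scale
                )
                nocoord = (
                    cfg.frac_trace + cfg.frac_basin_scale + cfg.frac_group_scale
                    <= u
                    < cfg.frac_trace + cfg.frac_basin_scale
                    + cfg.frac_group_scale + cfg.frac_missing_coords
                )
                rows.append({
                    "occurrence_no": f"O{occ_no}",
                    "identified_name": sp.published_name(year),
                    "clade_path": "|".join(sp.clade_path),
                    "max_ma": round(max_ma, 4),
                    "min_ma": round(min_ma, 4),
                    "lat": "" if nocoord else round(lat, 4),
                    "lng": "" if nocoord else round(lon, 4),
                    "collection_no": f"C{coll_no}",
                    "formation": fm["name"],
                    "reference_no": f"R{year}_{fm['name']}",
                    "ref_pubyr": year,
                    "geogscale": "basin" if basin else "site",
                    "stratscale": "group" if group else "bed",
                    "is_trace": "true" if trace else "false",
                    "true_species": sp.current_name(),
                    "time_bin_true": bin_name,
                })

    occurrences = pd.DataFrame(rows)
    opinions = pd.DataFrame(
        [
            {"kind": o.kind, "year": o.year,
             "from_name": o.from_name, "to_name": o.to_name}
            for o in truth.opinions
        ],
        columns=["kind", "year", "from_name", "to_name"],
    )
    references = (
        occurrences.groupby("reference_no")
        .agg(pubyr=("ref_pubyr", "first"), formation=("formation", "first"),
             n_occurrences=("occurrence_no", "size"))
        .reset_index()
        if len(occurrences)
        else pd.DataFrame(columns=["reference_no", "pubyr", "formation",
                                   "n_occurrences"])
    )

    truth_df = pd.DataFrame([
        {
            "species": sp.current_name(),
            "original_name": sp.name,
            "clade_path": "|".join(sp.clade_path),
            "mass_kg": sp.mass_kg,
            "category": sp.category,
            "time_bin": sp.time_bin,
            "occupancy": sp.occupancy,
        }
        for sp in truth.species
    ])

    registry = pd.DataFrame([
        {"clade_scope": "Mammalia", "proxy": "m1_area", "slope": 1.5,
         "intercept": 2.0, "x_units": "mm2", "mass_units": "g", "priority": 9},
        {"clade_scope": "Order0", "proxy": "m1_area", "slope": 1.6,
         "intercept": 1.9, "x_units": "mm2", "mass_units": "g", "priority": 1},
    ])
    meas_rows = []
    for sp in truth.species:
        if rng.random() >= cfg.frac_measured:
            continue
        reg = registry.iloc[1] if sp.clade_path[1] == "Order0" else registry.iloc[0]
        log10_g = math.log10(sp.mass_kg * 1000.0)
        noise = rng.normal(0.0, cfg.measurement_noise_sd_log10)
        log10_x = (log10_g + noise - reg["intercept"]) / reg["slope"]
        meas_rows.append({
            "species": sp.current_name(),
            "proxy": "m1_area",
            "value": 10.0 ** log10_x,
            "units": "mm2",
        })
    measurements = pd.DataFrame(
        meas_rows, columns=["species", "proxy", "value", "units"]
    )

    return {
        "occurrences": occurrences,
        "opinions": opinions,
        "references": references,
        "truth": truth_df,
        "measurements": measurements,
        "registry": registry,
    }


def simulate_world(
    config: SyntheticWorldConfig, seed: int | None = None
) -> tuple[SyntheticTruth, dict[str, pd.DataFrame]]:
    truth = simulate_species_pool(config, seed=seed)
    return truth, simulate_fossil_record(truth, seed=seed)


@dataclass(frozen=True)
class GroundTruthReport:
    counts: dict[str, int]
    skew: float | None
    median_mass_kg: float
    n_species: int


def ground_truth_report(
    truth: SyntheticTruth, scheme: SizeCategoryScheme = ORDER_OF_MAGNITUDE
) -> GroundTruthReport:
    """Exact tabulation of the true pool: the recovery target for the
    pipeline."""
    counts = {label: 0 for label in scheme.labels}
    indices = []
    masses = []
    for sp in truth.species:
        label = scheme.category(sp.mass_kg)
        counts[label] += 1
        indices.append(scheme.labels.index(label))
        masses.append(sp.mass_kg)
    return GroundTruthReport(
        counts=counts,
        skew=moment_skewness(indices),
        median_mass_kg=float(np.median(masses)),
        n_species=len(truth.species),
    )


def write_world(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
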