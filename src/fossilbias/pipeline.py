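"""End-to-end orchestration: filter -> bin -> mass -> distributions ->
coverage -> research-time analyses, as a configured, logged, reproducible
run writing tidy CSV outputs plus a manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
import pandas as pd

from . import __version__
from .coverage import IncidenceFrequencyTable, goods_u
from .distributions import (
    build_distribution,
    distribution_skew,
    mode_stats,
    standardized_distribution,
)
from .mass import (
    ORDER_OF_MAGNITUDE,
    SIMPLE,
    estimate_species_masses,
    read_measurements,
    read_registry,
)
from .occurrences import (
    DEFAULT_EXCLUDED_CLADES,
    TimeBin,
    assign_time_bins,
    default_time_bins,
    filter_occurrences,
    read_occurrences,
)
from .research_time import (
    DEFAULT_WINDOW,
    OpinionIndex,
    effort_proxies,
    median_mass_trajectory,
    read_opinions,
    skew_trajectory,
)
from .spatial import spatial_trajectory

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class RunConfig:
    occurrences: str
    out_dir: str
    opinions: str | None = None
    registry: str | None = None
    measurements: str | None = None
    bins: tuple[TimeBin, ...] = tuple(default_time_bins())
    scheme: str = "order_of_magnitude"
    quorum: float = 0.8
    window: tuple[int, int] = DEFAULT_WINDOW
    bootstrap_B: int = 200
    seed: int = 0
    excluded_clades: tuple[str, ...] = DEFAULT_EXCLUDED_CLADES

    def __post_init__(self):
        if not 0.0 < self.quorum < 1.0:
            raise ValueError("quorum must lie in (0, 1)")
        if self.window[0] >= self.window[1]:
            raise ValueError("research window start must precede end")

    def hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _scheme(config: RunConfig):
    return {"order_of_magnitude": ORDER_OF_MAGNITUDE, "simple": SIMPLE}[config.scheme]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write outputs under ``config.out_dir``.

    Returns the manifest: config hash, seed, package version and per-stage
    record counts (input = kept + removed at every reduction)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = _scheme(config)
    manifest: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    try:
        records = read_occurrences(config.occurrences)
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc
    manifest["stages"]["read"] = {"records": len(records)}

    kept, removal_log = filter_occurrences(records, config.excluded_clades)
    manifest["stages"]["filter"] = {
        "kept": len(kept), "removed": removal_log,
    }
    pd.DataFrame(
        [{"rule": k, "count": v} for k, v in removal_log.items()]
    ).to_csv(out / "removal_log.csv", index=False)

    bin_map = assign_time_bins(kept, config.bins)
    pd.DataFrame(
        [{"occurrence_id": k, "bin": v} for k, v in bin_map.items()]
    ).to_csv(out / "bin_map.csv", index=False)
    binned = [r for r in kept if bin_map[r.occurrence_id] is not None]
    manifest["stages"]["bin"] = {
        "assigned": len(binned),
        "dropped": len(kept) - len(binned),
    }

    opinions = read_opinions(config.opinions) if config.opinions else []
    index = OpinionIndex(opinions)
    present = config.window[1]

    # species -> clade path, under presently accepted names
    taxonomy: dict[str, tuple[str, ...]] = {}
    for rec in binned:
        name = index.resolve(rec.identification_events[-1][1], present)
        taxonomy.setdefault(name, rec.clade_path)

    if config.registry and config.measurements:
        registry = read_registry(config.registry)
        measurements = read_measurements(config.measurements)
        mass_records = estimate_species_masses(
            measurements, registry, taxonomy, scheme
        )
    else:
        mass_records = {}
    manifest["stages"]["mass"] = {
        "species": len(taxonomy),
        "measured": sum(
            1 for r in mass_records.values() if r.category_source == "measured"
        ),
        "imputed": sum(
            1
            for r in mass_records.values()
            if r.category_source == "imputed_from_relatives"
        ),
        "uncategorized": len(taxonomy) - len(mass_records),
    }
    pd.DataFrame(
        [
            {
                "species": r.species,
                "mass_kg": r.mass_kg,
                "category": r.category,
                "category_source": r.category_source,
            }
            for r in sorted(mass_records.values(), key=lambda r: r.species)
        ]
    ).to_csv(out / "species_masses.csv", index=False)

    # per-bin distributions and coverage
    dist_frames, cov_rows, summary_rows = [], [], []
    for tb in config.bins:
        recs = [r for r in binned if bin_map[r.occurrence_id] == tb.name]
        species_here: dict[str, list] = {}
        for rec in recs:
            name = index.resolve(rec.identification_events[-1][1], present)
            species_here.setdefault(name, []).append(rec)
        cat_records = [
            mass_records[s] for s in species_here if s in mass_records
        ]
        face = build_distribution(cat_records, scheme, tb.name)
        dist_frames.append(face.to_frame())

        pairs_by_cat: dict[str, list[tuple[str, str]]] = {}
        for name, rlist in species_here.items():
            if name not in mass_records:
                continue
            cat = mass_records[name].category
            for rec in rlist:
                pairs_by_cat.setdefault(cat, []).append((name, rec.collection_id))
        std = standardized_distribution(
            pairs_by_cat, scheme, tb.name, q=config.quorum,
            B=config.bootstrap_B, seed=config.seed,
        )
        dist_frames.append(std.to_frame())

        for cat, pairs in sorted(pairs_by_cat.items()):
            table = IncidenceFrequencyTable.from_incidences(pairs)
            cov_rows.append({
                "bin": tb.name, "category": cat, "T": table.T,
                "U": table.U, "S_obs": table.S_obs,
                "goods_u": goods_u(table),
            })
        summary_rows.append({
            "bin": tb.name,
            "n_species": len(cat_records),
            "skew_face_value": distribution_skew(face),
            "skew_standardized": distribution_skew(std),
            "mode_ratio": mode_stats(face).accessory_to_primary_ratio,
        })

    pd.concat(dist_frames, ignore_index=True).to_csv(
        out / "distributions.csv", index=False
    )
    pd.DataFrame(cov_rows).to_csv(out / "coverage.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "bin_summary.csv", index=False)
    manifest["stages"]["distributions"] = {"bins": len(config.bins)}

    # research-time trajectories (pooled across bins)
    species_categories = {
        s: scheme.labels.index(r.category) for s, r in mass_records.items()
    }
    species_masses = {
        s: r.mass_kg for s, r in mass_records.items() if r.mass_kg is not None
    }
    skew_df = skew_trajectory(binned, opinions, species_categories, config.window)
    skew_df.to_csv(out / "skew_trajectory.csv", index=False)
    med_df = median_mass_trajectory(binned, opinions, species_masses, config.window)
    med_df.to_csv(out / "median_mass_trajectory.csv", index=False)
    effort_df = effort_proxies(binned, config.window)
    effort_df.to_csv(out / "effort_proxies.csv", index=False)
    spatial_df = spatial_trajectory(binned, config.window)
    spatial_df.to_csv(out / "spatial_trajectory.csv", index=False)
    manifest["stages"]["research_time"] = {
        "years": config.window[1] - config.window[0] + 1
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
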