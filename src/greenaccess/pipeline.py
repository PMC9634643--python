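"""End-to-end pipeline: synthetic city → grid → detectors → accessibility → deviation.

Stages
------
1. ``synth``      generate the city (grid, parks, population, events, truth)
2. ``grid``       supply-point decomposition and grid roles
3. ``signaling``  residences, population P_k, visits, visitors P_i, mode shares
4. ``access``     per-mode × per-threshold Ga2SFCA, comprehensive overlay,
                  min–max score, five-grade classification
5. ``deviation``  supply–demand deviation Z and its three bands

Each run writes a manifest (config hash, seed, package/library versions)
and is deterministic for a fixed configuration: rerunning into a fresh
directory produces byte-identical artifacts.  A failing stage leaves a
``.partial`` marker naming the stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from greenaccess import io as gio
from greenaccess.accessibility import Ga2SFCA, ThresholdConfig, comprehensive_accessibility, \
    euclidean_provider, geometric_interval_breaks, grade, minmax_normalize
from greenaccess.config import StudyConfig
from greenaccess.deviation import classify_deviation, deviation_index
from greenaccess.grid import assign_roles, build_hex_grid, make_supply_points
from greenaccess.signaling import classify_trip_modes, compute_mode_shares, count_population, \
    count_visitors_by_residence, detect_residences, detect_visits
from greenaccess.synthetic import generate_city

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: StudyConfig, outdir) -> dict:
    """Execute every stage and write all artifacts under ``outdir``.

    Returns a result bundle: the synthetic city, detected surfaces, the
    per-threshold accessibility tables and deviation tables.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.write_text("synth")
    try:
        result = _run(config, out, marker)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive tagging
        raise PipelineError(marker.read_text(), exc) from exc
    marker.unlink(missing_ok=True)
    return result


def _run(config: StudyConfig, out: Path, marker: Path) -> dict:
    # ---- stage: synth --------------------------------------------------
    try:
        city = generate_city(config.city)
    except Exception as exc:
        raise PipelineError("synth", exc) from exc
    gio.write_parks_geojson(city.parks, out / "parks.geojson")
    pd.DataFrame(sorted(city.population.items()), columns=["cell_id", "persons"]).to_csv(
        out / "population_truth.csv", index=False)
    gio.write_events(city.events, out / "events.csv")
    gio.write_json(city.truth, out / "truth.json")
    logger.info("synth: %d cells, %d parks, %d events", len(city.grid), len(city.parks), len(city.events))

    # ---- stage: grid ---------------------------------------------------
    marker.write_text("grid")
    try:
        grid = city.grid
        supplies = make_supply_points(city.parks, config.large_area_threshold_hm2)
    except Exception as exc:
        raise PipelineError("grid", exc) from exc
    gio.write_supply_points(supplies, out / "supply_points.csv")

    # ---- stage: signaling ---------------------------------------------
    marker.write_text("signaling")
    try:
        residences = detect_residences(city.events, config.min_residence_days,
                                       config.night_start_h, config.night_end_h)
        population = count_population(residences, grid)
        assign_roles(grid, population.to_dict(), city.parks)
        visits = detect_visits(city.events, grid.ugs_cell_ids(), config.min_visit_dwell_min,
                               config.day_start_h, config.day_end_h)
        visitors = count_visitors_by_residence(visits, residences)
        for c in grid.cells:
            c.visitors = int(visitors.get(c.cell_id, 0))
        modes = classify_trip_modes(city.trips["distance_m"], city.trips["duration_h"]) \
            if len(city.trips) else np.array([], dtype=object)
        shares = compute_mode_shares(modes)
    except Exception as exc:
        raise PipelineError("signaling", exc) from exc
    pd.DataFrame(sorted(residences.items()), columns=["user_id", "cell_id"]).to_csv(
        out / "residences.csv", index=False)
    population.to_frame().to_csv(out / "population.csv")
    visits.to_csv(out / "visits.csv", index=False, float_format="%.3f")
    visitors.to_frame().to_csv(out / "visitors.csv")
    gio.write_mode_shares(shares, out / "mode_shares.json")
    logger.info("signaling: %d residents, %d visits, %d visitors; shares %s",
                len(residences), len(visits), int(visitors.sum()), shares.as_dict())

    # ---- stage: access -------------------------------------------------
    marker.write_text("access")
    try:
        od_by_mode = {
            mode: euclidean_provider(supplies, grid, config.detour_factors[mode], mode)
            for mode in config.speeds_kmh
        }
        surfaces = {}
        for minutes in config.thresholds_min:
            thr = ThresholdConfig(minutes=minutes, speeds=dict(config.speeds_kmh))
            per_mode = {m: Ga2SFCA(thr, m).compute(supplies, grid, od_by_mode[m])
                        for m in config.speeds_kmh}
            comp = comprehensive_accessibility(per_mode, shares)
            score = minmax_normalize(comp.to_numpy())
            breaks = geometric_interval_breaks(score, config.grade_classes, config.grade_ratio)
            grades = grade(score, breaks)
            table = pd.DataFrame({f"A_{m}": per_mode[m] for m in config.speeds_kmh})
            table["C"] = comp
            table["score"] = score
            table["grade"] = grades
            surfaces[minutes] = table
    except Exception as exc:
        raise PipelineError("access", exc) from exc
    for mode, od in od_by_mode.items():
        gio.write_od(od.to_table(), out / f"od_{mode}.csv")
    for minutes, table in surfaces.items():
        gio.write_surface(table, out / f"accessibility_{int(minutes)}min.csv")

    # ---- stage: deviation ---------------------------------------------
    marker.write_text("deviation")
    try:
        deviations = {}
        for minutes, table in surfaces.items():
            levels = table["grade"].astype(float) if config.level_source == "grade" else table["C"]
            z = deviation_index(levels, visitors)
            cat = classify_deviation(z, config.z_low, config.z_high)
            deviations[minutes] = pd.DataFrame({"Z": z, "category": cat})
    except Exception as exc:
        raise PipelineError("deviation", exc) from exc
    for minutes, table in deviations.items():
        gio.write_surface(table, out / f"deviation_{int(minutes)}min.csv")

    # ---- exports and manifest ------------------------------------------
    extra = surfaces[config.thresholds_min[0]].join(deviations[config.thresholds_min[0]])
    gio.write_cells_geojson(grid, out / "cells.geojson", extra=extra)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.city.seed,
        "versions": _versions(),
        "counts": {
            "cells": len(grid),
            "parks": len(city.parks),
            "supply_points": len(supplies),
            "events": int(len(city.events)),
            "residents": len(residences),
            "visitors": int(visitors.sum()),
            "trips": int(len(city.trips)),
        },
    }
    gio.write_json(manifest, out / "manifest.json")

    return {
        "city": city,
        "grid": grid,
        "supplies": supplies,
        "residences": residences,
        "population": population,
        "visits": visits,
        "visitors": visitors,
        "mode_shares": shares,
        "accessibility": surfaces,
        "deviation": deviations,
        "manifest": manifest,
    }


def _versions() -> dict:
    import greenaccess
    import shapely
    return {
        "greenaccess": greenaccess.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "shapely": shapely.__version__,
    }
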