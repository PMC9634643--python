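"""Synthetic study area: parks, population surface, users and signaling events.

The generator emulates the statistical structure the analysis assumes
about a mid-sized Chinese city observed through one operator's
signaling records for a calendar month:

* a rectangular extent tiled by 500 m hexagons (≈ 800 cells for a
  27 × 18 km extent);
* parks with lognormal areas, a configurable fraction forced to the
  "large park" class (≥ 100 hm², carrying 2–6 entrance points);
* population concentrated toward one or more centers (mixture of
  Gaussian kernels, multinomially allocated so the total is exact);
* users with a fixed residence who dwell there every night
  (21:30–07:30) and make Poisson-distributed daytime park visits,
  preferring large, nearby parks (area × Gaussian distance decay);
* trips whose mode is drawn from target mode shares and whose speed is
  uniform inside that mode's band, so speed-based classification
  inverts the assignment exactly.

Every latent assignment (residence, visits, modes) is stored in
``truth`` so detector-recovery tests are first-class.  With
``p_long_visit = 1`` all visits dwell ≥ 30 minutes and the downstream
detectors recover truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import MultiPoint, Point, Polygon

from greenaccess.accessibility import gaussian_decay
from greenaccess.grid import HexGrid, Park, assign_roles, build_hex_grid

__all__ = ["CityConfig", "SyntheticCity", "PlacementError",
           "generate_parks", "generate_population", "generate_signaling", "generate_city"]

#: speed (km/h) sampled uniformly inside each mode's band; walking floored
#: at 0.5 so trip durations stay finite
MODE_SPEED_RANGES = {"walking": (0.5, 5.0), "cycling": (5.0, 15.0), "driving": (15.0, 60.0)}
MODE_ORDER = ("walking", "cycling", "driving")


class PlacementError(RuntimeError):
    """Raised when parks cannot be placed without overlap within the retry budget."""


@dataclass
class CityConfig:
    """Parameters of the synthetic study area.

    Defaults describe the demo city: a 27 × 18 km extent (≈ 780 hexagon
    cells at 500 m side, the same order as the 827-cell study grid this
    emulates), 30 parks with a 15 % large-park fraction, 100,000
    residents observed through 20,000 users over a 31-day month, and
    trip mode shares targeted at the observed 9.06 / 18.41 / 72.53 %
    walk / cycle / drive split.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 27_000.0, 18_000.0)
    hex_side: float = 500.0
    n_parks: int = 30
    park_area_log_mean: float = 3.0   # lognormal params, hm² (median ≈ 20 hm²)
    park_area_log_sd: float = 1.0
    frac_large_parks: float = 0.15
    entrances_per_large_park: tuple[int, int] = (2, 6)
    pop_total: int = 100_000
    pop_centers: list[tuple[float, float, float, float]] = field(
        default_factory=lambda: [(13_500.0, 9_000.0, 4_000.0, 0.7),
                                 (8_000.0, 6_000.0, 2_500.0, 0.3)]
    )
    n_users: int = 20_000
    days: int = 31
    start_date: str = "2021-05-01"
    trips_per_user_mean: float = 3.0
    target_mode_shares: tuple[float, float, float] = (0.0906, 0.1841, 0.7253)
    p_long_visit: float = 0.9         # probability a visit dwells ≥ 30 min
    dest_decay_scale: float = 15_000.0  # m; park choice decay radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hex_side <= 0:
            raise ValueError("hex_side must be positive")
        if not 0.0 <= self.frac_large_parks <= 1.0:
            raise ValueError("frac_large_parks must lie in [0, 1]")
        if abs(sum(self.target_mode_shares) - 1.0) > 1e-9:
            raise ValueError("target_mode_shares must sum to 1")
        if self.pop_total < self.n_users:
            raise ValueError("pop_total must be at least n_users")


@dataclass
class SyntheticCity:
    """A generated city plus the latent truth behind its event records."""

    config: CityConfig
    grid: HexGrid
    parks: list[Park]
    population: dict[int, int]
    events: pd.DataFrame
    trips: pd.DataFrame
    truth: dict


def _convex_park_polygon(rng: np.random.Generator, cx: float, cy: float, area_m2: float) -> Polygon:
    """Convex polygon of exactly the requested area around (cx, cy)."""
    r = np.sqrt(area_m2 / np.pi)
    k = int(rng.integers(8, 13))
    ang = rng.uniform(0, 2 * np.pi, k)
    rad = r * np.sqrt(rng.uniform(0.4, 1.0, k))
    pts = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0:
        hull = Polygon([(cx - r, cy - r), (cx + r, cy - r), (cx + r, cy + r), (cx - r, cy + r)])
    scale = np.sqrt(area_m2 / hull.area)
    return affinity.scale(hull, xfact=scale, yfact=scale, origin=(cx, cy))


def _park_category(area_hm2: float) -> str:
    if area_hm2 >= 50:
        return "comprehensive"
    if area_hm2 >= 20:
        return "theme"
    if area_hm2 >= 5:
        return "community"
    return "garden"


def generate_parks(config: CityConfig, rng: np.random.Generator | None = None) -> list[Park]:
    """Place non-overlapping convex parks with lognormal areas.

    A ``frac_large_parks`` fraction (rounded) is forced into the large
    class (≥ 100 hm²) and given entrance points spread along the
    boundary; the remainder is truncated below 100 hm².
    """
    if config.n_parks < 1:
        raise ValueError("need at least one park")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_large = int(round(config.frac_large_parks * config.n_parks))

    areas_hm2: list[float] = []
    for i in range(config.n_parks):
        if i < n_large:
            areas_hm2.append(100.0 + float(rng.lognormal(np.log(30.0), 0.8)))
        else:
            a = float(rng.lognormal(config.park_area_log_mean, config.park_area_log_sd))
            for _ in range(100):
                if a < 100.0:
                    break
                a = float(rng.lognormal(config.park_area_log_mean, config.park_area_log_sd))
            areas_hm2.append(min(a, 99.0))
    # place big parks first: easier packing, deterministic order
    order = sorted(range(config.n_parks), key=lambda i: -areas_hm2[i])

    xmin, ymin, xmax, ymax = config.extent
    placed: list[Polygon] = [None] * config.n_parks
    for i in order:
        area_m2 = areas_hm2[i] * 1e4
        r = float(np.sqrt(area_m2 / np.pi))
        if 2 * r > min(xmax - xmin, ymax - ymin):
            raise PlacementError(f"park of {areas_hm2[i]:.0f} hm² does not fit in the extent")
        ok = False
        for _ in range(200):
            cx = rng.uniform(xmin + r, xmax - r)
            cy = rng.uniform(ymin + r, ymax - r)
            poly = _convex_park_polygon(rng, cx, cy, area_m2)
            if poly.bounds[0] < xmin or poly.bounds[1] < ymin or poly.bounds[2] > xmax or poly.bounds[3] > ymax:
                continue
            if any(p is not None and poly.intersects(p) for p in placed):
                continue
            placed[i] = poly
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place park {i} ({areas_hm2[i]:.0f} hm²) without overlap; "
                "enlarge the extent or reduce n_parks"
            )

    lo, hi = config.entrances_per_large_park
    parks: list[Park] = []
    for i in range(config.n_parks):
        poly = placed[i]
        entrances: list[tuple[float, float]] = []
        if areas_hm2[i] >= 100.0:
            n_ent = int(rng.integers(lo, hi + 1))
            ring = poly.exterior
            offset = rng.uniform(0.0, ring.length)
            for m in range(n_ent):
                p = ring.interpolate((offset + m * ring.length / n_ent) % ring.length)
                entrances.append((p.x, p.y))
        parks.append(Park(park_id=i, name=f"park_{i:03d}", polygon=poly,
                          area=areas_hm2[i], entrances=entrances,
                          category=_park_category(areas_hm2[i])))
    return parks


def generate_population(
    config: CityConfig,
    grid: HexGrid,
    rng: np.random.Generator | None = None,
) -> dict[int, int]:
    """Allocate ``pop_total`` persons to cells by a Gaussian-mixture density.

    The mixture is evaluated at cell centroids and the total is drawn
    multinomially, so counts are integers and their sum is exact.
    """
    if len(grid) == 0:
        raise ValueError("no cells to populate")
    if not config.pop_centers:
        raise ValueError("need at least one population center")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.pop_total == 0:
        return {c.cell_id: 0 for c in grid.cells}

    xy = grid.centroids
    dens = np.zeros(len(grid))
    for cx, cy, sd, w in config.pop_centers:
        d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
        dens += w * np.exp(-0.5 * d2 / (sd * sd))
    if dens.sum() == 0:
        dens[:] = 1.0
    counts = rng.multinomial(config.pop_total, dens / dens.sum())
    return {c.cell_id: int(n) for c, n in zip(grid.cells, counts)}


def _choose_rows(rng: np.random.Generator, cum_weights: np.ndarray, row_idx: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw: row ``i`` uses cumulative weights ``cum_weights[row_idx[i]]``."""
    u = rng.uniform(size=len(row_idx))
    cw = cum_weights[row_idx]
    return (u[:, None] > cw[:, :-1]).sum(axis=1)


def generate_signaling(
    config: CityConfig,
    grid: HexGrid,
    parks: list[Park],
    population: Mapping[int, int],
    rng: np.random.Generator | None = None,
) -> SyntheticCity:
    """Generate users, nightly residence dwells, park visits and trips.

    Each user dwells at their residence 21:30–07:30 every night of the
    observation month, giving clean residence detection; park visits are
    daytime dwell events in a green-space cell of the destination park.
    """
    if not parks:
        raise ValueError("no parks: generate parks first")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    assign_roles(grid, population, parks)

    res_cells = np.array([c.cell_id for c in grid.cells if c.population > 0])
    if res_cells.size == 0:
        raise ValueError("population surface is empty")
    res_pop = np.array([grid.cells[c].population for c in res_cells], dtype=float)

    # destination parks must contain at least one UGS cell so that visits land
    # in detectable cells
    ugs = [c for c in grid.cells if c.is_ugs]
    park_cells: dict[int, np.ndarray] = {}
    for p in parks:
        ids = [c.cell_id for c in ugs if p.polygon.intersects(Point(c.centroid))]
        if ids:
            park_cells[p.park_id] = np.array(ids)
    if not park_cells:
        raise ValueError("no UGS cells: parks are too small for the grid resolution")
    dest_parks = [p for p in parks if p.park_id in park_cells]

    centroids = grid.centroids
    n_users = config.n_users

    # residences ∝ population
    res_idx = rng.choice(len(res_cells), size=n_users, p=res_pop / res_pop.sum())
    residences = res_cells[res_idx]

    # park-choice weights per residential cell: area × distance decay
    park_xy = np.array([[p.polygon.centroid.x, p.polygon.centroid.y] for p in dest_parks])
    park_area = np.array([p.area for p in dest_parks])
    cell_xy = centroids[res_cells]
    d = np.hypot(cell_xy[:, None, 0] - park_xy[None, :, 0], cell_xy[:, None, 1] - park_xy[None, :, 1])
    w = park_area[None, :] * gaussian_decay(d, config.dest_decay_scale)
    w = np.where(w.sum(axis=1, keepdims=True) > 0, w, park_area[None, :])
    cumw = np.cumsum(w / w.sum(axis=1, keepdims=True), axis=1)

    t0 = pd.Timestamp(config.start_date)
    day_ns = np.int64(86_400_000_000_000)

    # ---- nightly residence events: every user, every night, 21:30 → 07:30
    nights = np.arange(config.days)
    night_user = np.repeat(np.arange(n_users), config.days)
    night_day = np.tile(nights, n_users)
    night_start = t0.value + night_day * day_ns + np.int64(21.5 * 3_600_000_000_000)
    night_end = night_start + np.int64(10 * 3_600_000_000_000)
    ev_user = [night_user]
    ev_start = [night_start]
    ev_end = [night_end]
    ev_cell = [residences[night_user]]

    # ---- park visits: Poisson count per user, one per distinct day
    n_trips = np.minimum(rng.poisson(config.trips_per_user_mean, n_users), config.days)
    trip_user = np.repeat(np.arange(n_users), n_trips)
    # distinct trip days per user via random permutation ranks
    day_keys = rng.uniform(size=(n_users, config.days))
    day_rank = np.argsort(day_keys, axis=1)
    slot = np.concatenate([np.arange(n) for n in n_trips]) if len(trip_user) else np.array([], int)
    trip_day = day_rank[trip_user, slot] if len(trip_user) else np.array([], int)

    park_pick = _choose_rows(rng, cumw, res_idx[trip_user]) if len(trip_user) else np.array([], int)
    # destination cell uniform among the park's UGS cells
    max_cells = max(len(v) for v in park_cells.values())
    cell_table = np.zeros((len(dest_parks), max_cells), dtype=int)
    cell_cum = np.zeros((len(dest_parks), max_cells))
    for j, p in enumerate(dest_parks):
        ids = park_cells[p.park_id]
        cell_table[j, : len(ids)] = ids
        cell_cum[j] = np.minimum(np.arange(1, max_cells + 1) / len(ids), 1.0)
    pick_col = _choose_rows(rng, cell_cum, park_pick) if len(trip_user) else np.array([], int)
    dest_cell = cell_table[park_pick, pick_col] if len(trip_user) else np.array([], int)

    long_visit = rng.uniform(size=len(trip_user)) < config.p_long_visit
    dwell_min = np.where(long_visit, rng.uniform(35.0, 120.0, len(trip_user)),
                         rng.uniform(10.0, 25.0, len(trip_user)))
    # visit fits wholly inside the 08:00–21:00 daytime window
    start_h = 8.0 + rng.uniform(size=len(trip_user)) * (13.0 - dwell_min / 60.0)
    v_start = t0.value + trip_day * day_ns + (start_h * 3_600_000_000_000).astype(np.int64)
    v_end = v_start + (dwell_min * 60_000_000_000).astype(np.int64)

    mode_idx = _choose_rows(rng, np.cumsum(np.array([config.target_mode_shares]), axis=1),
                            np.zeros(len(trip_user), dtype=int)) if len(trip_user) else np.array([], int)
    speed_lo = np.array([MODE_SPEED_RANGES[m][0] for m in MODE_ORDER])
    speed_hi = np.array([MODE_SPEED_RANGES[m][1] for m in MODE_ORDER])
    speed = rng.uniform(speed_lo[mode_idx], speed_hi[mode_idx]) if len(trip_user) else np.array([])

    origin_xy = centroids[residences[trip_user]] if len(trip_user) else np.zeros((0, 2))
    dest_xy = centroids[dest_cell] if len(trip_user) else np.zeros((0, 2))
    dist = np.maximum(np.hypot(*(origin_xy - dest_xy).T), 50.0) if len(trip_user) else np.array([])
    duration_h = dist / 1000.0 / speed if len(trip_user) else np.array([])

    ev_user.append(trip_user)
    ev_start.append(v_start)
    ev_end.append(v_end)
    ev_cell.append(dest_cell)

    events = pd.DataFrame({
        "user_id": np.concatenate(ev_user),
        "t_start": pd.to_datetime(np.concatenate(ev_start)),
        "t_end": pd.to_datetime(np.concatenate(ev_end)),
        "cell_id": np.concatenate(ev_cell).astype(int),
    }).sort_values(["user_id", "t_start"], kind="mergesort").reset_index(drop=True)
    events["user_id"] = "u" + events["user_id"].astype(str).str.zfill(6)

    user_labels = np.array(["u" + str(i).zfill(6) for i in range(n_users)])
    trips = pd.DataFrame({
        "user_id": user_labels[trip_user],
        "day": trip_day,
        "origin_cell": residences[trip_user].astype(int),
        "dest_cell": dest_cell.astype(int),
        "depart": pd.to_datetime(v_start - (duration_h * 3_600_000_000_000).astype(np.int64)),
        "arrive": pd.to_datetime(v_start),
        "distance_m": dist,
        "duration_h": duration_h,
        "mode": np.array(MODE_ORDER, dtype=object)[mode_idx] if len(trip_user) else np.array([], dtype=object),
    })

    truth = {
        "residences": {user_labels[i]: int(residences[i]) for i in range(n_users)},
        "visits": [
            {"user_id": user_labels[u], "cell_id": int(c),
             "date": str((t0 + pd.Timedelta(days=int(dd))).date()),
             "dwell_min": float(m), "long": bool(lv)}
            for u, c, dd, m, lv in zip(trip_user, dest_cell, trip_day, dwell_min, long_visit)
        ],
        "modes": list(np.array(MODE_ORDER, dtype=object)[mode_idx]) if len(trip_user) else [],
    }
    return SyntheticCity(config=config, grid=grid, parks=parks,
                         population=dict(population), events=events, trips=trips, truth=truth)


def generate_city(config: CityConfig) -> SyntheticCity:
    """End-to-end generation: grid → parks → population → signaling."""
    rng = np.random.default_rng(config.seed)
    grid = build_hex_grid(config.extent, config.hex_side)
    parks = generate_parks(config, rng)
    population = generate_population(config, grid, rng)
    return generate_signaling(config, grid, parks, population, rng)
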