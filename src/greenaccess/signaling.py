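"""Detectors over mobile-signaling event records.

An event is one user–cell interaction interval ``(user_id, t_start,
t_end, cell_id)``.  From a month of such records the module derives

* residences — per user, the cell with the longest cumulative dwell in
  the nightly window (21:00–08:00, spanning midnight), restricted to
  users present on strictly more than ``min_days`` distinct days;
* the residential population surface P_k;
* UGS visits — maximal runs of contiguous events in one green-space
  cell whose intersection with the daytime window (08:00–21:00) totals
  at least 30 minutes;
* the visitor surface P_i — distinct users with at least one visit,
  tallied at their residence cell;
* travel-mode classification by average trip speed (walking < 5 km/h,
  cycling 5–15 km/h, driving 15–60 km/h, above 60 excluded) and the
  resulting mode shares used as accessibility weights.

Events are handled as a pandas DataFrame with columns ``user_id``,
``t_start``, ``t_end`` (datetime64) and ``cell_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "ModeShares",
    "detect_residences",
    "count_population",
    "detect_visits",
    "count_visitors_by_residence",
    "classify_trip_mode",
    "classify_trip_modes",
    "compute_mode_shares",
    "normalize_events",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["user_id", "t_start", "t_end", "cell_id"]

#: Average-speed bands (km/h) per mode; half-open [lo, hi), driving closed at 60.
SPEED_BANDS = {"walking": (0.0, 5.0), "cycling": (5.0, 15.0), "driving": (15.0, 60.0)}
EXCLUDED = "excluded"


@dataclass(frozen=True)
class ModeShares:
    """Trip-count fractions per travel mode; the weights W_n of the overlay."""

    walking: float
    cycling: float
    driving: float

    def __post_init__(self) -> None:
        total = self.walking + self.cycling + self.driving
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"mode shares must sum to 1, got {total}")
        if min(self.walking, self.cycling, self.driving) < 0:
            raise ValueError("mode shares must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {"walking": self.walking, "cycling": self.cycling, "driving": self.driving}

    @classmethod
    def from_counts(cls, walking: int, cycling: int, driving: int) -> "ModeShares":
        total = walking + cycling + driving
        if total <= 0:
            raise ValueError("no usable trips")
        return cls(walking / total, cycling / total, driving / total)


def normalize_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, parse timestamps, and sort by user then start time."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events frame missing columns: {missing}")
    ev = events.copy()
    ev["t_start"] = pd.to_datetime(ev["t_start"])
    ev["t_end"] = pd.to_datetime(ev["t_end"])
    if (ev["t_end"] < ev["t_start"]).any():
        raise ValueError("event with t_end before t_start")
    return ev.sort_values(["user_id", "t_start"], kind="mergesort").reset_index(drop=True)


def _window_overlap_minutes(
    ev: pd.DataFrame, start_hour: float, end_hour: float
) -> pd.Series:
    """Minutes of each event interval inside a repeating daily window.

    The window runs from ``start_hour`` to ``end_hour``; when end ≤ start
    it spans midnight (e.g. 21:00→08:00 next day).  Events longer than a
    day are handled by summing over every candidate window anchor date.
    """
    start = ev["t_start"]
    end = ev["t_end"]
    # anchor dates from the day before the event starts through its last day
    first = start.dt.normalize() - pd.Timedelta(days=1)
    n_days = ((end.dt.normalize() - first).dt.days + 1).to_numpy()
    idx = np.repeat(ev.index.to_numpy(), n_days)
    offsets = np.concatenate([np.arange(n) for n in n_days]) if len(ev) else np.array([], dtype=int)
    anchors = first.to_numpy()[idx] + offsets.astype("timedelta64[D]")

    span = end_hour - start_hour if end_hour > start_hour else 24.0 - start_hour + end_hour
    wstart = anchors + pd.to_timedelta(start_hour, unit="h").to_timedelta64()
    wend = wstart + pd.to_timedelta(span, unit="h").to_timedelta64()
    s = np.maximum(start.to_numpy()[idx], wstart)
    e = np.minimum(end.to_numpy()[idx], wend)
    ov = np.maximum((e - s) / np.timedelta64(60, "s"), 0.0)
    return pd.Series(ov, index=idx).groupby(level=0).sum().reindex(ev.index, fill_value=0.0)


def detect_residences(
    events: pd.DataFrame,
    min_days: int = 10,
    night_start: float = 21.0,
    night_end: float = 8.0,
) -> dict:
    """Assign each sufficiently observed user to a residence cell.

    Users seen on strictly more than ``min_days`` distinct calendar days
    are retained; each one's residence is the cell with the longest
    cumulative dwell inside the nightly window, ties resolving to the
    lower cell id.  Retained users with zero nighttime dwell anywhere are
    dropped with a warning.
    """
    ev = normalize_events(events)
    if ev.empty:
        return {}

    # distinct days touched by any interval of the user
    n_span = (ev["t_end"].dt.normalize() - ev["t_start"].dt.normalize()).dt.days + 1
    idx = np.repeat(ev.index.to_numpy(), n_span.to_numpy())
    offs = np.concatenate([np.arange(n) for n in n_span]) if len(ev) else np.array([], int)
    dates = ev["t_start"].dt.normalize().to_numpy()[idx] + offs.astype("timedelta64[D]")
    day_frame = pd.DataFrame({"user_id": ev["user_id"].to_numpy()[idx], "date": dates})
    days_present = day_frame.drop_duplicates().groupby("user_id").size()
    retained = set(days_present.index[days_present > min_days])
    if not retained:
        return {}

    ev = ev[ev["user_id"].isin(retained)].reset_index(drop=True)
    ev["night_min"] = _window_overlap_minutes(ev, night_start, night_end)
    dwell = ev.groupby(["user_id", "cell_id"])["night_min"].sum().reset_index()
    dwell = dwell[dwell["night_min"] > 0]

    no_night = retained - set(dwell["user_id"])
    if no_night:
        logger.warning("%d retained user(s) have no nighttime dwell and were dropped", len(no_night))

    # longest dwell wins; ties go to the lower cell id
    dwell = dwell.sort_values(["user_id", "night_min", "cell_id"],
                              ascending=[True, False, True], kind="mergesort")
    best = dwell.drop_duplicates("user_id", keep="first")
    return dict(zip(best["user_id"], best["cell_id"].astype(int)))


def count_population(residences: Mapping, grid) -> pd.Series:
    """P_k: residents per cell, indexed over every grid cell (zeros kept)."""
    all_ids = pd.Index([c.cell_id for c in grid.cells], name="cell_id")
    if not residences:
        return pd.Series(0, index=all_ids, name="population")
    counts = pd.Series(list(residences.values())).value_counts()
    return counts.reindex(all_ids, fill_value=0).rename("population").astype(int)


def detect_visits(
    events: pd.DataFrame,
    ugs_cells: Iterable[int],
    min_dwell_min: float = 30.0,
    day_start: float = 8.0,
    day_end: float = 21.0,
) -> pd.DataFrame:
    """Find UGS visits: contiguous same-cell event runs with enough daytime dwell.

    A run is a maximal sequence of a user's consecutive events in one cell
    with no time gap between them; it counts as a visit when its overlap
    with the 08:00–21:00 window totals at least ``min_dwell_min`` minutes
    and the cell is a green-space cell.

    Returns a frame with columns user_id, cell_id, date, dwell_min.
    """
    ev = normalize_events(events)
    ugs = set(int(c) for c in ugs_cells)
    if ev.empty or not ugs:
        return pd.DataFrame(columns=["user_id", "cell_id", "date", "dwell_min"])

    ev = ev[ev["cell_id"].isin(ugs)].reset_index(drop=True)
    if ev.empty:
        return pd.DataFrame(columns=["user_id", "cell_id", "date", "dwell_min"])

    new_user = ev["user_id"] != ev["user_id"].shift()
    new_cell = ev["cell_id"] != ev["cell_id"].shift()
    gap = ev["t_start"] > ev["t_end"].shift()
    run_id = (new_user | new_cell | gap).cumsum()

    ev["day_min"] = _window_overlap_minutes(ev, day_start, day_end)
    runs = ev.groupby(run_id).agg(
        user_id=("user_id", "first"),
        cell_id=("cell_id", "first"),
        t_start=("t_start", "first"),
        dwell_min=("day_min", "sum"),
    )
    visits = runs[runs["dwell_min"] >= min_dwell_min].copy()
    visits["date"] = visits["t_start"].dt.date.astype(str)
    return visits[["user_id", "cell_id", "date", "dwell_min"]].reset_index(drop=True)


def count_visitors_by_residence(visits: pd.DataFrame, residences: Mapping) -> pd.Series:
    """P_i: distinct users with ≥ 1 UGS visit, tallied at their residence cell.

    Visits by users without a detected residence are ignored with a warning.
    A user with many visits still contributes exactly once.
    """
    if visits.empty:
        return pd.Series(dtype=int, name="visitors").rename_axis("cell_id")
    visitors = pd.Index(visits["user_id"].unique())
    known = visitors[visitors.isin(residences.keys())]
    orphans = len(visitors) - len(known)
    if orphans:
        logger.warning("%d visitor(s) have no detected residence; ignored", orphans)
    res_cells = pd.Series([residences[u] for u in known], dtype=int)
    return res_cells.value_counts().sort_index().rename("visitors").rename_axis("cell_id")


def classify_trip_mode(distance_m: float, duration_h: float) -> str:
    """Mode from average trip speed; speeds above 60 km/h are excluded."""
    if duration_h <= 0:
        raise ValueError("trip duration must be positive")
    speed = distance_m / 1000.0 / duration_h
    if speed < SPEED_BANDS["walking"][1]:
        return "walking"
    if speed < SPEED_BANDS["cycling"][1]:
        return "cycling"
    if speed <= SPEED_BANDS["driving"][1]:
        return "driving"
    return EXCLUDED


def classify_trip_modes(distance_m, duration_h) -> np.ndarray:
    """Vectorized :func:`classify_trip_mode`."""
    d = np.asarray(distance_m, dtype=float)
    t = np.asarray(duration_h, dtype=float)
    if (t <= 0).any():
        raise ValueError("trip duration must be positive")
    speed = d / 1000.0 / t
    out = np.full(speed.shape, EXCLUDED, dtype=object)
    out[speed <= 60.0] = "driving"
    out[speed < 15.0] = "cycling"
    out[speed < 5.0] = "walking"
    return out


def compute_mode_shares(trips) -> ModeShares:
    """Observed mode shares W_n over non-excluded trips.

    ``trips`` is either a DataFrame with a ``mode`` column or an iterable
    of mode labels; excluded trips do not enter the denominator.
    """
    if isinstance(trips, pd.DataFrame):
        modes = trips["mode"]
    else:
        modes = pd.Series(list(trips), dtype=object)
    counts = modes[modes != EXCLUDED].value_counts()
    usable = int(counts.sum())
    if usable == 0:
        raise ValueError("no usable trips to compute mode shares")
    return ModeShares.from_counts(
        int(counts.get("walking", 0)), int(counts.get("cycling", 0)), int(counts.get("driving", 0))
    )
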