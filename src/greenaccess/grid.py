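"""Regular-hexagon analysis lattice, grid roles, and park supply points.

The study area is tiled with flat-top regular hexagons of a configured
side length (default 500 m).  Each cell carries a residential population
``P_k`` and a UGS-visitor count ``P_i`` and is flagged as residential
(population > 0) and/or as green space (cell centroid falls inside a
park polygon; boundary counts as inside).  Residential-cell centroids
are the demand points of the catchment analysis.

Parks are decomposed into supply points: a park smaller than the large-park
threshold (100 hm²) contributes its centroid with the full area as supply
scale; a park at or above the threshold contributes one point per entrance,
splitting the area equally so that total supply area is conserved.

All coordinates are planar projected meters; 1 hm² = 10,000 m².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely import STRtree
from shapely.geometry import Point, Polygon

__all__ = [
    "HexCell",
    "HexGrid",
    "Park",
    "SupplyPoint",
    "OUTSIDE",
    "build_hex_grid",
    "assign_roles",
    "make_supply_points",
    "locate_cell",
    "hexagon_area",
]

#: Sentinel returned by :func:`locate_cell` for points not covered by any cell.
OUTSIDE = "outside"

SQRT3 = math.sqrt(3.0)


@dataclass
class HexCell:
    """One hexagonal grid unit of the analysis lattice."""

    cell_id: int
    centroid: tuple[float, float]
    polygon: Polygon
    population: int = 0
    visitors: int = 0
    is_residential: bool = False
    is_ugs: bool = False


@dataclass
class Park:
    """A public green space: polygon, area in hm², optional entrance points."""

    park_id: int
    name: str
    polygon: Polygon
    area: float  # hm²
    entrances: list[tuple[float, float]] = field(default_factory=list)
    category: str = "community"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"park {self.park_id}: area must be positive, got {self.area}")


@dataclass
class SupplyPoint:
    """A park service point with supply scale S_j (hm²)."""

    supply_id: int
    park_id: int
    location: tuple[float, float]
    supply_scale: float  # hm²


def hexagon_area(side: float) -> float:
    """Area of a regular hexagon with the given side length: 3√3/2 · side²."""
    return 1.5 * SQRT3 * side * side


def _hex_polygon(cx: float, cy: float, side: float) -> Polygon:
    # flat-top orientation; shared vertices of neighboring cells must come out
    # bitwise identical, so offsets are tabulated rather than recomputed by trig
    h = SQRT3 * side / 2.0
    offs = ((side, 0.0), (side / 2.0, h), (-side / 2.0, h),
            (-side, 0.0), (-side / 2.0, -h), (side / 2.0, -h))
    return Polygon([(cx + ox, cy + oy) for ox, oy in offs])


class HexGrid(Sequence):
    """A sequence of :class:`HexCell` plus spatial lookup over the lattice.

    Cells are ordered row-major (by centroid y, then x) with stable integer
    ids ``0..n-1``.
    """

    def __init__(self, cells: list[HexCell], side: float, extent: tuple[float, float, float, float]):
        self.cells = cells
        self.side = side
        self.extent = extent
        self._tree: STRtree | None = None

    def __len__(self) -> int:
        return len(self.cells)

    def __getitem__(self, i):
        return self.cells[i]

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of cell centroids in id order."""
        return np.asarray([c.centroid for c in self.cells], dtype=float)

    def population_series(self) -> dict[int, int]:
        return {c.cell_id: c.population for c in self.cells}

    def residential_cells(self) -> list[HexCell]:
        return [c for c in self.cells if c.is_residential]

    def ugs_cell_ids(self) -> set[int]:
        return {c.cell_id for c in self.cells if c.is_ugs}

    def _build_tree(self) -> STRtree:
        if self._tree is None:
            self._tree = STRtree([c.polygon for c in self.cells])
        return self._tree

    def locate(self, point: tuple[float, float]) -> int | str:
        """Cell id containing ``point``; shared boundaries resolve to the
        lower cell id; points not covered by any cell give :data:`OUTSIDE`."""
        tree = self._build_tree()
        p = Point(point)
        hits = tree.query(p, predicate="intersects")
        if len(hits) == 0:
            return OUTSIDE
        return int(min(self.cells[int(i)].cell_id for i in hits))


def build_hex_grid(extent: tuple[float, float, float, float], side: float) -> HexGrid:
    """Tile a rectangular extent with flat-top regular hexagons.

    Parameters
    ----------
    extent
        ``(xmin, ymin, xmax, ymax)`` in projected meters.
    side
        Hexagon side length in meters (the lattice constant; 500 m default
        upstream).

    Returns
    -------
    HexGrid
        Every lattice cell whose centroid lies inside the extent
        (boundary inclusive), with row-major stable ids.
    """
    xmin, ymin, xmax, ymax = extent
    if side <= 0:
        raise ValueError("hexagon side must be positive")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("extent is degenerate")

    dx = 1.5 * side          # column pitch
    dy = SQRT3 * side        # row pitch
    n_cols = int(math.floor((xmax - xmin) / dx)) + 1
    centers: list[tuple[float, float]] = []
    for col in range(n_cols):
        cx = xmin + col * dx
        y0 = ymin + (dy / 2.0 if col % 2 else 0.0)
        n_rows = int(math.floor((ymax - y0) / dy)) + 1 if y0 <= ymax else 0
        for row in range(n_rows):
            cy = y0 + row * dy
            centers.append((cx, cy))

    # row-major ids: sort by y then x (rounded to kill float jitter)
    centers.sort(key=lambda c: (round(c[1], 6), round(c[0], 6)))
    cells = [
        HexCell(cell_id=i, centroid=(cx, cy), polygon=_hex_polygon(cx, cy, side))
        for i, (cx, cy) in enumerate(centers)
    ]
    return HexGrid(cells, side=side, extent=tuple(extent))


def assign_roles(
    grid: HexGrid,
    population: Mapping[int, int],
    parks: Iterable[Park],
) -> HexGrid:
    """Set residential / UGS flags and per-cell population in place.

    A cell is residential iff its population is positive, and a UGS cell
    iff its centroid lies inside (or on the boundary of) any park polygon.
    Both flags may hold at once.
    """
    known = {c.cell_id for c in grid.cells}
    unknown = set(population) - known
    if unknown:
        raise KeyError(f"population mapping references unknown cell ids: {sorted(unknown)[:5]}")

    parks = list(parks)
    tree = STRtree([p.polygon for p in parks]) if parks else None
    for cell in grid.cells:
        pop = int(population.get(cell.cell_id, 0))
        if pop < 0:
            raise ValueError(f"cell {cell.cell_id}: negative population")
        cell.population = pop
        cell.is_residential = pop > 0
        if tree is not None:
            hits = tree.query(Point(cell.centroid), predicate="intersects")
            cell.is_ugs = len(hits) > 0
        else:
            cell.is_ugs = False
    return grid


def make_supply_points(
    parks: Iterable[Park],
    large_area_threshold: float = 100.0,
) -> list[SupplyPoint]:
    """Decompose parks into supply points.

    Parks below the threshold (hm²) become a single centroid point carrying
    the whole area; parks at or above it become one point per entrance with
    the area split equally, so the summed supply scale equals the park area.
    """
    points: list[SupplyPoint] = []
    sid = 0
    for park in parks:
        if park.area < large_area_threshold:
            c = park.polygon.centroid
            points.append(SupplyPoint(sid, park.park_id, (c.x, c.y), park.area))
            sid += 1
        else:
            if not park.entrances:
                raise ValueError(
                    f"park {park.park_id} ({park.area:.1f} hm²) is at/above the "
                    f"{large_area_threshold} hm² threshold but has no entrances"
                )
            share = park.area / len(park.entrances)
            for ex, ey in park.entrances:
                points.append(SupplyPoint(sid, park.park_id, (float(ex), float(ey)), share))
                sid += 1
    return points


def locate_cell(point: tuple[float, float], grid: HexGrid) -> int | str:
    """Functional wrapper for :meth:`HexGrid.locate`."""
    return grid.locate(point)
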