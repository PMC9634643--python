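import numpy as np
import pytest
from shapely.geometry import Polygon

from greenaccess import CityConfig, build_hex_grid, generate_city
from greenaccess.grid import HexCell, HexGrid, Park


def square_park(park_id, cx, cy, area_hm2, n_entrances=0):
    """A square park of exactly area_hm2 centered at (cx, cy)."""
    half = np.sqrt(area_hm2 * 1e4) / 2.0
    poly = Polygon([(cx - half, cy - half), (cx + half, cy - half),
                    (cx + half, cy + half), (cx - half, cy + half)])
    entrances = []
    if n_entrances:
        ring = poly.exterior
        entrances = [tuple(np.asarray(ring.interpolate(k * ring.length / n_entrances).coords[0]))
                     for k in range(n_entrances)]
    return Park(park_id=park_id, name=f"p{park_id}", polygon=poly,
                area=area_hm2, entrances=entrances)


def stub_grid(populations, coords=None):
    """A grid of bare cells (no geometry) for catchment math tests."""
    cells = []
    for i, pop in enumerate(populations):
        c = HexCell(cell_id=i, centroid=coords[i] if coords else (float(i), 0.0), polygon=None)
        c.population = int(pop)
        c.is_residential = pop > 0
        cells.append(c)
    return HexGrid(cells, side=1.0, extent=(0.0, 0.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_city():
    """A compact synthetic city used across detector tests (clean dwells)."""
    cfg = CityConfig(
        extent=(0.0, 0.0, 9000.0, 7500.0), n_parks=6, n_users=400,
        pop_total=5000, pop_centers=[(4500.0, 3750.0, 2500.0, 1.0)],
        frac_large_parks=0.34, trips_per_user_mean=2.0, p_long_visit=1.0, seed=7,
    )
    return generate_city(cfg)


@pytest.fixture(scope="session")
def demo_grid():
    return build_hex_grid((0.0, 0.0, 27_000.0, 18_000.0), 500.0)
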