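"""Ga2SFCA math: decay kernel, catchment steps, overlay, grading."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenaccess import (
    Ga2SFCA,
    ModeShares,
    ODMatrix,
    ThresholdConfig,
    accessibility_index,
    comprehensive_accessibility,
    euclidean_provider,
    ga2sfca,
    gaussian_decay,
    geometric_interval_breaks,
    grade,
    minmax_normalize,
    supply_demand_ratio,
    threshold_distance,
)
from greenaccess.grid import SupplyPoint

from conftest import stub_grid


def brute_force_ga2sfca(S, P, D, d0):
    """Independent double-loop reference of the two catchment steps."""
    e_half = math.exp(-0.5)

    def g(d):
        if d > d0:
            return 0.0
        return (math.exp(-0.5 * (d / d0) ** 2) - e_half) / (1.0 - e_half)

    n_j, n_i = D.shape
    R = []
    for j in range(n_j):
        denom = sum(g(D[j, i]) * P[i] for i in range(n_i) if D[j, i] <= d0)
        R.append(S[j] / denom if denom > 0 else 0.0)
    return [sum(g(D[j, i]) * R[j] for j in range(n_j) if D[j, i] <= d0) for i in range(n_i)]


def random_instance(rng, n_supply, n_cells, d0):
    S = rng.uniform(5.0, 200.0, n_supply)
    P = rng.integers(1, 500, n_cells)
    D = rng.uniform(0.0, 2.0 * d0, (n_supply, n_cells))
    # guarantee every supply point a populated cell in range
    D[np.arange(n_supply), rng.integers(0, n_cells, n_supply)] = rng.uniform(0, 0.5 * d0, n_supply)
    return S, P, D


def build(S, P, D, d0, mode="walking"):
    grid = stub_grid(P)
    supplies = [SupplyPoint(j, j, (0.0, 0.0), s) for j, s in enumerate(S)]
    od = ODMatrix(mode, D, [s.supply_id for s in supplies], [c.cell_id for c in grid.cells])
    thr = ThresholdConfig(minutes=60.0, speeds={mode: d0 / 1000.0})
    return supplies, grid, od, thr


class TestGaussianDecay:
    def test_anchor_values(self):
        assert gaussian_decay(0.0, 1250.0) == pytest.approx(1.0, abs=1e-15)
        assert gaussian_decay(1250.0, 1250.0) == pytest.approx(0.0, abs=1e-15)
        # (e^{-1/8} − e^{-1/2}) / (1 − e^{-1/2}) = 0.7013665732…
        assert gaussian_decay(625.0, 1250.0) == pytest.approx(0.7013665732, abs=1e-9)
        assert gaussian_decay(1250.1, 1250.0) == 0.0

    def test_strictly_decreasing_and_bounded(self):
        d = np.linspace(0.0, 1250.0, 1000)
        w = gaussian_decay(d, 1250.0)
        assert np.all(np.diff(w) < 0)
        assert np.all((w >= 0) & (w <= 1))

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            gaussian_decay(10.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(1.0, 1e5), st.floats(0.0, 1.0, exclude_max=True), st.floats(0.0, 1.0))
    def test_monotone_property(self, d0, f1, df):
        d1 = f1 * d0
        d2 = min(d1 + df * (d0 - d1) + 1e-9, d0)
        assert gaussian_decay(d1, d0) >= gaussian_decay(d2, d0)


class TestThresholds:
    @pytest.mark.parametrize("minutes,speed,expected", [
        (15, 5, 1250.0), (15, 15, 3750.0), (15, 30, 7500.0),
        (30, 5, 2500.0), (30, 15, 7500.0), (30, 30, 15000.0),
        (10, 6, 1000.0),
    ])
    def test_radius_table(self, minutes, speed, expected):
        assert threshold_distance(minutes, speed) == expected

    def test_config_radii_are_exact(self):
        thr = ThresholdConfig(minutes=15)
        assert thr.radii == {"walking": 1250.0, "cycling": 3750.0, "driving": 7500.0}

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            threshold_distance(0, 5)


class TestCatchmentSteps:
    def test_ratio_single_cell_at_origin(self):
        supplies, grid, od, thr = build([100.0], [1000], np.array([[0.0]]), 1000.0)
        r = supply_demand_ratio(supplies[0], grid.cells, od, 1000.0)
        assert r == pytest.approx(0.1)

    def test_boundary_cell_has_zero_weight(self):
        D = np.array([[0.0, 1000.0]])
        supplies, grid, od, thr = build([100.0], [500, 500], D, 1000.0)
        assert supply_demand_ratio(supplies[0], grid.cells, od, 1000.0) == pytest.approx(0.2)

    def test_ratio_at_half_radius(self):
        supplies, grid, od, thr = build([100.0], [1000], np.array([[500.0]]), 1000.0)
        r = supply_demand_ratio(supplies[0], grid.cells, od, 1000.0)
        assert r == pytest.approx(100.0 / (0.7013665732 * 1000.0), rel=1e-9)

    def test_single_pair_conservation_forces_a_equals_s_over_p(self):
        # one supply, one demand cell: P·A = S regardless of distance in range
        supplies, grid, od, thr = build([100.0], [1000], np.array([[500.0]]), 1000.0)
        ratios = {0: supply_demand_ratio(supplies[0], grid.cells, od, 1000.0)}
        a = accessibility_index(grid.cells[0], supplies, ratios, od, 1000.0)
        assert a == pytest.approx(0.1, rel=1e-12)

    def test_supplies_beyond_radius_contribute_nothing(self):
        D = np.array([[5000.0], [6000.0]])
        supplies, grid, od, thr = build([50.0, 60.0], [100], D, 1000.0)
        a = ga2sfca(supplies, grid, od, thr, "walking")
        assert (a == 0.0).all()

    def test_empty_supply_list_gives_zero_surface(self):
        grid = stub_grid([10, 20])
        od = ODMatrix("walking", np.zeros((0, 2)), [], [0, 1])
        a = ga2sfca([], grid, od, ThresholdConfig(), "walking")
        assert (a == 0.0).all() and len(a) == 2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_vectorized_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        d0 = 1000.0
        S, P, D = random_instance(rng, 10, 100, d0)
        supplies, grid, od, thr = build(S, P, D, d0)
        fast = ga2sfca(supplies, grid, od, thr, "walking").to_numpy()
        slow = np.array(brute_force_ga2sfca(S, P, D, d0))
        np.testing.assert_allclose(fast, slow, rtol=1e-12)

    def test_conservation_identity(self):
        rng = np.random.default_rng(123)
        d0 = 1.0
        S, P, D = random_instance(rng, 30, 200, d0)
        supplies, grid, od, thr = build(S, P, D, d0)
        A = ga2sfca(supplies, grid, od, thr, "walking").to_numpy()
        assert abs((A * P).sum() - S.sum()) / S.sum() < 1e-9

    def test_homogeneity_in_supply_and_population(self):
        rng = np.random.default_rng(5)
        d0 = 1.0
        S, P, D = random_instance(rng, 8, 50, d0)
        base = ga2sfca(*build(S, P, D, d0)[:3], ThresholdConfig(60.0, {"walking": d0 / 1000}), "walking")
        scaled_s = ga2sfca(*build(3.0 * S, P, D, d0)[:3], ThresholdConfig(60.0, {"walking": d0 / 1000}), "walking")
        np.testing.assert_allclose(scaled_s.to_numpy(), 3.0 * base.to_numpy(), rtol=1e-12)
        scaled_p = ga2sfca(*build(S, 4 * P, D, d0)[:3], ThresholdConfig(60.0, {"walking": d0 / 1000}), "walking")
        np.testing.assert_allclose(scaled_p.to_numpy(), base.to_numpy() / 4.0, rtol=1e-12)

    def test_increasing_population_weakly_decreases_access(self):
        rng = np.random.default_rng(11)
        d0 = 1.0
        S, P, D = random_instance(rng, 8, 50, d0)
        base = ga2sfca(*build(S, P, D, d0)[:3], ThresholdConfig(60.0, {"walking": d0 / 1000}), "walking")
        P2 = P.copy()
        P2[7] += 100
        bumped = ga2sfca(*build(S, P2, D, d0)[:3], ThresholdConfig(60.0, {"walking": d0 / 1000}), "walking")
        assert (bumped.to_numpy() <= base.to_numpy() + 1e-15).all()


class TestEuclideanProvider:
    def test_distances_scale_with_detour_factor(self):
        from greenaccess import build_hex_grid
        grid = build_hex_grid((0, 0, 2000, 2000), 500.0)
        sp = SupplyPoint(0, 0, grid.cells[0].centroid, 10.0)
        od1 = euclidean_provider([sp], grid, 1.0)
        od14 = euclidean_provider([sp], grid, 1.4)
        assert od1.distance(0, grid.cells[0].cell_id) == 0.0
        cid = grid.cells[3].cell_id
        assert od14.distance(0, cid) == pytest.approx(1.4 * od1.distance(0, cid))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            ODMatrix("walking", np.array([[-1.0]]), [0], [0])


class TestOverlayAndGrading:
    def test_convexity_with_observed_shares(self):
        shares = ModeShares(0.0906, 0.1841, 0.7253)
        idx = pd.Index([0, 1], name="cell_id")
        per_mode = {m: pd.Series([1.0, 2.0], index=idx) for m in ("walking", "cycling", "driving")}
        c = comprehensive_accessibility(per_mode, shares)
        np.testing.assert_allclose(c.to_numpy(), [1.0, 2.0])

    def test_degenerate_shares_select_single_mode(self):
        shares = ModeShares(1.0, 0.0, 0.0)
        idx = pd.Index([0], name="cell_id")
        per_mode = {"walking": pd.Series([3.0], index=idx),
                    "cycling": pd.Series([9.0], index=idx),
                    "driving": pd.Series([7.0], index=idx)}
        assert comprehensive_accessibility(per_mode, shares).iloc[0] == 3.0

    def test_weighted_overlay_arithmetic(self):
        shares = ModeShares(0.0906, 0.1841, 0.7253)
        idx = pd.Index([0], name="cell_id")
        per_mode = {"walking": pd.Series([2.0], index=idx),
                    "cycling": pd.Series([0.0], index=idx),
                    "driving": pd.Series([0.0], index=idx)}
        assert comprehensive_accessibility(per_mode, shares).iloc[0] == pytest.approx(0.1812)

    def test_mismatched_cell_sets_rejected(self):
        shares = ModeShares(0.5, 0.25, 0.25)
        per_mode = {"walking": pd.Series([1.0], index=pd.Index([0])),
                    "cycling": pd.Series([1.0], index=pd.Index([1])),
                    "driving": pd.Series([1.0], index=pd.Index([0]))}
        with pytest.raises(ValueError):
            comprehensive_accessibility(per_mode, shares)

    def test_minmax_normalization(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0.0, 0.5, 1.0])
        np.testing.assert_allclose(minmax_normalize([5, 5]), [0.0, 0.0])

    def test_geometric_breaks_closed_form(self):
        breaks = geometric_interval_breaks(np.array([0.0, 1.0]), k=5, ratio=2.0)
        np.testing.assert_allclose(breaks, [1 / 31, 3 / 31, 7 / 31, 15 / 31], rtol=1e-12)
        # class widths double
        edges = np.concatenate([[0.0], breaks, [1.0]])
        widths = np.diff(edges)
        np.testing.assert_allclose(widths[1:] / widths[:-1], 2.0, rtol=1e-12)

    def test_two_class_break(self):
        b = geometric_interval_breaks(np.array([0.0, 3.0]), k=2, ratio=2.0)
        np.testing.assert_allclose(b, [3.0 / 3.0])

    def test_grades_partition_and_edges(self):
        scores = np.array([0.0, 1 / 31, 0.5, 1.0])
        breaks = geometric_interval_breaks(np.array([0.0, 1.0]), 5, 2.0)
        g = grade(scores, breaks)
        assert g[0] == 1          # minimum in the lowest class
        assert g[1] == 2          # break value goes to the upper class
        assert g[-1] == 5         # maximum in the highest class
        assert set(g) <= {1, 2, 3, 4, 5}

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    def test_grading_is_monotone_in_score(self, scores):
        s = np.asarray(scores)
        breaks = geometric_interval_breaks(np.array([0.0, 1.0]), 5, 2.0)
        g = grade(s, breaks)
        order = np.argsort(s, kind="stable")
        assert (np.diff(g[order]) >= 0).all()

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            geometric_interval_breaks(np.array([0.0, 1.0]), 5, 1.0)
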