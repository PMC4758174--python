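"""Log-distance matrix and the twelve connectivity definitions."""

import numpy as np
import pytest

from nestnet.connectivity import (
    NestSite,
    RegistryError,
    build_all_connectivity,
    build_connectivity,
    connectivity_definitions,
    get_definition,
    log_distance_matrix,
    route_connected,
    straight_line_connected,
)
from nestnet.landscape import HabitatRaster, compute_mcp

from conftest import make_random_raster

#: Relaxing any constraint never disconnects a pair.
NESTING_ORDER = (
    [("C1", "C2"), ("C1", "C3"), ("C2", "C4"), ("C3", "C4"),
     ("C3", "C5"), ("C4", "C6"), ("C5", "C6")]
    + [("C1g", "C2g"), ("C1g", "C3g"), ("C2g", "C4g"), ("C3g", "C4g"),
       ("C3g", "C5g"), ("C4g", "C6g"), ("C5g", "C6g")]
    + [(x, x + "g") for x in ("C1", "C2", "C3", "C4", "C5", "C6")]
)


def big_hr():
    return compute_mcp([(-1e4, -1e4), (1e5, -1e4), (1e5, 1e5), (-1e4, 1e5)])


class TestLogDistanceMatrix:
    def test_coincident_nests(self):
        nests = [NestSite("a", 10, 10), NestSite("b", 10, 10)]
        D = log_distance_matrix(nests)
        assert D[0, 1] == 0.0 and D[1, 0] == 0.0

    def test_inverse_of_transform(self):
        d = np.e - 1.0
        nests = [NestSite("a", 0, 0), NestSite("b", d, 0)]
        assert log_distance_matrix(nests)[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        nests = [NestSite(f"n{i}", *rng.uniform(0, 1000, 2)) for i in range(10)]
        D = log_distance_matrix(nests)
        for i in range(10):
            for j in range(10):
                d = np.hypot(nests[i].x - nests[j].x, nests[i].y - nests[j].y)
                expected = 0.0 if i == j else np.log(d + 1.0)
                assert D[i, j] == pytest.approx(expected, abs=1e-12)


class TestRegistry:
    def test_exactly_twelve_definitions(self):
        defs = connectivity_definitions()
        assert len(defs) == 12
        gapless = [d for d in defs.values() if d.max_gap == 0]
        gapped = [d for d in defs.values() if d.max_gap == 50.0]
        assert len(gapless) == len(gapped) == 6

    def test_definition_table(self):
        c1 = get_definition("C1")
        assert c1.straight_line and c1.restrict_to_home_range and c1.max_gap == 0
        c6g = get_definition("C6g")
        assert not c6g.straight_line and not c6g.restrict_to_home_range
        assert c6g.max_gap == 50.0
        assert len(c6g.allowed_classes) == 2

    def test_unknown_name_lists_valid(self):
        with pytest.raises(RegistryError, match="C1g"):
            get_definition("C99")


class TestStraightLine:
    def test_contiguous_h1_connected_under_all(self):
        raster = HabitatRaster(grid=np.full((30, 30), 1), resolution=25.0)
        a, b = NestSite("a", 100, 100), NestSite("b", 600, 500)
        hr = big_hr()
        for name in connectivity_definitions():
            C = build_connectivity([a, b], raster, hr, name)
            assert C[0, 1] == 1, name

    def test_wide_water_band_blocks_all(self):
        # 100 m water band (4 cells) across the middle: gap > 50 m
        grid = np.full((30, 30), 1)
        grid[13:17, :] = 5
        raster = HabitatRaster(grid=grid, resolution=25.0)
        a = NestSite("a", 350, 100)   # south of the band
        b = NestSite("b", 350, 700)   # north of the band
        hr = big_hr()
        for name in connectivity_definitions():
            C = build_connectivity([a, b], raster, hr, name)
            assert C[0, 1] == 0, name

    def test_agrees_with_dense_sampling_oracle(self, rng):
        # the exact cell-traversal decomposition must agree with brute-force
        # dense resampling (0.1 m step, so quantization is far below any
        # gap-threshold ambiguity at this seed)
        hr = big_hr()
        for _ in range(10):
            raster = make_random_raster(rng, n=30)
            a = NestSite("a", *rng.uniform(50, 700, 2))
            b = NestSite("b", *rng.uniform(50, 700, 2))
            for name in ("C1", "C2", "C1g", "C2g"):
                defn = get_definition(name)
                got = straight_line_connected(a, b, raster, defn, hr)
                oracle = straight_line_connected(a, b, raster, defn, hr, step=0.1)
                assert got == oracle, name


class TestRouteConnected:
    def test_l_corridor_contrast(self):
        # H1 corridor in an L-shape; straight line crosses urban, free route ok.
        grid = np.full((20, 20), 3)
        grid[18, :] = 1    # bottom row corridor
        grid[:, 18] = 1    # right column corridor
        raster = HabitatRaster(grid=grid, resolution=25.0)
        a = NestSite("a", 40, 30)     # bottom-left, in H1
        b = NestSite("b", 462, 470)   # upper-right, in H1
        hr = big_hr()
        assert not straight_line_connected(a, b, raster, get_definition("C1"), hr)
        assert route_connected(a, b, raster, get_definition("C3"), hr)

    def test_islands_gap_contrast(self):
        # two H1 islands separated by a 50 m unsuitable strip (2 cells)
        grid = np.full((20, 20), 4)
        grid[:, :6] = 1
        grid[:, 8:] = 1
        raster = HabitatRaster(grid=grid, resolution=25.0)
        a = NestSite("a", 100, 250)
        b = NestSite("b", 400, 250)
        assert not route_connected(a, b, raster, get_definition("C5"))
        assert route_connected(a, b, raster, get_definition("C5g"))

    def test_single_nest_zero_matrix(self):
        raster = HabitatRaster(grid=np.full((5, 5), 1), resolution=25.0)
        C = build_connectivity([NestSite("a", 50, 50)], raster, None, "C5")
        assert C.shape == (1, 1) and C[0, 0] == 0

    def test_matches_flood_fill_oracle(self, rng):
        hr = None
        for trial in range(6):
            raster = make_random_raster(rng, n=25)
            nests = [NestSite(f"n{i}", *rng.uniform(30, 580, 2)) for i in range(4)]
            for name in ("C5", "C6", "C5g", "C6g"):
                defn = get_definition(name)
                C = build_connectivity(nests, raster, hr, name)
                for i in range(4):
                    for j in range(i + 1, 4):
                        oracle = flood_fill_connected(
                            nests[i], nests[j], raster, defn
                        )
                        assert C[i, j] == int(oracle), (trial, name, i, j)


def flood_fill_connected(a, b, raster, defn):
    """Brute-force BFS oracle over the same node/edge rule: allowed cells,
    8-neighbour edges, gap-jump edges by pairwise center distance."""
    from collections import deque

    codes = {int(c) for c in defn.allowed_classes}
    n_r, n_c = raster.grid.shape
    allowed = [
        (r, c) for r in range(n_r) for c in range(n_c)
        if int(raster.grid[r, c]) in codes
    ]
    allowed_set = set(allowed)
    centers = {rc: raster.cell_center(*rc) for rc in allowed}
    step = raster.resolution / 5.0
    reach = defn.max_gap + raster.resolution * np.sqrt(2.0) + step

    def neighbours(rc):
        r, c = rc
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and (r + dr, c + dc) in allowed_set:
                    out.append((r + dr, c + dc))
        if defn.max_gap > 0:
            x0, y0 = centers[rc]
            for other in allowed:
                if other != rc and other not in out:
                    x1, y1 = centers[other]
                    if np.hypot(x1 - x0, y1 - y0) <= reach:
                        out.append(other)
        return out

    def attach(nest):
        out = set()
        rc = raster.cell_at(nest.x, nest.y)
        if rc in allowed_set:
            out.add(rc)
        if defn.max_gap > 0:
            glide = defn.max_gap + raster.resolution * np.sqrt(2.0) / 2.0 + 1e-9
            for o in allowed:
                if np.hypot(centers[o][0] - nest.x, centers[o][1] - nest.y) <= glide:
                    out.add(o)
        return out

    if np.hypot(b.x - a.x, b.y - a.y) <= defn.max_gap:
        return True  # single direct glide
    start, goal = attach(a), attach(b)
    if not start or not goal:
        return False
    seen, queue = set(start), deque(start)
    while queue:
        cur = queue.popleft()
        if cur in goal:
            return True
        for nb in neighbours(cur):
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return bool(goal & seen)


class TestInvariants:
    def test_nesting_partial_order(self, rng):
        hr_pts = np.array([(50, 50), (700, 50), (700, 700), (50, 700)])
        for _ in range(5):
            raster = make_random_raster(rng, n=30)
            nests = [NestSite(f"n{i}", *rng.uniform(80, 650, 2)) for i in range(4)]
            hr = compute_mcp(hr_pts)
            mats = build_all_connectivity(nests, raster, hr)
            for loose, tight in NESTING_ORDER:
                assert not np.any(mats[loose] > mats[tight]), (loose, tight)

    def test_symmetric_binary(self, rng):
        raster = make_random_raster(rng, n=20)
        nests = [NestSite(f"n{i}", *rng.uniform(50, 450, 2)) for i in range(5)]
        hr = compute_mcp([(0, 0), (500, 0), (500, 500), (0, 500)])
        for name, C in build_all_connectivity(nests, raster, hr).items():
            assert np.array_equal(C, C.T), name
            assert set(np.unique(C)).issubset({0, 1}), name
            assert np.all(np.diag(C) == 0), name

    def test_straight_implies_route(self, rng):
        hr = compute_mcp([(0, 0), (700, 0), (700, 700), (0, 700)])
        for _ in range(5):
            raster = make_random_raster(rng, n=30)
            a = NestSite("a", *rng.uniform(50, 650, 2))
            b = NestSite("b", *rng.uniform(50, 650, 2))
            for s_name, r_name in (("C1", "C3"), ("C2", "C4"), ("C1g", "C3g"), ("C2g", "C4g")):
                if straight_line_connected(a, b, raster, get_definition(s_name), hr):
                    assert route_connected(a, b, raster, get_definition(r_name), hr), (s_name, r_name)

    def test_all_land_one_landmass_connected(self):
        grid = np.full((15, 15), 2)
        grid[0, :] = 1
        raster = HabitatRaster(grid=grid, resolution=25.0)
        a, b = NestSite("a", 30, 30), NestSite("b", 340, 360)
        assert route_connected(a, b, raster, get_definition("C6"))
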