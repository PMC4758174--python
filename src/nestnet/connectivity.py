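"""Inter-nest distance and habitat-connectivity matrices.

For each radio-tracked individual the nest network is summarized by two
pairwise matrices over its ``n`` daytime nest sites:

* ``D`` — log-transformed Euclidean distance, ``D_ij = log(d_ij + 1 m)``;
* ``C`` — a binary connectivity indicator under one of twelve alternative
  definitions of what it means for two nests to be "connected by habitat".

The twelve definitions cross three binary choices with a gap allowance:

=====  ===============  =============  ==================  ========
name   habitat allowed  route shape    restricted to HR    max gap
=====  ===============  =============  ==================  ========
C1     H1               straight line  yes                 0 m
C2     H1 + H2          straight line  yes                 0 m
C3     H1               free route     yes                 0 m
C4     H1 + H2          free route     yes                 0 m
C5     H1               free route     no                  0 m
C6     H1 + H2          free route     no                  0 m
C1g..  as above                                            50 m
=====  ===============  =============  ==================  ========

The 50 m gap tolerance of the ``g`` variants reflects the treeless distance
a flying squirrel can cross in a single glide.  Free routes are evaluated on
the raster grid: allowed cells are nodes, 8-neighbour adjacency gives edges,
and under a positive gap tolerance additional "gap-jump" edges join allowed
cells whose centers are close enough that the intervening gap is glidable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .landscape import HabitatClass, HabitatRaster, HomeRangePolygon

GAP_CROSSING_THRESHOLD = 50.0  # m; glidable treeless gap


class RegistryError(KeyError):
    pass


class OutOfExtentError(ValueError):
    pass


@dataclass(frozen=True)
class NestSite:
    nest_id: str
    x: float
    y: float
    nest_type: str = "cavity"  # cavity | twig | box | building

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("nest coordinates must be finite")
        if self.nest_type not in ("cavity", "twig", "box", "building"):
            raise ValueError(f"unknown nest_type {self.nest_type!r}")


@dataclass(frozen=True)
class ConnectivityDefinition:
    name: str
    allowed_classes: frozenset[HabitatClass]
    straight_line: bool
    restrict_to_home_range: bool
    max_gap: float


def _make_registry() -> dict[str, ConnectivityDefinition]:
    h1 = frozenset({HabitatClass.H1})
    h12 = frozenset({HabitatClass.H1, HabitatClass.H2})
    base = {
        "C1": (h1, True, True),
        "C2": (h12, True, True),
        "C3": (h1, False, True),
        "C4": (h12, False, True),
        "C5": (h1, False, False),
        "C6": (h12, False, False),
    }
    reg = {}
    for name, (classes, straight, restricted) in base.items():
        reg[name] = ConnectivityDefinition(name, classes, straight, restricted, 0.0)
        gname = name + "g"
        reg[gname] = ConnectivityDefinition(
            gname, classes, straight, restricted, GAP_CROSSING_THRESHOLD
        )
    return reg


_REGISTRY = _make_registry()


def connectivity_definitions() -> dict[str, ConnectivityDefinition]:
    """All twelve registered connectivity definitions, keyed by name."""
    return dict(_REGISTRY)


def get_definition(name: str) -> ConnectivityDefinition:
    try:
        return _REGISTRY[name]
    except KeyError:
        valid = ", ".join(sorted(_REGISTRY))
        raise RegistryError(f"unknown connectivity definition {name!r}; valid: {valid}") from None


def log_distance_matrix(nests: list[NestSite]) -> np.ndarray:
    """Pairwise ``log(d_ij + 1 m)`` with a zero diagonal.

    The +1 m offset keeps the transform finite for coincident nests; the
    diagonal is stored as 0 and is masked out of the movement model anyway.
    """
    if len(nests) < 2:
        raise ValueError("need at least 2 nest sites")
    xy = np.array([(s.x, s.y) for s in nests])
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    D = np.log1p(d)
    np.fill_diagonal(D, 0.0)
    return D


def _allowed_mask(
    raster: HabitatRaster, defn: ConnectivityDefinition, hr: HomeRangePolygon | None
) -> np.ndarray:
    """Boolean grid of cells traversable under ``defn``.

    Allowed-ness is a property of the whole cell (class membership, and for
    restricted definitions the cell center lying inside the home range), so
    the straight-line and free-route predicates agree on what counts as gap.
    """
    codes = np.array(sorted(int(c) for c in defn.allowed_classes))
    mask = np.isin(raster.grid, codes)
    if defn.restrict_to_home_range:
        if hr is None:
            raise ValueError(f"definition {defn.name} requires a home-range polygon")
        import shapely

        X, Y = raster.cell_centers()
        inside = shapely.covers(hr.shape, shapely.points(X.ravel(), Y.ravel()))
        mask &= inside.reshape(mask.shape)
    return mask


def _check_extent(raster: HabitatRaster, nest: NestSite) -> None:
    xmin, ymin, xmax, ymax = raster.extent
    if not (xmin <= nest.x < xmax and ymin <= nest.y < ymax):
        raise OutOfExtentError(f"nest {nest.nest_id!r} at ({nest.x}, {nest.y}) outside raster extent")


def _sample_allowed(
    raster: HabitatRaster, allowed: np.ndarray, pts: np.ndarray
) -> np.ndarray:
    """Whether each sample point lies in an allowed cell (outside extent = no)."""
    x0, y0 = raster.origin
    col = np.floor((pts[:, 0] - x0) / raster.resolution).astype(int)
    row = raster.nrows - 1 - np.floor((pts[:, 1] - y0) / raster.resolution).astype(int)
    ok = (0 <= row) & (row < raster.nrows) & (0 <= col) & (col < raster.ncols)
    out = np.zeros(len(pts), dtype=bool)
    out[ok] = allowed[row[ok], col[ok]]
    return out


def _segment_cell_intervals(
    raster: HabitatRaster, a: NestSite, b: NestSite
) -> tuple[np.ndarray, np.ndarray]:
    """Exact arc-length decomposition of the segment a->b over raster cells.

    Returns (midpoints t, interval lengths in m) for the pieces of the
    segment cut by cell boundaries, found by intersecting the segment with
    every grid line it crosses (an exact grid traversal, so gap lengths
    carry no sampling-step artifacts).
    """
    x0, y0 = raster.origin
    res = raster.resolution
    length = float(np.hypot(b.x - a.x, b.y - a.y))
    breaks = [0.0, 1.0]
    if length > 0:
        for (p0, p1, o) in ((a.x, b.x, x0), (a.y, b.y, y0)):
            if p1 != p0:
                k_lo = int(np.ceil((min(p0, p1) - o) / res))
                k_hi = int(np.floor((max(p0, p1) - o) / res))
                for k in range(k_lo, k_hi + 1):
                    t = (o + k * res - p0) / (p1 - p0)
                    if 0.0 < t < 1.0:
                        breaks.append(t)
    t = np.unique(np.asarray(breaks))
    mids = 0.5 * (t[:-1] + t[1:])
    return mids, (t[1:] - t[:-1]) * length


def straight_line_connected(
    a: NestSite,
    b: NestSite,
    raster: HabitatRaster,
    defn: ConnectivityDefinition,
    hr: HomeRangePolygon | None = None,
    *,
    step: float | None = None,
) -> bool:
    """Is the straight segment a->b traversable under ``defn``?

    The segment is decomposed exactly into per-cell arcs; each maximal
    contiguous run of arcs through non-allowed cells is a gap, and the pair
    is connected iff every gap is at most ``defn.max_gap`` (so under
    gapless definitions any positive-length non-allowed arc disconnects).
    Pass ``step`` to use an approximate fixed-step sampling evaluation
    instead (each non-allowed sample then counts as one step of gap).
    """
    if not defn.straight_line:
        raise ValueError(f"{defn.name} is not a straight-line definition")
    _check_extent(raster, a)
    _check_extent(raster, b)
    allowed = _allowed_mask(raster, defn, hr)
    if step is not None:
        length = float(np.hypot(b.x - a.x, b.y - a.y))
        n_steps = max(int(np.ceil(length / step)), 1)
        t = np.linspace(0.0, 1.0, n_steps + 1)
        pts = np.column_stack([a.x + t * (b.x - a.x), a.y + t * (b.y - a.y)])
        ok = _sample_allowed(raster, allowed, pts)
        seg_lengths = np.full(len(ok), float(step))
    else:
        mids, seg_lengths = _segment_cell_intervals(raster, a, b)
        pts = np.column_stack([a.x + mids * (b.x - a.x), a.y + mids * (b.y - a.y)])
        ok = _sample_allowed(raster, allowed, pts)
    if ok.all():
        return True
    gap, worst = 0.0, 0.0
    for good, seg in zip(ok, seg_lengths):
        if good:
            worst = max(worst, gap)
            gap = 0.0
        else:
            gap += seg
    worst = max(worst, gap)
    return bool(worst <= defn.max_gap + 1e-9)


def _components_with_gap_jumps(
    raster: HabitatRaster, allowed: np.ndarray, max_gap: float
) -> np.ndarray:
    """Component label per cell (0 = non-allowed), after merging components
    whose cells lie within gap-jump range of each other."""
    labels, n_comp = ndimage.label(allowed, structure=np.ones((3, 3)))
    if max_gap > 0 and n_comp > 1:
        step = raster.resolution / 5.0
        # Gap-jump reach: the glidable gap plus the grid quantum (a cell
        # diagonal to reach the far cell's center, one sampling step of slack
        # so a straight glide over a max-width gap is never lost to rounding).
        reach = max_gap + raster.resolution * np.sqrt(2.0) + step
        rows, cols = np.nonzero(allowed)
        X, Y = raster.cell_centers()
        centers = np.column_stack([X[rows, cols], Y[rows, cols]])
        cell_labels = labels[rows, cols]
        tree = cKDTree(centers)
        parent = np.arange(n_comp + 1)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in tree.query_pairs(reach):
            li, lj = find(cell_labels[i]), find(cell_labels[j])
            if li != lj:
                parent[lj] = li
        roots = np.array([find(k) for k in range(n_comp + 1)])
        labels = roots[labels]
    return labels


def _attach_nest(
    nest: NestSite,
    raster: HabitatRaster,
    allowed: np.ndarray,
    labels: np.ndarray,
    max_gap: float,
) -> frozenset[int]:
    """Component labels a nest can reach, possibly empty.

    A nest in an allowed cell belongs to that cell's component.  Under a
    positive gap tolerance it additionally reaches every allowed cell within
    glide range (gap plus the half-diagonal between a cell's edge and its
    center), so a nest in a non-allowed cell — an urban building nest, say —
    may attach to several components; under gapless definitions such a nest
    is unconnected to everything.
    """
    row, col = raster.cell_at(nest.x, nest.y)
    out = set()
    if allowed[row, col]:
        out.add(int(labels[row, col]))
    if max_gap > 0:
        rows, cols = np.nonzero(allowed)
        if len(rows):
            X, Y = raster.cell_centers()
            d = np.hypot(X[rows, cols] - nest.x, Y[rows, cols] - nest.y)
            reach = max_gap + raster.resolution * np.sqrt(2.0) / 2.0 + 1e-9
            out.update(int(v) for v in np.unique(labels[rows[d <= reach], cols[d <= reach]]))
    return frozenset(out)


def route_connected(
    a: NestSite,
    b: NestSite,
    raster: HabitatRaster,
    defn: ConnectivityDefinition,
    hr: HomeRangePolygon | None = None,
) -> bool:
    """Is there any (not necessarily straight) traversable route a->b?"""
    if defn.straight_line:
        raise ValueError(f"{defn.name} is a straight-line definition")
    _check_extent(raster, a)
    _check_extent(raster, b)
    if np.hypot(b.x - a.x, b.y - a.y) <= defn.max_gap:
        return True  # a single direct glide, no habitat needed
    allowed = _allowed_mask(raster, defn, hr)
    labels = _components_with_gap_jumps(raster, allowed, defn.max_gap)
    la = _attach_nest(a, raster, allowed, labels, defn.max_gap)
    lb = _attach_nest(b, raster, allowed, labels, defn.max_gap)
    return bool(la & lb)


def build_connectivity(
    nests: list[NestSite],
    raster: HabitatRaster,
    hr: HomeRangePolygon | None,
    definition: str | ConnectivityDefinition,
) -> np.ndarray:
    """Binary n x n connectivity matrix under one definition.

    Symmetric with a zero diagonal (the diagonal is masked by the movement
    model's identity term and never used).
    """
    defn = get_definition(definition) if isinstance(definition, str) else definition
    n = len(nests)
    C = np.zeros((n, n), dtype=int)
    if n <= 1:
        return C
    if defn.straight_line:
        for i in range(n):
            for j in range(i + 1, n):
                C[i, j] = C[j, i] = int(
                    straight_line_connected(nests[i], nests[j], raster, defn, hr)
                )
    else:
        allowed = _allowed_mask(raster, defn, hr)
        labels = _components_with_gap_jumps(raster, allowed, defn.max_gap)
        att = [_attach_nest(s, raster, allowed, labels, defn.max_gap) for s in nests]
        for i in range(n):
            for j in range(i + 1, n):
                direct = (
                    np.hypot(nests[i].x - nests[j].x, nests[i].y - nests[j].y)
                    <= defn.max_gap
                )
                C[i, j] = C[j, i] = int(direct or bool(att[i] & att[j]))
    return C


def build_all_connectivity(
    nests: list[NestSite], raster: HabitatRaster, hr: HomeRangePolygon | None
) -> dict[str, np.ndarray]:
    """All twelve connectivity matrices for one nest network."""
    return {
        name: build_connectivity(nests, raster, hr, defn)
        for name, defn in _REGISTRY.items()
    }
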