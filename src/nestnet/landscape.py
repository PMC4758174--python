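"""Habitat rasters, minimum-convex-polygon home ranges, and composition queries.

The study landscape is classified into five suitability classes for an
arboreal gliding squirrel:

    H1  suitable habitat   (mature spruce-dominated forest; breeding habitat)
    H2  movement habitat   (other forest > 10 m tall)
    H3  urban habitat      (residential areas, roads)
    H4  unsuitable habitat (clear-cuts, fields, sapling stands)
    H5  water bodies

rasterized on a regular 25 m grid.  Home ranges are 100 % minimum convex
polygons (MCP) of relocation fixes.  Composition queries count raster cells
by the cell-center rule: a cell belongs to a region iff its center lies
inside or on the boundary of the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Point, Polygon


class HabitatClass(IntEnum):
    """The five habitat suitability classes, coded 1-5 as in the raster."""

    H1 = 1  # suitable (mature spruce-dominated forest)
    H2 = 2  # movement habitat (other forest > 10 m)
    H3 = 3  # urban
    H4 = 4  # unsuitable (clear-cuts, fields, saplings)
    H5 = 5  # water


#: Classes a squirrel can traverse; water is never an allowed movement class.
LAND_CLASSES = (HabitatClass.H1, HabitatClass.H2, HabitatClass.H3, HabitatClass.H4)


class DegenerateGeometryError(ValueError):
    """Raised when a point set cannot support a convex polygon."""


class EmptyRegionError(ValueError):
    """Raised when a composition query counts zero raster cells."""


@dataclass(frozen=True)
class HabitatRaster:
    """A rectangular single-band habitat raster.

    Grid row 0 is the northernmost row (map convention); ``origin`` is the
    lower-left corner of the lower-left cell, in meters of a planar metric CRS.
    """

    grid: np.ndarray  # (nrows, ncols) of int class codes 1-5
    origin: tuple[float, float] = (0.0, 0.0)
    resolution: float = 25.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.int8)
        if grid.ndim != 2 or grid.size == 0:
            raise ValueError("raster grid must be 2-D and non-empty")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        codes = {int(c) for c in HabitatClass}
        if not set(np.unique(grid)).issubset(codes):
            raise ValueError("raster contains codes outside 1-5")
        object.__setattr__(self, "grid", grid)

    @property
    def nrows(self) -> int:
        return self.grid.shape[0]

    @property
    def ncols(self) -> int:
        return self.grid.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Planar coordinates of the center of cell (row, col)."""
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.resolution
        y = y0 + (self.nrows - row - 0.5) * self.resolution
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized centers: (X, Y) arrays of shape (nrows, ncols)."""
        x0, y0 = self.origin
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = x0 + (cols + 0.5) * self.resolution
        y = y0 + (self.nrows - rows - 0.5) * self.resolution
        return np.meshgrid(x, y)

    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.resolution))
        row = self.nrows - 1 - int(np.floor((y - y0) / self.resolution))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def class_at(self, x: float, y: float) -> HabitatClass:
        row, col = self.cell_at(x, y)
        return HabitatClass(int(self.grid[row, col]))

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.resolution, y0 + self.nrows * self.resolution)


@dataclass(frozen=True)
class HomeRangePolygon:
    """A 100 % MCP home range: convex polygon vertices (CCW) and area in ha."""

    vertices: np.ndarray  # (k, 2) ordered hull vertices
    area_ha: float
    individual_id: str | None = None
    _shape: Polygon = field(repr=False, compare=False, default=None)

    @property
    def shape(self) -> Polygon:
        if self._shape is None:
            object.__setattr__(self, "_shape", Polygon(self.vertices))
        return self._shape

    def contains(self, x: float, y: float) -> bool:
        """Closed-polygon membership: boundary points count as inside."""
        return self.shape.covers(Point(x, y))


def compute_mcp(fixes, individual_id: str | None = None) -> HomeRangePolygon:
    """100 % minimum convex polygon of relocation fixes.

    All fixes are used (no peeling).  Area is reported in hectares
    (1 ha = 10,000 m^2).

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 points are supplied or all points are collinear.
    """
    pts = np.asarray(fixes, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("fixes must be an (n, 2) array of planar points")
    who = f" for individual {individual_id!r}" if individual_id else ""
    if len(pts) < 3:
        raise DegenerateGeometryError(f"MCP needs >= 3 fixes{who}, got {len(pts)}")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull rejects collinear/degenerate input
        raise DegenerateGeometryError(f"fixes are collinear or degenerate{who}") from exc
    verts = pts[hull.vertices]  # CCW order in 2-D
    area_ha = hull.volume / 1e4  # 2-D "volume" is the polygon area in m^2
    return HomeRangePolygon(vertices=verts, area_ha=area_ha, individual_id=individual_id)


def _composition_of_mask(raster: HabitatRaster, inside: np.ndarray) -> dict[HabitatClass, float]:
    total = int(inside.sum())
    if total == 0:
        raise EmptyRegionError("composition query counted zero raster cells")
    props = {}
    for cls in HabitatClass:
        props[cls] = float(np.count_nonzero(raster.grid[inside] == int(cls))) / total
    return props


def composition_in_region(raster: HabitatRaster, region: HomeRangePolygon | Polygon) -> dict[HabitatClass, float]:
    """Habitat-class proportions over cells whose centers fall in ``region``.

    Boundary cell centers count as inside.  Proportions cover all five
    classes and sum to 1 over the counted cells.
    """
    shape = region.shape if isinstance(region, HomeRangePolygon) else region
    X, Y = raster.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    inside = shapely.covers(shape, pts).reshape(raster.grid.shape)
    return _composition_of_mask(raster, inside)


def composition_along_buffer(
    raster: HabitatRaster, path, radius: float = 25.0
) -> dict[HabitatClass, float]:
    """Habitat proportions within a Euclidean buffer of a movement path.

    ``path`` is a sequence of (x, y) points; a single point yields a disc
    buffer.  Default radius 25 m describes fine-scale habitat along bursts.
    """
    if radius <= 0:
        raise ValueError("buffer radius must be positive")
    pts = np.asarray(path, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("path must contain at least one point")
    geom = Point(pts[0]) if len(pts) == 1 else LineString(pts)
    return composition_in_region(raster, geom.buffer(radius, quad_segs=64))


# -- plain-text raster I/O (ESRI ASCII grid dialect) -------------------------

def read_ascii_grid(path: str | Path) -> HabitatRaster:
    """Read a habitat raster from an ESRI ASCII grid text file."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header field {key!r}")
    grid = np.loadtxt(lines[body_start:], dtype=np.int8, ndmin=2)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared nrows/ncols")
    return HabitatRaster(
        grid=grid,
        origin=(header["xllcorner"], header["yllcorner"]),
        resolution=header["cellsize"],
    )


def write_ascii_grid(raster: HabitatRaster, path: str | Path) -> None:
    """Write a habitat raster as an ESRI ASCII grid text file."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.resolution:.6f}\n")
        np.savetxt(fh, raster.grid, fmt="%d")


def write_polygon_csv(polygons: dict[str, HomeRangePolygon], path: str | Path) -> None:
    """Export polygons as a CSV vertex list (id, order, x, y)."""
    import pandas as pd

    rows = []
    for pid, poly in polygons.items():
        for order, (x, y) in enumerate(poly.vertices):
            rows.append({"id": pid, "order": order, "x": x, "y": y})
    pd.DataFrame(rows, columns=["id", "order", "x", "y"]).to_csv(path, index=False)
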