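"""Raster container, plain-text grid I/O, resampling and temporal compositing.

A :class:`Grid` is a 2-D array of values on a regular, axis-aligned,
north-up grid, together with its geotransform, an opaque CRS tag and a
nodata sentinel.  On disk a grid is an ESRI ASCII grid (``.asc``) — a
plain-text interchange format readable by every GIS — with the CRS tag
stored in an optional ``.prj`` sidecar.

Sub-annual indicator series (quarterly leaf-area index, 8-day fractional
vegetation cover and gross primary productivity) are held in a
:class:`GridStack` and collapsed to one annual grid per indicator with the
maximum value composite (MVC): the per-pixel maximum over all slices with a
valid observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridTransform",
    "Grid",
    "GridStack",
    "resample_nearest",
    "max_value_composite",
    "assert_aligned",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: default absolute tolerance on geotransform terms when comparing geometries
TRANSFORM_ATOL = 1e-9

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """North-up affine geotransform.

    ``(x0, y0)`` is the outer corner of the top-left cell; ``dx``/``dy`` are
    strictly positive cell sizes.  The center of cell ``(row, col)`` is
    ``(x0 + (col + 0.5) * dx, y0 - (row + 0.5) * dy)``.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError(f"cell sizes must be strictly positive, got dx={self.dx}, dy={self.dy}")

    def cell_center(self, row, col):
        """Coordinates of one or many cell centers (vectorized)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 - (np.asarray(row) + 0.5) * self.dy
        return x, y

    def approx_equal(self, other: "GridTransform", atol: float = TRANSFORM_ATOL) -> bool:
        return (
            abs(self.x0 - other.x0) <= atol
            and abs(self.y0 - other.y0) <= atol
            and abs(self.dx - other.dx) <= atol
            and abs(self.dy - other.dy) <= atol
        )


@dataclass
class Grid:
    """Single-band raster: values + geotransform + CRS tag + nodata sentinel."""

    values: np.ndarray
    transform: GridTransform
    crs: str = ""
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError(f"grid values must be a non-empty 2-D array, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of observed (non-nodata, finite) cells."""
        m = self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            m &= np.isfinite(self.values)
        return m

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """New grid on the same geometry."""
        return Grid(values=np.asarray(values), transform=self.transform, crs=self.crs,
                    nodata=self.nodata if nodata is None else nodata)

    def same_geometry(self, other: "Grid", atol: float = TRANSFORM_ATOL) -> bool:
        return (
            self.shape == other.shape
            and self.transform.approx_equal(other.transform, atol)
            and self.crs == other.crs
        )


@dataclass
class GridStack:
    """Ordered sub-annual slices of one indicator-year on a shared geometry."""

    slices: list[Grid]
    timestamps: list[int] = field(default_factory=list)
    year: int = 0

    def __post_init__(self) -> None:
        if not self.timestamps:
            self.timestamps = list(range(len(self.slices)))
        if len(self.timestamps) != len(self.slices):
            raise ValueError("one timestamp per slice required")
        if any(b <= a for a, b in zip(self.timestamps, self.timestamps[1:])):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.slices) >= 2 and not assert_aligned(self.slices):
            raise ValueError("stack slices do not share one geometry")

    def __len__(self) -> int:
        return len(self.slices)


def assert_aligned(grids: list[Grid], atol: float = TRANSFORM_ATOL) -> bool:
    """True iff all grids share shape, geotransform (within ``atol``) and CRS.

    Returns a boolean rather than raising so pipeline stages can attach
    stage-specific context to the failure.
    """
    if len(grids) < 2:
        raise ValueError("need at least two grids to compare alignment")
    first = grids[0]
    return all(first.same_geometry(g, atol) for g in grids[1:])


def _nearest_index(coord: np.ndarray, origin: float, step: float, n: int) -> np.ndarray:
    """Index of the source cell whose center is nearest to ``coord`` on one axis.

    Ties (coordinate exactly between two centers) resolve to the smaller
    index.  Out-of-extent coordinates yield -1.
    """
    u = (coord - origin) / step - 0.5  # real-valued index of the nearest-center problem
    idx = np.ceil(u - 0.5).astype(np.int64)  # round half *down* -> smaller index wins ties
    inside = (coord >= origin) & (coord <= origin + n * step)
    idx = np.clip(idx, 0, n - 1)
    return np.where(inside, idx, -1)


def resample_nearest(source: Grid, target_transform: GridTransform, target_shape: tuple[int, int]) -> Grid:
    """Nearest-neighbor resampling of ``source`` onto a target geometry.

    Each output cell takes the value of the source cell whose center is
    nearest the output cell center; equidistant ties pick the smaller row,
    then the smaller column.  Output cells outside the source extent, or
    whose nearest source cell is nodata, are nodata.  The CRSs must match:
    no implicit reprojection.
    """
    nrows, ncols = target_shape
    if nrows < 1 or ncols < 1:
        raise ValueError("target shape must be at least 1x1")

    st = source.transform
    # extent overlap check (outer bounds)
    sx0, sx1 = st.x0, st.x0 + source.shape[1] * st.dx
    sy1, sy0 = st.y0 - source.shape[0] * st.dy, st.y0
    tx0, tx1 = target_transform.x0, target_transform.x0 + ncols * target_transform.dx
    ty1, ty0 = target_transform.y0 - nrows * target_transform.dy, target_transform.y0
    if tx1 <= sx0 or tx0 >= sx1 or ty0 <= sy1 or ty1 >= sy0:
        raise ValueError("target extent does not overlap source extent")

    rows = np.arange(nrows)
    cols = np.arange(ncols)
    xc, yc = target_transform.cell_center(rows[:, None], cols[None, :])
    ci = _nearest_index(xc, st.x0, st.dx, source.shape[1])
    ri = _nearest_index(-yc, -st.y0, st.dy, source.shape[0])  # y decreases with row
    ri, ci = np.broadcast_arrays(ri, ci)

    out = np.full(target_shape, source.nodata, dtype=np.asarray(source.values).dtype)
    ok = (ri >= 0) & (ci >= 0)
    out[ok] = source.values[ri[ok], ci[ok]]
    return Grid(values=out, transform=target_transform, crs=source.crs, nodata=source.nodata)


def resample_to(source: Grid, reference: Grid) -> Grid:
    """Resample ``source`` onto the geometry of ``reference`` (nearest neighbor)."""
    if source.crs != reference.crs:
        raise ValueError(f"CRS mismatch: source {source.crs!r} vs reference {reference.crs!r}; "
                         "reprojection is not supported")
    return resample_nearest(source, reference.transform, reference.shape)


def max_value_composite(stack: GridStack) -> Grid:
    """Annual maximum value composite of a sub-annual stack.

    Per pixel: the maximum over slices with a valid observation; nodata only
    where every slice is nodata.
    """
    if len(stack) == 0:
        raise ValueError("cannot composite an empty stack")
    first = stack.slices[0]
    best = np.full(first.shape, -np.inf)
    any_valid = np.zeros(first.shape, dtype=bool)
    for sl in stack.slices:
        m = sl.valid_mask()
        np.maximum(best, np.where(m, sl.values, -np.inf), out=best)
        any_valid |= m
    out = np.where(any_valid, best, first.nodata)
    return first.with_values(out)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII grid (requires square cells).

    Values are written with 17 significant digits so float64 grids round-trip
    bit-exactly.  The CRS tag, when nonempty, goes to a ``.prj`` sidecar.
    """
    path = Path(path)
    t = grid.transform
    if not math.isclose(t.dx, t.dy, rel_tol=0, abs_tol=TRANSFORM_ATOL):
        raise ValueError("ASCII grid requires square cells")
    nrows, ncols = grid.shape
    yll = t.y0 - nrows * t.dy
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {t.x0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {t.dx!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.17g}" for v in row))
            fh.write("\n")
    if grid.crs:
        path.with_suffix(".prj").write_text(grid.crs + "\n")


def read_ascii_grid(path: str | Path, dtype=np.float64) -> Grid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any GIS)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=dtype))
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    values = np.vstack(rows)
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: data block {values.shape} does not match header ({nrows}, {ncols})")
    transform = GridTransform(
        x0=header["xllcorner"], y0=header["yllcorner"] + nrows * cell, dx=cell, dy=cell
    )
    prj = path.with_suffix(".prj")
    crs = prj.read_text().strip() if prj.exists() else ""
    return Grid(values=values, transform=transform, crs=crs,
                nodata=header.get("nodata_value", DEFAULT_NODATA))
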