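"""Inverse-distance-weighted interpolation onto regular grids.

IDW is the deterministic interpolator used to turn per-sample index values
(Nemerow P_N, Hakanson RI, raw concentrations) into continuous surfaces:
value(g) = sum(w_i v_i) / sum(w_i) with w_i = d_i^-power, exact at data
points and bounded by the input value range.  Classification is applied to
the interpolated surface (classify after interpolating), so legend breaks
cut a continuous field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import ClassificationScale, ValidationError


@dataclass(frozen=True)
class GridSpec:
    """Regular grid geometry: lower-left origin, square cells, nx x ny."""

    origin: tuple[float, float]
    cell_size: float
    nx: int
    ny: int

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return xs, ys


@dataclass(frozen=True)
class RasterField:
    """An interpolated (or classified) field on a regular grid.

    ``values`` has shape (ny, nx) with row 0 at the grid's southern edge.
    """

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray | None = None
    labels: tuple[str, ...] | None = None   # set for categorical fields

    def to_xyz(self) -> pd.DataFrame:
        """Plain-text XYZ export: one row per cell center."""
        xs, ys = self.grid.cell_centers()
        xx, yy = np.meshgrid(xs, ys)
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "value": self.values.ravel()}
        )

    def to_ascii_grid(self, path, nodata: float = -9999.0) -> None:
        """ESRI ASCII grid export (GeoTIFF-compatible plain text)."""
        values = self.values.astype(float).copy()
        if self.mask is not None:
            values[~self.mask] = nodata
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"ncols {self.grid.nx}\n")
            fh.write(f"nrows {self.grid.ny}\n")
            fh.write(f"xllcorner {self.grid.origin[0]}\n")
            fh.write(f"yllcorner {self.grid.origin[1]}\n")
            fh.write(f"cellsize {self.grid.cell_size}\n")
            fh.write(f"NODATA_value {nodata}\n")
            for row in values[::-1]:  # ASCII grids run north to south
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def default_grid(points_xy: np.ndarray, n: int = 100, padding: float = 0.05) -> GridSpec:
    """n x n grid over the samples' bounding box padded by ``padding`` per side."""
    xy = np.asarray(points_xy, dtype=float)
    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    dx, dy = xmax - xmin, ymax - ymin
    if dx == 0 and dy == 0:
        dx = dy = 1.0
    xmin -= padding * dx
    ymin -= padding * dy
    span = max(dx * (1 + 2 * padding), dy * (1 + 2 * padding))
    cell = span / n
    return GridSpec(origin=(xmin, ymin), cell_size=cell, nx=n, ny=n)


def idw_interpolate(
    points,
    grid: GridSpec | None = None,
    power: float = 2.0,
    max_neighbors: int | None = None,
    eps: float | None = None,
) -> RasterField:
    """IDW interpolation of scattered (x, y, value) points onto a grid.

    Parameters
    ----------
    points
        Sequence of (x, y, value) triples or an (n, 3) array.
    grid
        Target geometry; default 100 x 100 over the 5%-padded bounding box.
    power
        Distance-decay exponent (> 0); as power grows the surface converges
        to nearest-neighbor assignment.
    max_neighbors
        Use only the k nearest samples per cell (default: all samples).
    eps
        Coincidence radius: a cell within ``eps`` of a sample returns that
        sample's value exactly.  Default 1e-9 times the domain diagonal.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValidationError("points must be a non-empty (n, 3) array of x, y, value")
    if power <= 0:
        raise ValidationError("power must be > 0")
    xy, values = pts[:, :2], pts[:, 2]
    if grid is None:
        grid = default_grid(xy)
    if eps is None:
        span = xy.max(axis=0) - xy.min(axis=0)
        diag = float(np.hypot(*span))
        eps = 1e-9 * (diag if diag > 0 else 1.0)

    xs, ys = grid.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    cells = np.column_stack([xx.ravel(), yy.ravel()])
    # (cells, samples) distance matrix; survey sizes keep this small.
    d = np.sqrt(((cells[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))

    if max_neighbors is not None and max_neighbors < len(xy):
        keep = np.argsort(d, axis=1)[:, :max_neighbors]
        rows = np.arange(len(cells))[:, None]
        mask = np.zeros_like(d, dtype=bool)
        mask[rows, keep] = True
    else:
        mask = np.ones_like(d, dtype=bool)

    with np.errstate(divide="ignore"):
        w = np.where(mask, d**-power, 0.0)
    coincident = d <= eps
    out = np.empty(len(cells))
    hit = coincident.any(axis=1)
    if hit.any():
        first = coincident[hit].argmax(axis=1)
        out[hit] = values[first]
    free = ~hit
    if free.any():
        wf = w[free]
        out[free] = (wf @ values) / wf.sum(axis=1)
    return RasterField(grid=grid, values=out.reshape(grid.ny, grid.nx))


def classify_field(
    field: RasterField, scale: ClassificationScale
) -> tuple[RasterField, pd.Series]:
    """Cell-wise classification of a continuous field.

    Returns the categorical field (ordinal class codes, with ``labels``)
    and the percentage frequency of each occurring class.
    """
    flat = field.values.ravel()
    codes = np.array([scale.index(v) for v in flat]).reshape(field.values.shape)
    counts = pd.Series(codes.ravel()).value_counts().sort_index()
    freq = 100.0 * counts / counts.sum()
    freq.index = [scale.labels[i] for i in freq.index]
    freq.index.name = scale.name
    categorical = RasterField(
        grid=field.grid, values=codes, mask=field.mask, labels=scale.labels
    )
    return categorical, freq


def plot_field(field: RasterField, samples_xy=None, ax=None, title=None, cmap="viridis"):
    """Render a field with optional sample-point overlay (returns the Axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    xs, ys = field.grid.cell_centers()
    extent = (
        field.grid.origin[0],
        field.grid.origin[0] + field.grid.nx * field.grid.cell_size,
        field.grid.origin[1],
        field.grid.origin[1] + field.grid.ny * field.grid.cell_size,
    )
    im = ax.imshow(field.values, origin="lower", extent=extent, cmap=cmap, aspect="equal")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if samples_xy is not None:
        xy = np.asarray(samples_xy, dtype=float)
        ax.plot(xy[:, 0], xy[:, 1], "k.", ms=4)
    if title:
        ax.set_title(title)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    return ax
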