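"""Spatial covariate surfaces on regular metre grids.

Two covariate families drive the settlement analysis: a kernel-density
"habitat attractiveness" surface built from cumulative nest locations
(leaving out the focal site-year so the covariate carries no same-year
social information), and exponential distance-decay proximity surfaces
around song-playback stations.  Both live on the same 10 m planar grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

DEFAULT_CELL = 10.0
DEFAULT_BANDWIDTH = 50.0
DEFAULT_DECAY = 200.0


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window in metres."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("window dimensions must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0)
            & (x < self.x0 + self.width)
            & (y >= self.y0)
            & (y < self.y0 + self.height)
        )


@dataclass
class GridRaster:
    """Covariate surface on a regular grid.

    ``values[i, j]`` is the cell whose centre is at
    ``(x0 + (j + 0.5) * cell, y0 + (i + 0.5) * cell)``; row index runs
    south to north.  Cells are half-open ``[x, x + cell)`` so every point
    strictly inside the extent belongs to exactly one cell.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("raster values must be finite")

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the gridded area."""
        return (
            self.x0,
            self.x0 + self.ncol * self.cell,
            self.y0,
            self.y0 + self.nrow * self.cell,
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened x and y coordinates of all cell centres (row-major)."""
        xs = self.x0 + (np.arange(self.ncol) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.nrow) + 0.5) * self.cell
        xg, yg = np.meshgrid(xs, ys)
        return xg.ravel(), yg.ravel()

    def aligned_with(self, other: "GridRaster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell, other.cell)
        )


def grid_for_window(window: Window, cell: float = DEFAULT_CELL) -> tuple[int, int]:
    """Number of (rows, cols) of `cell`-sized cells covering `window`."""
    ncol = int(np.ceil(window.width / cell - 1e-9))
    nrow = int(np.ceil(window.height / cell - 1e-9))
    return nrow, ncol


def sample_raster(raster: GridRaster, x, y) -> np.ndarray | float:
    """Value of the cell containing each point (nearest-cell rule).

    Raises ``ValueError`` for any point outside the gridded extent, even
    marginally: covariates are undefined off the window.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0
    col = np.floor((np.atleast_1d(x) - raster.x0) / raster.cell).astype(int)
    row = np.floor((np.atleast_1d(y) - raster.y0) / raster.cell).astype(int)
    bad = (col < 0) | (col >= raster.ncol) | (row < 0) | (row >= raster.nrow)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"point ({np.atleast_1d(x)[i]}, {np.atleast_1d(y)[i]}) lies outside "
            f"the raster extent {raster.extent}"
        )
    out = raster.values[row, col]
    return float(out[0]) if scalar else out


def build_attractiveness_raster(
    nests: pd.DataFrame,
    window: Window,
    exclude: tuple[str, int] | None = None,
    bandwidth: float = DEFAULT_BANDWIDTH,
    cell: float = DEFAULT_CELL,
    floor: float | None = None,
) -> GridRaster:
    """Kernel-density habitat-attractiveness surface from nest records.

    Sums isotropic Gaussian kernels (sd = `bandwidth` metres) centred on
    every nest except those from the excluded (site, year), evaluated at
    cell centres on the intensity scale (expected nests per m^2, so cell
    area times the summed surface recovers the nest count for interior
    nests).  A small positive floor is added so that downstream powers
    H**alpha are defined for every cell; by default it is 1e-6 times the
    maximum cell value.

    Parameters
    ----------
    nests
        Table with at least ``x``, ``y`` and, when `exclude` is used,
        ``site`` and ``year`` columns.
    exclude
        ``(site, year)`` whose nests are dropped before estimation —
        the leave-one-site-year-out rule that keeps the covariate free
        of same-year social information.
    """
    nrow, ncol = grid_for_window(window, cell)
    if exclude is not None:
        site, year = exclude
        keep = ~((nests["site"] == site) & (nests["year"] == int(year)))
        nests = nests.loc[keep]
    xs = nests["x"].to_numpy(dtype=float)
    ys = nests["y"].to_numpy(dtype=float)

    cx = window.x0 + (np.arange(ncol) + 0.5) * cell
    cy = window.y0 + (np.arange(nrow) + 0.5) * cell
    if len(xs) == 0:
        values = np.zeros((nrow, ncol))
    else:
        # separable Gaussian: exp(-dx^2/2s^2) outer exp(-dy^2/2s^2)
        s2 = bandwidth**2
        kx = np.exp(-((cx[None, :] - xs[:, None]) ** 2) / (2 * s2))
        ky = np.exp(-((cy[None, :] - ys[:, None]) ** 2) / (2 * s2))
        values = np.einsum("nr,nc->rc", ky, kx) / (2 * np.pi * s2)
    if floor is None:
        floor = 1e-6 * values.max() if values.max() > 0 else 1e-6
    return GridRaster(window.x0, window.y0, cell, values + floor)


def build_proximity_raster(
    stations: pd.DataFrame,
    window: Window,
    subset: str = "all",
    decay: float = DEFAULT_DECAY,
    cell: float = DEFAULT_CELL,
) -> GridRaster:
    """Distance-decay proximity surface exp(-d/decay) to playback stations.

    `d` is the distance from each cell centre to the nearest station
    midpoint (the midpoint of the paired speakers is the simulated
    territory centre).  ``subset='low_only'`` keeps only stations with
    ``song_rate_class == 'low'`` (males of low apparent competitive
    ability); ``'all'`` keeps every station.
    """
    if subset not in ("all", "low_only"):
        raise ValueError(f"unknown subset {subset!r}")
    if subset == "low_only":
        stations = stations.loc[stations["song_rate_class"] == "low"]
    if len(stations) == 0:
        raise ValueError("no playback stations left after subsetting")
    mids = station_midpoints(stations)
    nrow, ncol = grid_for_window(window, cell)
    cx = window.x0 + (np.arange(ncol) + 0.5) * cell
    cy = window.y0 + (np.arange(nrow) + 0.5) * cell
    xg, yg = np.meshgrid(cx, cy)
    d, _ = cKDTree(mids).query(np.column_stack([xg.ravel(), yg.ravel()]))
    return GridRaster(window.x0, window.y0, cell, np.exp(-d / decay).reshape(nrow, ncol))


def station_midpoints(stations: pd.DataFrame) -> np.ndarray:
    """(n, 2) array of speaker-pair midpoints ('territory centres')."""
    if {"ax", "ay", "bx", "by"} <= set(stations.columns):
        mx = (stations["ax"].to_numpy(float) + stations["bx"].to_numpy(float)) / 2
        my = (stations["ay"].to_numpy(float) + stations["by"].to_numpy(float)) / 2
    else:  # already midpoint form
        mx = stations["x"].to_numpy(float)
        my = stations["y"].to_numpy(float)
    return np.column_stack([mx, my])


def raster_correlation(
    a: GridRaster, b: GridRaster, mask: np.ndarray | None = None
) -> tuple[float, float, float, int]:
    """Pearson correlation between two aligned rasters with a Fisher-z 95% CI.

    Used to quantify how stable the leave-one-year-out attractiveness
    surface is across years.  Returns ``(r, ci_low, ci_high, n)``.
    """
    if not a.aligned_with(b):
        raise ValueError("rasters are not on identical grids")
    av = a.values.ravel()
    bv = b.values.ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        av, bv = av[m], bv[m]
    n = av.size
    if n < 4:
        raise ValueError("need at least 4 cells to estimate a correlation")
    res = stats.pearsonr(av, bv)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), float(ci.low), float(ci.high), int(n)


def write_ascii_grid(raster: GridRaster, path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (rows north to south, as the format requires)."""
    header = (
        f"ncols {raster.ncol}\n"
        f"nrows {raster.nrow}\n"
        f"xllcorner {raster.x0}\n"
        f"yllcorner {raster.y0}\n"
        f"cellsize {raster.cell}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values[::-1], fmt="%.10g")


def read_ascii_grid(path) -> GridRaster:
    """Read an ESRI ASCII grid into a :class:`GridRaster`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline().split()
            if len(line) != 2 or not line[0][0].isalpha():
                break
            header[line[0].lower()] = float(line[1])
            pos = fh.tell()
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    cell = header.get("cellsize", DEFAULT_CELL)
    x0 = header.get("xllcorner", 0.0)
    y0 = header.get("yllcorner", 0.0)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
        if np.isnan(values).any():
            raise ValueError("raster contains NODATA cells inside the window")
    return GridRaster(x0, y0, cell, values[::-1])
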