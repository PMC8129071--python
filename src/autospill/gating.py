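"""Automated forward/side-scatter gating of the cell or bead population.

The gate isolates the scatter population of interest (cells or beads) from
debris and other contamination without manual input, via a fixed multi-step
procedure:

1. trim extreme scatter values (1% / 99% empirical quantiles per axis);
2. estimate the 2-d event density on a regular grid with a wide kernel
   (bandwidth factor 3), smooth with a moving average (window 3), locate the
   density maxima, and tessellate events by nearest maximum;
3. select the target maximum, ignoring debris peaks that sit below 5% of the
   trimmed range on BOTH scatter axes;
4. bound a rectangular region around the target tile (median +- 3 x mean
   absolute deviation per axis);
5. repeat density estimation inside the region (bandwidth factor 2, window 2)
   and tessellate again to split the target peak from close neighbors;
6. estimate the density once more on the winning tile (bandwidth factor 1),
   keep events whose density exceeds 33% of the density range within the
   tile, and gate on the convex hull of the kept events.

All steps are deterministic; ties in maxima ordering are broken by lower FSC
then lower SSC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import convolve2d
from scipy.spatial import ConvexHull, Delaunay
from scipy.spatial.distance import cdist

from .io import AutospillError, EventTable

__all__ = [
    "DensitySurface",
    "GatePolygon",
    "GateResult",
    "GatingConfig",
    "TooFewEventsError",
    "DegenerateRegionError",
    "trim_extremes",
    "estimate_density",
    "find_maxima",
    "tessellate",
    "select_target",
    "bound_region",
    "compute_gate",
]


class TooFewEventsError(AutospillError):
    pass


class DegenerateRegionError(AutospillError):
    pass


@dataclass(frozen=True)
class GatingConfig:
    trim_quantiles: tuple[float, float] = (0.01, 0.99)
    grid_size: int = 100
    bandwidth_factors: tuple[float, float, float] = (3.0, 2.0, 1.0)
    windows: tuple[int, int] = (3, 2)
    debris_range_fraction: float = 0.05
    density_threshold_fraction: float = 0.33
    min_events: int = 100
    min_gated_events: int = 50


@dataclass(frozen=True)
class DensitySurface:
    """2-d kernel density estimate on a regular grid."""

    grid: np.ndarray  # (nx, ny), grid[i, j] = density at (x_coords[i], y_coords[j])
    x_coords: np.ndarray
    y_coords: np.ndarray
    bandwidth_factor: float

    def __post_init__(self) -> None:
        if np.any(self.grid < 0):
            raise ValueError("density must be nonnegative")
        if np.any(np.diff(self.x_coords) <= 0) or np.any(np.diff(self.y_coords) <= 0):
            raise ValueError("grid axes must be strictly increasing")

    def at_points(self, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the density at event coordinates."""
        interp = RegularGridInterpolator(
            (self.x_coords, self.y_coords), self.grid, bounds_error=False, fill_value=0.0
        )
        return interp(points)


@dataclass(frozen=True)
class Maximum:
    location: tuple[float, float]
    density: float
    grid_index: tuple[int, int]


@dataclass(frozen=True)
class GatePolygon:
    """Convex gate polygon in (FSC, SSC) coordinates."""

    vertices: np.ndarray  # (k, 2), ordered counterclockwise

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
            raise ValueError("a gate polygon needs at least 3 (FSC, SSC) vertices")

    def contains(self, points: np.ndarray) -> np.ndarray:
        tri = Delaunay(self.vertices)
        return tri.find_simplex(np.asarray(points, dtype=np.float64)) >= 0


@dataclass(frozen=True)
class GateResult:
    polygon: GatePolygon
    gated: EventTable
    inside_mask: np.ndarray  # over the input events
    target_maximum: tuple[float, float]


def _nrd_bandwidth(v: np.ndarray) -> float:
    # normal reference rule per axis: 1.06 * min(sd, IQR/1.349) * n^(-1/5)
    sd = float(np.std(v, ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        raise DegenerateRegionError("zero variance on a scatter axis")
    return 1.06 * spread * v.size ** (-1.0 / 5.0)


def trim_extremes(
    events: EventTable, quantiles: tuple[float, float] = (0.01, 0.99)
) -> EventTable:
    """Drop events outside the per-axis [1%, 99%] scatter quantile interval."""
    if events.n_events < 100:
        raise TooFewEventsError(
            f"gating needs at least 100 events, got {events.n_events}"
        )
    xy = events.scatter()
    lo, hi = np.quantile(xy, quantiles, axis=0)
    keep = np.all((xy >= lo) & (xy <= hi), axis=1)
    return events.take(keep)


def estimate_density(
    points: np.ndarray,
    bandwidth_factor: float,
    grid_size: int = 100,
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> DensitySurface:
    """Gaussian-product kernel density of 2-d points on a regular grid.

    The per-axis bandwidth is the normal reference (Silverman-type) rule
    multiplied by ``bandwidth_factor``; larger factors give the deliberately
    oversmoothed surfaces used for coarse peak finding.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.shape[0] < 3 or np.unique(points, axis=0).shape[0] < 3:
        raise TooFewEventsError("density estimation needs at least 3 distinct points")
    x, y = points[:, 0], points[:, 1]
    hx = _nrd_bandwidth(x) * bandwidth_factor
    hy = _nrd_bandwidth(y) * bandwidth_factor
    if extent is None:
        extent = ((x.min(), x.max()), (y.min(), y.max()))
    (x0, x1), (y0, y1) = extent
    if not (x1 > x0 and y1 > y0):
        raise DegenerateRegionError("degenerate density extent")
    gx = np.linspace(x0, x1, grid_size)
    gy = np.linspace(y0, y1, grid_size)
    # separable kernel: density = Ax @ Ay / n with Ax (grid x events)
    ax = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ay = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    grid = ax @ ay.T / points.shape[0]
    return DensitySurface(grid=grid, x_coords=gx, y_coords=gy, bandwidth_factor=bandwidth_factor)


def find_maxima(surface: DensitySurface, window: int) -> list[Maximum]:
    """Local maxima of the moving-average-smoothed density grid.

    The grid is smoothed by a ``window x window`` moving average (windows
    shrink at the grid boundary; no padding values are invented). A cell is a
    maximum when strictly greater than all its 8 neighbors. Maxima are ordered
    by decreasing smoothed density; exact ties are broken by lower FSC, then
    lower SSC. On a fully flat (plateau) surface the tie-break rule alone
    selects the lowest-FSC/lowest-SSC cell of the global plateau, so at least
    one maximum is always returned.
    """
    kernel = np.ones((window, window))
    smooth = convolve2d(surface.grid, kernel, mode="same") / convolve2d(
        np.ones_like(surface.grid), kernel, mode="same"
    )
    nx, ny = smooth.shape
    padded = np.full((nx + 2, ny + 2), -np.inf)
    padded[1:-1, 1:-1] = smooth
    neighbors = np.stack(
        [
            padded[1 + di : 1 + di + nx, 1 + dj : 1 + dj + ny]
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            if not (di == 0 and dj == 0)
        ]
    ).max(axis=0)
    is_max = smooth > neighbors

    idx = np.argwhere(is_max)
    if idx.size == 0:  # plateau fallback
        flat = np.argwhere(smooth == smooth.max())
        idx = flat[:1]
    maxima = [
        Maximum(
            location=(float(surface.x_coords[i]), float(surface.y_coords[j])),
            density=float(smooth[i, j]),
            grid_index=(int(i), int(j)),
        )
        for i, j in idx
    ]
    maxima.sort(key=lambda m: (-m.density, m.location[0], m.location[1]))
    return maxima


def tessellate(
    points: np.ndarray,
    maxima: list[Maximum],
    ranges: tuple[tuple[float, float], tuple[float, float]],
) -> np.ndarray:
    """Assign each point to its nearest maximum (Voronoi membership).

    Distances are Euclidean in axis-normalized coordinates (each axis scaled
    to unit trimmed range). Equidistant points go to the higher-density
    maximum, which is first in the (density-ordered) maxima list.
    """
    if not maxima:
        raise ValueError("tessellation requires at least one maximum")
    points = np.asarray(points, dtype=np.float64)
    (x0, x1), (y0, y1) = ranges
    span = np.array([max(x1 - x0, 1e-300), max(y1 - y0, 1e-300)])
    norm_points = points / span
    centers = np.array([m.location for m in maxima]) / span
    return np.argmin(cdist(norm_points, centers), axis=1)


def select_target(
    maxima: list[Maximum],
    ranges: tuple[tuple[float, float], tuple[float, float]],
    debris_fraction: float = 0.05,
) -> int:
    """Pick the target maximum, skipping low-FSC *and* low-SSC debris peaks.

    A maximum is discarded when both coordinates sit below ``debris_fraction``
    of the trimmed range above the range minimum; of the survivors the
    highest-density one wins. If every maximum is discarded the overall
    highest is used as fallback.
    """
    (x0, x1), (y0, y1) = ranges
    x_cut = x0 + debris_fraction * (x1 - x0)
    y_cut = y0 + debris_fraction * (y1 - y0)
    for i, m in enumerate(maxima):
        if not (m.location[0] < x_cut and m.location[1] < y_cut):
            return i
    return 0


def bound_region(points: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    """Rectangle [median - 3*MAD, median + 3*MAD] per axis, clipped to data.

    MAD here is the *mean* absolute deviation about the median.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.shape[0] == 0:
        raise DegenerateRegionError("empty tile")
    bounds = []
    for axis in range(2):
        v = points[:, axis]
        med = float(np.median(v))
        mad = float(np.mean(np.abs(v - med)))
        if mad == 0.0:
            raise DegenerateRegionError("zero mean absolute deviation in tile")
        lo = max(med - 3.0 * mad, float(v.min()))
        hi = min(med + 3.0 * mad, float(v.max()))
        bounds.append((lo, hi))
    return bounds[0], bounds[1]


def compute_gate(events: EventTable, config: GatingConfig | None = None) -> GateResult:
    """Run the full scatter-gating pipeline on one control."""
    cfg = config or GatingConfig()
    bw1, bw2, bw3 = cfg.bandwidth_factors
    w1, w2 = cfg.windows

    trimmed = trim_extremes(events, cfg.trim_quantiles)
    xy = trimmed.scatter()
    ranges = ((float(xy[:, 0].min()), float(xy[:, 0].max())),
              (float(xy[:, 1].min()), float(xy[:, 1].max())))

    # first, coarse tessellation over the full trimmed data
    surface1 = estimate_density(xy, bw1, cfg.grid_size)
    maxima1 = find_maxima(surface1, w1)
    labels1 = tessellate(xy, maxima1, ranges)
    target = select_target(maxima1, ranges, cfg.debris_range_fraction)
    tile_points = xy[labels1 == target]
    if tile_points.shape[0] == 0:
        raise DegenerateRegionError("target tile holds no events")

    # rectangular region around the target tile
    region = bound_region(tile_points)
    (rx0, rx1), (ry0, ry1) = region
    in_region = (
        (xy[:, 0] >= rx0) & (xy[:, 0] <= rx1) & (xy[:, 1] >= ry0) & (xy[:, 1] <= ry1)
    )
    region_points = xy[in_region]
    if region_points.shape[0] < 3:
        raise TooFewEventsError("fewer than 3 events inside the gating region")

    # second, finer tessellation inside the region
    surface2 = estimate_density(region_points, bw2, cfg.grid_size, extent=region)
    maxima2 = find_maxima(surface2, w2)
    labels2 = tessellate(region_points, maxima2, region)
    final_points = region_points[labels2 == 0]  # tile of the highest maximum
    if final_points.shape[0] < 3:
        raise TooFewEventsError("winning tile holds fewer than 3 events")

    # final density threshold and convex hull
    surface3 = estimate_density(final_points, bw3, cfg.grid_size)
    dens = surface3.at_points(final_points)
    threshold = dens.min() + cfg.density_threshold_fraction * (dens.max() - dens.min())
    kept = final_points[dens > threshold]
    if kept.shape[0] < 3:
        raise TooFewEventsError("density threshold left fewer than 3 events")
    hull = ConvexHull(kept)
    polygon = GatePolygon(kept[hull.vertices])

    all_xy = events.scatter()
    inside = polygon.contains(all_xy)
    if int(inside.sum()) < cfg.min_gated_events:
        raise TooFewEventsError(
            f"gate encloses only {int(inside.sum())} events "
            f"(minimum {cfg.min_gated_events})"
        )
    return GateResult(
        polygon=polygon,
        gated=events.take(inside),
        inside_mask=inside,
        target_maximum=maxima1[target].location,
    )
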