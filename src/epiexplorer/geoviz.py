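"""Cartographic computations: proportional symbols, marker styling, KDE heatmaps.

These functions compute the *geometry and intensity* behind the maps; actual
rendering (to a web map or a static figure) is left to downstream GIS tools via
the exporters in :mod:`epiexplorer.io_formats`.

Distances are metric. Because the study areas are sub-kilometer neighborhood
clusters, a local equirectangular projection about the scope centroid is
accurate to well under a meter — far below the 10 m default cell size — so no
full projection library is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .core_model import Category, EARTH_RADIUS_M, StudyStore, ValidationError, parse_month
from .explore import _resolve_scope, _variable_value, _check_variable

__all__ = [
    "MARKER_COLORS",
    "SymbolSpec",
    "HeatmapGrid",
    "category_style",
    "proportional_symbols",
    "heatmap_grid",
    "heatmap_slider",
]

#: Map-marker color per site category (bijective over the four categories).
MARKER_COLORS: Mapping[Category, str] = {
    Category.PIPE_CISTERN: "yellow",
    Category.DRAINAGE: "green",
    Category.OCEAN: "blue",
    Category.COMBINED: "white",
}

#: Kernel support radius in bandwidths; beyond this the Gaussian is cut to 0.
KERNEL_TRUNCATION = 3.0


@dataclass(frozen=True)
class SymbolSpec:
    """One proportional symbol: position, value, pixel radius, fill color."""

    point_id: str
    lon: float
    lat: float
    value: float
    radius_px: float
    fill: str  # "red" for the focus point, "green" otherwise


@dataclass(frozen=True)
class HeatmapGrid:
    """A north-up raster of kernel-density intensity for one month.

    ``intensity`` is row-major with row 0 at the northern edge. Units are
    (variable weight) per square meter: the kernel is a normalized 2-D
    Gaussian, so summing ``intensity * cell_size_m**2`` over the grid recovers
    the total input weight (up to the mass lost to truncation at
    :data:`KERNEL_TRUNCATION` bandwidths and to edge effects).
    """

    bounds: tuple[float, float, float, float]  # (lon_min, lat_min, lon_max, lat_max)
    cell_size_m: float
    bandwidth_m: float
    period: str
    intensity: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def total_mass(self) -> float:
        """Integrated intensity = sum(cells) * cell area, in weight units."""
        return float(self.intensity.sum()) * self.cell_size_m**2

    def argmax_lonlat(self) -> tuple[float, float]:
        """Center (lon, lat) of the cell with the highest intensity."""
        r, c = np.unravel_index(int(self.intensity.argmax()), self.intensity.shape)
        lon_min, lat_min, lon_max, lat_max = self.bounds
        nrows, ncols = self.intensity.shape
        dlon = (lon_max - lon_min) / ncols
        dlat = (lat_max - lat_min) / nrows
        return lon_min + (c + 0.5) * dlon, lat_max - (r + 0.5) * dlat


def category_style(category: Union[Category, str]) -> str:
    """Marker color for a site category (pipe/cistern yellow, drainage green,
    ocean blue, combined white)."""
    return MARKER_COLORS[Category.coerce(category)]


def proportional_symbols(
    store: StudyStore,
    variable: str,
    period: str,
    scope: Union[str, Sequence[str]] = "all",
    focus: Optional[str] = None,
    r_min: float = 4.0,
    r_max: float = 20.0,
) -> list[SymbolSpec]:
    """Symbol specs for all scope points observed in a month.

    Radii follow square-root scaling, ``r = r_min + (r_max - r_min) *
    sqrt(v / v_max)``, so symbol *area* is proportional to the value — the
    standard proportional-symbol convention. If every value is zero all
    symbols get ``r_min``. The focus point is filled red, all others green.
    Points lacking an observation for the period are omitted.
    """
    _check_variable(variable)
    parse_month(period)
    ids = sorted(set(_resolve_scope(store, scope)))
    if focus is not None and focus not in ids:
        raise ValidationError("focus", f"{focus!r} is not in the resolved scope")
    observed = []
    for pid in ids:
        v = _variable_value(store, pid, period, variable)
        if v is not None:
            observed.append((pid, float(v)))
    if focus is not None and focus not in {pid for pid, _ in observed}:
        raise ValidationError(
            "focus", f"{focus!r} has no {variable} observation for {period}"
        )
    if not observed:
        raise ValidationError(
            "period", f"no point in scope has a {variable} observation for {period}"
        )
    v_max = max(v for _, v in observed)
    symbols = []
    for pid, v in observed:
        frac = math.sqrt(v / v_max) if v_max > 0 else 0.0
        wp = store.get_point(pid)
        symbols.append(
            SymbolSpec(
                point_id=pid,
                lon=wp.lon,
                lat=wp.lat,
                value=v,
                radius_px=r_min + (r_max - r_min) * frac,
                fill="red" if pid == focus else "green",
            )
        )
    return symbols


def _local_projection(lats: Sequence[float], lons: Sequence[float]):
    """Equirectangular projection about the centroid: (lon, lat) -> meters."""
    lat0 = sum(lats) / len(lats)
    lon0 = sum(lons) / len(lons)
    kx = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * math.pi / 180.0
    ky = EARTH_RADIUS_M * math.pi / 180.0

    def to_xy(lon: float, lat: float) -> tuple[float, float]:
        return (lon - lon0) * kx, (lat - lat0) * ky

    return to_xy, kx, ky, lon0, lat0


def _grid_geometry(
    store: StudyStore,
    ids: Sequence[str],
    bandwidth_m: float,
    cell_size_m: float,
):
    """Shared raster geometry: bounds = point extent padded by 3 bandwidths."""
    pts = [store.get_point(pid) for pid in ids]
    lats = [p.lat for p in pts]
    lons = [p.lon for p in pts]
    to_xy, kx, ky, lon0, lat0 = _local_projection(lats, lons)
    pad = KERNEL_TRUNCATION * bandwidth_m
    xs = [(p.lon - lon0) * kx for p in pts]
    ys = [(p.lat - lat0) * ky for p in pts]
    x_min, x_max = min(xs) - pad, max(xs) + pad
    y_min, y_max = min(ys) - pad, max(ys) + pad
    ncols = max(1, math.ceil((x_max - x_min) / cell_size_m))
    nrows = max(1, math.ceil((y_max - y_min) / cell_size_m))
    bounds = (
        lon0 + x_min / kx,
        lat0 + y_min / ky,
        lon0 + (x_min + ncols * cell_size_m) / kx,
        lat0 + (y_min + nrows * cell_size_m) / ky,
    )
    return to_xy, (x_min, y_min), (nrows, ncols), bounds


def _kde_intensity(
    xy_weights: Sequence[tuple[float, float, float]],
    origin_xy: tuple[float, float],
    shape: tuple[int, int],
    cell_size_m: float,
    bandwidth_m: float,
) -> np.ndarray:
    """Truncated-Gaussian KDE evaluated at cell centers (row 0 = north)."""
    nrows, ncols = shape
    x0, y0 = origin_xy
    cx = x0 + (np.arange(ncols) + 0.5) * cell_size_m
    # row 0 is the northern (max-y) row
    cy = y0 + (nrows - np.arange(nrows) - 0.5) * cell_size_m
    grid = np.zeros((nrows, ncols))
    s2 = bandwidth_m**2
    norm = 1.0 / (2.0 * math.pi * s2)
    cutoff2 = (KERNEL_TRUNCATION * bandwidth_m) ** 2
    for px, py, w in xy_weights:
        d2 = (cx[None, :] - px) ** 2 + (cy[:, None] - py) ** 2
        kern = np.where(d2 <= cutoff2, norm * np.exp(-0.5 * d2 / s2), 0.0)
        grid += w * kern
    return grid


def heatmap_grid(
    store: StudyStore,
    variable: str,
    period: str,
    bandwidth_m: float = 50.0,
    cell_size_m: float = 10.0,
    scope: Union[str, Sequence[str]] = "all",
    log_weights: bool = False,
    _geometry=None,
) -> HeatmapGrid:
    """Kernel-density intensity surface of a variable for one month.

    Each observed point contributes a 2-D Gaussian kernel (bandwidth
    ``bandwidth_m``, truncated at 3 bandwidths) weighted by its variable
    value; raw weights by default, ``log10(1 + value)`` with ``log_weights``
    for series that span many orders of magnitude. The grid covers the scope
    points' extent padded by 3 bandwidths.
    """
    _check_variable(variable)
    parse_month(period)
    if bandwidth_m <= 0:
        raise ValidationError("bandwidth_m", f"must be > 0, got {bandwidth_m}")
    if cell_size_m <= 0:
        raise ValidationError("cell_size_m", f"must be > 0, got {cell_size_m}")
    ids = sorted(set(_resolve_scope(store, scope)))
    observed = []
    for pid in ids:
        v = _variable_value(store, pid, period, variable)
        if v is not None:
            observed.append((pid, float(v)))
    if not observed and _geometry is None:
        raise ValidationError(
            "period", f"no point in scope has a {variable} observation for {period}"
        )
    if _geometry is None:
        _geometry = _grid_geometry(store, ids, bandwidth_m, cell_size_m)
    to_xy, origin_xy, shape, bounds = _geometry
    xyw = []
    for pid, v in observed:
        wp = store.get_point(pid)
        w = math.log10(1.0 + v) if log_weights else v
        xyw.append((*to_xy(wp.lon, wp.lat), w))
    intensity = _kde_intensity(xyw, origin_xy, shape, cell_size_m, bandwidth_m)
    return HeatmapGrid(
        bounds=bounds,
        cell_size_m=cell_size_m,
        bandwidth_m=bandwidth_m,
        period=period,
        intensity=intensity,
    )


def heatmap_slider(
    store: StudyStore,
    variable: str,
    periods: Sequence[str],
    bandwidth_m: float = 50.0,
    cell_size_m: float = 10.0,
    scope: Union[str, Sequence[str]] = "all",
    log_weights: bool = False,
) -> list[HeatmapGrid]:
    """One heatmap per period on a single shared grid geometry.

    Frames share bounds and dimensions (the scope points' union extent) so a
    time slider can pseudo-animate them on an absolute, comparable scale;
    periods with no observations yield all-zero grids.
    """
    if not periods:
        raise ValidationError("periods", "at least one period required")
    ids = sorted(set(_resolve_scope(store, scope)))
    if not ids:
        raise ValidationError("scope", f"scope {scope!r} resolves to no points")
    geometry = _grid_geometry(store, ids, bandwidth_m, cell_size_m)
    return [
        heatmap_grid(
            store,
            variable,
            period,
            bandwidth_m=bandwidth_m,
            cell_size_m=cell_size_m,
            scope=ids,
            log_weights=log_weights,
            _geometry=geometry,
        )
        for period in periods
    ]
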