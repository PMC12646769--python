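"""Elevation derivatives (slope, aspect, ruggedness) and point covariate
extraction.

Slope and aspect use Horn's 3x3 finite-difference stencil with
edge-replicated borders.  Aspect is reported as the compass direction of
steepest *ascent* (degrees clockwise from north, in [0, 360)); flat cells
get NaN.  The ruggedness index of a cell is the square root of the sum of
squared elevation differences to its (available) eight neighbours.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError
from .rasters import LandscapeStack, Raster

log = logging.getLogger(__name__)


def _check_finite(elev: np.ndarray) -> None:
    bad = np.argwhere(~np.isfinite(elev))
    if bad.size:
        cells = ", ".join(f"({r},{c})" for r, c in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise DataError(f"non-finite elevation at cells {cells}{more}")


def slope_aspect(elevation: Raster) -> tuple[Raster, Raster]:
    """Per-cell slope (degrees, >= 0) and upslope aspect (degrees from north).

    Returns
    -------
    (slope, aspect):
        Aligned rasters.  Aspect is NaN wherever the surface is locally flat.
    """
    z = np.asarray(elevation.data, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise DataError("elevation raster must be at least 3x3")
    _check_finite(z)
    res = elevation.res
    zp = np.pad(z, 1, mode="edge")
    nw, n, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w, e = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    # Horn weights; dz/dy positive northwards (row index grows southwards)
    dzdx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8 * res)
    dzdy = ((nw + 2 * n + ne) - (sw + 2 * s + se)) / (8 * res)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(dzdx, dzdy)) % 360.0
    aspect = np.where(grad == 0, np.nan, aspect)
    mk = lambda d: Raster(d, elevation.x0, elevation.y_top, elevation.res)
    return mk(slope), mk(aspect)


def tri(elevation: Raster) -> Raster:
    """Terrain ruggedness: sqrt of summed squared differences to the eight
    neighbours; border cells use only the neighbours that exist."""
    z = np.asarray(elevation.data, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise DataError("elevation raster must be at least 3x3")
    _check_finite(z)
    zp = np.pad(z, 1, mode="constant", constant_values=np.nan)
    total = np.zeros_like(z)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = zp[1 + dr : zp.shape[0] - 1 + dr, 1 + dc : zp.shape[1] - 1 + dc]
            diff = z - nb
            total += np.where(np.isnan(nb), 0.0, diff**2)
    out = np.sqrt(total)
    return Raster(out, elevation.x0, elevation.y_top, elevation.res)


def add_terrain(stack: LandscapeStack) -> LandscapeStack:
    """Attach slope/aspect/TRI derived from the stack's elevation layer."""
    stack.slope, stack.aspect = slope_aspect(stack.elevation)
    stack.tri = tri(stack.elevation)
    return stack


def extract_covariates(
    points: pd.DataFrame | np.ndarray,
    stack: LandscapeStack,
) -> pd.DataFrame:
    """Sample landscape covariates at point locations.

    Parameters
    ----------
    points:
        Either an (n, 2) array of (x, y) or a DataFrame with ``x``/``y``
        columns (extra columns are carried through).
    stack:
        Landscape with terrain layers attached.

    Returns
    -------
    DataFrame with one row per *in-extent* point: ``road``, ``water``
    (0/1 ints), ``cover`` (class name), ``tri`` plus ``slope``/``aspect``.
    Out-of-extent points are dropped; the count is logged.
    """
    if not stack.has_terrain():
        add_terrain(stack)
    if isinstance(points, pd.DataFrame):
        df = points.reset_index(drop=True).copy()
        x = df["x"].to_numpy(float)
        y = df["y"].to_numpy(float)
    else:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = pts[:, 0], pts[:, 1]
        df = pd.DataFrame({"x": x, "y": y})

    inside = stack.grid.contains(x, y)
    n_out = int((~inside).sum())
    if n_out:
        log.info("extract_covariates: %d of %d points outside extent, dropped", n_out, len(x))
    df = df.loc[inside].reset_index(drop=True)
    x, y = x[inside], y[inside]
    df["road"] = stack.road.values_at(x, y).astype(int)
    df["water"] = stack.water.values_at(x, y).astype(int)
    df["cover"] = stack.cover_names_at(x, y)
    df["tri"] = stack.tri.values_at(x, y)
    df["slope"] = stack.slope.values_at(x, y)
    df["aspect"] = stack.aspect.values_at(x, y)
    return df
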