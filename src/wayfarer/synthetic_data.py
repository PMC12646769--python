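"""Synthetic landscapes and GPS tracks with planted ground truth.

The generator exists so every downstream stage is testable offline: it
plants known selection coefficients, movement distributions and per-habitat
speeds, then emits dual-rate GPS tracks over a patchy raster landscape.

The walker is selection-consistent by construction: at each 5-minute
decision it samples candidate endpoints from the stage's gamma step-length
and von Mises turning-angle distributions and picks one with probability
proportional to ``exp(beta' x)`` evaluated at the candidate endpoints.
1 Hz positions are emitted along the chosen step as a laterally wiggling
walk with habitat-dependent speed and path straightness (any window time
left over is spent stationary at the endpoint), so habitats that are faster
and straighter genuinely yield cheaper seconds downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, DataError
from .rasters import COVER_CLASSES, COVER_CODES, LandscapeStack, Raster
from .terrain import add_terrain
from .tracks import STAGE_ACTIVE, STAGE_LOCAL, STAGE_RESIDENT, STAGES, Track

log = logging.getLogger(__name__)

COVARIATES = ("road", "water", "cover_glade", "cover_riverine",
              "cover_bare_soil", "cover_black_cotton", "tri_z")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape generator."""

    n_cells: int = 400
    resolution: float = 10.0  # m / cell
    patch_length_scale: float = 8.0  # cells; habitat patch smoothing
    cover_weights: dict = field(
        default_factory=lambda: {
            "scrub": 0.50, "glade": 0.20, "riverine": 0.05,
            "bare_soil": 0.15, "black_cotton": 0.10,
        }
    )
    n_roads: int = 2
    road_half_width: float = 15.0  # m to either side of the centreline
    n_rivers: int = 1
    water_half_width: float = 15.0  # m; the water layer buffer
    riverine_half_width: float = 30.0  # m; the riverine-cover buffer
    dem_length_scale: float = 30.0  # cells
    dem_amplitude: float = 4.0  # m
    dem_base: float = 1000.0  # m
    seed: int = 0

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be > 0")
        if min(self.road_half_width, self.water_half_width,
               self.riverine_half_width) < 0:
            raise ConfigurationError("buffer half-widths must be >= 0")
        if abs(sum(self.cover_weights.values()) - 1.0) > 1e-9:
            raise ConfigurationError("cover class weights must sum to 1")
        if set(self.cover_weights) - set(COVER_CLASSES):
            raise ConfigurationError("unknown cover class in weights")
        extent = self.n_cells * self.resolution
        need = 4 * max(self.road_half_width, self.riverine_half_width, self.resolution)
        if (self.n_roads > 0 or self.n_rivers > 0) and extent < need:
            raise ConfigurationError(
                f"grid extent {extent} m too small for requested linear features"
            )


@dataclass
class WalkerConfig:
    """Movement and selection parameters of the synthetic walker."""

    # per-stage gamma step-length (shape, scale in m) at 5-min resolution
    step_shape: dict = field(default_factory=lambda: {
        STAGE_RESIDENT: 2.0, STAGE_LOCAL: 2.0, STAGE_ACTIVE: 2.5})
    step_scale: dict = field(default_factory=lambda: {
        STAGE_RESIDENT: 25.0, STAGE_LOCAL: 40.0, STAGE_ACTIVE: 60.0})
    # per-stage von Mises turning-angle concentration
    kappa: dict = field(default_factory=lambda: {
        STAGE_RESIDENT: 0.5, STAGE_LOCAL: 0.7, STAGE_ACTIVE: 1.5})
    # planted selection coefficients per stage, keyed by COVARIATES entries
    beta: dict = field(default_factory=lambda: {
        STAGE_RESIDENT: {"road": -0.3, "cover_glade": 0.5, "cover_riverine": -0.1,
                         "tri_z": -0.1},
        STAGE_LOCAL: {"road": 0.3, "cover_glade": 0.7, "cover_riverine": -0.3,
                      "tri_z": -0.1},
        STAGE_ACTIVE: {"road": 1.2, "cover_glade": 0.5, "cover_riverine": -0.5,
                       "tri_z": -0.3},
    })
    # 1 Hz emission speed by habitat ('road' overrides cover)
    speeds: dict = field(default_factory=lambda: {
        "road": 1.6, "scrub": 0.8, "glade": 1.0, "riverine": 0.6,
        "bare_soil": 1.0, "black_cotton": 0.8})
    # 1 Hz path straightness by habitat: net step displacement divided by
    # the distance actually walked (roads are straight, scrub is tortuous)
    straightness: dict = field(default_factory=lambda: {
        "road": 0.9, "scrub": 0.45, "glade": 0.6, "riverine": 0.4,
        "bare_soil": 0.6, "black_cotton": 0.45})
    # strength of the pull towards the day roost (resident/local stages)
    roost_bias: dict = field(default_factory=lambda: {
        STAGE_RESIDENT: 2.0, STAGE_LOCAL: 1.0, STAGE_ACTIVE: 0.0})
    # strength of the persistent daily heading (active stage)
    heading_bias: dict = field(default_factory=lambda: {
        STAGE_RESIDENT: 0.0, STAGE_LOCAL: 0.0, STAGE_ACTIVE: 2.5})
    day_start_hour: float = 6.0
    day_end_hour: float = 19.0
    n_candidates: int = 50
    jitter_sd: float = 0.25  # m, 1 Hz positional noise
    seed: int = 0

    def validate(self) -> None:
        for d, what in ((self.step_shape, "gamma shape"),
                        (self.step_scale, "gamma scale"),
                        (self.kappa, "kappa")):
            if any(v <= 0 for v in d.values()):
                raise ConfigurationError(f"{what} must be > 0")
        if any(v <= 0 for v in self.speeds.values()):
            raise ConfigurationError("habitat speeds must be > 0")
        if not (self.day_start_hour <= 6.0 and self.day_end_hour >= 19.0):
            raise ConfigurationError("daily schedule must cover 06:00-19:00")
        if self.n_candidates < 2:
            raise ConfigurationError("need at least 2 candidate endpoints")


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, n: int, length_scale: float) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal((n, n)), length_scale,
                                     mode="wrap")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _segment_distance(px, py, ax, ay, bx, by):
    """Distance from points (px, py) to segment (a, b)."""
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    if L2 == 0:
        return np.hypot(px - ax, py - ay)
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / L2, 0.0, 1.0)
    return np.hypot(px - (ax + t * vx), py - (ay + t * vy))


def _polyline_mask(raster: Raster, vertices: np.ndarray, half_width: float) -> np.ndarray:
    X, Y = raster.cell_centres()
    dist = np.full(raster.shape, np.inf)
    for (ax, ay), (bx, by) in zip(vertices[:-1], vertices[1:]):
        dist = np.minimum(dist, _segment_distance(X, Y, ax, ay, bx, by))
    return dist <= half_width


def _random_transect(rng: np.random.Generator, x0, y0, extent) -> np.ndarray:
    """A straight polyline crossing the whole grid at a random angle."""
    cx = x0 + rng.uniform(0.25, 0.75) * extent
    cy = y0 + rng.uniform(0.25, 0.75) * extent
    ang = rng.uniform(0, np.pi)
    d = 2 * extent
    return np.array([
        [cx - d * np.cos(ang), cy - d * np.sin(ang)],
        [cx + d * np.cos(ang), cy + d * np.sin(ang)],
    ])


def _random_river(rng: np.random.Generator, x0, y0, extent) -> np.ndarray:
    """A gently wandering polyline spanning the grid west to east."""
    n_vert = 6
    xs = x0 + np.linspace(-0.1, 1.1, n_vert) * extent
    yc = y0 + rng.uniform(0.3, 0.7) * extent
    ys = yc + np.cumsum(rng.normal(0, 0.08 * extent, n_vert))
    return np.column_stack([xs, ys])


def generate_landscape(config: LandscapeConfig) -> LandscapeStack:
    """Build an aligned cover/road/water/elevation stack from the config.

    Cover patches come from rank-thresholding a smoothed Gaussian field at
    the cumulative class weights; roads are buffered straight transects;
    the river is a buffered wandering polyline whose wider buffer overrides
    cover as riverine habitat.  The road area fraction is reported in
    ``meta['road_fraction']``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    res = config.resolution
    extent = n * res
    x0, y_top = 0.0, extent
    grid = Raster(np.zeros((n, n)), x0, y_top, res)

    # cover classes from a single rank-transformed smooth field
    u = _smooth_field(rng, n, config.patch_length_scale)
    ranks = stats_rankdata(u)
    cover = np.zeros((n, n), dtype=int)
    cum = 0.0
    order = [c for c in COVER_CLASSES if config.cover_weights.get(c, 0) > 0]
    for cls in order:
        w = config.cover_weights[cls]
        lo, hi = cum, cum + w
        sel = (ranks >= lo) & (ranks < hi if hi < 1 else ranks <= 1)
        cover[sel] = COVER_CODES[cls]
        cum = hi

    # roads
    road = np.zeros((n, n), dtype=int)
    for _ in range(config.n_roads):
        verts = _random_transect(rng, x0, 0.0, extent)
        road |= _polyline_mask(grid, verts, config.road_half_width)

    # river: water buffer + riverine cover buffer
    water = np.zeros((n, n), dtype=int)
    for _ in range(config.n_rivers):
        verts = _random_river(rng, x0, 0.0, extent)
        water |= _polyline_mask(grid, verts, config.water_half_width)
        riverine = _polyline_mask(grid, verts, config.riverine_half_width)
        cover[riverine] = COVER_CODES["riverine"]

    dem = config.dem_base + config.dem_amplitude * _smooth_field(
        rng, n, config.dem_length_scale
    ) if config.dem_amplitude > 0 else np.full((n, n), config.dem_base)

    stack = LandscapeStack(
        cover=Raster(cover, x0, y_top, res),
        road=Raster(road, x0, y_top, res),
        water=Raster(water, x0, y_top, res),
        elevation=Raster(dem, x0, y_top, res),
        meta={
            "seed": config.seed,
            "road_fraction": float(road.mean()),
            "resolution": res,
            "n_cells": n,
        },
    )
    add_terrain(stack)
    stack.meta["tri_mean"] = float(stack.tri.data.mean())
    stack.meta["tri_sd"] = float(stack.tri.data.std() or 1.0)
    return stack


def stats_rankdata(u: np.ndarray) -> np.ndarray:
    """Rank-transform to (0, 1]; ties broken by position (deterministic)."""
    flat = u.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = (np.arange(flat.size) + 1) / flat.size
    return ranks.reshape(u.shape)


# ---------------------------------------------------------------------------
# covariates and candidate choice
# ---------------------------------------------------------------------------

def endpoint_covariates(stack: LandscapeStack, xs: np.ndarray, ys: np.ndarray) -> dict:
    """Planted-model covariate vectors at candidate endpoints (landscape-wide
    TRI standardisation, matching the fitting side's convention)."""
    cov = stack.cover.values_at(xs, ys)
    tri_z = (stack.tri.values_at(xs, ys) - stack.meta["tri_mean"]) / stack.meta["tri_sd"]
    return {
        "road": stack.road.values_at(xs, ys),
        "water": stack.water.values_at(xs, ys),
        "cover_glade": (cov == COVER_CODES["glade"]).astype(float),
        "cover_riverine": (cov == COVER_CODES["riverine"]).astype(float),
        "cover_bare_soil": (cov == COVER_CODES["bare_soil"]).astype(float),
        "cover_black_cotton": (cov == COVER_CODES["black_cotton"]).astype(float),
        "tri_z": tri_z,
    }


def selection_utility(stack: LandscapeStack, beta: dict, xs, ys) -> np.ndarray:
    """beta' x at candidate endpoints."""
    covs = endpoint_covariates(stack, np.asarray(xs, float), np.asarray(ys, float))
    u = np.zeros(np.shape(xs))
    for name, b in beta.items():
        if name not in covs:
            raise ConfigurationError(f"unknown planted covariate '{name}'")
        u = u + b * covs[name]
    return u


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi) (documented boundary policy)."""
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v >= span, 2 * span - v - 1e-9, v)
    return v + lo


def sample_candidates(
    rng: np.random.Generator,
    stack: LandscapeStack,
    x: float,
    y: float,
    prev_bearing: float | None,
    shape: float,
    scale: float,
    kappa: float,
    m: int,
):
    """Candidate endpoints from the movement kernel, reflected into the
    raster.  Returns (xs, ys, bearings, lengths)."""
    lengths = rng.gamma(shape, scale, size=m)
    if prev_bearing is None:
        bearings = rng.uniform(-np.pi, np.pi, size=m)
    else:
        bearings = prev_bearing + rng.vonmises(0.0, kappa, size=m)
    xs = x + lengths * np.sin(bearings)
    ys = y + lengths * np.cos(bearings)
    g = stack.grid
    eps = g.res * 1e-6
    xs = _reflect(xs, g.x0 + eps, g.x_max - eps)
    ys = _reflect(ys, g.y_min + eps, g.y_top - eps)
    return xs, ys, bearings, lengths


def choose_candidate(rng: np.random.Generator, utilities: np.ndarray) -> int:
    """Multinomial draw with probabilities proportional to exp(utility)."""
    u = utilities - utilities.max()
    p = np.exp(u)
    p /= p.sum()
    return int(rng.choice(len(p), p=p))


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

def _habitat_movement(
    stack: LandscapeStack, walker: WalkerConfig, x: float, y: float
) -> tuple[float, float]:
    """(speed m/s, path straightness) of the habitat at a point."""
    if stack.road.values_at(x, y) == 1:
        name = "road"
    else:
        name = stack.cover_names_at(np.asarray([x]), np.asarray([y]))[0]
    return walker.speeds.get(name, 1.0), walker.straightness.get(name, 0.6)


def _emit_step_positions(
    rng: np.random.Generator,
    x: float, y: float, nx: float, ny: float,
    speed: float, straightness: float,
    window: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """1 Hz positions for one 5-minute step.

    The walker covers the step's chord with a laterally wiggling path whose
    total walked length is chord / straightness, moving at ``speed``; any
    window time left over is spent stationary at the endpoint.  Returns
    ``window`` positions (seconds 1..window of the step).
    """
    L = float(np.hypot(nx - x, ny - y))
    if L == 0:
        return np.full(window, nx), np.full(window, ny)
    path_target = L / max(straightness, L / (window * speed), 1e-9)
    t_move = int(np.clip(np.ceil(path_target / speed), 1, window))
    frac = np.minimum(np.arange(1, window + 1) / t_move, 1.0)
    px = x + frac * (nx - x)
    py = y + frac * (ny - y)
    if path_target > L * 1.01 and t_move >= 8:
        # perpendicular sinusoid sized (by bisection) to stretch the walked
        # path towards path_target
        ux, uy = (nx - x) / L, (ny - y) / L
        perp_x, perp_y = -uy, ux
        n_cycles = max(1, t_move // 30)
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * n_cycles * frac[:t_move] + phase) - np.sin(phase)
        lo, hi = 0.0, 3.0 * path_target / n_cycles
        base_x, base_y = px[:t_move], py[:t_move]
        for _ in range(25):
            amp = 0.5 * (lo + hi)
            wx = base_x + amp * wave * perp_x
            wy = base_y + amp * wave * perp_y
            arc = np.hypot(np.diff(wx, prepend=x), np.diff(wy, prepend=y)).sum()
            if arc < path_target:
                lo = amp
            else:
                hi = amp
        px[:t_move] = base_x + amp * wave * perp_x
        py[:t_move] = base_y + amp * wave * perp_y
    return px, py


def simulate_track(
    landscape: LandscapeStack,
    walker: WalkerConfig,
    stage_schedule: list[str],
    individual_id: str = "bird01",
    start_xy: tuple[float, float] | None = None,
    start_date: str = "2019-09-07",
    emit: str = "1hz",
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate one individual over ``len(stage_schedule)`` days.

    Each day runs 06:00-19:00.  Active-dispersal days add a persistent
    heading bias (aimed at a random interior target >= 1.8 km away) so the
    roost-to-roost displacement exceeds the classifier thresholds; resident
    and local days add a pull back towards the day's starting roost.
    Walkers leaving the raster are reflected at the boundary.

    ``emit='1hz'`` writes one fix per second; ``emit='5min'`` writes only
    the step-boundary fixes (fast path for distribution checks).
    """
    walker.validate()
    unknown = set(stage_schedule) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages in schedule: {sorted(unknown)}")
    if emit not in ("1hz", "5min"):
        raise ConfigurationError("emit must be '1hz' or '5min'")
    rng = np.random.default_rng(walker.seed) if rng is None else rng
    g = landscape.grid
    if start_xy is None:
        start_xy = (
            g.x0 + 0.5 * (g.x_max - g.x0),
            g.y_min + 0.5 * (g.y_top - g.y_min),
        )
    x, y = float(start_xy[0]), float(start_xy[1])
    if not g.contains(np.asarray([x]), np.asarray([y]))[0]:
        raise DataError("walker start position outside the raster")

    day0 = pd.Timestamp(start_date)
    n_steps_per_day = int(
        (walker.day_end_hour - walker.day_start_hour) * 3600 // 300
    )
    times: list[np.ndarray] = []
    px: list[np.ndarray] = []
    py: list[np.ndarray] = []
    stages_out: list[np.ndarray] = []
    prev_bearing: float | None = None

    for day_i, stage in enumerate(stage_schedule):
        day = day0 + pd.Timedelta(days=day_i)
        roost = (x, y)
        target = None
        if walker.heading_bias.get(stage, 0.0) > 0:
            target = _pick_day_target(rng, g, x, y)
        day_times, day_x, day_y = [], [], []
        # first fix of the day at the roost
        t_cursor = 0.0
        day_times.append(t_cursor); day_x.append(x); day_y.append(y)
        for _ in range(n_steps_per_day):
            xs, ys, bearings, lengths = sample_candidates(
                rng, landscape, x, y, prev_bearing,
                walker.step_shape[stage], walker.step_scale[stage],
                walker.kappa[stage], walker.n_candidates,
            )
            util = selection_utility(landscape, walker.beta.get(stage, {}), xs, ys)
            rb = walker.roost_bias.get(stage, 0.0)
            if rb > 0:
                d_roost = np.hypot(xs - roost[0], ys - roost[1])
                util = util - rb * d_roost / 100.0
            hb = walker.heading_bias.get(stage, 0.0)
            if hb > 0 and target is not None:
                d_target = np.hypot(target[0] - x, target[1] - y)
                if d_target > 300.0:
                    # steer towards the day target while it is far ...
                    to_target = np.arctan2(target[0] - x, target[1] - y)
                    util = util + hb * np.cos(bearings - to_target)
                else:
                    # ... then hold position near it (keeps the evening
                    # roost at the planted displacement)
                    d_cand = np.hypot(xs - target[0], ys - target[1])
                    util = util - hb * d_cand / 100.0
            k = choose_candidate(rng, util)
            nx, ny = float(xs[k]), float(ys[k])
            L = float(np.hypot(nx - x, ny - y))
            if emit == "1hz":
                speed, straight = _habitat_movement(landscape, walker, x, y)
                sx, sy = _emit_step_positions(rng, x, y, nx, ny, speed, straight)
                day_x.extend(sx)
                day_y.extend(sy)
                day_times.extend(t_cursor + np.arange(1, 301))
            else:
                day_x.append(nx); day_y.append(ny)
                day_times.append(t_cursor + 300.0)
            t_cursor += 300.0
            prev_bearing = float(np.arctan2(nx - x, ny - y)) if L > 0 else prev_bearing
            x, y = nx, ny
        tabs = day.normalize() + pd.to_timedelta(
            np.asarray(day_times) + walker.day_start_hour * 3600, unit="s"
        )
        times.append(tabs.to_numpy())
        dx = np.asarray(day_x)
        dy = np.asarray(day_y)
        if emit == "1hz":
            if walker.jitter_sd > 0:
                dx = dx + rng.normal(0, walker.jitter_sd, dx.size)
                dy = dy + rng.normal(0, walker.jitter_sd, dy.size)
            eps = g.res * 1e-6
            dx = _reflect(dx, g.x0 + eps, g.x_max - eps)
            dy = _reflect(dy, g.y_min + eps, g.y_top - eps)
        px.append(dx)
        py.append(dy)
        stages_out.append(np.repeat(stage, dx.size))

    df = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(np.concatenate(times)),
            "x": np.concatenate(px),
            "y": np.concatenate(py),
            "resolution_flag": "hi" if emit == "1hz" else "lo",
            "true_stage": np.concatenate(stages_out),
        }
    )
    return Track(
        individual_id=individual_id,
        df=df,
        meta={
            "planted_beta": walker.beta,
            "stage_schedule": list(stage_schedule),
            "speeds": walker.speeds,
            "emit": emit,
        },
    )


def _pick_day_target(rng, grid, x, y, min_dist=1600.0) -> tuple[float, float]:
    """Random interior point at least ``min_dist`` away (the day's travel
    target; keeps active-dispersal days inside the raster).  Requires a
    raster large enough to hold such a displacement."""
    for _ in range(500):
        tx = grid.x0 + rng.uniform(0.1, 0.9) * (grid.x_max - grid.x0)
        ty = grid.y_min + rng.uniform(0.1, 0.9) * (grid.y_top - grid.y_min)
        if np.hypot(tx - x, ty - y) >= min_dist:
            return (float(tx), float(ty))
    raise ConfigurationError(
        "raster extent too small for active-dispersal displacements "
        f"(need an interior target >= {min_dist:.0f} m from the roost)"
    )


# ---------------------------------------------------------------------------
# dual-rate emission
# ---------------------------------------------------------------------------

def emit_dual_rate(track: Track, hi_res_hours_per_day: float = 4.5) -> Track:
    """Thin a 1 Hz track to the tags' dual-rate duty cycle.

    Each day keeps a contiguous 1 Hz window of ``hi_res_hours_per_day``
    hours from the start of the duty day (flag 'hi') and one fix per
    5-minute boundary elsewhere (flag 'lo').  A window covering the whole
    day returns the track unchanged (all 'hi').
    """
    if hi_res_hours_per_day < 0:
        raise ConfigurationError("hi_res_hours_per_day must be >= 0")
    df = track.df
    dates = df["timestamp"].dt.normalize()
    sec_of_day = (df["timestamp"] - dates).dt.total_seconds().to_numpy()
    keep = np.zeros(len(df), dtype=bool)
    flags = np.empty(len(df), dtype=object)
    for _, idx in df.groupby(dates).indices.items():
        s = sec_of_day[idx]
        s0 = s[0]
        hi_mask = (s - s0 <= hi_res_hours_per_day * 3600) & (hi_res_hours_per_day > 0)
        lo_mask = ~hi_mask & (np.mod(s - s0, 300.0) == 0)
        keep[idx] = hi_mask | lo_mask
        flags[idx[hi_mask]] = "hi"
        flags[idx[lo_mask]] = "lo"
    out = df.loc[keep].copy()
    out["resolution_flag"] = flags[keep]
    return Track(individual_id=track.individual_id, df=out.reset_index(drop=True),
                 meta={**track.meta, "hi_res_hours_per_day": hi_res_hours_per_day})
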