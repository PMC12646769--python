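"""Track data model, I/O, discretization, roosts and day classification.

A :class:`Track` wraps the time-ordered GPS fixes of one individual.  The
operations here turn raw fixes into the two discretizations used downstream:

* 5-minute observed steps (with a 10 m minimum-displacement filter) feeding
  the step-selection analysis, and
* 50 m net-displacement segments over contiguous 1 Hz data feeding the
  energetics pipeline.

Daily summaries (roost-to-roost displacement, path length, straightness)
drive the movement-stage classifier and the settlement detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("individual_id", "timestamp", "x", "y")

STAGE_ACTIVE = "active_dispersal"
STAGE_LOCAL = "local_transience"
STAGE_RESIDENT = "resident"
STAGES = (STAGE_RESIDENT, STAGE_LOCAL, STAGE_ACTIVE)

#: day classifier defaults
DISPLACEMENT_HI = 1500.0  # m: active regardless of straightness
DISPLACEMENT_LO = 1200.0  # m: active if straightness also exceeds ...
STRAIGHTNESS_MIN = 0.3


@dataclass
class Track:
    """Time-ordered fixes for one individual.

    ``df`` columns: ``timestamp`` (datetime64), ``x``, ``y`` (metres),
    ``resolution_flag`` ('hi'|'lo'), optionally ``true_stage`` (synthetic
    ground truth).  ``meta`` carries generator metadata (planted
    coefficients, seeds) when the track is synthetic.
    """

    individual_id: str
    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if "resolution_flag" not in df.columns:
            df["resolution_flag"] = "hi"
        t = df["timestamp"]
        if t.duplicated().any():
            dup = t[t.duplicated()].iloc[0]
            raise DataError(
                f"duplicate timestamp {dup} for individual '{self.individual_id}'"
            )
        if not t.is_monotonic_increasing:
            row = int(np.argmin(np.diff(t.to_numpy()) > np.timedelta64(0)))
            raise DataError(
                f"non-monotonic timestamps for individual '{self.individual_id}' "
                f"near row {row + 1}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def seconds(self) -> np.ndarray:
        """Timestamps as epoch seconds (float)."""
        return self.df["timestamp"].astype("int64").to_numpy() / 1e9

    def dates(self) -> pd.Series:
        return self.df["timestamp"].dt.normalize()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracks(path: str | Path) -> list[Track]:
    """Read a multi-individual track CSV into one :class:`Track` each.

    Fixes are sorted by time within individual; a duplicated timestamp for
    an individual raises :class:`DataError` naming them.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"track file missing column(s): {', '.join(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamps: {exc}") from exc
    tracks = []
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = sub.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
        tracks.append(Track(individual_id=str(ind), df=sub.drop(columns=["individual_id"])))
    return tracks


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        d = tr.df.copy()
        d.insert(0, "individual_id", tr.individual_id)
        frames.append(d)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(REQUIRED_COLUMNS) + ["resolution_flag"]
    )
    if "timestamp" in out.columns and len(out):
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def bearing(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Compass bearing in radians, clockwise from +y (north)."""
    return np.arctan2(dx, dy)


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = (a + np.pi) % (2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


# ---------------------------------------------------------------------------
# 5-minute steps
# ---------------------------------------------------------------------------

def discretize_5min(
    track: Track,
    min_step: float = 10.0,
    step_seconds: float = 300.0,
    match_tol: float = 1.0,
) -> pd.DataFrame:
    """Cut a track into consecutive 5-minute observed steps.

    Window boundaries are anchored at the track's first fix.  A candidate
    step joins the fixes matched to two consecutive boundaries (a fix
    matches a boundary if within ``match_tol`` seconds; boundaries with no
    matching fix are gaps).  Steps whose net displacement is below
    ``min_step`` are dropped; a retained step gets a turning angle only if
    its immediate predecessor window produced a retained step.

    Returns a DataFrame of retained steps with columns ``t_start``,
    ``t_end``, ``x_start`` .. ``y_end``, ``length``, ``bearing``,
    ``turn_angle`` (NaN when undefined), ``has_angle``.  Filter-funnel
    counts sit in ``df.attrs``: ``n_windows``, ``n_candidate_steps``,
    ``n_retained``.
    """
    sec = track.seconds
    if len(sec) < 2 or sec[-1] - sec[0] < 2 * step_seconds:
        raise DataError("track must span at least two 5-minute windows")
    t0 = sec[0]
    n_bound = int(np.floor((sec[-1] - t0) / step_seconds)) + 1
    bounds = t0 + np.arange(n_bound) * step_seconds
    # nearest fix per boundary
    idx = np.searchsorted(sec, bounds)
    idx = np.clip(idx, 0, len(sec) - 1)
    prev = np.clip(idx - 1, 0, len(sec) - 1)
    pick = np.where(
        np.abs(sec[prev] - bounds) <= np.abs(sec[idx] - bounds), prev, idx
    )
    matched = np.abs(sec[pick] - bounds) <= match_tol
    n_gaps = int((~matched).sum())
    if n_gaps:
        log.info(
            "discretize_5min[%s]: %d of %d boundaries without a fix (gaps)",
            track.individual_id, n_gaps, n_bound,
        )

    xs = track.df["x"].to_numpy(float)
    ys = track.df["y"].to_numpy(float)
    rows = []
    prev_boundary_retained: dict[int, int] = {}  # boundary index -> row number
    for b in range(n_bound - 1):
        if not (matched[b] and matched[b + 1]):
            continue
        i, j = pick[b], pick[b + 1]
        dx, dy = xs[j] - xs[i], ys[j] - ys[i]
        L = float(np.hypot(dx, dy))
        retained = L >= min_step
        if retained:
            br = float(bearing(dx, dy))
            prev_row = prev_boundary_retained.get(b)
            if prev_row is not None:
                angle = float(wrap_angle(br - rows[prev_row]["bearing"]))
                has_angle = True
            else:
                angle, has_angle = np.nan, False
            rows.append(
                dict(
                    t_start=pd.Timestamp(sec[i] * 1e9, unit="ns"),
                    t_end=pd.Timestamp(sec[j] * 1e9, unit="ns"),
                    x_start=xs[i], y_start=ys[i],
                    x_end=xs[j], y_end=ys[j],
                    length=L, bearing=br,
                    turn_angle=angle, has_angle=has_angle,
                )
            )
            prev_boundary_retained[b + 1] = len(rows) - 1
        # dropped step: the next window still starts at boundary b+1, but
        # the turning-angle chain is broken (no entry for b+1)
    steps = pd.DataFrame(
        rows,
        columns=[
            "t_start", "t_end", "x_start", "y_start", "x_end", "y_end",
            "length", "bearing", "turn_angle", "has_angle",
        ],
    )
    n_candidates = int((matched[:-1] & matched[1:]).sum())
    steps.attrs.update(
        n_windows=n_bound - 1, n_candidate_steps=n_candidates, n_retained=len(steps)
    )
    return steps


# ---------------------------------------------------------------------------
# roosts and day classification
# ---------------------------------------------------------------------------

def extract_roosts(
    track: Track,
    day_start: str = "06:00",
    day_end: str = "19:00",
    boundary_tol_minutes: float = 30.0,
) -> pd.DataFrame:
    """First/last fix of each tag duty day, flagged complete when both sit
    within ``boundary_tol_minutes`` of the duty-cycle boundaries."""
    df = track.df
    dates = df["timestamp"].dt.normalize()
    tol = pd.Timedelta(minutes=boundary_tol_minutes)
    out = []
    for date, sub in df.groupby(dates, sort=True):
        first, last = sub.iloc[0], sub.iloc[-1]
        start_expect = date + pd.Timedelta(day_start + ":00")
        end_expect = date + pd.Timedelta(day_end + ":00")
        complete = (
            abs(first["timestamp"] - start_expect) <= tol
            and abs(last["timestamp"] - end_expect) <= tol
        )
        out.append(
            dict(
                date=date,
                morning_x=first["x"], morning_y=first["y"],
                evening_x=last["x"], evening_y=last["y"],
                complete=bool(complete),
            )
        )
    return pd.DataFrame(out)


def day_summaries(
    track: Track,
    day_start: str = "06:00",
    day_end: str = "19:00",
    boundary_tol_minutes: float = 30.0,
) -> pd.DataFrame:
    """Per-day roost displacement D, path length P and straightness S = D/P.

    D for day *d* is the distance between the evening roosts of days *d-1*
    and *d*; the first day and days flagged incomplete have NaN D and are
    excluded from classification.  P sums consecutive-fix distances over all
    fixes of the day (mixed resolutions pooled; see module notes).
    """
    roosts = extract_roosts(track, day_start, day_end, boundary_tol_minutes)
    if roosts.empty:
        return roosts
    df = track.df
    dates = df["timestamp"].dt.normalize()
    path = (
        pd.DataFrame(
            {
                "date": dates,
                "d": np.hypot(
                    df["x"].diff().to_numpy(), df["y"].diff().to_numpy()
                ),
            }
        )
        .assign(d=lambda f: np.where(dates.diff().dt.days.fillna(0) != 0, np.nan, f["d"]))
        .groupby("date")["d"].sum(min_count=0)
    )
    roosts = roosts.merge(path.rename("path_length"), on="date", how="left")
    roosts["path_length"] = roosts["path_length"].fillna(0.0)
    ex, ey = roosts["evening_x"].to_numpy(), roosts["evening_y"].to_numpy()
    disp = np.full(len(roosts), np.nan)
    disp[1:] = np.hypot(np.diff(ex), np.diff(ey))
    # a displacement needs both nights' roosts from complete days
    comp = roosts["complete"].to_numpy(bool)
    disp[1:] = np.where(comp[1:] & comp[:-1], disp[1:], np.nan)
    roosts["displacement"] = disp
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(roosts["path_length"] > 0, disp / roosts["path_length"], np.nan)
    roosts["straightness"] = np.clip(s, None, 1.0)
    return roosts


def classify_day(
    displacement: float, straightness: float, resident: bool = False
) -> str:
    """Classify one day from roost displacement D (m) and straightness S.

    Active dispersal iff D > 1500, or D > 1200 and S > 0.3.  Otherwise the
    day is 'local_transience' for transient birds or 'resident' for
    residents.
    """
    if displacement is None or not np.isfinite(displacement):
        raise DataError("displacement must be finite for classification")
    if displacement > 0 and (straightness is not None and np.isfinite(straightness)
                             and straightness > 1.0):
        raise DataError("straightness > 1 implies path length < displacement")
    if displacement > DISPLACEMENT_HI:
        return STAGE_ACTIVE
    if displacement > DISPLACEMENT_LO and np.isfinite(straightness) and straightness > STRAIGHTNESS_MIN:
        return STAGE_ACTIVE
    return STAGE_RESIDENT if resident else STAGE_LOCAL


def classify_days(summaries: pd.DataFrame, resident: bool = False) -> pd.DataFrame:
    """Vectorised :func:`classify_day` over a day-summary table.

    Days without a finite displacement (first day, incomplete days) get a
    NaN classification and are excluded downstream.
    """
    out = summaries.copy()
    labels = []
    for _, row in out.iterrows():
        if not np.isfinite(row["displacement"]):
            labels.append(None)
        else:
            labels.append(
                classify_day(row["displacement"], row["straightness"], resident)
            )
    out["classification"] = labels
    return out


def detect_settlement(
    summaries: pd.DataFrame, radius: float = 200.0, window: int = 14
) -> pd.Timestamp | None:
    """Earliest date from which the evening roosts of ``window`` consecutive
    days all lie within ``radius`` of their centroid (back-dated start)."""
    if len(summaries) < window:
        return None
    ex = summaries["evening_x"].to_numpy(float)
    ey = summaries["evening_y"].to_numpy(float)
    dates = summaries["date"].to_numpy()
    for i in range(len(summaries) - window + 1):
        sx, sy = ex[i : i + window], ey[i : i + window]
        cx, cy = sx.mean(), sy.mean()
        if np.hypot(sx - cx, sy - cy).max() <= radius:
            return pd.Timestamp(dates[i])
    return None


# ---------------------------------------------------------------------------
# 50 m net displacements
# ---------------------------------------------------------------------------

def hi_res_runs(track: Track, max_gap: float = 1.5) -> list[np.ndarray]:
    """Index arrays of contiguous 1 Hz ('hi') runs within the track."""
    mask = (track.df["resolution_flag"] == "hi").to_numpy()
    sec = track.seconds
    runs: list[np.ndarray] = []
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return runs
    breaks = np.nonzero((np.diff(idx) != 1) | (np.diff(sec[idx]) > max_gap))[0]
    for chunk in np.split(idx, breaks + 1):
        if chunk.size >= 2:
            runs.append(chunk)
    return runs


def net_displacements_50m(track: Track, radius: float = 50.0) -> pd.DataFrame:
    """Segment contiguous 1 Hz data into >= ``radius`` net displacements.

    Scanning from a segment's first fix, the segment closes at the first
    fix whose straight-line distance from the start reaches ``radius``; the
    next fix starts a new segment.  The realized (closing) distance
    ``d_true`` is stored for cost-of-transport; an unclosed trailing
    segment is discarded.
    """
    xs = track.df["x"].to_numpy(float)
    ys = track.df["y"].to_numpy(float)
    sec = track.seconds
    rows = []
    for run_id, run in enumerate(hi_res_runs(track)):
        rx, ry = xs[run], ys[run]
        n = run.size
        i = 0
        while i < n - 1:
            # scan in growing chunks for the closing fix
            j = None
            lo = i + 1
            while lo < n:
                hi = min(lo + 600, n)
                d = np.hypot(rx[lo:hi] - rx[i], ry[lo:hi] - ry[i])
                k = np.nonzero(d >= radius)[0]
                if k.size:
                    j = lo + int(k[0])
                    d_true = float(d[k[0]])
                    break
                lo = hi
            if j is None:
                break  # unclosed tail
            rows.append(
                dict(
                    run_id=run_id,
                    i_start=int(run[i]), i_end=int(run[j]),
                    t_start=pd.Timestamp(sec[run[i]] * 1e9, unit="ns"),
                    t_end=pd.Timestamp(sec[run[j]] * 1e9, unit="ns"),
                    x_start=float(rx[i]), y_start=float(ry[i]),
                    x_end=float(rx[j]), y_end=float(ry[j]),
                    n_seconds=int(round(sec[run[j]] - sec[run[i]])),
                    d_true=d_true,
                )
            )
            i = j + 1  # next time point starts the next displacement
    return pd.DataFrame(
        rows,
        columns=[
            "run_id", "i_start", "i_end", "t_start", "t_end",
            "x_start", "y_start", "x_end", "y_end", "n_seconds", "d_true",
        ],
    )
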