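"""Per-second locomotion energetics and cost of transport (CoT).

The physiological model maps per-second speed and experienced incline to
oxygen consumption using treadmill regressions for a terrestrial galliform:
a stationary rate of 19.1 ml O2 kg-1 min-1 and moving rates

    VO2 = 24.0 v + 27.2   (level)
    VO2 = 30.7 v + 27.6   (10% incline)
    VO2 = 47.7 v + 21.3   (20% incline)

in ml O2 kg-1 min-1 with v in m s-1, converted to J kg-1 s-1 at
20.1 J ml-1 O2.  The incline experienced along a bearing is
theta' = atan(tan(theta) * cos(dpsi)) with dpsi measured from the upslope
aspect; percent grade PG = 100 tan(theta') is binned at 5% and 15% and
downhill movement is costed as level ground.

CoT for a >= 50 m net displacement is the summed per-second energy divided
by the realised displacement distance (J kg-1 m-1).  Per-stage linear
models compare habitat CoT against a road reference with pairwise
contrasts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DataError, GradeError
from .hmm import MovementHMM, fit_hmm, ten_second_steps
from .rasters import LandscapeStack
from .terrain import add_terrain
from .tracks import Track, hi_res_runs, net_displacements_50m

log = logging.getLogger(__name__)

INCLINE_LEVEL = 0
INCLINE_10 = 10
INCLINE_20 = 20


@dataclass(frozen=True)
class EnergeticsModel:
    """Constants of the speed/incline oxygen-consumption model."""

    stationary_rate: float = 19.1  # ml O2 kg-1 min-1
    level_line: tuple[float, float] = (24.0, 27.2)  # slope, intercept
    incline10_line: tuple[float, float] = (30.7, 27.6)
    incline20_line: tuple[float, float] = (47.7, 21.3)
    joules_per_ml_o2: float = 20.1
    grade_edges: tuple[float, float] = (5.0, 15.0)
    max_grade: float = 25.0  # beyond this no regression applies

    def line(self, incline: int) -> tuple[float, float]:
        return {
            INCLINE_LEVEL: self.level_line,
            INCLINE_10: self.incline10_line,
            INCLINE_20: self.incline20_line,
        }[incline]

    def vo2_per_min(self, v: float, incline: int = INCLINE_LEVEL, moving: bool = True) -> float:
        """Oxygen consumption in ml O2 kg-1 min-1."""
        if v < 0:
            raise DataError("speed must be non-negative")
        if not moving:
            return self.stationary_rate
        slope, intercept = self.line(incline)
        return slope * v + intercept

    def energy_per_second(self, v, incline: int = INCLINE_LEVEL, moving: bool = True) -> float:
        """Energy in J kg-1 s-1."""
        return self.vo2_per_min(v, incline, moving) / 60.0 * self.joules_per_ml_o2

    def oxygen_to_energy(self, vo2_per_second: float) -> float:
        """Convert ml O2 kg-1 s-1 to J kg-1 s-1."""
        return vo2_per_second * self.joules_per_ml_o2


DEFAULT_MODEL = EnergeticsModel()


# ---------------------------------------------------------------------------
# experienced incline
# ---------------------------------------------------------------------------

def experienced_slope(theta_deg, dpsi_deg):
    """Incline experienced moving at ``dpsi_deg`` from the upslope aspect.

    theta' = atan(tan(theta) * cos(dpsi)); the sign (uphill positive)
    comes from cos(dpsi).  |theta'| <= theta always.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta >= 90) or np.any(theta < 0):
        raise DataError("terrain slope must lie in [0, 90) degrees")
    dpsi = np.radians(np.asarray(dpsi_deg, dtype=float))
    out = np.degrees(np.arctan(np.tan(np.radians(theta)) * np.cos(dpsi)))
    return out if out.shape else float(out)


def percent_grade(theta_prime_deg):
    """PG = 100 * tan(theta')."""
    return np.tan(np.radians(np.asarray(theta_prime_deg, dtype=float))) * 100.0


def incline_class(theta_prime_deg, model: EnergeticsModel = DEFAULT_MODEL):
    """Bin experienced slope into the 0/10/20% incline classes via PG.

    PG < 5 (including all downhill grades) -> level; 5 <= PG < 15 -> 10%;
    15 <= PG < max -> 20%.  Grades at or beyond ``model.max_grade`` have no
    supporting regression and raise :class:`GradeError`.
    """
    pg = np.asarray(percent_grade(theta_prime_deg))
    if np.any(pg >= model.max_grade):
        raise GradeError(
            f"experienced grade >= {model.max_grade}% is outside the "
            "range covered by the oxygen-consumption regressions"
        )
    lo, hi = model.grade_edges
    out = np.where(pg < lo, INCLINE_LEVEL, np.where(pg < hi, INCLINE_10, INCLINE_20))
    return out if out.shape else int(out)


# ---------------------------------------------------------------------------
# per-second energies along a 1 Hz run
# ---------------------------------------------------------------------------

def per_second_energies(
    xs: np.ndarray,
    ys: np.ndarray,
    moving: np.ndarray,
    stack: LandscapeStack,
    model: EnergeticsModel = DEFAULT_MODEL,
) -> np.ndarray:
    """Energy (J kg-1 s-1) for each of the n-1 seconds of a 1 Hz run.

    Speed and bearing for second *t* come from the fix pair (t, t+1);
    slope and aspect from the cell containing fix *t*.  ``moving`` is a
    boolean per-second mask (length n-1), typically from the HMM decode.
    """
    if not stack.has_terrain():
        add_terrain(stack)
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    dx, dy = np.diff(xs), np.diff(ys)
    v = np.hypot(dx, dy)
    moving = np.asarray(moving, bool)
    if moving.shape != v.shape:
        raise DataError("moving mask must have length n_fixes - 1")
    bearing_deg = np.degrees(np.arctan2(dx, dy))
    slope = stack.slope.values_at(xs[:-1], ys[:-1])
    aspect = stack.aspect.values_at(xs[:-1], ys[:-1])
    # flat cells have undefined aspect: experienced slope is zero there
    dpsi = np.where(np.isfinite(aspect), bearing_deg - aspect, 90.0)
    theta = np.where(np.isfinite(aspect), slope, 0.0)
    theta_p = experienced_slope(theta, dpsi)
    classes = incline_class(np.where(moving, theta_p, 0.0), model)
    energies = np.full(v.shape, model.stationary_rate / 60.0 * model.joules_per_ml_o2)
    for inc in (INCLINE_LEVEL, INCLINE_10, INCLINE_20):
        sel = moving & (classes == inc)
        if sel.any():
            s, b = model.line(inc)
            energies[sel] = (s * v[sel] + b) / 60.0 * model.joules_per_ml_o2
    return energies


def compute_cot(energies: np.ndarray, d_true: float) -> float:
    """CoT = summed per-second energy / realised displacement distance."""
    if d_true <= 0:
        raise DataError("displacement distance must be positive")
    return float(np.sum(energies) / d_true)


# ---------------------------------------------------------------------------
# displacement labelling and assembly
# ---------------------------------------------------------------------------

def label_displacement_habitat(
    x_start: float, y_start: float, x_end: float, y_end: float, stack: LandscapeStack
) -> str | None:
    """Habitat label for one displacement, or None when excluded.

    Road at both endpoints wins regardless of cover; otherwise both
    endpoints must share a cover class.  Off-raster endpoints exclude the
    displacement.
    """
    xs = np.array([x_start, x_end])
    ys = np.array([y_start, y_end])
    if not stack.grid.contains(xs, ys).all():
        return None
    road = stack.road.values_at(xs, ys)
    if road[0] == 1 and road[1] == 1:
        return "road"
    cov = stack.cover_names_at(xs, ys)
    if cov[0] == cov[1]:
        return str(cov[0])
    return None


def fit_hmm_tracks(
    track_list: list[Track],
    seed: int = 0,
    max_windows: int = 4000,
    n_states: int = 4,
) -> MovementHMM:
    """Fit one movement HMM on the pooled 1 Hz runs of several tracks.

    Sequences are added in order until ``max_windows`` ten-second windows
    are accumulated (EM cost is linear in windows; the emission parameters
    stabilise long before the full dataset is needed).  Decoding always
    uses every window.
    """
    seqs = []
    budget = max_windows
    for tr in track_list:
        xs = tr.df["x"].to_numpy(float)
        ys = tr.df["y"].to_numpy(float)
        for r in hi_res_runs(tr):
            lengths, angles = ten_second_steps(xs[r], ys[r])
            if len(lengths) < 2:
                continue
            seqs.append((lengths[:budget], angles[:budget]))
            budget -= len(seqs[-1][0])
            if budget <= 0:
                return fit_hmm(seqs, n_states=n_states, seed=seed)
    return fit_hmm(seqs, n_states=n_states, seed=seed)


def displacement_records(
    track: Track,
    stack: LandscapeStack,
    stage_by_date: dict | None = None,
    model: EnergeticsModel = DEFAULT_MODEL,
    radius: float = 50.0,
    hmm: MovementHMM | None = None,
    hmm_seed: int = 0,
    moving_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full displacement/CoT table for one track.

    Fits (or reuses) the movement HMM on the track's 1 Hz runs, decodes a
    per-second moving mask, segments >= ``radius`` net displacements,
    labels their habitat and computes per-displacement CoT.  Displacements
    crossing habitats or leaving the raster are excluded (counted in
    ``attrs``).  ``moving_mask`` (aligned to track rows, length n) may be
    supplied to bypass the HMM, e.g. for constructed tracks.
    """
    if not stack.has_terrain():
        add_terrain(stack)
    runs = hi_res_runs(track)
    if not runs:
        return pd.DataFrame()
    xs = track.df["x"].to_numpy(float)
    ys = track.df["y"].to_numpy(float)
    if moving_mask is None:
        if hmm is None:
            seqs = [ten_second_steps(xs[r], ys[r]) for r in runs]
            hmm = fit_hmm(seqs, seed=hmm_seed)
        moving_mask = np.zeros(len(track.df), dtype=bool)
        for r in runs:
            lengths, angles = ten_second_steps(xs[r], ys[r])
            if len(lengths) < 2:
                continue
            win_moving = hmm.moving_mask(lengths, angles)
            # each second inherits its 10 s window's state
            sec_idx = np.minimum(np.arange(r.size) // 10, len(win_moving) - 1)
            moving_mask[r] = win_moving[sec_idx]

    disp = net_displacements_50m(track, radius=radius)
    rows = []
    n_mixed = n_outside = 0
    for _, d in disp.iterrows():
        habitat = label_displacement_habitat(
            d["x_start"], d["y_start"], d["x_end"], d["y_end"], stack
        )
        if habitat is None:
            n_mixed += 1
            continue
        i, j = int(d["i_start"]), int(d["i_end"])
        energies = per_second_energies(
            xs[i : j + 1], ys[i : j + 1], moving_mask[i:j], stack, model
        )
        date = pd.Timestamp(d["t_start"]).normalize()
        rows.append(
            dict(
                individual=track.individual_id,
                stage=(stage_by_date or {}).get(date),
                t_start=d["t_start"], t_end=d["t_end"],
                habitat=habitat,
                d_true=d["d_true"],
                n_seconds=d["n_seconds"],
                energy=float(energies.sum()),
                cot=compute_cot(energies, d["d_true"]),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "individual", "stage", "t_start", "t_end", "habitat",
            "d_true", "n_seconds", "energy", "cot",
        ],
    )
    out.attrs["counts"] = dict(
        displacements=len(disp), mixed_habitat=n_mixed, outside=n_outside,
        kept=len(out),
    )
    return out


# ---------------------------------------------------------------------------
# per-stage CoT models
# ---------------------------------------------------------------------------

@dataclass
class CotStageModel:
    stage: str
    coefficients: pd.DataFrame  # term, estimate, se, t, p, ci
    contrasts: pd.DataFrame  # pairwise habitat differences
    n: int
    reference: str
    mixed: bool = False


def _pairwise_contrasts(params, cov, habitats, reference):
    """All pairwise habitat differences with Wald tests, from a
    reference-coded fit (reference level coefficient is 0)."""

    def coef_name(h):
        return None if h == reference else h

    rows = []
    for a, b in itertools.combinations(habitats, 2):
        ca, cb = coef_name(a), coef_name(b)
        est = (params.get(ca, 0.0) if ca else 0.0) - (params.get(cb, 0.0) if cb else 0.0)
        var = 0.0
        if ca and ca in cov.index:
            var += cov.loc[ca, ca]
        if cb and cb in cov.index:
            var += cov.loc[cb, cb]
        if ca and cb and ca in cov.index and cb in cov.index:
            var -= 2 * cov.loc[ca, cb]
        se = np.sqrt(max(var, 0.0))
        z = est / se if se > 0 else np.nan
        rows.append(
            dict(contrast=f"{a} - {b}", estimate=est, se=se, z=z,
                 p=2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan)
        )
    return pd.DataFrame(rows)


def cot_models(
    records: pd.DataFrame,
    reference: str = "road",
    mixed: bool = False,
    min_per_level: int = 2,
) -> dict[str, CotStageModel]:
    """Per-stage linear models ``cot ~ habitat`` with a road reference.

    Stages with fewer than two habitat levels carrying ``min_per_level``
    records are skipped with a warning.  With ``mixed=True`` a
    per-individual random-intercept model is fitted alongside OLS and its
    table reported instead.
    """
    out: dict[str, CotStageModel] = {}
    for stage, sub in records.dropna(subset=["stage"]).groupby("stage"):
        counts = sub["habitat"].value_counts()
        levels = [h for h, c in counts.items() if c >= min_per_level]
        if len(levels) < 2:
            log.warning("cot_models: stage '%s' has < 2 usable habitat levels, skipped", stage)
            continue
        sub = sub[sub["habitat"].isin(levels)].copy()
        ref = reference if reference in levels else levels[0]
        sub["habitat"] = pd.Categorical(
            sub["habitat"], categories=[ref] + [h for h in levels if h != ref]
        )
        formula = f"cot ~ C(habitat, Treatment('{ref}'))"
        if mixed and sub["individual"].nunique() > 1:
            fit = smf.mixedlm(formula, sub, groups=sub["individual"]).fit(reml=True)
        else:
            fit = smf.ols(formula, sub).fit()
        # tidy the statsmodels term names back to habitat labels
        def clean(term: str) -> str:
            if term == "Intercept":
                return "Intercept"
            return term.split("[T.")[-1].rstrip("]")

        ci = fit.conf_int()
        coef = pd.DataFrame(
            {
                "term": [clean(t) for t in fit.params.index],
                "estimate": fit.params.to_numpy(),
                "se": fit.bse.to_numpy(),
                "stat": fit.tvalues.to_numpy(),
                "p": fit.pvalues.to_numpy(),
                "ci_lo": ci[0].to_numpy(),
                "ci_hi": ci[1].to_numpy(),
            }
        )
        params = {clean(t): v for t, v in fit.params.items() if t != "Intercept"}
        cov = fit.cov_params()
        cov = cov.rename(index=clean, columns=clean)
        contrasts = _pairwise_contrasts(params, cov, levels, ref)
        out[stage] = CotStageModel(
            stage=stage, coefficients=coef, contrasts=contrasts,
            n=len(sub), reference=ref, mixed=mixed,
        )
    return out
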