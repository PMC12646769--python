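"""Step-selection analysis.

Pipeline: fit per-(individual, stage) step-length (gamma) and turning-angle
(von Mises) distributions; sample alternative steps for each observed step
to build matched strata; attach endpoint covariates; and estimate selection
with a conditional (fixed-effects) logistic regression maximised by
Newton-Raphson on the stratified conditional likelihood

    L(beta) = prod_strata exp(beta' x_case) / sum_j exp(beta' x_j).

Relative selection strength (RSS) per term is exp(beta_hat) with Wald
intervals.  Three design variants are supported: per-stage coefficients
(``within_stage``), main effects plus stage interactions against a resident
reference (``vs_resident``), and a two-level transient/resident variant
(``two_level``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .errors import (
    ConfigurationError,
    DataError,
    RankDeficiencyError,
    SeparationError,
)
from .rasters import COVER_CLASSES, LandscapeStack
from .terrain import extract_covariates
from .tracks import STAGE_ACTIVE, STAGE_LOCAL, STAGE_RESIDENT, wrap_angle

log = logging.getLogger(__name__)

DEFAULT_N_ALTERNATIVES = 20
VARIANTS = ("within_stage", "vs_resident", "two_level")


# ---------------------------------------------------------------------------
# movement distributions
# ---------------------------------------------------------------------------

@dataclass
class StepDistributions:
    """Gamma step-length and von Mises turning-angle fits keyed by
    (individual, stage); keys below the sample floor fall back to
    stage-pooled fits (flagged in ``fallback_keys``)."""

    gamma: dict  # key -> (shape, scale)
    vonmises: dict  # key -> (mu, kappa)
    fallback_keys: set = field(default_factory=set)

    def params_for(self, individual: str, stage: str):
        key = (individual, stage)
        if key in self.gamma:
            return self.gamma[key], self.vonmises[key]
        key = (None, stage)
        return self.gamma[key], self.vonmises[key]


def _fit_gamma(lengths: np.ndarray) -> tuple[float, float]:
    lengths = np.asarray(lengths, dtype=float)
    if np.ptp(lengths) == 0:
        raise DataError("degenerate step-length sample (all values equal)")
    shape, _, scale = stats.gamma.fit(lengths, floc=0)
    return float(shape), float(scale)


def _fit_vonmises(angles: np.ndarray, fix_mu: bool = False) -> tuple[float, float]:
    angles = np.asarray(angles, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        return 0.0, 1e-6
    if fix_mu:
        kappa, _, _ = stats.vonmises.fit(angles, floc=0, fscale=1)
        mu = 0.0
    else:
        kappa, mu, _ = stats.vonmises.fit(angles, fscale=1)
    return float(wrap_angle(mu)), float(max(kappa, 1e-8))


def fit_step_distributions(
    steps: pd.DataFrame,
    min_steps: int = 30,
    fix_mu: bool = False,
) -> StepDistributions:
    """MLE movement distributions per (individual, stage).

    ``steps`` needs ``individual``, ``stage``, ``length`` and ``turn_angle``
    columns.  Keys with fewer than ``min_steps`` steps use the stage-pooled
    fit (stored under key ``(None, stage)``).
    """
    gamma_fits: dict = {}
    vm_fits: dict = {}
    fallback: set = set()
    for stage, pooled in steps.groupby("stage"):
        gamma_fits[(None, stage)] = _fit_gamma(pooled["length"].to_numpy())
        vm_fits[(None, stage)] = _fit_vonmises(
            pooled["turn_angle"].to_numpy(), fix_mu
        )
    for (ind, stage), sub in steps.groupby(["individual", "stage"]):
        if len(sub) >= min_steps:
            gamma_fits[(ind, stage)] = _fit_gamma(sub["length"].to_numpy())
            vm_fits[(ind, stage)] = _fit_vonmises(sub["turn_angle"].to_numpy(), fix_mu)
        else:
            fallback.add((ind, stage))
    return StepDistributions(gamma=gamma_fits, vonmises=vm_fits, fallback_keys=fallback)


# ---------------------------------------------------------------------------
# alternative steps and strata
# ---------------------------------------------------------------------------

def sample_alternative_endpoints(
    rng: np.random.Generator,
    x_start: float,
    y_start: float,
    prev_bearing: float | None,
    gamma_params: tuple[float, float],
    vm_params: tuple[float, float],
    m: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``m`` candidate endpoints from the movement kernel.

    When no previous bearing exists the direction is uniform and only the
    length distribution is used.
    """
    shape, scale = gamma_params
    lengths = rng.gamma(shape, scale, size=m)
    if prev_bearing is None or not np.isfinite(prev_bearing):
        bearings = rng.uniform(-np.pi, np.pi, size=m)
    else:
        mu, kappa = vm_params
        bearings = prev_bearing + rng.vonmises(mu, kappa, size=m)
    return x_start + lengths * np.sin(bearings), y_start + lengths * np.cos(bearings)


def generate_alternatives(
    step: pd.Series,
    dists: StepDistributions,
    landscape: LandscapeStack,
    m: int = DEFAULT_N_ALTERNATIVES,
    rng: np.random.Generator | None = None,
    max_resample: int = 100,
) -> pd.DataFrame:
    """Build one stratum: the observed step (case) plus ``m`` alternatives.

    Alternative endpoints outside the raster are resampled (up to
    ``max_resample`` rounds); if candidates still fall outside, the stratum
    keeps fewer alternatives (logged by the caller via ``n_short``).
    """
    if m <= 0:
        raise ConfigurationError("number of alternative steps must be positive")
    rng = np.random.default_rng() if rng is None else rng
    gp, vp = dists.params_for(step["individual"], step["stage"])
    prev_b = step["bearing"] - step["turn_angle"] if step["has_angle"] else None
    xs = np.empty(0)
    ys = np.empty(0)
    for _ in range(max_resample):
        need = m - xs.size
        if need <= 0:
            break
        cx, cy = sample_alternative_endpoints(
            rng, step["x_start"], step["y_start"], prev_b, gp, vp, need
        )
        ok = landscape.grid.contains(cx, cy)
        xs = np.concatenate([xs, cx[ok]])
        ys = np.concatenate([ys, cy[ok]])
    xs, ys = xs[:m], ys[:m]
    out = pd.DataFrame(
        {
            "x_end": np.concatenate([[step["x_end"]], xs]),
            "y_end": np.concatenate([[step["y_end"]], ys]),
            "is_case": np.concatenate([[1], np.zeros(xs.size, dtype=int)]),
        }
    )
    out["individual"] = step["individual"]
    out["stage"] = step["stage"]
    out["length_only"] = not bool(step["has_angle"])
    return out


def build_strata(
    steps: pd.DataFrame,
    dists: StepDistributions,
    landscape: LandscapeStack,
    m: int = DEFAULT_N_ALTERNATIVES,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Assemble the full strata table with endpoint covariates attached.

    ``steps`` must carry ``individual`` and ``stage`` columns in addition to
    the discretizer output.  Returns rows keyed by ``stratum_id`` with
    ``is_case``, covariates (``road``, ``water``, ``cover``, ``tri``) and
    grouping labels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = []
    n_short = 0
    for sid, (_, step) in enumerate(steps.iterrows()):
        stratum = generate_alternatives(step, dists, landscape, m=m, rng=rng)
        if len(stratum) < m + 1:
            n_short += 1
        stratum.insert(0, "stratum_id", sid)
        parts.append(stratum)
    if not parts:
        return pd.DataFrame(
            columns=["stratum_id", "x_end", "y_end", "is_case", "individual",
                     "stage", "length_only"]
        )
    strata = pd.concat(parts, ignore_index=True)
    if n_short:
        log.info("build_strata: %d strata kept with fewer than %d alternatives", n_short, m)
    cov = extract_covariates(
        strata.rename(columns={"x_end": "x", "y_end": "y"}), landscape
    )
    if len(cov) != len(strata):  # cases are observed, always inside
        raise DataError("case endpoint outside raster extent")
    return cov.rename(columns={"x": "x_end", "y": "y_end"})


def filter_habitat_posthoc(
    strata: pd.DataFrame,
    drop_classes: tuple[str, ...] = ("black_cotton", "bare_soil"),
) -> pd.DataFrame:
    """Remove steps in the dropped cover classes.

    A stratum whose *case* endpoint sits in a dropped class is removed
    entirely; elsewhere only the offending alternatives are removed.  Strata
    left with fewer than two steps are removed too.  Counts are recorded in
    ``attrs['posthoc_counts']``.
    """
    dropped = strata["cover"].isin(drop_classes)
    bad_strata = set(strata.loc[dropped & (strata["is_case"] == 1), "stratum_id"])
    keep = ~strata["stratum_id"].isin(bad_strata) & ~dropped
    out = strata.loc[keep]
    sizes = out.groupby("stratum_id")["is_case"].size()
    small = set(sizes.index[sizes < 2])
    out = out.loc[~out["stratum_id"].isin(small)].reset_index(drop=True)
    out.attrs["posthoc_counts"] = dict(
        strata_in=int(strata["stratum_id"].nunique()),
        strata_case_dropped=len(bad_strata),
        strata_too_small=len(small),
        steps_removed=int(len(strata) - len(out)),
        strata_out=int(out["stratum_id"].nunique()),
    )
    return out


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def covariate_columns(
    strata: pd.DataFrame, standardize_tri: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Expand raw covariates into model columns.

    Cover becomes dummies against the scrub reference; TRI is z-scored over
    the rows in use (mean/sd recorded in attrs).
    """
    out = strata.copy()
    cols = ["road", "water"]
    for cls in COVER_CLASSES[1:]:
        name = f"cover_{cls}"
        vals = (strata["cover"] == cls).astype(int)
        if vals.any():
            out[name] = vals
            cols.append(name)
    if standardize_tri:
        mu, sd = strata["tri"].mean(), strata["tri"].std()
        sd = sd if sd > 0 else 1.0
        out["tri_z"] = (strata["tri"] - mu) / sd
        out.attrs["tri_standardization"] = {"mean": float(mu), "sd": float(sd)}
        cols.append("tri_z")
    else:
        cols.append("tri")
    return out, cols


def build_design(
    strata: pd.DataFrame,
    variant: str = "within_stage",
    standardize_tri: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct the design matrix for one model variant.

    * ``within_stage`` - one column per covariate per movement stage; each
      coefficient tests selection against zero within that stage.
    * ``vs_resident`` - covariate main effects (residents as reference)
      plus covariate-by-stage interaction columns for the two transient
      stages; interactions test differences from residents.
    * ``two_level`` - as ``vs_resident`` with a single transient level.

    Stage main effects are stratum-constant and therefore absorbed by the
    conditioning; they are never included.  Returns ``(X, info)`` where
    ``X`` is indexed like ``strata`` and ``info`` holds per-row stratum ids
    and case flags.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(
            f"unknown model variant '{variant}'; expected one of {VARIANTS}"
        )
    expanded, cols = covariate_columns(strata, standardize_tri)
    stage = expanded["stage"]
    X = pd.DataFrame(index=expanded.index)
    if variant == "within_stage":
        stages = [s for s in (STAGE_RESIDENT, STAGE_LOCAL, STAGE_ACTIVE)
                  if (stage == s).any()]
        for s in stages:
            ind = (stage == s).astype(float)
            for c in cols:
                X[f"{c}:{s}"] = expanded[c] * ind
    elif variant == "vs_resident":
        for c in cols:
            X[c] = expanded[c].astype(float)
        for s in (STAGE_LOCAL, STAGE_ACTIVE):
            if not (stage == s).any():
                continue
            ind = (stage == s).astype(float)
            for c in cols:
                X[f"{c}:{s}"] = expanded[c] * ind
    else:  # two_level
        transient = stage.isin([STAGE_LOCAL, STAGE_ACTIVE]).astype(float)
        for c in cols:
            X[c] = expanded[c].astype(float)
        for c in cols:
            X[f"{c}:transient"] = expanded[c] * transient
    info = expanded[["stratum_id", "is_case", "individual", "stage"]].copy()
    return X, info


# ---------------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------------

@dataclass
class SelectionFit:
    """Converged conditional-logistic fit."""

    beta: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_strata: int
    n_steps: int
    n_iter: int
    converged: bool
    score_norm: float
    variant: str = ""
    #: set when the converged solution has implausibly large coefficients —
    #: the usual signature of (quasi-)separation, e.g. a stage with no case
    #: steps on a feature; the Wald SEs of the affected terms are meaningless
    separation_suspect: bool = False

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.beta.index)

    def summary(self) -> pd.DataFrame:
        se = self.se
        z = self.beta / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": self.beta, "se": se, "z": z, "p": p}
        )


def _prepare_arrays(X: pd.DataFrame, info: pd.DataFrame):
    order = np.argsort(info["stratum_id"].to_numpy(), kind="stable")
    Xv = X.to_numpy(float)[order]
    y = info["is_case"].to_numpy(int)[order]
    sid = info["stratum_id"].to_numpy()[order]
    starts = np.nonzero(np.r_[True, sid[1:] != sid[:-1]])[0]
    counts = np.diff(np.r_[starts, len(sid)])
    case_per = np.add.reduceat(y, starts)
    if not np.all(case_per == 1):
        raise DataError("every stratum must contain exactly one case step")
    return Xv, y, starts, counts


def _check_rank(Xc: np.ndarray, names: list[str]) -> None:
    if Xc.shape[0] == 0:
        raise DataError("no strata to fit")
    sv = np.linalg.svd(Xc, compute_uv=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    rank = int((sv > tol).sum())
    if rank < Xc.shape[1]:
        # name columns not supported by the independent ones via pivoted QR
        _, _, piv = sla.qr(Xc, pivoting=True, mode="economic")
        aliased = [names[piv[i]] for i in range(rank, len(names))]
        raise RankDeficiencyError(sorted(set(aliased)) or names)


def fit_clr(
    X: pd.DataFrame,
    info: pd.DataFrame,
    variant: str = "",
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
    max_iter: int = 50,
    max_beta: float = 35.0,
    suspect_beta: float = 15.0,
) -> SelectionFit:
    """Maximise the stratified conditional likelihood by Newton-Raphson.

    Starts at beta = 0 with step-halving; the conditional log likelihood is
    concave, so iterates increase it monotonically.  Divergence of
    ``||beta||`` beyond ``max_beta`` raises :class:`SeparationError`; a
    converged solution with ``||beta||`` beyond ``suspect_beta`` is returned
    with ``separation_suspect`` set (quasi-separation converges in score
    long before the coefficients stop being absurd).
    """
    names = list(X.columns)
    Xv, y, starts, counts = _prepare_arrays(X, info)
    sidx = np.repeat(np.arange(len(starts)), counts)
    # within-stratum centring for the rank check (stratum-constant columns
    # carry no information in a conditional likelihood)
    means = np.add.reduceat(Xv, starts, axis=0) / counts[:, None]
    _check_rank(Xv - means[sidx], names)

    def loglik_parts(beta):
        eta = Xv @ beta
        smax = np.maximum.reduceat(eta, starts)
        ex = np.exp(eta - smax[sidx])
        denom = np.add.reduceat(ex, starts)
        ll = float(eta[y == 1].sum() - (smax + np.log(denom)).sum())
        probs = ex / denom[sidx]
        return ll, probs

    beta = np.zeros(Xv.shape[1])
    ll, probs = loglik_parts(beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        grad = Xv.T @ (y - probs)
        xbar = np.add.reduceat(probs[:, None] * Xv, starts, axis=0)
        H = (Xv * probs[:, None]).T @ Xv - xbar.T @ xbar  # observed information
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, probs_new = loglik_parts(cand)
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        beta, d_ll = cand, ll_new - ll
        ll, probs = ll_new, probs_new
        if np.max(np.abs(beta)) > max_beta:
            raise SeparationError(
                "conditional-logistic fit diverged (||beta|| > "
                f"{max_beta}); a covariate may perfectly separate cases"
            )
        grad = Xv.T @ (y - probs)
        if np.max(np.abs(grad)) < tol_score or abs(d_ll) < tol_loglik:
            converged = True
            break
    xbar = np.add.reduceat(probs[:, None] * Xv, starts, axis=0)
    H = (Xv * probs[:, None]).T @ Xv - xbar.T @ xbar
    cov = np.linalg.inv(H)
    cov = (cov + cov.T) / 2
    return SelectionFit(
        beta=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=ll,
        n_strata=len(starts),
        n_steps=len(y),
        n_iter=n_iter,
        converged=converged,
        score_norm=float(np.max(np.abs(Xv.T @ (y - probs)))),
        variant=variant,
        separation_suspect=bool(np.max(np.abs(beta)) > suspect_beta),
    )


def drop_degenerate_columns(X: pd.DataFrame, info: pd.DataFrame) -> pd.DataFrame:
    """Drop columns with no within-stratum variation (they carry no
    information in a conditional likelihood and would alias)."""
    centred = X.to_numpy(float) - X.groupby(info["stratum_id"].to_numpy()) \
        .transform("mean").to_numpy(float)
    norms = np.abs(centred).max(axis=0)
    dead = [c for c, nz in zip(X.columns, norms) if nz < 1e-12]
    if dead:
        log.info("dropping %d degenerate design columns: %s", len(dead), dead)
    return X.drop(columns=dead)


def fit_selection(
    strata: pd.DataFrame,
    variant: str = "within_stage",
    drop_degenerate: bool = False,
    **kwargs,
) -> SelectionFit:
    """Convenience wrapper: build the design for ``variant`` and fit."""
    X, info = build_design(strata, variant)
    if drop_degenerate:
        X = drop_degenerate_columns(X, info)
    return fit_clr(X, info, variant=variant, **kwargs)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def rss_report(fit: SelectionFit, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-term relative selection strength table.

    RSS = exp(beta_hat); the CI is exp(beta_hat +/- z * SE); significance
    stars follow the usual 0.05/0.01/0.001 thresholds.
    """
    zcrit = stats.norm.ppf(0.5 + ci_level / 2)
    summ = fit.summary()
    out = summ.copy()
    with np.errstate(over="ignore"):
        out["rss"] = np.exp(summ["estimate"])
        out["log_rss"] = summ["estimate"]
        out["rss_lo"] = np.exp(summ["estimate"] - zcrit * summ["se"])
        out["rss_hi"] = np.exp(summ["estimate"] + zcrit * summ["se"])
    out["stars"] = [_stars(p) for p in summ["p"]]
    out.index.name = "term"
    return out
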