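"""Four-state hidden Markov movement classifier.

Emissions are gamma (10 s step length) and von Mises (turning angle, when
defined); parameters are estimated by EM (Baum-Welch) from several seeded
random starts, keeping the best log likelihood.  After fitting, states are
relabelled so that occupied states sort ascending by mean step length —
state 1 is the quietest — and "moving" means state >= 2.

Missing turning angles (first step of a window sequence, or zero-length
steps) contribute only the length likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .errors import ConvergenceError, DataError

log = logging.getLogger(__name__)

_MIN_LEN = 1e-3  # m: floor for 10 s step lengths to keep gamma support open


def _weighted_gamma_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE via Newton on the shape equation."""
    wsum = w.sum()
    if wsum <= 0:
        return 1.0, 1.0
    mean = float((w * x).sum() / wsum)
    meanlog = float((w * np.log(x)).sum() / wsum)
    s = np.log(mean) - meanlog
    if s <= 0:  # numerically constant sample
        return 1e6, mean / 1e6
    k = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)  # standard start
    for _ in range(40):
        f = np.log(k) - special.digamma(k) - s
        fp = 1 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2
        if abs(k_new - k) < 1e-10 * k:
            k = k_new
            break
        k = k_new
    k = float(np.clip(k, 1e-3, 1e6))
    return k, mean / k


def _a1inv(r: float) -> float:
    """Approximate inverse of I1/I0 (Best & Fisher) for von Mises kappa."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1 / (r**3 - 4 * r**2 + 3 * r)


def _weighted_vonmises_mle(a: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    if wsum <= 0:
        return 0.0, 1e-6
    c = float((w * np.cos(a)).sum() / wsum)
    s = float((w * np.sin(a)).sum() / wsum)
    r = min(np.hypot(c, s), 1 - 1e-9)
    mu = float(np.arctan2(s, c))
    return mu, float(np.clip(_a1inv(r), 1e-6, 1e4))


@dataclass
class MovementHMM:
    """Fitted 4-state movement model (states 1..4 ascending by step length)."""

    n_states: int
    startprob: np.ndarray
    transmat: np.ndarray
    gamma_params: np.ndarray  # (n_states, 2): shape, scale
    vm_params: np.ndarray  # (n_states, 2): mu, kappa
    occupancy: np.ndarray = field(default=None)
    loglik: float = float("nan")

    @property
    def mean_lengths(self) -> np.ndarray:
        return self.gamma_params[:, 0] * self.gamma_params[:, 1]

    def _log_emissions(self, lengths: np.ndarray, angles: np.ndarray) -> np.ndarray:
        T = len(lengths)
        logb = np.zeros((T, self.n_states))
        have_angle = np.isfinite(angles)
        for s in range(self.n_states):
            k, sc = self.gamma_params[s]
            logb[:, s] = stats.gamma.logpdf(lengths, k, scale=sc)
            mu, kappa = self.vm_params[s]
            logb[have_angle, s] += stats.vonmises.logpdf(angles[have_angle], kappa, loc=mu)
        return logb

    def viterbi(self, lengths: np.ndarray, angles: np.ndarray) -> np.ndarray:
        """Most likely state sequence (1-based labels)."""
        logb = self._log_emissions(lengths, angles)
        logA = np.log(self.transmat + 1e-300)
        T, S = logb.shape
        delta = np.log(self.startprob + 1e-300) + logb[0]
        back = np.zeros((T, S), dtype=int)
        for t in range(1, T):
            scores = delta[:, None] + logA
            back[t] = np.argmax(scores, axis=0)
            delta = scores[back[t], np.arange(S)] + logb[t]
        states = np.zeros(T, dtype=int)
        states[-1] = int(np.argmax(delta))
        for t in range(T - 2, -1, -1):
            states[t] = back[t + 1, states[t + 1]]
        return states + 1

    def moving_mask(self, lengths: np.ndarray, angles: np.ndarray) -> np.ndarray:
        """True where the decoded state is a moving state (>= 2)."""
        return self.viterbi(lengths, angles) >= 2


def _forward_backward(logb, startprob, transmat):
    T, S = logb.shape
    A = transmat
    alpha = np.zeros((T, S))
    scale = np.zeros(T)
    a = startprob * np.exp(logb[0] - logb[0].max())
    scale0 = a.sum()
    alpha[0] = a / scale0
    logZ = np.log(scale0) + logb[0].max()
    for t in range(1, T):
        shift = logb[t].max()
        a = (alpha[t - 1] @ A) * np.exp(logb[t] - shift)
        sc = a.sum()
        alpha[t] = a / sc
        logZ += np.log(sc) + shift
        scale[t] = sc
    beta = np.ones((T, S))
    xi_sum = np.zeros((S, S))
    for t in range(T - 2, -1, -1):
        shift = logb[t + 1].max()
        b = np.exp(logb[t + 1] - shift) * beta[t + 1]
        xi = alpha[t][:, None] * A * b[None, :]
        xi_sum += xi / xi.sum()
        beta[t] = A @ b
        beta[t] /= beta[t].sum()
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post, xi_sum, logZ


def ten_second_steps(
    xs: np.ndarray, ys: np.ndarray, window: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a 1 Hz run to ``window``-second steps.

    Returns (lengths, angles); angles are NaN for the first step and after
    near-zero steps where the bearing is undefined.
    """
    xi = xs[::window]
    yi = ys[::window]
    dx = np.diff(xi)
    dy = np.diff(yi)
    lengths = np.hypot(dx, dy)
    bear = np.arctan2(dx, dy)
    angles = np.full_like(lengths, np.nan)
    defined = lengths > _MIN_LEN
    ok = defined[1:] & defined[:-1]
    turn = (bear[1:] - bear[:-1] + np.pi) % (2 * np.pi) - np.pi
    angles[1:][ok] = turn[ok]
    return np.maximum(lengths, _MIN_LEN), angles


def fit_hmm(
    sequences: list[tuple[np.ndarray, np.ndarray]],
    n_states: int = 4,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_steps: int = 500,
) -> MovementHMM:
    """EM-fit the movement HMM on (lengths, angles) sequences.

    ``n_starts`` seeded random initialisations are run; the best final log
    likelihood wins.  States are relabelled ascending by mean step length,
    with effectively unoccupied states (posterior mass < 0.5%) placed last
    (their emission parameters never left the initialisation and carry no
    ranking information).
    """
    sequences = [
        (np.maximum(np.asarray(l, float), _MIN_LEN), np.asarray(a, float))
        for l, a in sequences
        if len(l) >= 2
    ]
    n_total = sum(len(l) for l, _ in sequences)
    if n_total < min_steps:
        raise DataError(
            f"need at least {min_steps} ten-second steps to fit the HMM, got {n_total}"
        )
    all_len = np.concatenate([l for l, _ in sequences])
    rng = np.random.default_rng(seed)
    best: MovementHMM | None = None
    for _ in range(n_starts):
        model = _em_once(sequences, all_len, n_states, rng, max_iter, tol)
        if model is not None and (best is None or model.loglik > best.loglik):
            best = model
    if best is None:
        raise ConvergenceError("HMM EM failed to produce a finite log likelihood")
    return _sort_states(best)


def _em_once(sequences, all_len, n_states, rng, max_iter, tol) -> MovementHMM | None:
    # init: hard-assign windows to jittered log-length quantile centres and
    # fit per-group emissions (sharper than a flat-shape start, which tends
    # to stall in split local optima)
    all_angles = np.concatenate([a for _, a in sequences])
    log_len = np.log(all_len)
    centres = np.quantile(log_len, np.linspace(0.03, 0.97, n_states))
    centres = centres + rng.normal(0, 0.25 * (np.ptp(centres) / n_states + 0.1),
                                   size=n_states)
    assign = np.argmin(np.abs(log_len[:, None] - centres[None, :]), axis=1)
    gamma_params = np.zeros((n_states, 2))
    vm_params = np.zeros((n_states, 2))
    have_angle0 = np.isfinite(all_angles)
    for s in range(n_states):
        w = (assign == s).astype(float)
        if w.sum() < 3:
            w = np.full(all_len.shape, 1e-3)
        gamma_params[s] = _weighted_gamma_mle(all_len, w)
        vm_params[s] = _weighted_vonmises_mle(
            all_angles[have_angle0], w[have_angle0]
        )
    transmat = np.full((n_states, n_states), 0.1 / (n_states - 1))
    np.fill_diagonal(transmat, 0.9)
    startprob = np.full(n_states, 1 / n_states)
    model = MovementHMM(n_states, startprob, transmat, gamma_params, vm_params)

    prev_ll = -np.inf
    for it in range(max_iter):
        posts, xi_tot, ll = [], np.zeros((n_states, n_states)), 0.0
        start_acc = np.zeros(n_states)
        for lengths, angles in sequences:
            logb = model._log_emissions(lengths, angles)
            post, xi, logZ = _forward_backward(logb, model.startprob, model.transmat)
            posts.append(post)
            xi_tot += xi
            start_acc += post[0]
            ll += logZ
        if not np.isfinite(ll):
            return None
        w = np.vstack(posts)
        lengths_all = np.concatenate([l for l, _ in sequences])
        angles_all = np.concatenate([a for _, a in sequences])
        have_angle = np.isfinite(angles_all)
        for s in range(n_states):
            model.gamma_params[s] = _weighted_gamma_mle(lengths_all, w[:, s])
            if have_angle.any():
                model.vm_params[s] = _weighted_vonmises_mle(
                    angles_all[have_angle], w[have_angle, s]
                )
        rows = xi_tot.sum(axis=1, keepdims=True)
        model.transmat = np.where(rows > 0, xi_tot / np.maximum(rows, 1e-300), 1 / n_states)
        model.startprob = start_acc / start_acc.sum()
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    model.loglik = prev_ll
    model.occupancy = w.sum(axis=0) / w.sum()
    return model


def _sort_states(model: MovementHMM) -> MovementHMM:
    occ = model.occupancy
    occupied = occ >= 0.005
    means = model.mean_lengths
    # occupied states first, ascending by mean length; starved states last
    order = np.lexsort((means, ~occupied))
    inv = np.argsort(order)
    return MovementHMM(
        n_states=model.n_states,
        startprob=model.startprob[order],
        transmat=model.transmat[np.ix_(order, order)],
        gamma_params=model.gamma_params[order],
        vm_params=model.vm_params[order],
        occupancy=occ[order],
        loglik=model.loglik,
    )
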