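"""Partially coupled binary Markov model of multi-channel gating.

A membrane patch is modelled as ``N`` identical two-state (closed/open)
channels observed through the aggregate open count ``k in {0..N}``.  The
one-step transition matrix over ``k`` is a convex mixture

    T = (1 - kappa) * T_unc + kappa * T_cpl

where ``T_unc`` is the fully independent (uncoupled) kinetics — each open
channel stays open with probability ``rho`` and each closed channel stays
closed with probability ``sigma_c`` — and ``T_cpl`` moves all channels in
unison: the single-channel chain is applied to the majority state of the
current configuration (ties broken toward open), so coupled rows place mass
only on the extreme levels 0 and N.

The module provides construction, stationary analysis, seeded simulation,
exact log-likelihood of an observed level sequence, and maximum-likelihood
fitting of ``(kappa, rho, sigma_c)`` by multi-start projected gradient
ascent in logit space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, logit
from scipy.stats import binom

__all__ = [
    "CoupledMarkovParams",
    "TransitionMatrix",
    "LevelSequence",
    "FitResult",
    "build_transition_matrix",
    "stationary_distribution",
    "simulate_chain",
    "simulate_sweeps",
    "transition_counts",
    "loglik",
    "fit_params",
]

#: per-step floor applied to the log of a forbidden (zero-probability) transition
LOG_FLOOR = -700.0


@dataclass(frozen=True)
class CoupledMarkovParams:
    """Parameters of the partially coupled gating chain.

    Parameters
    ----------
    n_channels : int
        Number of channels N in the patch (>= 1).
    kappa : float
        Coupling coefficient in [0, 1]; 0 = independent, 1 = unison gating.
    rho : float
        Per-step open-to-open probability of a single channel.
    sigma_c : float
        Per-step closed-to-closed probability of a single channel.
    unitary_current : float, optional
        Single-channel current amplitude in pA (> 0).
    dt : float, optional
        Seconds per discrete step (> 0); 1e-4 matches 10 kHz sampling.
    """

    n_channels: int
    kappa: float
    rho: float
    sigma_c: float
    unitary_current: float = 1.0
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if int(self.n_channels) != self.n_channels or self.n_channels < 1:
            raise ValueError("n_channels must be an integer >= 1")
        for name in ("kappa", "rho", "sigma_c"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.rho == 1.0 and self.sigma_c == 1.0:
            raise ValueError("rho and sigma_c cannot both be 1 (frozen chain)")
        if self.unitary_current <= 0:
            raise ValueError("unitary_current must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def p_inf(self) -> float:
        """Stationary open probability of a single uncoupled channel."""
        return (1.0 - self.sigma_c) / ((1.0 - self.sigma_c) + (1.0 - self.rho))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CoupledMarkovParams":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix over the aggregate open-channel count."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(p < -1e-15):
            raise ValueError("transition matrix has negative entries")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("rows must sum to 1 within 1e-12")
        object.__setattr__(self, "probs", p)

    @property
    def n_channels(self) -> int:
        return self.probs.shape[0] - 1

    def to_csv(self, path) -> None:
        np.savetxt(path, self.probs, delimiter=",")


@dataclass(frozen=True)
class LevelSequence:
    """Integer open-channel levels sampled every ``dt`` seconds."""

    levels: np.ndarray
    dt: float
    n_channels: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=np.int64)
        if lv.ndim != 1:
            raise ValueError("levels must be a 1-D sequence")
        if lv.size and (lv.min() < 0 or lv.max() > self.n_channels):
            raise ValueError("levels must lie in {0..n_channels}")
        object.__setattr__(self, "levels", lv)

    def __len__(self) -> int:
        return self.levels.size

    def to_json(self) -> str:
        return json.dumps(
            {"levels": self.levels.tolist(), "dt": self.dt, "n_channels": self.n_channels}
        )

    @classmethod
    def from_json(cls, s: str) -> "LevelSequence":
        d = json.loads(s)
        return cls(np.asarray(d["levels"]), d["dt"], d["n_channels"])


def _build_probs(n: int, kappa: float, rho: float, sigma_c: float) -> np.ndarray:
    """Mixture matrix as a plain array (fast path for fitting)."""
    t_unc = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        stay_open = binom.pmf(np.arange(k + 1), k, rho)
        newly_open = binom.pmf(np.arange(n - k + 1), n - k, 1.0 - sigma_c)
        t_unc[k, :] = np.convolve(stay_open, newly_open)
    t_cpl = np.zeros_like(t_unc)
    for k in range(n + 1):
        if 2 * k >= n:  # majority open (tie -> open)
            t_cpl[k, n] = rho
            t_cpl[k, 0] = 1.0 - rho
        else:
            t_cpl[k, 0] = sigma_c
            t_cpl[k, n] = 1.0 - sigma_c
    return (1.0 - kappa) * t_unc + kappa * t_cpl


def build_transition_matrix(params: CoupledMarkovParams) -> TransitionMatrix:
    """Build T = (1-kappa)*T_unc + kappa*T_cpl over levels {0..N}."""
    return TransitionMatrix(
        _build_probs(params.n_channels, params.kappa, params.rho, params.sigma_c)
    )


def stationary_distribution(t: TransitionMatrix) -> np.ndarray:
    """Stationary distribution pi with pi @ T = pi and sum(pi) = 1.

    A reducible chain (attainable only at parameter boundaries, e.g.
    kappa = 1 with rho = 1) is flagged with a warning and a boundary
    distribution over the absorbing extreme levels is returned.
    """
    p = t.probs
    w, v = np.linalg.eig(p.T)
    one = np.isclose(w.real, 1.0, atol=1e-9) & np.isclose(w.imag, 0.0, atol=1e-9)
    idx = np.flatnonzero(one)
    if idx.size == 0:  # numerical fallback
        idx = np.array([int(np.argmin(np.abs(w - 1.0)))])
    if idx.size > 1:
        warnings.warn(
            "reducible chain: stationary distribution is not unique; "
            "returning a boundary distribution",
            RuntimeWarning,
        )
        n = p.shape[0] - 1
        absorbing = [k for k in (0, n) if p[k, k] >= 1.0 - 1e-12]
        pi = np.zeros(p.shape[0])
        if absorbing:
            pi[absorbing] = 1.0 / len(absorbing)
        else:
            pi[0] = 1.0
        return pi
    pi = v[:, idx[0]].real
    pi = np.clip(pi / pi.sum(), 0.0, None)
    pi /= pi.sum()
    # power-iteration polish for the fixed-point identity
    for _ in range(200):
        nxt = pi @ p
        if np.max(np.abs(nxt - pi)) < 1e-14:
            pi = nxt
            break
        pi = nxt
    return pi / pi.sum()


def simulate_chain(
    params: CoupledMarkovParams,
    n_steps: int,
    seed: int,
    initial_level: int | None = None,
) -> LevelSequence:
    """Simulate the configuration-level process for ``n_steps`` samples.

    Each step an independent Bernoulli(kappa) coupling indicator selects a
    unison move (single-channel chain applied to the majority state) or
    independent per-channel moves.  Identical seeds give identical output.

    Parameters
    ----------
    initial_level : int or None
        Starting level; ``None`` draws it from the stationary distribution.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    n = params.n_channels
    rng = np.random.default_rng(seed)
    if initial_level is None:
        pi = stationary_distribution(build_transition_matrix(params))
        k = int(rng.choice(n + 1, p=pi))
    else:
        if not 0 <= initial_level <= n:
            raise ValueError("initial_level outside {0..N}")
        k = int(initial_level)
    kap, rho, sig = params.kappa, params.rho, params.sigma_c
    out = np.empty(n_steps, dtype=np.int64)
    out[0] = k
    pos = 1
    chunk = 65536
    while pos < n_steps:
        m = min(chunk, n_steps - pos)
        uc = rng.random(m).tolist()
        uu = rng.random(m).tolist()
        upc = rng.random((m, n)).tolist()
        for i in range(m):
            if uc[i] < kap:
                if 2 * k >= n:
                    k = n if uu[i] < rho else 0
                else:
                    k = 0 if uu[i] < sig else n
            else:
                row = upc[i]
                s = 0
                for j in range(k):
                    if row[j] < rho:
                        s += 1
                for j in range(k, n):
                    if row[j] >= sig:
                        s += 1
                k = s
            out[pos + i] = k
        pos += m
    return LevelSequence(out, params.dt, n)


def simulate_sweeps(
    params: CoupledMarkovParams,
    n_sweeps: int,
    n_steps: int,
    seed: int,
    initial_level: int | None = 0,
) -> np.ndarray:
    """Vectorized simulation of many independent sweeps.

    Returns an ``(n_sweeps, n_steps)`` integer array of levels.  Semantics
    per sweep match :func:`simulate_chain` (per-step Bernoulli(kappa)
    coupling indicator); the random stream differs because sweeps advance
    in lock-step.
    """
    if n_steps < 1 or n_sweeps < 1:
        raise ValueError("n_sweeps and n_steps must be >= 1")
    n = params.n_channels
    rng = np.random.default_rng(seed)
    if initial_level is None:
        pi = stationary_distribution(build_transition_matrix(params))
        k = rng.choice(n + 1, size=n_sweeps, p=pi).astype(np.int64)
    else:
        k = np.full(n_sweeps, int(initial_level), dtype=np.int64)
    kap, rho, sig = params.kappa, params.rho, params.sigma_c
    out = np.empty((n_sweeps, n_steps), dtype=np.int64)
    out[:, 0] = k
    for t in range(1, n_steps):
        couple = rng.random(n_sweeps) < kap
        uu = rng.random(n_sweeps)
        stays = rng.binomial(k, rho)
        opens = rng.binomial(n - k, 1.0 - sig)
        indep = stays + opens
        maj_open = 2 * k >= n
        unison = np.where(maj_open, np.where(uu < rho, n, 0), np.where(uu < sig, 0, n))
        k = np.where(couple, unison, indep)
        out[:, t] = k
    return out


def transition_counts(seq: LevelSequence) -> np.ndarray:
    """(N+1)x(N+1) matrix of observed one-step transition counts."""
    n = seq.n_channels
    c = np.zeros((n + 1, n + 1))
    np.add.at(c, (seq.levels[:-1], seq.levels[1:]), 1.0)
    return c


def _loglik_counts(counts: np.ndarray, probs: np.ndarray) -> tuple[float, int]:
    logp = np.where(probs > 0.0, np.log(np.where(probs > 0.0, probs, 1.0)), LOG_FLOOR)
    forbidden = int(counts[(probs <= 0.0)].sum())
    return float(np.sum(counts * logp)), forbidden


def loglik(seq: LevelSequence, params: CoupledMarkovParams) -> float:
    """Exact Markov log-likelihood (nats) of a level sequence.

    Forbidden transitions (probability exactly zero under ``params``)
    contribute ``LOG_FLOOR`` nats per step and trigger a warning.
    """
    if len(seq) < 2:
        raise ValueError("sequence must contain at least 2 samples")
    if seq.n_channels != params.n_channels:
        raise ValueError("sequence and params disagree on n_channels")
    probs = _build_probs(params.n_channels, params.kappa, params.rho, params.sigma_c)
    ll, forbidden = _loglik_counts(transition_counts(seq), probs)
    if forbidden:
        warnings.warn(
            f"{forbidden} forbidden transition(s) floored at {LOG_FLOOR} nats each",
            RuntimeWarning,
        )
    return ll


@dataclass
class FitResult:
    """Outcome of :func:`fit_params`."""

    params: CoupledMarkovParams
    loglik: float
    n_iter: int
    start_index: int
    converged: bool
    degenerate: bool = False
    message: str = ""


_DEFAULT_STARTS = (
    (0.5, 0.5, 0.5),
    (0.1, 0.9, 0.9),
    (0.9, 0.9, 0.9),
    (0.3, 0.7, 0.8),
    (0.05, 0.6, 0.95),
)

_THETA_CLIP = 35.0  # |logit| bound; expit(35) differs from 1 by ~6e-16


def _ascend(counts, n, theta0, max_iter, tol, grad_h):
    """Adaptive-step gradient ascent on the logit-parameterized loglik."""

    def f(theta):
        kap, rho, sig = expit(theta)
        return _loglik_counts(counts, _build_probs(n, kap, rho, sig))[0]

    theta = np.clip(np.asarray(theta0, dtype=float), -_THETA_CLIP, _THETA_CLIP)
    fval = f(theta)
    lr = 0.05
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        g = np.empty(3)
        for d in range(3):
            e = np.zeros(3)
            e[d] = grad_h
            g[d] = (f(theta + e) - f(theta - e)) / (2.0 * grad_h)
        gnorm = np.linalg.norm(g)
        if gnorm == 0.0:
            converged = True
            break
        improved = False
        for _ in range(60):
            cand = np.clip(theta + lr * g, -_THETA_CLIP, _THETA_CLIP)
            fcand = f(cand)
            if fcand >= fval:
                improved = True
                break
            lr *= 0.5
        if not improved:
            converged = True
            break
        delta = fcand - fval
        theta, fval = cand, fcand
        lr = min(lr * 1.5, 50.0)
        if delta < tol:
            converged = True
            break
    return theta, fval, it, converged


def fit_params(
    seq: LevelSequence,
    n_channels: int | None = None,
    init: CoupledMarkovParams | None = None,
    n_starts: int = 5,
    max_iter: int = 5000,
    tol: float = 1e-8,
    grad_h: float = 1e-5,
) -> FitResult:
    """Maximum-likelihood fit of (kappa, rho, sigma_c) from a level sequence.

    Multi-start gradient ascent with central-difference gradients in logit
    space; convergence when the loglik improvement drops below ``tol`` or
    after ``max_iter`` iterations.  An all-constant sequence carries no
    kinetic information and returns a flagged boundary estimate.
    """
    if len(seq) < 2:
        raise ValueError("sequence must contain at least 2 samples")
    n = seq.n_channels if n_channels is None else int(n_channels)
    if seq.levels.max(initial=0) > n:
        raise ValueError("observed levels exceed n_channels")
    dt = seq.dt
    unitary = init.unitary_current if init is not None else 1.0

    uniq = np.unique(seq.levels)
    if uniq.size == 1:
        k = int(uniq[0])
        rho = 1.0 if k == n else (init.rho if init is not None else 0.5)
        sig = 1.0 if k < n else (init.sigma_c if init is not None else 0.5)
        if k not in (0, n):
            rho, sig = 1.0, 1.0 - 1e-12  # interior constant level: both boundaries
        kap = init.kappa if init is not None else 0.0
        params = CoupledMarkovParams(n, kap, rho, sig, unitary, dt)
        return FitResult(
            params,
            loglik=0.0,
            n_iter=0,
            start_index=-1,
            converged=True,
            degenerate=True,
            message="constant level sequence: boundary estimate, parameters not identifiable",
        )

    counts = transition_counts(LevelSequence(seq.levels, dt, n))
    starts: list[tuple[float, float, float]] = []
    if init is not None:
        starts.append((init.kappa, init.rho, init.sigma_c))
    starts.extend(_DEFAULT_STARTS)
    starts = starts[: max(n_starts, 1)]

    best = None
    for i, s in enumerate(starts):
        theta0 = logit(np.clip(s, 1e-6, 1.0 - 1e-6))
        theta, fval, n_iter, conv = _ascend(counts, n, theta0, max_iter, tol, grad_h)
        if best is None or fval > best[1]:
            best = (theta, fval, n_iter, i, conv)
    theta, fval, n_iter, start_idx, conv = best
    kap, rho, sig = (float(x) for x in expit(theta))
    params = CoupledMarkovParams(n, kap, rho, sig, unitary, dt)
    return FitResult(params, float(fval), n_iter, start_idx, conv)
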