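"""Exact stochastic simulation of the feedback circuit.

The discrete counterpart of the Langevin model is a four-channel birth-death
network on integer copy numbers:

    X -> X+1   at rate k_xy * H(y; K_xy, n)
    X -> X-1   at rate mu_x * x
    Y -> Y+1   at rate k_yx * H(x; K_yx, n)
    Y -> Y-1   at rate mu_y * y

simulated with the Gillespie direct method (exponential waiting times, channel
chosen proportional to propensity).  Hill functions are evaluated at integer
copy numbers directly; no volume scaling is applied.  The state (0, 0) is
absorbing: H(0) = 0 silences both birth channels, so once both products are
extinct nothing can restart.

The inner loops are JIT-compiled with numba; a run with the same seed and
parameters reproduces the identical trajectory bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from numba import njit

from . import __version__ as _version
from .dynamics import find_fixed_points
from .errors import InsufficientDataError, InvalidParameterError, InvalidSetupError
from .lna import CovarianceMatrix, InformationSummary, information_summary
from .params import ConstitutiveGeneParams, FeedbackLoopParams, StatePoint

__all__ = [
    "SSAConfig",
    "Trajectory",
    "MomentEstimate",
    "gillespie_run",
    "constitutive_run",
    "stationary_moments",
    "empirical_mi",
    "memory_persistence",
]

_CHUNK = 1 << 20  # events simulated per kernel call before arrays are grown

# Largest correlation magnitude accepted from sampled moments before clipping;
# guards against round-off pushing an empirical rho past 1.
_RHO_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class SSAConfig:
    """Run configuration: seed, total simulated time and burn-in (min)."""

    seed: int
    t_total: float
    t_burnin: float = 0.0
    initial_state: StatePoint = StatePoint(0, 0)

    def __post_init__(self) -> None:
        if not 0 <= self.t_burnin < self.t_total:
            raise InvalidParameterError(
                f"need 0 <= t_burnin < t_total, got ({self.t_burnin}, {self.t_total})"
            )
        x, y = self.initial_state
        if x < 0 or y < 0 or x != int(x) or y != int(y):
            raise InvalidParameterError("initial state must have non-negative integer entries")


@dataclass(frozen=True)
class Trajectory:
    """Piecewise-constant jump path of the two copy numbers.

    ``times[0] = 0`` holds the initial state; entry i of ``xs``/``ys`` is the
    state on [times[i], times[i+1]) and the last state extends to ``t_end``.
    ``t_end`` equals the configured horizon, or the absorption time when the
    run reached (0, 0) early.
    """

    times: np.ndarray = field(repr=False)
    xs: np.ndarray = field(repr=False)
    ys: np.ndarray = field(repr=False)
    t_end: float
    absorbed: bool
    seed: int
    params: Optional[FeedbackLoopParams] = None

    @property
    def n_events(self) -> int:
        return len(self.times) - 1

    def state_at_end(self) -> StatePoint:
        return StatePoint(int(self.xs[-1]), int(self.ys[-1]))

    def to_tsv(self, path: str | Path) -> None:
        """Write time / x / y columns with seed, parameters and version in
        comment headers."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# grn-memory {_version}\n")
            fh.write(f"# seed={self.seed} t_end={self.t_end:g} absorbed={self.absorbed}\n")
            if self.params is not None:
                fh.write(f"# params={self.params.to_dict()}\n")
            fh.write("time\tx\ty\n")
            for t, x, y in zip(self.times, self.xs, self.ys):
                fh.write(f"{t:.6f}\t{int(x)}\t{int(y)}\n")


@dataclass(frozen=True)
class MomentEstimate:
    """Time-weighted stationary moments of a trajectory window.

    Each state is weighted by its holding time, not by event count.  The
    standard errors of the means come from batch means over 32 equal-time
    batches.
    """

    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    cov_xy: float
    t_obs: float
    absorbed: bool
    se_mean_x: float = math.nan
    se_mean_y: float = math.nan

    def covariance(self) -> CovarianceMatrix:
        return CovarianceMatrix(var_x=self.var_x, var_y=self.var_y, cov_xy=self.cov_xy)


@njit(cache=False)
def _loop_kernel(x, y, t, t_end, kxy, kyx, Kxy_n, Kyx_n, n, mux, muy, times, xs, ys, seed):
    """Direct-method SSA chunk for the two-species loop.

    Records up to len(times) events; returns (stored, x, y, t, absorbed).
    Seeds numba's RNG when seed >= 0, otherwise continues the current stream.
    """
    if seed >= 0:
        np.random.seed(seed)
    cap = times.shape[0]
    m = 0
    absorbed = False
    while m < cap:
        yn = float(y) ** n
        xn = float(x) ** n
        bx = kxy * yn / (Kxy_n + yn)
        by = kyx * xn / (Kyx_n + xn)
        dx = mux * x
        dy = muy * y
        total = bx + dx + by + dy
        if total <= 0.0:
            absorbed = True
            break
        dt = np.random.exponential(1.0 / total)
        if t + dt > t_end:
            t = t_end
            break
        t = t + dt
        r = np.random.random() * total
        if r < bx:
            x += 1
        elif r < bx + dx:
            x -= 1
        elif r < bx + dx + by:
            y += 1
        else:
            y -= 1
        times[m] = t
        xs[m] = x
        ys[m] = y
        m += 1
    return m, x, y, t, absorbed


@njit(cache=False)
def _constitutive_kernel(x, t, t_end, k, mu, times, xs, seed):
    """Single-species birth-death chunk: constant birth k, linear death mu*x."""
    if seed >= 0:
        np.random.seed(seed)
    cap = times.shape[0]
    m = 0
    while m < cap:
        total = k + mu * x
        dt = np.random.exponential(1.0 / total)
        if t + dt > t_end:
            t = t_end
            break
        t = t + dt
        if np.random.random() * total < k:
            x += 1
        else:
            x -= 1
        times[m] = t
        xs[m] = x
        m += 1
    return m, x, t


def gillespie_run(p: FeedbackLoopParams, cfg: SSAConfig) -> Trajectory:
    """Exact SSA trajectory of the loop up to cfg.t_total.

    Terminates early (with ``absorbed=True``) if the absorbing state (0, 0)
    is reached; that is a legitimate outcome of the dynamics, not an error.
    Identical seed, parameters and configuration yield a bit-identical path.
    """
    x = int(cfg.initial_state.x)
    y = int(cfg.initial_state.y)
    t = 0.0
    Kxy_n = p.K_xy**p.n
    Kyx_n = p.K_yx**p.n
    t_parts = [np.array([0.0])]
    x_parts = [np.array([x], dtype=np.int64)]
    y_parts = [np.array([y], dtype=np.int64)]
    seed = int(cfg.seed)
    absorbed = False
    while True:
        tb = np.empty(_CHUNK)
        xb = np.empty(_CHUNK, dtype=np.int64)
        yb = np.empty(_CHUNK, dtype=np.int64)
        m, x, y, t, absorbed = _loop_kernel(
            x, y, t, cfg.t_total, p.k_xy, p.k_yx, Kxy_n, Kyx_n, p.n, p.mu_x, p.mu_y,
            tb, xb, yb, seed,
        )
        seed = -1  # subsequent chunks continue the stream
        if m:
            t_parts.append(tb[:m].copy())
            x_parts.append(xb[:m].copy())
            y_parts.append(yb[:m].copy())
        if absorbed or t >= cfg.t_total:
            break
    return Trajectory(
        times=np.concatenate(t_parts),
        xs=np.concatenate(x_parts),
        ys=np.concatenate(y_parts),
        t_end=t if absorbed else cfg.t_total,
        absorbed=absorbed,
        seed=int(cfg.seed),
        params=p,
    )


def constitutive_run(p: ConstitutiveGeneParams, cfg: SSAConfig) -> Trajectory:
    """Exact SSA of the unregulated gene (stationary law: Poisson(k_x/mu_x)).

    Returned as a Trajectory with the Y component identically zero so the
    same moment estimators apply.
    """
    x = int(cfg.initial_state.x)
    t = 0.0
    t_parts = [np.array([0.0])]
    x_parts = [np.array([x], dtype=np.int64)]
    seed = int(cfg.seed)
    while True:
        tb = np.empty(_CHUNK)
        xb = np.empty(_CHUNK, dtype=np.int64)
        m, x, t = _constitutive_kernel(x, t, cfg.t_total, p.k_x, p.mu_x, tb, xb, seed)
        seed = -1
        if m:
            t_parts.append(tb[:m].copy())
            x_parts.append(xb[:m].copy())
        if t >= cfg.t_total:
            break
    times = np.concatenate(t_parts)
    xs = np.concatenate(x_parts)
    return Trajectory(
        times=times,
        xs=xs,
        ys=np.zeros_like(xs),
        t_end=cfg.t_total,
        absorbed=False,
        seed=int(cfg.seed),
        params=None,
    )


def _window_weights(tr: Trajectory, a: float, b: float) -> np.ndarray:
    """Holding time of each recorded state inside the window (a, b]."""
    starts = tr.times
    ends = np.append(tr.times[1:], tr.t_end)
    return np.clip(np.minimum(ends, b) - np.maximum(starts, a), 0.0, None)


def stationary_moments(tr: Trajectory, t_burnin: float, n_batches: int = 32) -> MomentEstimate:
    """Time-weighted first and second moments over (t_burnin, t_end].

    If the trajectory was absorbed the window ends at the absorption time,
    so the estimate describes the dynamics conditioned on survival.  Mean
    standard errors use batch means over ``n_batches`` equal-time batches.
    """
    t_end = tr.t_end
    if t_burnin >= t_end:
        raise InsufficientDataError(
            f"burn-in {t_burnin:g} leaves no observation window before t_end {t_end:g}"
        )
    w = _window_weights(tr, t_burnin, t_end)
    T = w.sum()
    if T <= 0:
        raise InsufficientDataError("empty post-burn-in window")
    x = tr.xs.astype(float)
    y = tr.ys.astype(float)
    mx = float(w @ x) / T
    my = float(w @ y) / T
    vx = float(w @ (x - mx) ** 2) / T
    vy = float(w @ (y - my) ** 2) / T
    cxy = float(w @ ((x - mx) * (y - my))) / T

    edges = np.linspace(t_burnin, t_end, n_batches + 1)
    bm_x = np.empty(n_batches)
    bm_y = np.empty(n_batches)
    for i in range(n_batches):
        wb = _window_weights(tr, edges[i], edges[i + 1])
        Tb = wb.sum()
        if Tb > 0:
            bm_x[i] = (wb @ x) / Tb
            bm_y[i] = (wb @ y) / Tb
        else:
            bm_x[i] = mx
            bm_y[i] = my
    se_x = float(np.std(bm_x, ddof=1) / math.sqrt(n_batches))
    se_y = float(np.std(bm_y, ddof=1) / math.sqrt(n_batches))
    return MomentEstimate(
        mean_x=mx, mean_y=my, var_x=vx, var_y=vy, cov_xy=cxy,
        t_obs=float(T), absorbed=tr.absorbed, se_mean_x=se_x, se_mean_y=se_y,
    )


def empirical_mi(m: MomentEstimate) -> InformationSummary:
    """Gaussian plug-in mutual information from sampled moments.

    Feeds the empirical covariance through the Gaussian formula.  Sampling
    round-off occasionally pushes the empirical correlation past +-1; it is
    clipped to magnitude 1 - 1e-12 rather than raising, since the moments
    themselves are valid.
    """
    denom = math.sqrt(m.var_x * m.var_y)
    cov = m.cov_xy
    if denom > 0 and abs(cov) > _RHO_CLIP * denom:
        cov = math.copysign(_RHO_CLIP * denom, cov)
    return information_summary(CovarianceMatrix(var_x=m.var_x, var_y=m.var_y, cov_xy=cov))


def _persistence_threshold(p: FeedbackLoopParams, on: StatePoint) -> float:
    """Memory threshold: the interior unstable/saddle point when one separates
    OFF from ON, otherwise half the ON mean."""
    fps = find_fixed_points(p)
    interior = [
        f for f in fps
        if not f.is_stable and 0.0 < f.state.x < on.x and 0.0 < f.state.y < on.y
    ]
    if interior:
        return float(interior[-1].state.x)
    return 0.5 * float(on.x)


def memory_persistence(
    p: FeedbackLoopParams,
    on_state: StatePoint,
    n_rep: int,
    t_horizon: float,
    seed: int,
    threshold: float | None = None,
    require_stable: bool = True,
) -> float:
    """Fraction of replicates still in the ON basin after ``t_horizon`` min.

    Each of ``n_rep`` independent SSA replicates starts at ``on_state``
    (which must sit near a stable fixed point); a replicate persists if it
    was not absorbed at (0, 0) and both copy numbers remain at or above the
    memory threshold at the horizon.  Replicate seeds derive
    deterministically from ``seed``.  ``require_stable=False`` skips the
    check that ``on_state`` sits near a stable active fixed point, allowing
    persistence to be measured in regimes with no ON attractor at all (an
    explicit ``threshold`` is then recommended).
    """
    if n_rep < 1:
        raise InvalidParameterError("n_rep must be >= 1")
    if t_horizon < 0:
        raise InvalidParameterError("t_horizon must be non-negative")
    if require_stable:
        fps = find_fixed_points(p)
        stable = [f for f in fps if f.is_stable and f.state.x > 0]

        def _near(f):
            return (abs(f.state.x - on_state.x) <= max(1.0, 0.25 * f.state.x)
                    and abs(f.state.y - on_state.y) <= max(1.0, 0.25 * f.state.y))

        if not any(_near(f) for f in stable):
            raise InvalidSetupError(
                f"on_state {tuple(on_state)} is not near a stable active fixed point "
                f"(stable points: {[tuple(f.state) for f in stable]})"
            )
    thr = _persistence_threshold(p, on_state) if threshold is None else float(threshold)
    if t_horizon == 0:
        return 1.0
    rep_seeds = np.random.SeedSequence(int(seed)).generate_state(n_rep, dtype=np.uint32) >> 1
    alive = 0
    for rs in rep_seeds:
        tr = gillespie_run(p, SSAConfig(seed=int(rs), t_total=t_horizon, initial_state=on_state))
        xe, ye = tr.state_at_end()
        if not tr.absorbed and xe >= thr and ye >= thr:
            alive += 1
    return alive / n_rep
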