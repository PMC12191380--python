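"""Deterministic skeleton of the feedback circuit.

Hill activation, the drift field of the double positive feedback loop, its
Jacobian, and a fixed-point finder with linear stability classification.
The Y-nullcline is substituted into the X-nullcline to reduce root finding
to one dimension, which is robust because both nullclines are monotone for
Hill activation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, InvalidParameterError
from .params import ConstitutiveGeneParams, FeedbackLoopParams, PromoterBindingParams, StatePoint

__all__ = [
    "hill_activation",
    "hill_derivative",
    "constitutive_steady_state",
    "qss_bound_fraction",
    "drift",
    "jacobian",
    "FixedPoint",
    "find_fixed_points",
]

logger = logging.getLogger(__name__)

# Stability classification tolerance on eigenvalue real parts (1/min).
_EIG_TOL = 1e-9
# Residual tolerance for refined nullcline roots.
_ROOT_TOL = 1e-10
# Drift max-norm bound every returned fixed point must satisfy (copies/min).
_DRIFT_TOL = 1e-8


def _validate_hill(K: float, n: float) -> None:
    if not K > 0:
        raise InvalidParameterError(f"Hill constant K must be > 0, got {K!r}")
    if not n >= 1:
        raise InvalidParameterError(f"Hill coefficient n must be >= 1, got {n!r}")


def hill_activation(v, K: float, n: float):
    """Activating Hill function v^n / (K^n + v^n), in [0, 1).

    Saturating occupancy of a promoter by an activator at level ``v``:
    half-maximal at v = K, sharper with larger cooperativity n.  Accepts
    scalars or arrays in ``v``; evaluated in a form that cannot overflow
    for large v.
    """
    _validate_hill(K, n)
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise InvalidParameterError("activator level v must be non-negative")
    # For v > K use 1 / (1 + (K/v)^n) so v^n never overflows.
    small = v <= K
    safe_v = np.where(small, v, K)
    lo = safe_v**n / (K**n + safe_v**n)
    big_v = np.where(small, K, v)
    hi = 1.0 / (1.0 + (K / big_v) ** n)
    out = np.where(small, lo, hi)
    return float(out) if out.ndim == 0 else out


def hill_derivative(v: float, K: float, n: float) -> float:
    """d/dv of the Hill function: n K^n v^(n-1) / (K^n + v^n)^2."""
    _validate_hill(K, n)
    if v < 0:
        raise InvalidParameterError("activator level v must be non-negative")
    if v == 0.0:
        # Limit: 1/K for n == 1, zero slope for n > 1.
        return 1.0 / K if n == 1.0 else 0.0
    h = hill_activation(v, K, n)
    return n / v * h * (1.0 - h)


def constitutive_steady_state(p: ConstitutiveGeneParams) -> float:
    """Unique fixed point k_x / mu_x of dX/dt = k_x - mu_x X."""
    return p.k_x / p.mu_x


def qss_bound_fraction(x: float, p: PromoterBindingParams) -> float:
    """Quasi-steady-state promoter occupancy x / (K + x), K = k_off/k_on.

    Valid when TF-DNA binding equilibrates fast relative to synthesis;
    identical to ``hill_activation(x, K, 1)``.
    """
    if x < 0:
        raise InvalidParameterError("TF level must be non-negative")
    return hill_activation(x, p.K, 1.0)


def drift(s: StatePoint, p: FeedbackLoopParams) -> np.ndarray:
    """Deterministic rates (dX/dt, dY/dt) at state ``s`` (copies/min)."""
    x, y = s
    fx = p.k_xy * hill_activation(y, p.K_xy, p.n) - p.mu_x * x
    fy = p.k_yx * hill_activation(x, p.K_yx, p.n) - p.mu_y * y
    return np.array([fx, fy])


def jacobian(s: StatePoint, p: FeedbackLoopParams) -> np.ndarray:
    """Jacobian of the drift field at ``s`` (1/min).

    Diagonal entries are the degradation rates -mu_x, -mu_y; off-diagonals
    are the local gains of the two Hill activations.
    """
    x, y = s
    return np.array(
        [
            [-p.mu_x, p.k_xy * hill_derivative(y, p.K_xy, p.n)],
            [p.k_yx * hill_derivative(x, p.K_yx, p.n), -p.mu_y],
        ]
    )


@dataclass(frozen=True)
class FixedPoint:
    """A root of the drift field with its linearization.

    ``stability`` is 'stable' (both eigenvalue real parts < -1e-9/min),
    'saddle' (real parts of opposite sign), or 'unstable' otherwise;
    marginal spectra (|Re| <= 1e-9) are labelled unstable and logged.
    """

    state: StatePoint
    jacobian: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray
    stability: str

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    def to_dict(self) -> dict:
        return {
            "x": self.state.x,
            "y": self.state.y,
            "jacobian": np.asarray(self.jacobian).tolist(),
            "eigenvalues_re": np.real(self.eigenvalues).tolist(),
            "eigenvalues_im": np.imag(self.eigenvalues).tolist(),
            "stability": self.stability,
        }


def _classify(eigenvalues: np.ndarray, state: StatePoint) -> str:
    re = np.real(eigenvalues)
    if np.all(re < -_EIG_TOL):
        return "stable"
    if np.any(re < -_EIG_TOL) and np.any(re > _EIG_TOL):
        return "saddle"
    if np.any(np.abs(re) <= _EIG_TOL):
        logger.warning("marginal eigenvalue at fixed point %s: Re=%s", tuple(state), re)
    return "unstable"


def _make_fixed_point(x: float, y: float, p: FeedbackLoopParams) -> FixedPoint:
    s = StatePoint(x, y)
    J = jacobian(s, p)
    eig = np.linalg.eigvals(J)
    order = np.argsort(eig.real)
    return FixedPoint(state=s, jacobian=J, eigenvalues=eig[order], stability=_classify(eig, s))


def find_fixed_points(
    p: FeedbackLoopParams,
    *,
    grid_points: int = 2048,
    max_bisections: int = 200,
) -> list[FixedPoint]:
    """All fixed points of the loop in [0, k_xy/mu_x] x [0, k_yx/mu_y].

    Substituting the Y-nullcline y(x) = (k_yx/mu_y) H(x; K_yx, n) into the
    X-nullcline leaves the scalar equation

        f(x) = (k_xy/mu_x) H(y(x); K_xy, n) - x = 0.

    ``f`` is scanned on a uniform grid over [0, (k_xy/mu_x)(1 + 1e-6)] and
    each sign change is refined by bisection to |f| <= 1e-10; roots closer
    than 1e-6 of the box width are merged.  The origin is always a fixed
    point (an inactive promoter produces nothing) and is always included.

    Returns the fixed points sorted by x, each with Jacobian, eigenvalues
    and a stability label.
    """
    box_x = p.k_xy / p.mu_x

    def y_null(x: float) -> float:
        return (p.k_yx / p.mu_y) * hill_activation(x, p.K_yx, p.n)

    def f(x: float) -> float:
        return (p.k_xy / p.mu_x) * hill_activation(y_null(x), p.K_xy, p.n) - x

    xs = np.linspace(0.0, box_x * (1.0 + 1e-6), grid_points)
    fs = np.array([f(x) for x in xs])

    roots = [0.0]
    for i in range(1, grid_points - 1):
        a, b = xs[i], xs[i + 1]
        fa, fb = fs[i], fs[i + 1]
        if fa == 0.0:
            roots.append(a)
            continue
        if fa * fb < 0.0:
            for _ in range(max_bisections):
                m = 0.5 * (a + b)
                fm = f(m)
                if abs(fm) <= _ROOT_TOL:
                    break
                if fa * fm < 0.0:
                    b = m
                else:
                    a, fa = m, fm
            else:
                raise ConvergenceError(
                    f"bisection did not reach |f| <= {_ROOT_TOL} in bracket "
                    f"[{xs[i]:.6g}, {xs[i + 1]:.6g}]"
                )
            roots.append(m)
    if fs[-1] == 0.0:
        roots.append(xs[-1])

    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > 1e-6 * box_x:
            merged.append(r)

    out = []
    for r in merged:
        fp = _make_fixed_point(r, y_null(r), p)
        res = float(np.max(np.abs(drift(fp.state, p))))
        if res > _DRIFT_TOL:
            raise ConvergenceError(
                f"refined root ({fp.state.x:.6g}, {fp.state.y:.6g}) has drift "
                f"residual {res:.3g} > {_DRIFT_TOL}"
            )
        out.append(fp)
    return out
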