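"""Linear-noise approximation around a stable fixed point.

The fluctuations dx = (X, Y) - (x*, y*) obey the linear Langevin system
d(dx)/dt = J dx + xi(t) with independent white noises of intensity D, so
the stationary covariance solves the Lyapunov equation

    J Sigma + Sigma J^T + D = 0.

From Sigma the Gaussian mutual information between the two gene products
is I(X;Y) = -1/2 log2(1 - rho^2) bits, equivalently
1/2 log2[Sigma(X) / Sigma(X|Y)] with the conditional variance
Sigma(X|Y) = Sigma(X) - Sigma(X,Y)^2 / Sigma(Y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg

from .dynamics import FixedPoint, drift, hill_activation
from .errors import (
    DegenerateDistributionError,
    EntropyUndefinedError,
    InvalidParameterError,
    NotApplicableError,
    StabilityError,
)
from .params import FeedbackLoopParams

__all__ = [
    "NoiseSpec",
    "NoiseMatrix",
    "CovarianceMatrix",
    "InformationSummary",
    "noise_matrix",
    "solve_lyapunov",
    "symmetric_closed_form",
    "gaussian_mi",
    "normalized_mi",
    "gaussian_entropy",
    "information_summary",
]


@dataclass(frozen=True)
class NoiseSpec:
    """How the white-noise intensities of the Langevin equations are set.

    mode='poissonian' derives them from the reaction fluxes at the fixed
    point (birth flux + death flux per species, the diffusion of the
    underlying birth-death process); mode='explicit' uses amp_x/amp_y
    verbatim (copies^2/min).
    """

    mode: str = "poissonian"
    amp_x: float = 0.0
    amp_y: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("poissonian", "explicit"):
            raise InvalidParameterError(f"unknown noise mode {self.mode!r}")
        if self.amp_x < 0 or self.amp_y < 0:
            raise InvalidParameterError("noise amplitudes must be non-negative")


@dataclass(frozen=True)
class NoiseMatrix:
    """Diagonal noise matrix D = diag(d_x, d_y); off-diagonals are zero
    because the two noises are independent."""

    d_x: float
    d_y: float

    def __post_init__(self) -> None:
        if self.d_x < 0 or self.d_y < 0:
            raise InvalidParameterError("noise intensities must be non-negative")

    def as_matrix(self) -> np.ndarray:
        return np.diag([self.d_x, self.d_y])


@dataclass(frozen=True)
class CovarianceMatrix:
    """Stationary (co)variances of the two gene products (copies^2)."""

    var_x: float
    var_y: float
    cov_xy: float

    def __post_init__(self) -> None:
        if self.var_x < 0 or self.var_y < 0:
            raise InvalidParameterError("variances must be non-negative")
        # Cauchy-Schwarz with a small slack for floating-point round-off.
        bound = self.var_x * self.var_y
        if self.cov_xy**2 > bound * (1.0 + 1e-9) + 1e-300:
            raise InvalidParameterError(
                f"cov^2 = {self.cov_xy**2:.6g} violates Cauchy-Schwarz bound {bound:.6g}"
            )

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.var_x, self.cov_xy], [self.cov_xy, self.var_y]])

    @property
    def correlation(self) -> float:
        """Pearson correlation rho = cov / sqrt(var_x var_y)."""
        denom = math.sqrt(self.var_x * self.var_y)
        if denom == 0.0:
            raise DegenerateDistributionError("correlation undefined with zero variance")
        return self.cov_xy / denom


@dataclass(frozen=True)
class InformationSummary:
    """Mutual information between the two gene products.

    ``nmi`` is None when a marginal entropy is non-positive, in which case
    the normalization is undefined and withheld.
    """

    mi_bits: float
    correlation: float
    nmi: Optional[float] = None


def noise_matrix(fp: FixedPoint, p: FeedbackLoopParams, spec: NoiseSpec = NoiseSpec()) -> NoiseMatrix:
    """Noise matrix D at a fixed point.

    Poissonian mode sums the birth and death fluxes of each species at the
    fixed point, d_x = k_xy H(y*; K_xy, n) + mu_x x* (and analogously for
    Y); at a fixed point the fluxes balance, so each entry equals
    2 mu * mean.  Explicit mode passes the amplitudes through unchanged.
    """
    if spec.mode == "explicit":
        return NoiseMatrix(d_x=spec.amp_x, d_y=spec.amp_y)
    x, y = fp.state
    res = float(np.max(np.abs(drift(fp.state, p))))
    scale = max(p.k_xy, p.k_yx, 1.0)
    if res > 1e-6 * scale:
        raise InvalidParameterError(
            f"state ({x:.6g}, {y:.6g}) is not a fixed point of these parameters "
            f"(drift residual {res:.3g})"
        )
    d_x = p.k_xy * hill_activation(y, p.K_xy, p.n) + p.mu_x * x
    d_y = p.k_yx * hill_activation(x, p.K_yx, p.n) + p.mu_y * y
    return NoiseMatrix(d_x=d_x, d_y=d_y)


def solve_lyapunov(J: np.ndarray, D: NoiseMatrix | np.ndarray) -> CovarianceMatrix:
    """Stationary covariance solving J Sigma + Sigma J^T + D = 0.

    Requires J Hurwitz (all eigenvalue real parts negative); otherwise the
    fluctuations have no stationary distribution and a StabilityError is
    raised.  The residual of the returned solution is bounded by
    1e-10 * ||D||.
    """
    J = np.asarray(J, dtype=float)
    Dm = D.as_matrix() if isinstance(D, NoiseMatrix) else np.asarray(D, dtype=float)
    eig = np.linalg.eigvals(J)
    if np.any(eig.real >= 0):
        raise StabilityError(
            f"Jacobian is not Hurwitz (eigenvalue real parts {np.sort(eig.real)}); "
            "the linear-noise approximation is undefined at an unstable point"
        )
    if not np.any(Dm):
        return CovarianceMatrix(0.0, 0.0, 0.0)
    sigma = linalg.solve_continuous_lyapunov(J, -Dm)
    sigma = 0.5 * (sigma + sigma.T)
    resid = np.max(np.abs(J @ sigma + sigma @ J.T + Dm))
    if resid > 1e-10 * np.max(np.abs(Dm)):
        raise StabilityError(f"Lyapunov residual {resid:.3g} exceeds tolerance")
    # Round-off can leave a variance infinitesimally negative.
    return CovarianceMatrix(
        var_x=max(sigma[0, 0], 0.0), var_y=max(sigma[1, 1], 0.0), cov_xy=sigma[0, 1]
    )


def symmetric_closed_form(p: FeedbackLoopParams, m: float) -> CovarianceMatrix:
    """Closed-form covariance for the symmetric loop at its self-consistent point.

    For a symmetric loop with n = 1, Hill constant tied to the stationary
    mean (K = m) and Poissonian noise, the Jacobian at the active fixed
    point (m, m) is [[-mu, mu/2], [mu/2, -mu]] and D = 2 mu m I.  With
    a = mu, b = mu/2, d = 2 mu m the Lyapunov solution is

        var = d a / (2 (a^2 - b^2)) = 4 m / 3,
        cov = var * b / a          = 2 m / 3,

    giving a constant Fano factor 4/3 and correlation 1/2 at every
    expression level.  Derived independently of the numerical solver and
    used as its oracle.
    """
    if not p.is_symmetric:
        raise NotApplicableError("closed form requires a symmetric parameter set")
    if p.n != 1.0:
        raise NotApplicableError("closed form requires Hill coefficient n = 1")
    if abs(p.K_xy - m) > 1e-9 * max(m, 1.0):
        raise NotApplicableError(
            f"closed form requires the self-consistency rule K = mean (K={p.K_xy}, m={m})"
        )
    mu = p.mu_x
    a, b, d = mu, 0.5 * mu, 2.0 * mu * m
    var = d * a / (2.0 * (a * a - b * b))
    cov = var * b / a
    return CovarianceMatrix(var_x=var, var_y=var, cov_xy=cov)


def gaussian_mi(c: CovarianceMatrix) -> InformationSummary:
    """Mutual information of a bivariate Gaussian with covariance ``c``.

    I(X;Y) = -1/2 log2(1 - rho^2) bits; zero iff the covariance vanishes,
    diverging as |rho| -> 1.  Undefined (DegenerateDistributionError) for
    zero variances or perfect correlation.
    """
    if c.var_x <= 0 or c.var_y <= 0:
        raise DegenerateDistributionError("mutual information requires positive variances")
    rho = c.correlation
    if abs(rho) >= 1.0:
        raise DegenerateDistributionError(f"perfectly correlated variables (rho={rho})")
    mi = -0.5 * math.log2(1.0 - rho * rho)
    return InformationSummary(mi_bits=mi, correlation=rho, nmi=None)


def gaussian_entropy(var: float) -> float:
    """Differential entropy 1/2 log2(2 pi e var) of a Gaussian, in bits."""
    if var <= 0:
        raise DegenerateDistributionError("entropy requires positive variance")
    return 0.5 * math.log2(2.0 * math.pi * math.e * var)


def normalized_mi(c: CovarianceMatrix) -> float:
    """Mutual information normalized by the mean marginal entropy.

    Returns 2 I(X;Y) / (H(X) + H(Y)) with Gaussian differential entropies
    in bits.  Along the symmetric n=1 sweep the raw MI is constant while
    the entropies grow with expression level, so this ratio decreases.
    Raises EntropyUndefinedError when an entropy is non-positive (variance
    below 1/(2 pi e) copies^2), where the normalization loses meaning.
    """
    hx = gaussian_entropy(c.var_x)
    hy = gaussian_entropy(c.var_y)
    if hx <= 0 or hy <= 0:
        raise EntropyUndefinedError(
            f"non-positive marginal entropy (H(X)={hx:.4g}, H(Y)={hy:.4g}); "
            "normalized MI is undefined"
        )
    return 2.0 * gaussian_mi(c).mi_bits / (hx + hy)


def information_summary(c: CovarianceMatrix) -> InformationSummary:
    """MI, correlation and (when defined) normalized MI for covariance ``c``."""
    base = gaussian_mi(c)
    try:
        nmi = normalized_mi(c)
    except EntropyUndefinedError:
        nmi = None
    return InformationSummary(mi_bits=base.mi_bits, correlation=base.correlation, nmi=nmi)
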