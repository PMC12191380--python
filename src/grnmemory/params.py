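"""Parameter containers for the gene-circuit models.

Everything is expressed in copy numbers (dimensionless molecule counts) and
minutes: synthesis rates in copies/min, degradation rates in 1/min, Hill
constants in copies.  Copy number and concentration are used interchangeably
(the circuit has no explicit volume).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

from .errors import InvalidParameterError

__all__ = [
    "FeedbackLoopParams",
    "ConstitutiveGeneParams",
    "PromoterBindingParams",
    "StatePoint",
]


class StatePoint(NamedTuple):
    """A point in the (X, Y) copy-number plane."""

    x: float
    y: float


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class FeedbackLoopParams:
    """Rates and affinities of the double positive feedback loop.

    The deterministic dynamics are

        dX/dt = k_xy * Y^n / (K_xy^n + Y^n) - mu_x * X
        dY/dt = k_yx * X^n / (K_yx^n + X^n) - mu_y * Y

    i.e. each gene product activates the other's synthesis through a Hill
    function and decays linearly.

    Parameters
    ----------
    k_xy, k_yx : float
        Maximal synthesis rates of X and Y (copies/min).
    K_xy, K_yx : float
        Half-maximal activation thresholds: K_xy is the Y level giving
        half-maximal X synthesis, K_yx the X level for Y (copies).
    n : float
        Hill coefficient (cooperativity), >= 1.
    mu_x, mu_y : float
        First-order degradation rates (1/min).
    """

    k_xy: float
    k_yx: float
    K_xy: float
    K_yx: float
    n: float
    mu_x: float
    mu_y: float

    def __post_init__(self) -> None:
        for name in ("k_xy", "k_yx", "K_xy", "K_yx", "mu_x", "mu_y"):
            _require_positive(name, getattr(self, name))
        if not self.n >= 1:
            raise InvalidParameterError(f"Hill coefficient n must be >= 1, got {self.n!r}")

    @property
    def is_symmetric(self) -> bool:
        """True when X and Y play interchangeable roles."""
        return (
            self.k_xy == self.k_yx
            and self.K_xy == self.K_yx
            and self.mu_x == self.mu_y
        )

    @classmethod
    def symmetric(cls, k: float, K: float, mu: float, n: float = 1.0) -> "FeedbackLoopParams":
        """Symmetric loop: identical rates and affinities for both genes."""
        return cls(k_xy=k, k_yx=k, K_xy=K, K_yx=K, n=n, mu_x=mu, mu_y=mu)

    @classmethod
    def autoregulatory(cls, k: float, K: float, mu: float, n: float = 1.0) -> "FeedbackLoopParams":
        """Positive autoregulation as a degenerate configuration.

        A single self-activating gene dx/dt = k*H(x; K, n) - mu*x is the
        restriction of the symmetric loop to its diagonal X = Y; the same
        machinery (fixed points, LNA, SSA) applies with X and Y identified.
        """
        return cls.symmetric(k=k, K=K, mu=mu, n=n)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeedbackLoopParams":
        keys = {"k_xy", "k_yx", "K_xy", "K_yx", "n", "mu_x", "mu_y"}
        missing = keys - set(d)
        if missing:
            raise InvalidParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(d[k]) for k in keys})

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FeedbackLoopParams":
        """Load from a JSON file path or a JSON string."""
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class ConstitutiveGeneParams:
    """Unregulated gene: constant synthesis k_x, linear degradation mu_x."""

    k_x: float
    mu_x: float

    def __post_init__(self) -> None:
        _require_positive("k_x", self.k_x)
        _require_positive("mu_x", self.mu_x)


@dataclass(frozen=True)
class PromoterBindingParams:
    """TF-DNA binding kinetics X + D <-> XD with total DNA D_total.

    The derived dissociation constant K = k_off / k_on (copies) sets the TF
    level at which half the promoters are occupied.
    """

    k_on: float
    k_off: float
    D_total: float

    def __post_init__(self) -> None:
        _require_positive("k_on", self.k_on)
        _require_positive("k_off", self.k_off)
        _require_positive("D_total", self.D_total)

    @property
    def K(self) -> float:
        """Dissociation constant k_off / k_on (copies)."""
        return self.k_off / self.k_on
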