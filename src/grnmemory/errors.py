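"""Exception hierarchy for grnmemory.

All errors derive from :class:`GrnMemoryError` so callers can catch the
package's failures with a single except clause.  Parameter-validation
failures additionally derive from :class:`ValueError`.
"""


class GrnMemoryError(Exception):
    """Base class for all grnmemory errors."""


class InvalidParameterError(GrnMemoryError, ValueError):
    """A rate, affinity, Hill coefficient or noise amplitude is out of range."""


class StabilityError(GrnMemoryError):
    """The Jacobian is not Hurwitz; the linear-noise approximation is undefined."""


class ConvergenceError(GrnMemoryError):
    """A root refinement failed to converge; the message names the bracket."""


class DegenerateDistributionError(GrnMemoryError):
    """A covariance matrix is singular or perfectly correlated (|rho| >= 1)."""


class EntropyUndefinedError(DegenerateDistributionError):
    """A Gaussian differential entropy is non-positive; normalized MI is withheld."""


class InsufficientDataError(GrnMemoryError):
    """A trajectory window contains no usable observation time."""


class NotApplicableError(GrnMemoryError):
    """A closed form was requested outside the regime where it holds."""


class InvalidSetupError(GrnMemoryError):
    """A simulation experiment was configured inconsistently with the dynamics."""
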