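import matplotlib
import pytest

matplotlib.use("Agg")

from grnmemory import FeedbackLoopParams


@pytest.fixture(scope="session")
def basal_params() -> FeedbackLoopParams:
    """Symmetric loop at the basal expression level: k=5/min, mu=0.5/min,
    n=1, K tied to the stationary mean (5 copies)."""
    return FeedbackLoopParams.symmetric(k=5.0, K=5.0, mu=0.5, n=1.0)


@pytest.fixture(scope="session")
def bistable_params() -> FeedbackLoopParams:
    """Cooperative (n=2) loop with a genuine ON/OFF pair: fixed points at
    (0,0) stable, (4,4) saddle, (16,16) stable."""
    return FeedbackLoopParams.symmetric(k=20.0, K=8.0, mu=1.0, n=2.0)
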