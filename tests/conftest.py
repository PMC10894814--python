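import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rplsig.containers import ExpressionMatrix, Signature

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def toy_signature() -> Signature:
    return Signature(["R1", "R2"], ["L1", "L2"])


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    """4 genes x 4 samples, linear scale, chosen so arm sums are easy numbers."""
    values = pd.DataFrame(
        {
            "s1": [4.0, 3.0, 1.0, 1.0],
            "s2": [1.0, 1.0, 4.0, 3.0],
            "s3": [2.0, 2.0, 2.0, 2.0],
            "s4": [8.0, 8.0, 0.0, 2.0],
        },
        index=["R1", "R2", "L1", "L2"],
    )
    return ExpressionMatrix(values, "linear")


@pytest.fixture
def labelled_cohort():
    """10 vs 10 cohort with one strongly planted gene and flat background."""
    rng = np.random.default_rng(42)
    n = 20
    samples = [f"s{i}" for i in range(n)]
    groups = ["A"] * 10 + ["B"] * 10
    base = rng.lognormal(3.0, 0.2, size=(30, n))
    planted = np.where(np.array(groups) == "A", 100.0, 25.0) + np.arange(n) * 1e-6
    values = pd.DataFrame(
        np.vstack([planted, base]),
        index=["PLANT"] + [f"BG{i}" for i in range(30)],
        columns=samples,
    )
    expr = ExpressionMatrix(values, "linear")
    labels = pd.DataFrame({"sample_id": samples, "group": groups})
    return expr, labels
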