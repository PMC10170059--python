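import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from refstab import CtMatrix, ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr():
    """3 conditions × 2 replicates, 4 genes, strictly positive TPM."""
    samples = ["a1", "a2", "b1", "b2", "c1", "c2"]
    conds = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
    rng = np.random.default_rng(7)
    vals = pd.DataFrame(
        2.0 ** rng.uniform(4, 12, size=(4, 6)),
        index=[f"g{i}" for i in range(1, 5)],
        columns=samples,
    )
    return ExpressionMatrix(vals, conds)


@pytest.fixture
def random_ct(rng):
    """6 genes × 8 samples of plausible Ct values, no missing wells."""
    vals = pd.DataFrame(
        rng.uniform(15, 32, size=(6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(8)],
    )
    return CtMatrix(vals)
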