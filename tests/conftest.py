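import numpy as np
import pandas as pd
import pytest

from mrnasig import CohortConfig, ExpressionMatrix, SignatureModel, generate_cohort


@pytest.fixture
def tiny_expr():
    """4 probes x 4 samples, two probes sharing a gene, one unannotated."""
    values = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0],
            [10.0, 12.0, 8.0, 10.0],
            [2.0, 2.1, 1.9, 2.0],
            [5.0, 5.0, 5.0, 5.0],
        ],
        index=["pA", "pB", "pC", "pD"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, {"pA": "G1", "pB": "G2", "pC": "G2"})


@pytest.fixture(scope="session")
def small_cohort():
    """Modest synthetic cohort shared across read-only tests."""
    cfg = CohortConfig(n_samples=80, n_probes=150, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_fit():
    """One fitted default cohort (the heavyweight shared fixture)."""
    model, truth = SignatureModel.from_synthetic(CohortConfig(seed=3))
    results = model.fit()
    return model, truth, results
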