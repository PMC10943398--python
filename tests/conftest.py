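import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cuprosep.containers import CASE, CONTROL, ExpressionMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_matrix(case_rows, control_rows, genes=None, batch=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from per-group row lists."""
    case_rows = np.atleast_2d(np.asarray(case_rows, dtype=float))
    control_rows = np.atleast_2d(np.asarray(control_rows, dtype=float))
    X = np.vstack([case_rows, control_rows])
    n = X.shape[0]
    genes = list(genes) if genes is not None else [f"g{j}" for j in range(X.shape[1])]
    samples = [f"s{i}" for i in range(n)]
    group = pd.Series([CASE] * len(case_rows) + [CONTROL] * len(control_rows), index=samples)
    if batch is None:
        batch = ["B1"] * n
    return ExpressionMatrix(
        pd.DataFrame(X, index=samples, columns=genes), group, pd.Series(batch, index=samples)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort reused by several read-only tests."""
    from cuprosep import simulate_cohort

    return simulate_cohort(
        n_case=30, n_control=30, n_genes=400, de_fraction=0.05, lfc_mean=1.0,
        batch_count=2, batch_sd=0.4, noise_sd=0.5, seed=7,
    )
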