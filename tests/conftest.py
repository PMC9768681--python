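import numpy as np
import pandas as pd
import pytest

from omicstack import BlockSpec, ENConfig, SyntheticSpec, generate_cohort
from omicstack.datasets import CohortDataset, OmicsBlock

# fast solver settings used throughout the unit tests: a short lambda path
# with glmnet's p>=n floor, loose-but-adequate coordinate tolerance, and a
# support cap, all sized for small simulated cohorts
FAST = dict(inner_folds=4, n_lambda=15, tol=1e-3, dfmax=10, lambda_min_ratio=0.01)


@pytest.fixture
def fast_cfg():
    return ENConfig(seed=1, **FAST)


@pytest.fixture
def tiny_cohort():
    """12 patients, one 15-feature block with strong sparse signal."""
    spec = SyntheticSpec(
        n_patients=12,
        blocks=[BlockSpec(name="b0", p=15, n_latent=3, n_signal=3,
                          effect_size=1.8)],
        seed=42,
    )
    ds, truth = generate_cohort(spec)
    return ds, truth


@pytest.fixture
def two_block_cohort():
    spec = SyntheticSpec(
        n_patients=14,
        blocks=[
            BlockSpec(name="met", p=20, n_latent=4, n_signal=3, effect_size=1.5),
            BlockSpec(name="prot", p=12, n_latent=3, n_signal=2, effect_size=1.5),
        ],
        seed=7,
    )
    ds, truth = generate_cohort(spec)
    return ds, truth


def longitudinal_cohort(n_patients=12, n_visits=3, features=None, seed=0,
                        outcome=None):
    """Hand-built cohort with fixed visit weeks, for univariate tests."""
    rng = np.random.default_rng(seed)
    pats = [f"P{i:02d}" for i in range(n_patients)]
    y = np.array([i % 2 for i in range(n_patients)]) if outcome is None else outcome
    rows = [
        (f"{p}_s{v}", p, 8.0 + 10 * v + rng.uniform(0, 2))
        for p in pats
        for v in range(n_visits)
    ]
    meta = pd.DataFrame(rows, columns=["sample_id", "patient_id", "week"])
    meta = meta.set_index("sample_id")
    blocks = {}
    if features is not None:
        blocks["b"] = OmicsBlock("b", pd.DataFrame(features, index=meta.index))
    return CohortDataset(samples=meta,
                         outcomes=pd.Series(y, index=pats),
                         blocks=blocks)
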