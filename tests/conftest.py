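import numpy as np
import pandas as pd
import pytest

from rmskit import target_discovery as td


@pytest.fixture
def toy_study():
    """2 genes x 2 samples study (both samples one condition)."""
    values = pd.DataFrame(
        [[1.0, 4.0], [3.0, 2.0]], index=["g1", "g2"], columns=["s1", "s2"]
    )
    return td.ExpressionStudy(
        values=values,
        sample_conditions=pd.Series({"s1": "a", "s2": "a"}),
        replicate_index=pd.Series({"s1": 1, "s2": 2}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def make_study(values: np.ndarray, conditions: list[str]) -> td.ExpressionStudy:
    """Build a study from a raw matrix and per-column condition labels."""
    cols = [f"{c}_{i}" for i, c in enumerate(conditions)]
    genes = [f"g{i}" for i in range(values.shape[0])]
    return td.ExpressionStudy(
        values=pd.DataFrame(values, index=genes, columns=cols),
        sample_conditions=pd.Series(dict(zip(cols, conditions))),
        replicate_index=pd.Series({c: i for i, c in enumerate(cols)}),
    )
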