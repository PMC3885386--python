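import numpy as np
import pandas as pd
import pytest

from zodet.io import CONTROL, EXPERIMENTAL, ExpressionMatrix, SampleDesign


def make_matrix(values, probes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


def make_design(control_ids, experimental_ids) -> SampleDesign:
    return SampleDesign(
        {**{s: CONTROL for s in control_ids},
         **{s: EXPERIMENTAL for s in experimental_ids}}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort(rng):
    """20 controls + 5 experimental samples over 50 probes, pure null."""
    values = rng.standard_normal((50, 25))
    ctl = [f"c{i}" for i in range(20)]
    exp = [f"e{i}" for i in range(5)]
    matrix = make_matrix(values, samples=ctl + exp)
    return matrix, make_design(ctl, exp)
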