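import numpy as np
import pandas as pd
import pytest

from ygate.simulate import make_paper_fixture


@pytest.fixture(scope="session")
def paper_fixture():
    """The bundled synthetic 9M/7F worked-example dataset (deterministic)."""
    return make_paper_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_matrix(rng):
    """A 5x3 matrix of plausible log2 fluorescence values."""
    values = rng.normal(6.0, 2.0, (5, 3))
    return pd.DataFrame(
        values,
        index=pd.Index([f"p{i}" for i in range(5)], name="probe_id"),
        columns=[f"s{j}" for j in range(3)],
    )
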