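import numpy as np
import pandas as pd
import pytest

from splicerhythm.containers import TimedMatrix
from splicerhythm.synthio import baboon_times, cellline_times, mouse_array_times


@pytest.fixture(scope="session")
def mouse_times():
    return mouse_array_times()


@pytest.fixture(scope="session")
def baboon_grid():
    return baboon_times()


@pytest.fixture(scope="session")
def cellline_grid():
    return cellline_times()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, times, units="log2cpm", ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"F{i:03d}" for i in range(values.shape[0])]
    return TimedMatrix(pd.DataFrame(values, index=ids), np.asarray(times, float), units)
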