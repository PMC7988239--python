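import numpy as np
import pytest

from proturn import LogisticParams, TimeSeries
from proturn.estimate import FitWindow
from proturn.synthetic import MrnaShape, SyntheticSpec, make_mrna, make_replicates


@pytest.fixture(scope="session")
def window():
    """The Collagen-IV-style modelling window: 0-15 h at 2-min steps."""
    return FitWindow(0.0, 15.0, 2.0)


@pytest.fixture(scope="session")
def clean_spec(window):
    """Noiseless single-replicate synthetic recipe at the default truth."""
    return SyntheticSpec(
        noise_cv=0.0, replicate_cv=0.0, n_replicates=1, seed=11, window=window
    )


@pytest.fixture(scope="session")
def clean_trace(clean_spec):
    traces, rates = make_replicates(clean_spec)
    return traces[0], rates[0]


@pytest.fixture(scope="session")
def default_mrna(clean_spec):
    return make_mrna(clean_spec)


@pytest.fixture(scope="session")
def noisy_spec(window):
    """ColIV-like noisy study: 10 replicates, 5% noise, 20% rate variability."""
    return SyntheticSpec(seed=7, window=window)


@pytest.fixture
def logistic_params():
    return LogisticParams(K=10.0, t_i=5.0, r=1.0)


@pytest.fixture
def simple_series():
    return TimeSeries([0.0, 1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0, 5.0])
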