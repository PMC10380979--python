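import pytest

from costspace import PredictorProfile


@pytest.fixture
def revel_like():
    """Operating point with the printed REVEL sensitivity/specificity."""
    return PredictorProfile("REVEL", 0.92, 0.94)


@pytest.fixture
def crossing_pair():
    """Two predictors whose MISC cost lines cross at rc1 = 1/2 for rho = 1/2."""
    return (
        PredictorProfile("A", 0.9, 0.7),
        PredictorProfile("B", 0.7, 0.9),
    )
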