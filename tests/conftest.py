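import numpy as np
import pytest

from lipoquant import SLDSet, SAXSSeriesSpec, generate_saxs_series


@pytest.fixture
def slds():
    """The fixed soy-PC / aquaporin SLD set used throughout."""
    return SLDSet()


@pytest.fixture
def q_grid():
    """Measured q window, log-spaced."""
    return np.geomspace(0.004, 0.35, 60)


@pytest.fixture
def noiseless_series():
    """The default four-sample series with zero noise (model curves exactly)."""
    return generate_saxs_series(SAXSSeriesSpec(noise=0.0, seed=0))
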