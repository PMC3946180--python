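import numpy as np
import pytest

from hhtexcess.emd import emd


@pytest.fixture(scope="session")
def noise_decompositions():
    """20 plain-EMD decompositions of unit white noise, n = 1024.

    Shared by the filter-bank and IMF-property tests; the heavier
    calibration runs live in the acceptance suite.
    """
    rng = np.random.default_rng(2024)
    out = []
    for _ in range(20):
        x = rng.standard_normal(1024)
        out.append((x, emd(x)))
    return out
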