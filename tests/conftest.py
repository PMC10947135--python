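import numpy as np
import pytest

import tvmiss as tv


@pytest.fixture(scope="session")
def coeffs():
    """Shipped normal-outcome generating coefficients."""
    return tv.default_coefficients()


@pytest.fixture(scope="session")
def big_panel(coeffs):
    """Large complete cohort shared by weight/MSM recovery tests."""
    return tv.generate_complete_panel(100_000, coeffs, seed=2024)


@pytest.fixture(scope="session")
def small_panel(coeffs):
    return tv.generate_complete_panel(500, coeffs, seed=11)
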