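import numpy as np
import pytest

from elastofit import (
    HyperelasticParams,
    REFERENCE_COEFFICIENTS,
    StressStretchCurve,
    uniaxial_stress,
)


@pytest.fixture(scope="session")
def grid100() -> np.ndarray:
    """The standardized stretch grid: 1.01 to 2.00 in steps of 0.01."""
    return 1.0 + 0.01 * np.arange(1, 101)


def all_reference_params():
    """Every (fvf, model, c1, c2) row of the reference coefficient table."""
    return [
        (fvf, model, c1, c2)
        for fvf, row in REFERENCE_COEFFICIENTS.items()
        for model, (c1, c2) in row.items()
    ]


def make_clean_curve(model: str, c1: float, c2: float, grid: np.ndarray):
    params = HyperelasticParams(model, c1, c2)
    return StressStretchCurve(grid, uniaxial_stress(params, grid), interval=0.01)
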