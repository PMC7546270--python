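import numpy as np
import pytest

from leafedm import ResponseSeries


@pytest.fixture
def toy_exp_series() -> ResponseSeries:
    """Fixed 5-point series with roughly exponential shape, used against grid oracles."""
    return ResponseSeries(
        species="toy",
        pathway="C3",
        predictor_kind="enzyme_activity",
        predictor_name="toy enzyme",
        x=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
        y=np.array([2.0, 3.1, 5.4, 8.7, 15.1]),
    )


@pytest.fixture
def toy_nitrogen_series() -> ResponseSeries:
    """Fixed 6-point leaf-N series with saturating log-rate shape."""
    return ResponseSeries(
        species="toy",
        pathway="C3",
        predictor_kind="leaf_N",
        predictor_name="leaf N per area",
        x=np.array([5.0, 15.0, 30.0, 50.0, 80.0, 120.0]),
        y=np.array([3.2, 9.5, 21.0, 35.0, 52.0, 60.0]),
    )


def make_enzyme_series(x, y) -> ResponseSeries:
    return ResponseSeries(
        species="test",
        pathway="C3",
        predictor_kind="enzyme_activity",
        predictor_name="enzyme",
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
    )


def make_nitrogen_series(x, y) -> ResponseSeries:
    return ResponseSeries(
        species="test",
        pathway="C3",
        predictor_kind="leaf_N",
        predictor_name="leaf N per area",
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
    )
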