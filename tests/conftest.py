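import numpy as np
import pandas as pd
import pytest
from datetime import date

from moonsim.ephemeris import MENAI_BRIDGE
from moonsim.foraging_synth import generate_dataset, reversal_params, study_design
from moonsim.skybright import SkyModelParams, brightness_series, minute_grid, normalize_series

try:  # hypothesis is an optional test dependency; derandomize when present
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def menai():
    return MENAI_BRIDGE


@pytest.fixture(scope="session")
def short_params():
    """Sky model with a short normalization window bracketing the February
    2020 full moon, so tests can normalize without a full-year run."""
    return SkyModelParams(norm_window=(date(2020, 2, 5), date(2020, 2, 12)))


@pytest.fixture(scope="session")
def short_series(menai, short_params):
    """Normalized brightness series, 5-12 Feb 2020 (covers its own window)."""
    grid = minute_grid(date(2020, 2, 5), date(2020, 2, 12))
    ser = brightness_series(menai, grid, short_params)
    return normalize_series(ser, short_params)


@pytest.fixture(scope="session")
def reversal_data():
    """One synthetic dataset under the default reversal scenario."""
    return generate_dataset(study_design(), reversal_params(seed=1))
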