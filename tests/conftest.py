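import numpy as np
import pytest

from flimlite.core import DecayCurve, FLIDataset, TimeAxis
from flimlite.synthetic import DEFAULT_FREQUENCY_MHZ, make_irf

PERIOD_NS = 1000.0 / DEFAULT_FREQUENCY_MHZ  # 78.02 MHz laser


@pytest.fixture(scope="session")
def axis256() -> TimeAxis:
    return TimeAxis.regular(256, PERIOD_NS)


@pytest.fixture(scope="session")
def axis1024() -> TimeAxis:
    return TimeAxis.regular(1024, PERIOD_NS)


@pytest.fixture(scope="session")
def axis4096() -> TimeAxis:
    return TimeAxis.regular(4096, PERIOD_NS)


@pytest.fixture
def delta_irf():
    """Factory: an effectively instantaneous IRF in the first bin."""

    def make(axis: TimeAxis) -> DecayCurve:
        return make_irf(axis, axis.bin_centers_ns[0], axis.bin_width_ns / 100)

    return make


@pytest.fixture
def gauss_irf():
    """Factory: a realistic Gaussian IRF (default FWHM 0.3 ns at 2 ns)."""

    def make(axis: TimeAxis, center_ns: float = 2.0, fwhm_ns: float = 0.3) -> DecayCurve:
        return make_irf(axis, center_ns, fwhm_ns)

    return make


@pytest.fixture
def random_cube():
    """Factory: a small random-count dataset."""

    def make(n_bins=64, rows=7, cols=7, seed=0, period_ns=PERIOD_NS) -> FLIDataset:
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(n_bins, rows, cols))
        return FLIDataset(counts, TimeAxis.regular(n_bins, period_ns))

    return make
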