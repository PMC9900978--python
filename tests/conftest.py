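import numpy as np
import pytest

from voltim.synthetic_movies import (
    AcquisitionSpec,
    CellSpec,
    SensorModel,
    make_protocol,
    render_movie,
)


@pytest.fixture(scope="session")
def step_movie():
    """Protocol-1 movie of one homogeneous cell (bleach-free sensor)."""
    prot = make_protocol("protocol1", {"acquisition_rate": 100.0})
    acq = AcquisitionSpec.from_rate(100.0, n_rows=90, n_cols=90)
    sensor = SensorModel(bleach_fast_amp=0.0, bleach_slow_tau=1e12)
    movie, truth = render_movie(
        CellSpec(expression=20.0), None, prot, acq, sensor, seed=42
    )
    return movie, truth


@pytest.fixture(scope="session")
def bleaching_movie():
    """Protocol-1 movie with the default bleaching sensor."""
    prot = make_protocol("protocol1", {"acquisition_rate": 100.0})
    acq = AcquisitionSpec.from_rate(100.0, n_rows=90, n_cols=90)
    movie, truth = render_movie(
        CellSpec(expression=20.0), None, prot, acq, seed=43
    )
    return movie, truth


@pytest.fixture
def disk_target():
    """12 um disk amplitude target on a 256-point, 250 um focal grid."""
    n = 256
    dx = 250.0 / n
    c = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n]
    rr = ((xx - c) ** 2 + (yy - c) ** 2) * dx**2
    return (rr <= 36.0).astype(float), rr, dx
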