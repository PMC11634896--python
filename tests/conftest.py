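import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, max_examples=60)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def landscape():
    from grassmap.synthio import generate_landscape

    return generate_landscape(seed=11, shape=(120, 120))


@pytest.fixture(scope="session")
def signatures():
    from grassmap.synthio import signature_preset

    return signature_preset("easy")


@pytest.fixture(scope="session")
def one_year_composites(landscape, signatures):
    """Composites plus index cube for one synthetic year."""
    from grassmap.composite import build_composite_series
    from grassmap.indices import build_index_cube
    from grassmap.synthio import generate_acquisitions

    acq = generate_acquisitions(
        landscape, signatures, [2020], cloud_prob=0.15, seed=5
    )
    composites, report = build_composite_series(acq, [2020])
    return composites, build_index_cube(composites), report


def make_stack(values, qa=None, cloud_cover=0.0, date=None):
    """Tiny AcquisitionStack helper: one scalar or array per band."""
    import datetime as dt

    from grassmap.composite import AcquisitionStack
    from grassmap.core import BAND_NAMES

    values = np.asarray(values, dtype=float)
    if values.ndim == 0:
        values = np.full((len(BAND_NAMES), 2, 2), float(values))
    if qa is None:
        qa = np.ones(values.shape[1:], dtype=np.uint8)
    return AcquisitionStack(
        date=date or dt.date(2020, 1, 10),
        bands=values,
        qa=np.asarray(qa),
        cloud_cover=cloud_cover,
    )
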