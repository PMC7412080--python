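import numpy as np
import pytest

from actigap.io_formats import SensorSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_triaxial_series(
    n=300, fs=50.0, seed=0, labels=None, subject_id="s1"
) -> SensorSeries:
    """Random tri-axial series used as generic pipeline input."""
    r = np.random.default_rng(seed)
    t = np.arange(n) / fs
    values = r.normal(size=(n, 3))
    return SensorSeries(
        timestamps=t,
        values=values,
        labels=labels if labels is not None else "walk",
        subject_id=subject_id,
        sampling_rate=fs,
    )


@pytest.fixture
def triaxial_series():
    return make_triaxial_series()
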