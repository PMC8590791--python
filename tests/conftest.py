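from datetime import datetime

import numpy as np
import pytest

from wristpa.classify import CutoffScheme
from wristpa.raw import EpochSeries


@pytest.fixture
def scheme():
    return CutoffScheme()


@pytest.fixture
def rng():
    return np.random.default_rng(20190603)


def make_epochs(
    enmo,
    wear=None,
    sleep=None,
    epoch_length=5.0,
    start=datetime(2019, 6, 3),
):
    """Build an EpochSeries from plain arrays (defaults: all wear)."""
    return EpochSeries(
        start_time=start,
        epoch_length=epoch_length,
        enmo=np.asarray(enmo, dtype=float),
        wear=wear,
        sleep=sleep,
    )


def random_day(rng, n_epochs=17280, epoch_length=5.0, wear_frac=0.9):
    """A random full civil day: mixed intensities, random wear flags."""
    enmo = rng.choice(
        [0.0, 0.01, 0.05, 0.2, 0.5], size=n_epochs, p=[0.4, 0.2, 0.2, 0.15, 0.05]
    )
    wear = rng.random(n_epochs) < wear_frac
    return make_epochs(enmo, wear=wear, epoch_length=epoch_length)
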