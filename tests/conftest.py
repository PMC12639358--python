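import datetime as dt

import numpy as np
import pytest

from trapdiel import DetectionRecord, SolarTable


@pytest.fixture
def symmetric_solar() -> SolarTable:
    """Sunrise 06:00 / sunset 18:00 in every month: a 12-h symmetric day."""
    return SolarTable(sunrise={m: 360.0 for m in range(1, 13)},
                      sunset={m: 1080.0 for m in range(1, 13)})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def make_record(site="CT01", species="agouti", day="2019-02-01", time="12:00",
                n=1) -> DetectionRecord:
    return DetectionRecord(site_id=site, species=species,
                           timestamp=dt.datetime.fromisoformat(f"{day}T{time}"),
                           n_individuals=n)
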