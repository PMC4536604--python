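import datetime as dt

import pytest

from cd4qc import synthetic
from cd4qc.duplicate import DuplicatePair


@pytest.fixture
def one_lab_config():
    """90 days, one laboratory, duplicates + one rotating control lot."""
    return synthetic.SimulationConfig(
        labs=(
            synthetic.LabProfile(
                lab_id="L1", analytical_cv=0.05, uses_controls=True
            ),
        ),
        n_days=90,
        seed=20130101,
        control_lots=(
            synthetic.ControlLotSpec(
                product="Multi-Check", level="normal", true_mean=600,
                shelf_life_days=30,
            ),
        ),
    )


@pytest.fixture
def noise_free_config():
    return synthetic.SimulationConfig(
        labs=(
            synthetic.LabProfile(lab_id="L1", analytical_cv=0.0, uses_controls=True),
        ),
        n_days=60,
        seed=7,
        control_lots=(
            synthetic.ControlLotSpec(
                product="IMMUNO-TROL", level="low", true_mean=300,
                shelf_life_days=90,
            ),
        ),
    )


def make_pair(
    day1,
    day2,
    lab_id="L1",
    level="normal",
    date=dt.date(2013, 1, 1),
    instrument="FACSCount",
):
    return DuplicatePair(
        lab_id=lab_id,
        instrument=instrument,
        date=date,
        level=level,
        day1_count=day1,
        day2_count=day2,
    )
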