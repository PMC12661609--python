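import datetime as dt
import pathlib
import sys

import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))  # for peak_oracle

from pbt.io_formats import DailySeries, GlucoseSample


def make_day(values, date=dt.date(2023, 1, 1), start="00:00", step_min=5):
    """Build a DailySeries from a value list at fixed cadence."""
    t0 = dt.datetime.combine(date, dt.time.fromisoformat(start))
    return DailySeries(
        date,
        [
            GlucoseSample(t0 + dt.timedelta(minutes=step_min * i), float(v))
            for i, v in enumerate(values)
        ],
    )


@pytest.fixture
def day_factory():
    return make_day
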