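import datetime as dt

import numpy as np
import pytest

from epiclim.io import CaseRecord, CaseTable, DailyCounts, StudyPeriod

TABLE1_COUNTS = [1, 2, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 2, 1, 1, 1, 0, 0, 0, 0]
TABLE1_ONSET_DAYS = [1, 2, 2, 3, 9, 15, 15, 16, 17, 18]  # 1-based day numbers
TABLE1_FLAGS = "1111111000111111111110"


def make_cases(
    day_indices,
    period: StudyPeriod,
    lats=None,
    lons=None,
    **traits,
) -> CaseTable:
    """Build a CaseTable from 0-based day offsets and optional coordinates."""
    n = len(day_indices)
    lats = [32.9] * n if lats is None else list(lats)
    lons = [-117.1] * n if lons is None else list(lons)
    records = []
    for i, d in enumerate(day_indices):
        kw = {k: (None if v[i] is None else v[i]) for k, v in traits.items()}
        records.append(
            CaseRecord(
                case_id=f"c{i:04d}",
                onset_date=period.start + dt.timedelta(days=int(d)),
                lat=float(lats[i]),
                lon=float(lons[i]),
                **kw,
            )
        )
    return CaseTable(records=tuple(records), period=period)


@pytest.fixture
def table1_period() -> StudyPeriod:
    return StudyPeriod(dt.date(2010, 1, 1), dt.date(2010, 1, 22))


@pytest.fixture
def table1_counts(table1_period) -> DailyCounts:
    return DailyCounts(table1_period, np.array(TABLE1_COUNTS))


@pytest.fixture
def table1_cases(table1_period) -> CaseTable:
    return make_cases([d - 1 for d in TABLE1_ONSET_DAYS], table1_period)


@pytest.fixture
def year_period() -> StudyPeriod:
    return StudyPeriod(dt.date(2010, 1, 1), dt.date(2010, 12, 31))
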