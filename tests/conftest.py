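from datetime import date

import pytest

from epiexplorer import Category, EpiSample, StudyStore, WaterPoint
from epiexplorer.synthetic import StudyConfig, case_study_fixture, generate_study


@pytest.fixture(scope="session")
def m13_store():
    """The M13/M1 case study: one huge July-2017 spike next to a silent twin."""
    return case_study_fixture("M13_M1")


@pytest.fixture(scope="session")
def s17_store():
    """The S17 case study: a three-month contamination episode."""
    return case_study_fixture("S17")


@pytest.fixture(scope="session")
def p1_store():
    """The P1 case study: a two-month sampling-protocol artifact."""
    return case_study_fixture("P1")


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (38 points, 3 neighborhoods, 15 months)."""
    return generate_study(StudyConfig(seed=7))


def make_fc_store(series, point_id="X1", lon=-72.34, lat=18.56):
    """A single-point store with the given {month: fc} history."""
    store = StudyStore()
    store.add_water_point(
        WaterPoint(point_id, point_id[0], Category.PIPE_CISTERN, lon, lat)
    )
    for month, fc in series.items():
        y, m = (int(x) for x in month.split("-"))
        store.add_epi_sample(
            EpiSample(point_id=point_id, sample_date=date(y, m, 15), fc_count=fc)
        )
    return store
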