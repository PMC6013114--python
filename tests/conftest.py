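import datetime as dt

import pytest
from shapely.geometry import box

from strandeffort.records import (
    DEFAULT_WINDOWS,
    StrandingRecord,
    Subgroup,
    SubgroupDefinition,
)


@pytest.fixture
def aor_polygon():
    """Rectangular area-of-response in lon/lat covering both subgroups."""
    return box(-91.0, 29.0, -88.0, 31.0)


@pytest.fixture
def subgroup_defs():
    """Two adjacent, non-overlapping subgroup boxes splitting the AOR."""
    la = SubgroupDefinition(
        Subgroup.LA_REMOTE, box(-91.0, 29.0, -89.5, 31.0), *DEFAULT_WINDOWS[Subgroup.LA_REMOTE]
    )
    ms = SubgroupDefinition(
        Subgroup.MS_BARRIER_ISLANDS,
        box(-89.4999, 29.0, -88.0, 31.0),
        *DEFAULT_WINDOWS[Subgroup.MS_BARRIER_ISLANDS],
    )
    return [la, ms]


@pytest.fixture
def make_record():
    def _make(
        record_id="r1",
        date=dt.date(2011, 6, 10),
        lon=-90.0,
        lat=30.0,
        species="Tursiops truncatus",
        condition="dead",
        comment="",
        location_text="",
    ):
        return StrandingRecord(
            record_id=record_id,
            report_date=date,
            lon=lon,
            lat=lat,
            species=species,
            condition=condition,
            comment=comment,
            location_text=location_text,
            source="test",
        )

    return _make
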