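"""Parsing, validation, filtering and grouping of Level A stranding records.

Level A data are the minimal standardized reports collected for each
stranded marine mammal (date, coordinates, species, condition, free-text
comments).  This module turns a raw CSV export into a clean analysis set:

* coordinates arrive in a mix of dialects (decimal degrees, degrees
  decimal-minutes, degrees-minutes-seconds) and are normalised to signed
  decimal degrees;
* records are filtered in four audited stages (coordinates, species and
  condition, area-of-response membership, coordinate/description
  mismatches) with per-stage tallies;
* retained records are assigned to a geographic subgroup (point in
  polygon) and a temporal group (Pre-Spill / Active Response /
  Post-RADC) using per-subgroup calendar-month windows.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Subgroup",
    "TemporalGroup",
    "TemporalWindow",
    "SubgroupDefinition",
    "StrandingRecord",
    "FilterReport",
    "parse_coordinate",
    "parse_report_date",
    "filter_records",
    "assign_groups",
    "months_in_window",
    "read_records_csv",
    "load_polygon_geojson",
    "load_subgroups_geojson",
    "PRE_SPILL_WINDOW",
    "DEFAULT_WINDOWS",
]


class Subgroup(str, enum.Enum):
    """Geographic subgroups corresponding to oil-spill areas of operations."""

    LA_PUBLIC_PRIVATE = "LA_PUBLIC_PRIVATE"
    LA_REMOTE = "LA_REMOTE"
    MS_BARRIER_ISLANDS = "MS_BARRIER_ISLANDS"
    AL_MOBILE = "AL_MOBILE"
    AL_BSNWR_ORANGE_BEACH = "AL_BSNWR_ORANGE_BEACH"


class TemporalGroup(str, enum.Enum):
    PRE_SPILL = "PRE_SPILL"
    ACTIVE = "ACTIVE"
    POST_RADC = "POST_RADC"


_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


def _month_index(ym: str) -> int:
    m = _MONTH_RE.match(ym)
    if not m:
        raise ValueError(f"month must be 'YYYY-MM', got {ym!r}")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in {ym!r}")
    return year * 12 + (month - 1)


@dataclass(frozen=True)
class TemporalWindow:
    """Inclusive range of calendar months, e.g. TemporalWindow('2010-05', '2013-12')."""

    start: str
    end: str

    def __post_init__(self) -> None:
        if _month_index(self.start) > _month_index(self.end):
            raise ValueError(f"window start {self.start} after end {self.end}")

    @property
    def n_months(self) -> int:
        return _month_index(self.end) - _month_index(self.start) + 1

    def contains(self, date: _dt.date) -> bool:
        idx = date.year * 12 + (date.month - 1)
        return _month_index(self.start) <= idx <= _month_index(self.end)

    def month_labels(self) -> list[str]:
        """Ordered 'YYYY-MM' labels covering the window."""
        i0 = _month_index(self.start)
        return [f"{i // 12:04d}-{i % 12 + 1:02d}" for i in range(i0, i0 + self.n_months)]


def months_in_window(window: TemporalWindow) -> int:
    """Inclusive calendar-month count of a window (both endpoint months counted)."""
    return window.n_months


#: Pre-Spill period shared by all subgroups (Jan 1996 - Apr 2010).
PRE_SPILL_WINDOW = TemporalWindow("1996-01", "2010-04")

#: Five-year Pre-Spill slice free of earlier unusual-mortality events,
#: used for the Active-vs-Pre rate comparisons (May 2005 - Apr 2010).
PRE_SPILL_5YR_WINDOW = TemporalWindow("2005-05", "2010-04")

#: Active Response / Post-RADC month windows per subgroup.  The Active ->
#: Post transition varied across the area of response as removal actions
#: were declared complete.
DEFAULT_WINDOWS: dict[Subgroup, tuple[TemporalWindow, TemporalWindow]] = {
    Subgroup.LA_PUBLIC_PRIVATE: (TemporalWindow("2010-05", "2014-03"), TemporalWindow("2014-04", "2015-04")),
    Subgroup.LA_REMOTE: (TemporalWindow("2010-05", "2013-12"), TemporalWindow("2014-01", "2015-04")),
    Subgroup.MS_BARRIER_ISLANDS: (TemporalWindow("2010-05", "2013-04"), TemporalWindow("2013-05", "2015-04")),
    Subgroup.AL_MOBILE: (TemporalWindow("2010-05", "2013-05"), TemporalWindow("2013-06", "2015-04")),
    Subgroup.AL_BSNWR_ORANGE_BEACH: (TemporalWindow("2010-05", "2013-05"), TemporalWindow("2013-06", "2015-04")),
}


@dataclass(frozen=True)
class SubgroupDefinition:
    name: Subgroup
    polygon: BaseGeometry
    active_window: TemporalWindow
    post_radc_window: TemporalWindow

    def __post_init__(self) -> None:
        if _month_index(self.active_window.end) >= _month_index(self.post_radc_window.start):
            raise ValueError(f"{self.name}: active window must precede post-RADC window")


@dataclass
class StrandingRecord:
    """One Level A style stranding report (already coordinate-parsed)."""

    record_id: str
    report_date: _dt.date | None
    lon: float | None
    lat: float | None
    species: str
    condition: str
    comment: str = ""
    location_text: str = ""
    source: str = ""


# --------------------------------------------------------------------------
# coordinate parsing

_HEMI_RE = re.compile(r"[NSEW]", re.IGNORECASE)
_NUM_RE = re.compile(r"[-+]?\d+(?:\.\d+)?")


def parse_coordinate(text: str) -> float | None:
    """Parse a coordinate string in any common Level A dialect.

    Accepts signed decimal degrees (``-89.5``), degrees decimal-minutes
    (``89 30.25 W``) and degrees-minutes-seconds (``30° 15' 30" N``),
    with optional hemisphere letters and unit glyphs.  Returns signed
    decimal degrees, or ``None`` when the text cannot be read under the
    dialect rules (minutes/seconds must lie in [0, 60); at most three
    numeric parts; only the whole string's sign may be negative).
    Failure is a value, not an exception, so the record-filter stage can
    drop unparseable rows while keeping an audit trail.
    """
    if text is None:
        return None
    s = str(text).strip()
    if not s:
        return None

    hemis = _HEMI_RE.findall(s)
    if len(hemis) > 1:
        return None
    hemi = hemis[0].upper() if hemis else None

    nums = _NUM_RE.findall(s)
    if not 1 <= len(nums) <= 3:
        return None
    # anything left after removing numbers, hemisphere and unit glyphs is junk
    leftover = _NUM_RE.sub("", s)
    leftover = _HEMI_RE.sub("", leftover)
    if re.search(r"[^\s°ºo'′’\"″:,.\-+]", leftover):
        return None

    parts = [float(v) for v in nums]
    if any(v < 0 for v in parts[1:]):
        return None
    # finer parts forbid fractional coarser parts ("30.5 15" is malformed)
    for coarse in parts[:-1]:
        if coarse != int(coarse):
            return None
    if any(v >= 60 for v in parts[1:]):
        return None

    magnitude = abs(parts[0])
    if len(parts) >= 2:
        magnitude += parts[1] / 60.0
    if len(parts) == 3:
        magnitude += parts[2] / 3600.0

    negative = parts[0] < 0 or s.lstrip().startswith("-")
    if hemi in ("S", "W"):
        if negative:
            return None  # "-89.5 W" is contradictory
        negative = True
    return -magnitude if negative else magnitude


def format_coordinate(value: float, dialect: str = "dd") -> str:
    """Render decimal degrees into a dialect (``dd``, ``dm`` or ``dms``).

    Round-trips through :func:`parse_coordinate` to within 1e-9 degrees.
    """
    sign = "-" if value < 0 else ""
    v = abs(value)
    if dialect == "dd":
        return f"{value:.9f}"
    deg = int(v)
    rem = (v - deg) * 60.0
    if dialect == "dm":
        return f"{sign}{deg} {rem:.9f}"
    if dialect == "dms":
        minutes = int(rem)
        sec = (rem - minutes) * 60.0
        return f"{sign}{deg} {minutes} {sec:.9f}"
    raise ValueError(f"unknown dialect {dialect!r}")


_ISO_DATE_RE = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")
_US_DATE_RE = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")


def parse_report_date(text: str) -> _dt.date | None:
    """Parse ISO ``YYYY-MM-DD`` or US ``m/d/yyyy`` dates.

    A slash date whose month field exceeds 12 could only be read
    day-first; rather than guessing a dialect the value is rejected.
    """
    if text is None:
        return None
    s = str(text).strip()
    m = _ISO_DATE_RE.match(s)
    if m:
        try:
            return _dt.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
        except ValueError:
            return None
    m = _US_DATE_RE.match(s)
    if m:
        month, day, year = int(m.group(1)), int(m.group(2)), int(m.group(3))
        try:
            return _dt.date(year, month, day)
        except ValueError:
            return None
    return None


# --------------------------------------------------------------------------
# filtering

@dataclass
class FilterReport:
    """Stage tallies of the four-step record filter, with dropped ids."""

    input_count: int = 0
    after_coordinate_filter: int = 0
    after_species_condition_filter: int = 0
    after_aor_filter: int = 0
    after_mismatch_filter: int = 0
    dropped_coordinate: list[str] = field(default_factory=list)
    dropped_species_condition: list[str] = field(default_factory=list)
    dropped_aor: list[str] = field(default_factory=list)
    dropped_mismatch: list[str] = field(default_factory=list)

    @property
    def tallies(self) -> tuple[int, int, int, int, int]:
        return (
            self.input_count,
            self.after_coordinate_filter,
            self.after_species_condition_filter,
            self.after_aor_filter,
            self.after_mismatch_filter,
        )

    def validate(self) -> None:
        t = self.tallies
        if any(b > a for a, b in zip(t, t[1:])):
            raise AssertionError(f"filter tallies must be non-increasing: {t}")
        drops = (
            len(self.dropped_coordinate),
            len(self.dropped_species_condition),
            len(self.dropped_aor),
            len(self.dropped_mismatch),
        )
        for (a, b), d in zip(zip(t, t[1:]), drops):
            if a - b != d:
                raise AssertionError("dropped + retained must equal previous stage count")

    def to_frame(self) -> pd.DataFrame:
        names = [
            "input",
            "after_coordinate_filter",
            "after_species_condition_filter",
            "after_aor_filter",
            "after_mismatch_filter",
        ]
        return pd.DataFrame({"stage": names, "records": list(self.tallies)})


#: species strings accepted as bottlenose dolphin (matched case-insensitively)
BOTTLENOSE_ALIASES = frozenset({"tursiops truncatus", "bottlenose dolphin"})


def _is_bottlenose(species: str) -> bool:
    return str(species).strip().lower() in BOTTLENOSE_ALIASES


def filter_records(
    records: Sequence[StrandingRecord],
    aor_polygon: BaseGeometry,
    mismatch_ids: Iterable[str] = (),
    study_window: TemporalWindow = TemporalWindow("1996-01", "2015-12"),
) -> tuple[list[StrandingRecord], FilterReport]:
    """Apply the four-stage record filter and return survivors plus an audit.

    Stages, in order: (1) drop records with missing, unparseable or
    out-of-range coordinates or dates; (2) keep dead bottlenose dolphins
    only; (3) keep points inside the area-of-response polygon (boundary
    inclusive); (4) drop ids on the supplied coordinate/description
    mismatch list (the mismatch judgement itself is manual upstream).
    """
    if aor_polygon is None or aor_polygon.is_empty or not aor_polygon.is_valid:
        raise ValueError("area-of-response polygon is missing or invalid")
    mismatch = set(mismatch_ids)

    report = FilterReport(input_count=len(records))

    stage1: list[StrandingRecord] = []
    for r in records:
        ok = (
            r.lon is not None
            and r.lat is not None
            and -180.0 <= r.lon <= 180.0
            and -90.0 <= r.lat <= 90.0
            and r.report_date is not None
            and study_window.contains(r.report_date)
        )
        (stage1.append(r) if ok else report.dropped_coordinate.append(r.record_id))
    report.after_coordinate_filter = len(stage1)

    stage2 = []
    for r in stage1:
        if _is_bottlenose(r.species) and str(r.condition).strip().lower() == "dead":
            stage2.append(r)
        else:
            report.dropped_species_condition.append(r.record_id)
    report.after_species_condition_filter = len(stage2)

    stage3 = []
    for r in stage2:
        if aor_polygon.covers(Point(r.lon, r.lat)):
            stage3.append(r)
        else:
            report.dropped_aor.append(r.record_id)
    report.after_aor_filter = len(stage3)

    stage4 = []
    for r in stage3:
        if r.record_id in mismatch:
            report.dropped_mismatch.append(r.record_id)
        else:
            stage4.append(r)
    report.after_mismatch_filter = len(stage4)

    report.validate()
    return stage4, report


def assign_groups(
    record: StrandingRecord,
    subgroups: Sequence[SubgroupDefinition],
) -> tuple[Subgroup | None, TemporalGroup | None]:
    """Assign a retained record to (geographic subgroup, temporal group).

    Subgroup by point-in-polygon (boundary inclusive); the polygons must
    partition space — membership in two subgroups raises.  Temporal group
    compares the report month with the shared Pre-Spill window and the
    subgroup's Active / Post-RADC windows.
    """
    pt = Point(record.lon, record.lat)
    hits = [sg for sg in subgroups if sg.polygon.covers(pt)]
    if len(hits) > 1:
        names = [h.name.value for h in hits]
        raise ValueError(f"record {record.record_id} falls in overlapping subgroups {names}")
    if not hits:
        return None, None
    sg = hits[0]
    if record.report_date is None:
        return sg.name, None
    if PRE_SPILL_WINDOW.contains(record.report_date):
        return sg.name, TemporalGroup.PRE_SPILL
    if sg.active_window.contains(record.report_date):
        return sg.name, TemporalGroup.ACTIVE
    if sg.post_radc_window.contains(record.report_date):
        return sg.name, TemporalGroup.POST_RADC
    return sg.name, None


# --------------------------------------------------------------------------
# I/O

RECORD_COLUMNS = [
    "record_id",
    "report_date",
    "latitude",
    "longitude",
    "species",
    "condition",
    "comment",
    "location_text",
    "source",
]


def read_records_csv(path: str | Path) -> list[StrandingRecord]:
    """Read the standard record CSV, parsing coordinates and dates.

    Unparseable coordinates/dates become ``None`` fields (dropped later
    at filter stage 1), so a dirty export reads without raising.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record CSV missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            StrandingRecord(
                record_id=row.record_id,
                report_date=parse_report_date(row.report_date),
                lon=parse_coordinate(row.longitude),
                lat=parse_coordinate(row.latitude),
                species=row.species,
                condition=row.condition,
                comment=row.comment,
                location_text=row.location_text,
                source=row.source,
            )
        )
    return out


def records_to_frame(records: Sequence[StrandingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "report_date": [r.report_date.isoformat() if r.report_date else "" for r in records],
            "latitude": [r.lat for r in records],
            "longitude": [r.lon for r in records],
            "species": [r.species for r in records],
            "condition": [r.condition for r in records],
            "comment": [r.comment for r in records],
            "location_text": [r.location_text for r in records],
            "source": [r.source for r in records],
        }
    )


def load_polygon_geojson(path: str | Path) -> BaseGeometry:
    """Load a single polygon (Feature, FeatureCollection or bare geometry)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
        if len(geoms) != 1:
            raise ValueError(f"expected exactly one feature in {path}, got {len(geoms)}")
        return geoms[0]
    if gj.get("type") == "Feature":
        return shape(gj["geometry"])
    return shape(gj)


def load_subgroups_geojson(
    path: str | Path,
    windows: dict[Subgroup, tuple[TemporalWindow, TemporalWindow]] | None = None,
) -> list[SubgroupDefinition]:
    """Load subgroup polygons from a FeatureCollection with a ``name`` property."""
    windows = windows or DEFAULT_WINDOWS
    with open(path) as fh:
        gj = json.load(fh)
    defs = []
    for feat in gj["features"]:
        name = Subgroup(feat["properties"]["name"])
        active, post = windows[name]
        defs.append(SubgroupDefinition(name, shape(feat["geometry"]), active, post))
    return defs
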