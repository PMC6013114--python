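"""Attribution of stranding reports to a reporting-party class.

Each Active Response record is attributed to exactly one of four classes:

* ``RESPONSE_COMMENT`` — the free-text comment names an oil-spill
  response party (SCAT team, Task Force, BP work crew, ...);
* ``NOT_RESPONSE`` — the comment names a party explicitly unrelated to
  the response;
* ``PROXIMITY_161M`` — the comment is silent, but a response team was
  within 161 m (1/10 mile) of the stranding on the day it was reported;
* ``UNKNOWN`` — none of the above.

``RESPONSE_COMMENT`` and ``PROXIMITY_161M`` together form the
"response-related" set whose share of all Active Response reports is the
headline effort-inflation quantity.  Precedence is comment-positive >
comment-negative > proximity > unknown: the responder databases were
consulted only for records whose comments did not specify a reporting
party, so a comment always wins over the distance rule.
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
from shapely import wkt as _wkt
from shapely.geometry.base import BaseGeometry

__all__ = [
    "CommentClass",
    "AttributionLabel",
    "CommentLexicon",
    "DEFAULT_LEXICON",
    "ResponderPresence",
    "AttributionTally",
    "classify_comment",
    "nearest_responder_distance",
    "attribute",
    "tally_attribution",
    "read_presences",
    "RESPONSE_RADIUS_M",
]

#: Detection radius around response teams: 1/10 mile, used exactly.
RESPONSE_RADIUS_M = 161.0


class CommentClass(str, enum.Enum):
    RESPONSE = "RESPONSE"
    NOT_RESPONSE = "NOT_RESPONSE"
    UNSPECIFIED = "UNSPECIFIED"


class AttributionLabel(str, enum.Enum):
    RESPONSE_COMMENT = "RESPONSE_COMMENT"
    NOT_RESPONSE = "NOT_RESPONSE"
    PROXIMITY_161M = "PROXIMITY_161M"
    UNKNOWN = "UNKNOWN"

    @property
    def response_related(self) -> bool:
        return self in (AttributionLabel.RESPONSE_COMMENT, AttributionLabel.PROXIMITY_161M)


@dataclass(frozen=True)
class CommentLexicon:
    """Case-insensitive pattern sets for reading reporting-party comments.

    Patterns are regular expressions searched anywhere in the comment.
    Response patterns take precedence over non-response patterns, so the
    two sets need not be disjoint on every conceivable comment.
    """

    response_patterns: tuple[str, ...]
    non_response_patterns: tuple[str, ...]

    def describe(self) -> dict:
        return {
            "response_patterns": list(self.response_patterns),
            "non_response_patterns": list(self.non_response_patterns),
        }


#: Conservative default lexicon: explicit response-organisation names for
#: the positive set, explicit unaffiliated reporting parties for the
#: negative set.  Deployments extend it; every pipeline run logs the
#: lexicon in its manifest for auditability.
DEFAULT_LEXICON = CommentLexicon(
    response_patterns=(
        r"scat\s+team",
        r"task\s+force",
        r"bp\s+work\s+crew",
        r"bp\s+crew",
        # deliberately anchored to an agentive verb: a bare "oil spill
        # response" substring also occurs inside negations ("not related
        # to the oil spill response") and must not match
        r"(found|discovered|reported|located)\s+by\s+(the\s+)?oil\s+spill\s+respon",
        r"response\s+(team|crew|worker)",
        r"clean[\s-]?up\s+crew",
        r"wildlife\s+branch",
    ),
    non_response_patterns=(
        r"not\s+(related\s+to|affiliated\s+with)\s+the\s+(oil\s+spill|response)",
        r"unrelated\s+to\s+the\s+(oil\s+spill|response)",
        r"member\s+of\s+the\s+public",
        r"local\s+resident",
        r"beach[\s-]?goer",
        r"fisherman|fishermen|charter\s+captain",
        r"tourist",
    ),
)


def classify_comment(comment: str, lexicon: CommentLexicon = DEFAULT_LEXICON) -> CommentClass:
    """Classify a free-text comment as RESPONSE / NOT_RESPONSE / UNSPECIFIED.

    Empty or whitespace-only comments are UNSPECIFIED.  Response patterns
    are checked first and win on any overlap.
    """
    text = (comment or "").strip().lower()
    if not text:
        return CommentClass.UNSPECIFIED
    for pat in lexicon.response_patterns:
        if re.search(pat, text):
            return CommentClass.RESPONSE
    for pat in lexicon.non_response_patterns:
        if re.search(pat, text):
            return CommentClass.NOT_RESPONSE
    return CommentClass.UNSPECIFIED


@dataclass(frozen=True)
class ResponderPresence:
    """A response team's surveyed shoreline segment on one calendar day.

    Geometry is a polyline (or point set) in planar metres; distances to
    it are perpendicular point-to-geometry distances, not vertex-to-vertex.
    """

    segment_id: str
    date: _dt.date
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ValueError(f"presence {self.segment_id} {self.date}: empty geometry")


def nearest_responder_distance(
    point_xy: tuple[float, float],
    record_date: _dt.date,
    presences: Sequence[ResponderPresence],
) -> float | None:
    """Minimum distance (m) from the stranding to any same-day presence.

    Returns ``None`` when no team was out on that calendar date.  Same-day
    means equal local calendar date — no ±1-day window, matching the rule
    that the team must have been there *on the day the stranding was
    reported*.
    """
    pt = Point(*point_xy)
    dists = [p.geometry.distance(pt) for p in presences if p.date == record_date]
    return min(dists) if dists else None


def attribute(
    point_xy: tuple[float, float],
    record_date: _dt.date,
    comment: str,
    presences: Sequence[ResponderPresence],
    lexicon: CommentLexicon = DEFAULT_LEXICON,
    radius: float = RESPONSE_RADIUS_M,
) -> tuple[AttributionLabel, float | None]:
    """Attribute one Active Response record; returns (label, same-day distance).

    The distance is reported even when a comment decided the label, for
    audit output.  The radius comparison is boundary-inclusive (<=).
    """
    cls = classify_comment(comment, lexicon)
    dist = nearest_responder_distance(point_xy, record_date, presences)
    if cls is CommentClass.RESPONSE:
        return AttributionLabel.RESPONSE_COMMENT, dist
    if cls is CommentClass.NOT_RESPONSE:
        return AttributionLabel.NOT_RESPONSE, dist
    if dist is not None and dist <= radius:
        return AttributionLabel.PROXIMITY_161M, dist
    return AttributionLabel.UNKNOWN, dist


_LABEL_ORDER = [
    AttributionLabel.NOT_RESPONSE,
    AttributionLabel.RESPONSE_COMMENT,
    AttributionLabel.PROXIMITY_161M,
    AttributionLabel.UNKNOWN,
]


@dataclass
class AttributionTally:
    """Per-year, per-label counts of Active Response records."""

    table: pd.DataFrame  # index: label value; columns: years + 'Total'
    total: int
    response_related: int

    @property
    def response_related_fraction(self) -> float:
        return self.response_related / self.total if self.total else 0.0


def tally_attribution(
    labels: Sequence[AttributionLabel],
    dates: Sequence[_dt.date],
) -> AttributionTally:
    """Cross-tabulate labels by calendar year, with totals and the
    response-related fraction (comment-positive + proximity over all)."""
    if len(labels) != len(dates):
        raise ValueError("labels and dates must align")
    years = sorted({d.year for d in dates})
    tab = pd.DataFrame(0, index=[l.value for l in _LABEL_ORDER], columns=years, dtype=int)
    for lab, d in zip(labels, dates):
        tab.loc[lab.value, d.year] += 1
    tab["Total"] = tab.sum(axis=1)
    total = len(labels)
    rr = int(
        tab.loc[AttributionLabel.RESPONSE_COMMENT.value, "Total"]
        + tab.loc[AttributionLabel.PROXIMITY_161M.value, "Total"]
    )
    return AttributionTally(table=tab, total=total, response_related=rr)


# --------------------------------------------------------------------------
# I/O

def read_presences(path: str | Path) -> list[ResponderPresence]:
    """Read responder presences from GeoJSON (properties: segment_id, date)
    or CSV with columns (segment_id, date, wkt)."""
    path = Path(path)
    out: list[ResponderPresence] = []
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            gj = json.load(fh)
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        for f in feats:
            props = f["properties"]
            out.append(
                ResponderPresence(
                    segment_id=str(props["segment_id"]),
                    date=_dt.date.fromisoformat(props["date"]),
                    geometry=shape(f["geometry"]),
                )
            )
        return out
    df = pd.read_csv(path, dtype=str)
    for row in df.itertuples(index=False):
        out.append(
            ResponderPresence(
                segment_id=str(row.segment_id),
                date=_dt.date.fromisoformat(row.date),
                geometry=_wkt.loads(row.wkt),
            )
        )
    return out


def attribution_frame(
    record_ids: Sequence[str],
    labels: Sequence[AttributionLabel],
    distances: Sequence[float | None],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": list(record_ids),
            "label": [l.value for l in labels],
            "same_day_min_distance_m": [d if d is not None else "" for d in distances],
        }
    )
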