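"""Synthetic stranding studies with known ground truth.

The generator emulates the joint structure the pipeline assumes:

* per-subgroup *true* carcass arrivals are homogeneous-in-time monthly
  Poisson counts beached uniformly along a shoreline polyline, with
  optional injected spatial clusters (Gaussian displacement around a
  centre, extra Poisson intensity, active month window);
* a responder schedule places survey teams on shoreline segments daily,
  with a monthly active-segment fraction ramp emulating the drawdown of
  the response workforce;
* a detection model reports each carcass with probability ``p_responder``
  when a team is within the detection radius (161 m) on the stranding
  day, and with the baseline public probability otherwise; reported
  records receive free-text comments drawn from class-appropriate
  template mixes, deliberately including ambiguous strings and silent
  comments so both the lexicon and the proximity rule are exercised.

Every record carries ground-truth flags, so attribution, rate and
hotspot analyses can be scored against the truth.  All randomness flows
from one root seed through independent named streams, so each stage is
reproducible in isolation.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .linkage import ResponderPresence, nearest_responder_distance
from .records import TemporalWindow
from . import utm

__all__ = [
    "InjectedCluster",
    "MortalityConfig",
    "DetectionConfig",
    "ResponderScheduleConfig",
    "SyntheticStudy",
    "simulate_strandings",
    "simulate_responders",
    "apply_detection",
    "truth_report",
    "default_study",
    "default_configs",
    "default_hotspot_study",
]

RESPONSE_TEMPLATES = (
    "Initially discovered by SCAT team during segment survey.",
    "Carcass was reported by BP work crew.",
    "Found by Task Force 3 during shoreline sweep.",
    "Reported by oil spill response crew on patrol.",
    # ambiguous on purpose: matches both pattern sets; response wins
    "Reported by BP work crew; local resident also present on scene.",
)
NON_RESPONSE_TEMPLATES = (
    "Reported by a local resident walking the beach.",
    "Found by fisherman; not related to the oil spill response.",
    "Member of the public called the stranding hotline.",
    "Charter captain reported carcass drifting near the pass.",
)
UNSPECIFIED_TEMPLATES = (
    "",
    "Carcass moderately decomposed; code 3.",
    "Floating near marsh edge; no reporter details recorded.",
    "Badly scavenged; photographs taken for identification.",
)


@dataclass(frozen=True)
class InjectedCluster:
    """Extra Poisson intensity spread Gaussian-ly around a planar centre."""

    subgroup: str
    center: tuple[float, float]
    sigma_m: float
    extra_rate: float  # events per month on top of the background
    window: TemporalWindow | None = None  # None = whole simulation window

    def __post_init__(self) -> None:
        if self.sigma_m <= 0:
            raise ValueError("cluster sigma must be positive")
        if self.extra_rate < 0:
            raise ValueError("cluster extra rate must be non-negative")


@dataclass
class MortalityConfig:
    """True-carcass intensity model: per-subgroup monthly Poisson rates on
    shoreline polylines, plus optional injected clusters."""

    rates: dict[str, float]  # subgroup -> true carcasses per month
    shorelines: dict[str, LineString]
    clusters: tuple[InjectedCluster, ...] = ()

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("monthly rates must be non-negative")
        if set(self.rates) != set(self.shorelines):
            raise ValueError("rates and shorelines must cover the same subgroups")


@dataclass
class DetectionConfig:
    """Reporting model.  ``p_public`` may be a single probability or a
    per-subgroup mapping (remote shorelines see fewer passers-by)."""

    p_public: float | dict[str, float] = 0.15
    p_responder: float = 0.95
    radius_m: float = 161.0
    #: probability a responder-reported record's comment names the response
    #: (the rest stay unspecified and must be caught by the proximity rule)
    p_comment_given_response: float = 0.57
    #: probability a public report's comment names a non-response party
    p_comment_given_public: float = 0.23

    def public_prob(self, subgroup: str) -> float:
        if isinstance(self.p_public, dict):
            return self.p_public[subgroup]
        return self.p_public

    def validate(self) -> None:
        probs = list(self.p_public.values()) if isinstance(self.p_public, dict) else [self.p_public]
        probs += [self.p_responder, self.p_comment_given_response, self.p_comment_given_public]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if isinstance(self.p_public, dict):
            if any(self.p_responder < p for p in self.p_public.values()):
                raise ValueError("effort-inflation scenarios need p_responder >= p_public")
        elif self.p_responder < self.p_public:
            raise ValueError("effort-inflation scenarios need p_responder >= p_public")


@dataclass
class ResponderScheduleConfig:
    """Daily segment-survey schedule with a monthly activity ramp.

    ``fraction_start``/``fraction_end`` give the fraction of segments
    surveyed per day at the first and last month of the window, linearly
    interpolated between (emulating the workforce drawdown from tens of
    thousands of responders to roughly a thousand).  ``always_on``
    segments are surveyed every survey day regardless of the ramp.
    """

    segments: tuple[tuple[str, LineString], ...]
    fraction_start: float = 0.35
    fraction_end: float = 0.02
    survey_days_per_week: int = 7
    always_on: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for f in (self.fraction_start, self.fraction_end):
            if not 0.0 <= f <= 1.0:
                raise ValueError("active-segment fractions must lie in [0, 1]")
        if not 0 <= self.survey_days_per_week <= 7:
            raise ValueError("survey days per week must be 0..7")


@dataclass
class SyntheticStudy:
    """Simulated carcasses, reported records, presences and ground truth."""

    true_strandings: pd.DataFrame  # carcass_id, date, x, y, subgroup, cluster
    records: pd.DataFrame  # reported subset + comment text
    presences: list[ResponderPresence]
    truth: pd.DataFrame  # per reported record: flags + same-day distance
    detection: DetectionConfig

    def reported_ids(self) -> list[str]:
        return list(self.records["record_id"])


def _streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Independent, reproducible child streams from one root seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _month_days(label: str) -> list[_dt.date]:
    year, month = int(label[:4]), int(label[5:7])
    ndays = calendar.monthrange(year, month)[1]
    return [_dt.date(year, month, d) for d in range(1, ndays + 1)]


def simulate_strandings(
    config: MortalityConfig,
    window: TemporalWindow,
    seed: int,
) -> pd.DataFrame:
    """Draw the true (reported *and* unreported) carcass set.

    Monthly counts are Poisson(rate) per subgroup (plus cluster
    contributions inside their windows); positions are arc-length
    uniform along the subgroup shoreline, cluster positions Gaussian
    around the cluster centre; the stranding day is uniform in month.
    """
    rng = _streams(seed, "strandings")["strandings"]
    rows = []
    k = 0
    for label in window.month_labels():
        days = _month_days(label)
        mid = days[0]
        for sg, lam in config.rates.items():
            line = config.shorelines[sg]
            count = rng.poisson(lam)
            for _ in range(count):
                pos = line.interpolate(rng.uniform(0.0, line.length))
                rows.append(
                    {
                        "carcass_id": f"c{k:06d}",
                        "date": days[rng.integers(len(days))],
                        "x": pos.x,
                        "y": pos.y,
                        "subgroup": sg,
                        "cluster": -1,
                    }
                )
                k += 1
        for ci, cl in enumerate(config.clusters):
            if cl.window is not None and not cl.window.contains(mid):
                continue
            # carcasses beach on shore: the cluster spreads along-shore,
            # Gaussian in arc length around the centre's shoreline foot
            line = config.shorelines[cl.subgroup]
            s_center = line.project(Point(cl.center))
            count = rng.poisson(cl.extra_rate)
            for _ in range(count):
                s = float(np.clip(s_center + rng.normal(0.0, cl.sigma_m), 0.0, line.length))
                pos = line.interpolate(s)
                rows.append(
                    {
                        "carcass_id": f"c{k:06d}",
                        "date": days[rng.integers(len(days))],
                        "x": pos.x,
                        "y": pos.y,
                        "subgroup": cl.subgroup,
                        "cluster": ci,
                    }
                )
                k += 1
    cols = ["carcass_id", "date", "x", "y", "subgroup", "cluster"]
    return pd.DataFrame(rows, columns=cols)


def simulate_responders(
    config: ResponderScheduleConfig,
    window: TemporalWindow,
    seed: int,
) -> list[ResponderPresence]:
    """Daily segment presences over the window, deterministic under seed."""
    rng = _streams(seed, "responders")["responders"]
    labels = window.month_labels()
    n_months = len(labels)
    seg_ids = [sid for sid, _ in config.segments]
    seg_geoms = dict(config.segments)
    ramp_ids = [sid for sid in seg_ids if sid not in config.always_on]

    presences: list[ResponderPresence] = []
    for mi, label in enumerate(labels):
        t = mi / max(n_months - 1, 1)
        frac = config.fraction_start + t * (config.fraction_end - config.fraction_start)
        n_active = int(round(frac * len(ramp_ids)))
        for day in _month_days(label):
            if day.weekday() >= config.survey_days_per_week:
                continue
            chosen = list(config.always_on)
            if n_active > 0:
                idx = rng.choice(len(ramp_ids), size=n_active, replace=False)
                chosen += [ramp_ids[i] for i in sorted(idx)]
            for sid in chosen:
                presences.append(ResponderPresence(sid, day, seg_geoms[sid]))
    return presences


def apply_detection(
    true_strandings: pd.DataFrame,
    presences: Sequence[ResponderPresence],
    config: DetectionConfig,
    seed: int,
) -> SyntheticStudy:
    """Draw which carcasses become Level A reports, with truth labels.

    A carcass with a same-day team within the radius is reported with
    ``p_responder`` (reporting party: the responder); otherwise it is
    reported with the public baseline probability (reporting party: the
    public).  On a surveyed beach the team is the party on scene, so the
    two channels do not compete.  Comments are drawn from the
    class-appropriate template mix; a known fraction of responder
    reports stay unspecified so that only the 161 m proximity rule can
    recover them.
    """
    config.validate()
    streams = _streams(seed, "detect", "comments")
    rng, crng = streams["detect"], streams["comments"]

    by_date: dict[_dt.date, list[ResponderPresence]] = {}
    for p in presences:
        by_date.setdefault(p.date, []).append(p)

    rec_rows, truth_rows = [], []
    j = 0
    for row in true_strandings.itertuples(index=False):
        dist = nearest_responder_distance((row.x, row.y), row.date, by_date.get(row.date, []))
        covered = dist is not None and dist <= config.radius_m
        if covered:
            responder_report = rng.random() < config.p_responder
            reported = responder_report
        else:
            responder_report = False
            reported = rng.random() < config.public_prob(row.subgroup)
        if not reported:
            continue
        if responder_report:
            true_class = "RESPONSE"
            if crng.random() < config.p_comment_given_response:
                comment = RESPONSE_TEMPLATES[crng.integers(len(RESPONSE_TEMPLATES))]
            else:
                comment = UNSPECIFIED_TEMPLATES[crng.integers(len(UNSPECIFIED_TEMPLATES))]
        else:
            true_class = "PUBLIC"
            if crng.random() < config.p_comment_given_public:
                comment = NON_RESPONSE_TEMPLATES[crng.integers(len(NON_RESPONSE_TEMPLATES))]
            else:
                comment = UNSPECIFIED_TEMPLATES[crng.integers(len(UNSPECIFIED_TEMPLATES))]
        record_id = f"r{j:06d}"
        j += 1
        rec_rows.append(
            {
                "record_id": record_id,
                "carcass_id": row.carcass_id,
                "date": row.date,
                "x": row.x,
                "y": row.y,
                "subgroup": row.subgroup,
                "comment": comment,
            }
        )
        truth_rows.append(
            {
                "record_id": record_id,
                "was_response_detected": bool(responder_report),
                "true_class": true_class,
                "same_day_distance_m": dist if dist is not None else np.nan,
                "cluster": row.cluster,
            }
        )
    rec_cols = ["record_id", "carcass_id", "date", "x", "y", "subgroup", "comment"]
    truth_cols = ["record_id", "was_response_detected", "true_class", "same_day_distance_m", "cluster"]
    return SyntheticStudy(
        true_strandings=true_strandings,
        records=pd.DataFrame(rec_rows, columns=rec_cols),
        presences=list(presences),
        truth=pd.DataFrame(truth_rows, columns=truth_cols),
        detection=config,
    )


def truth_report(study: SyntheticStudy) -> dict:
    """Ground-truth summary: detection rate, class counts, true
    response-detected fraction among reported records."""
    n_true = len(study.true_strandings)
    n_rep = len(study.records)
    n_resp = int(study.truth["was_response_detected"].sum())
    return {
        "n_true_strandings": n_true,
        "n_reported": n_rep,
        "carcass_detection_rate": n_rep / n_true if n_true else 0.0,
        "n_response_detected": n_resp,
        "n_public": n_rep - n_resp,
        "true_response_fraction": n_resp / n_rep if n_rep else 0.0,
    }


# --------------------------------------------------------------------------
# default study conditions

#: Planar frame anchored in UTM zone 15 so synthetic coordinates can be
#: exported as plausible lon/lat when the CSV schema is needed.
_ORIGIN = (300000.0, 3300000.0)

PRE_WINDOW = TemporalWindow("2005-05", "2010-04")  # 60 months
ACTIVE_WINDOW = TemporalWindow("2010-05", "2013-12")  # 44 months
POST_WINDOW = TemporalWindow("2014-01", "2015-04")  # 16 months
FULL_WINDOW = TemporalWindow("2005-05", "2015-04")


def _shoreline(length_m: float, y: float = 0.0) -> LineString:
    x0, y0 = _ORIGIN
    return LineString([(x0, y0 + y), (x0 + length_m, y0 + y)])


def _tiled_segments(line: LineString, seg_len: float, prefix: str) -> tuple[tuple[str, LineString], ...]:
    n = int(np.ceil(line.length / seg_len))
    out = []
    for i in range(n):
        a = line.interpolate(i * seg_len)
        b = line.interpolate(min((i + 1) * seg_len, line.length))
        out.append((f"{prefix}{i:03d}", LineString([a, b])))
    return tuple(out)


def default_configs() -> tuple[MortalityConfig, ResponderScheduleConfig, DetectionConfig]:
    """Default single-subgroup study emulating a remote shoreline.

    A 120 km shoreline with a true carcass intensity of 4.2/month, a
    public reporting probability of 0.15 (remote coast: the published
    pre-spill reported rate of ~0.63/month then corresponds to the full
    true intensity), responder coverage ramping from 35% down to 2% of
    segments per day across the active window, and near-certain
    responder reporting (0.95) within 161 m.  Under these conditions
    roughly 58% of active-window reports are response-attributable,
    matching the published headline share.
    """
    shoreline = _shoreline(120000.0)
    mortality = MortalityConfig(rates={"REMOTE": 4.2}, shorelines={"REMOTE": shoreline})
    schedule = ResponderScheduleConfig(
        segments=_tiled_segments(shoreline, 5000.0, "seg"),
        fraction_start=0.35,
        fraction_end=0.02,
        survey_days_per_week=7,
    )
    detection = DetectionConfig(p_public=0.15, p_responder=0.95)
    return mortality, schedule, detection


def default_study(seed: int, rate_scale: float = 1.0) -> SyntheticStudy:
    """Simulate the default study across pre/active/post windows.

    Responders are present only during the active window.  ``rate_scale``
    multiplies the true intensity (used by recovery tests that need
    thousands of reports while keeping the same structure).
    """
    mortality, schedule, detection = default_configs()
    mortality = MortalityConfig(
        rates={k: v * rate_scale for k, v in mortality.rates.items()},
        shorelines=mortality.shorelines,
        clusters=mortality.clusters,
    )
    true_df = simulate_strandings(mortality, FULL_WINDOW, seed)
    presences = simulate_responders(schedule, ACTIVE_WINDOW, seed + 1)
    return apply_detection(true_df, presences, detection, seed + 2)


def default_hotspot_study(seed: int) -> SyntheticStudy:
    """Hotspot scenario: diffuse background plus one responder-reported cluster.

    A 300 km shoreline with sparse background strandings reported mostly
    by the public, and an injected along-shore cluster (sigma 6 km,
    roughly ten times the local background surface density) whose
    stretch of coast the response surveys every day — so the cluster's
    records are overwhelmingly response-attributed, and removing
    attributed records should dissolve the hotspot.  The cluster scale
    deliberately exceeds the fine aggregation tolerance used for
    subgroup-scale hotspot runs, so the cluster spreads over several
    aggregated events (a lone spike event is not a Gi* hotspot).
    """
    shoreline = _shoreline(300000.0)
    x0, y0 = _ORIGIN
    cluster_center = (x0 + 150000.0, y0)
    mortality = MortalityConfig(
        rates={"COAST": 3.0},
        shorelines={"COAST": shoreline},
        clusters=(
            InjectedCluster(
                subgroup="COAST",
                center=cluster_center,
                sigma_m=6000.0,
                extra_rate=2.5,
                window=ACTIVE_WINDOW,
            ),
        ),
    )
    segments = _tiled_segments(shoreline, 5000.0, "seg")
    always_on = tuple(
        sid for sid, geom in segments if geom.distance(Point(cluster_center)) <= 10000.0
    )
    schedule = ResponderScheduleConfig(
        segments=segments,
        fraction_start=0.10,
        fraction_end=0.05,
        survey_days_per_week=7,
        always_on=always_on,
    )
    detection = DetectionConfig(p_public=0.25, p_responder=0.95)
    true_df = simulate_strandings(mortality, ACTIVE_WINDOW, seed)
    presences = simulate_responders(schedule, ACTIVE_WINDOW, seed + 1)
    return apply_detection(true_df, presences, detection, seed + 2)


# --------------------------------------------------------------------------
# export in the schemas the record/linkage modules consume

def study_records_csv(study: SyntheticStudy, path: str | Path, zone: int = 15) -> None:
    """Write reported records in the standard Level A style CSV schema,
    converting the planar frame back to lon/lat."""
    lon, lat = utm.utm_inverse(study.records["x"].to_numpy(), study.records["y"].to_numpy(), zone=zone)
    out = pd.DataFrame(
        {
            "record_id": study.records["record_id"],
            "report_date": [d.isoformat() for d in study.records["date"]],
            "latitude": [f"{v:.6f}" for v in lat],
            "longitude": [f"{v:.6f}" for v in lon],
            "species": "Tursiops truncatus",
            "condition": "dead",
            "comment": study.records["comment"],
            "location_text": "",
            "source": "synthetic",
        }
    )
    out.to_csv(path, index=False)


def presences_csv(presences: Sequence[ResponderPresence], path: str | Path) -> None:
    pd.DataFrame(
        {
            "segment_id": [p.segment_id for p in presences],
            "date": [p.date.isoformat() for p in presences],
            "wkt": [p.geometry.wkt for p in presences],
        }
    ).to_csv(path, index=False)
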