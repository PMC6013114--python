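"""End-to-end study orchestration.

``run_study`` drives the full chain — filtering, responder attribution,
rate analytics, and the spatial hotspot pipeline — and collects every
table the analysis produces into a :class:`ReportBundle`, optionally
writing them as CSV/JSON artifacts plus a run manifest (config, seed,
lexicon) for auditability.

Two input modes exist: ``synthetic`` (the default study conditions from
:mod:`strandeffort.synthetic`, fully self-contained) and ``files``
(record CSV, responder CSV/GeoJSON, area-of-response and subgroup
polygons in the schemas documented in the records/linkage modules).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic, utm
from .hotspots import (
    WeightScheme,
    clip_to_buffer,
    gi_scores_frame,
    gi_star,
    idw_surface,
    integrate_collect,
    isa_profile,
    significant_area,
)
from .linkage import (
    DEFAULT_LEXICON,
    AttributionLabel,
    AttributionTally,
    CommentLexicon,
    attribute,
    attribution_frame,
    read_presences,
    tally_attribution,
)
from .rates import bonferroni_alpha, compare_rates, monthly_rate, monthly_series, poisson_gof, u_chart, u_chart_frame
from .records import (
    FilterReport,
    TemporalGroup,
    assign_groups,
    filter_records,
    load_polygon_geojson,
    load_subgroups_geojson,
    read_records_csv,
)

__all__ = ["StudyConfig", "ReportBundle", "run_study", "load_config"]


@dataclass
class StudyConfig:
    """Flat run configuration (mirrors the key=value config file)."""

    mode: str = "synthetic"  # "synthetic" | "files"
    seed: int = 0
    out_dir: str | None = None
    # files mode inputs
    records_csv: str | None = None
    presences_path: str | None = None
    aor_geojson: str | None = None
    subgroups_geojson: str | None = None
    mismatch_csv: str | None = None
    # analysis constants (defaults mirror the study constants)
    radius_m: float = 161.0
    aggregation_tolerance_m: float = 25000.0
    idw_cell_size_m: float = 2000.0
    idw_power: float = 2.0
    z_threshold: float = 1.96
    alpha: float = 0.05
    family_size: int = 5
    utm_zone: int = 15
    lexicon: CommentLexicon = field(default_factory=lambda: DEFAULT_LEXICON)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")
        if self.mode == "files":
            for key in ("records_csv", "aor_geojson", "subgroups_geojson"):
                path = getattr(self, key)
                if path is None or not Path(path).exists():
                    raise ValueError(f"files mode requires existing {key} (got {path!r})")


_CONFIG_FIELDS = {f.name: f.type for f in dataclasses.fields(StudyConfig)}


def load_config(path: str | Path) -> StudyConfig:
    """Read a flat ``key = value`` config file (# comments allowed)."""
    cfg = StudyConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "lexicon" or key not in _CONFIG_FIELDS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, bool):
            parsed: object = value.lower() in ("1", "true", "yes")
        elif isinstance(current, int) and not isinstance(current, bool):
            parsed = int(value)
        elif isinstance(current, float):
            parsed = float(value)
        else:
            parsed = value
        setattr(cfg, key, parsed)
    cfg.validate()
    return cfg


@dataclass
class ReportBundle:
    """Every table the study produces, as tidy DataFrames."""

    filter_report: FilterReport | None
    attribution_tally: AttributionTally | None
    attribution: pd.DataFrame
    rates_table: pd.DataFrame
    comparisons: pd.DataFrame
    gof_table: pd.DataFrame
    u_chart_table: pd.DataFrame
    hotspot_summary: pd.DataFrame
    gi_scores: pd.DataFrame
    manifest: dict
    warnings: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.filter_report is not None:
            self.filter_report.to_frame().to_csv(out / "filter_report.csv", index=False)
        if self.attribution_tally is not None:
            self.attribution_tally.table.to_csv(out / "attribution_tally.csv")
        self.attribution.to_csv(out / "attribution.csv", index=False)
        self.rates_table.to_csv(out / "rates.csv", index=False)
        self.comparisons.to_csv(out / "rate_comparisons.csv", index=False)
        self.gof_table.to_csv(out / "poisson_gof.csv", index=False)
        self.u_chart_table.to_csv(out / "u_chart.csv", index=False)
        self.hotspot_summary.to_csv(out / "hotspot_summary.csv", index=False)
        self.gi_scores.to_csv(out / "gi_scores.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))


def _attribute_records(records: pd.DataFrame, presences, config: StudyConfig) -> pd.DataFrame:
    labels, dists = [], []
    for row in records.itertuples(index=False):
        lab, d = attribute(
            (row.x, row.y), row.date, row.comment, presences, config.lexicon, config.radius_m
        )
        labels.append(lab)
        dists.append(d)
    out = attribution_frame(records["record_id"], labels, dists)
    out["date"] = list(records["date"])
    out["response_related"] = [l.response_related for l in labels]
    return out


def _hotspot_variant(points: np.ndarray, config: StudyConfig, variant: str):
    """Aggregate -> ISA -> Gi* -> IDW -> clip -> area, for one record set."""
    fld = integrate_collect(points, tolerance=config.aggregation_tolerance_m)
    profile = isa_profile(fld)
    scheme = WeightScheme(threshold_d0=profile.peak_distance)
    scores = gi_star(fld, scheme)
    pad = profile.peak_distance
    xmin, ymin = fld.points.min(axis=0) - pad - config.idw_cell_size_m
    xmax, ymax = fld.points.max(axis=0) + pad + config.idw_cell_size_m
    surf = idw_surface(
        fld.points,
        [s.gi_star for s in scores],
        cell_size=config.idw_cell_size_m,
        power=config.idw_power,
        bounds=(xmin, ymin, xmax, ymax),
    )
    clipped = clip_to_buffer(surf, fld, radius=profile.peak_distance)
    area = significant_area(clipped, z_threshold=config.z_threshold)
    frame = gi_scores_frame(fld, scores)
    frame.insert(0, "variant", variant)
    summary = {
        "variant": variant,
        "n_records": len(points),
        "n_events": fld.n,
        "isa_peak_distance_m": profile.peak_distance,
        "isa_no_local_peak": profile.no_local_peak,
        "significant_area_km2": area,
        "cell_size_m": config.idw_cell_size_m,
    }
    return summary, frame, clipped


def run_study(config: StudyConfig) -> ReportBundle:
    """Run the full analysis and return the bundle of result tables."""
    config.validate()
    warnings: list[str] = []
    manifest = {
        "config": {k: v for k, v in dataclasses.asdict(config).items() if k != "lexicon"},
        "lexicon": config.lexicon.describe(),
    }

    if config.mode == "synthetic":
        bundle = _run_synthetic(config, manifest, warnings)
    else:
        bundle = _run_files(config, manifest, warnings)
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def _empty_bundle(manifest: dict, warnings: list[str], filter_report=None) -> ReportBundle:
    return ReportBundle(
        filter_report=filter_report,
        attribution_tally=None,
        attribution=pd.DataFrame(),
        rates_table=pd.DataFrame(),
        comparisons=pd.DataFrame(),
        gof_table=pd.DataFrame(),
        u_chart_table=pd.DataFrame(),
        hotspot_summary=pd.DataFrame(),
        gi_scores=pd.DataFrame(),
        manifest=manifest,
        warnings=warnings,
    )


def _rate_block(
    subgroup: str,
    dates_pre,
    dates_active,
    dates_post,
    removed_active_dates,
    windows: tuple,
    config: StudyConfig,
    warnings: list[str],
):
    """Rates, U-chart stages, GOF and comparisons for one subgroup."""
    w_pre, w_active, w_post = windows
    s_pre = monthly_series(dates_pre, w_pre, subgroup)
    s_active = monthly_series(dates_active, w_active, subgroup)
    s_post = monthly_series(dates_post, w_post, subgroup)
    s_removed = monthly_series(removed_active_dates, w_active, subgroup)

    rates_row = {
        "subgroup": subgroup,
        "pre_spill_rate": monthly_rate(s_pre),
        "active_rate": monthly_rate(s_active),
        "active_removed_rate": monthly_rate(s_removed),
        "post_radc_rate": monthly_rate(s_post),
        "pre_months": len(s_pre.counts),
        "active_months": len(s_active.counts),
        "post_months": len(s_post.counts),
        "active_count": s_active.total,
        "active_removed_count": s_removed.total,
        "post_count": s_post.total,
        "pre_count": s_pre.total,
    }

    from .records import TemporalWindow

    full = TemporalWindow(w_pre.start, w_post.end)
    all_dates = list(dates_pre) + list(dates_active) + list(dates_post)
    s_full = monthly_series(all_dates, full, subgroup)
    n_pre, n_act = len(s_pre.counts), len(s_active.counts)
    stages = u_chart(
        s_full,
        [
            ("PRE_SPILL", 0, n_pre),
            ("ACTIVE", n_pre, n_pre + n_act),
            ("POST_RADC", n_pre + n_act, len(s_full.counts)),
        ],
    )
    chart = u_chart_frame(s_full, stages)
    chart.insert(0, "subgroup", subgroup)

    gof_rows = []
    for label, series in (("ACTIVE", s_active), ("POST_RADC", s_post)):
        try:
            g = poisson_gof(series)
            gof_rows.append(
                {
                    "subgroup": subgroup,
                    "period": label,
                    "chi_square": g.chi_square,
                    "df": g.df,
                    "p_value": g.p_value,
                    "cochran_ok": g.cochran_ok,
                }
            )
        except ValueError as exc:
            warnings.append(f"GOF skipped for {subgroup}/{label}: {exc}")

    comp_rows = []
    if s_removed.total + s_post.total > 0:
        c = compare_rates(s_removed.total, len(s_removed.counts), s_post.total, len(s_post.counts))
        comp_rows.append(
            {
                "subgroup": subgroup,
                "comparison": "ACTIVE_REMOVED_vs_POST_RADC",
                "x1": c.x1,
                "T1": c.T1,
                "x2": c.x2,
                "T2": c.T2,
                "sample_rate_ratio": c.sample_rate_ratio,
                "p_value": c.p_value,
                "ci95_low": c.ci95_low,
                "ci95_high": c.ci95_high,
            }
        )
    return rates_row, chart, gof_rows, comp_rows


def _run_synthetic(config: StudyConfig, manifest: dict, warnings: list[str]) -> ReportBundle:
    study = synthetic.default_study(config.seed)
    manifest["study"] = "synthetic default"
    manifest["truth"] = synthetic.truth_report(study)

    rec = study.records
    in_active = rec["date"].map(synthetic.ACTIVE_WINDOW.contains)
    active = rec[in_active]
    attr = _attribute_records(active, study.presences, config)
    tally = tally_attribution(
        [AttributionLabel(v) for v in attr["label"]], list(attr["date"])
    )

    removed_ids = set(attr.loc[attr["response_related"], "record_id"])
    kept_active = active[~active["record_id"].isin(removed_ids)]
    manifest["alpha_adjusted"] = bonferroni_alpha(config.alpha, config.family_size)

    rates_row, chart, gof_rows, comp_rows = _rate_block(
        "REMOTE",
        list(rec.loc[rec["date"].map(synthetic.PRE_WINDOW.contains), "date"]),
        list(active["date"]),
        list(rec.loc[rec["date"].map(synthetic.POST_WINDOW.contains), "date"]),
        list(kept_active["date"]),
        (synthetic.PRE_WINDOW, synthetic.ACTIVE_WINDOW, synthetic.POST_WINDOW),
        config,
        warnings,
    )

    # hotspot scenario: separate study with a planted responder-reported
    # cluster, analysed at the subgroup (fine) scale: 3 km aggregation,
    # 500 m cells — the coarse 25 km/2 km defaults suit basin-wide runs
    hs_cfg = dataclasses.replace(config, aggregation_tolerance_m=3000.0, idw_cell_size_m=500.0)
    hs = synthetic.default_hotspot_study(config.seed)
    hs_attr = _attribute_records(hs.records, hs.presences, config)
    hs_removed = set(hs_attr.loc[hs_attr["response_related"], "record_id"])
    pts_all = hs.records[["x", "y"]].to_numpy()
    pts_removed = hs.records[~hs.records["record_id"].isin(hs_removed)][["x", "y"]].to_numpy()
    summaries, frames = [], []
    for variant, pts in (("ALL_RECORDS", pts_all), ("RESPONSE_REMOVED", pts_removed)):
        if len(pts) < 4:
            warnings.append(f"hotspot variant {variant}: too few records, skipped")
            continue
        summary, frame, _ = _hotspot_variant(pts, hs_cfg, variant)
        summaries.append(summary)
        frames.append(frame)

    return ReportBundle(
        filter_report=None,
        attribution_tally=tally,
        attribution=attr,
        rates_table=pd.DataFrame([rates_row]),
        comparisons=pd.DataFrame(comp_rows),
        gof_table=pd.DataFrame(gof_rows),
        u_chart_table=chart,
        hotspot_summary=pd.DataFrame(summaries),
        gi_scores=pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(),
        manifest=manifest,
        warnings=warnings,
    )


def _run_files(config: StudyConfig, manifest: dict, warnings: list[str]) -> ReportBundle:
    records = read_records_csv(config.records_csv)
    aor = load_polygon_geojson(config.aor_geojson)
    subgroups = load_subgroups_geojson(config.subgroups_geojson)
    mismatch = []
    if config.mismatch_csv:
        mismatch = list(pd.read_csv(config.mismatch_csv, dtype=str)["record_id"])
    retained, filt = filter_records(records, aor, mismatch)
    if not retained:
        warnings.append("no records retained after filtering; empty bundle")
        return _empty_bundle(manifest, warnings, filter_report=filt)

    presences = read_presences(config.presences_path) if config.presences_path else []
    zone = config.utm_zone
    planar = utm.project_to_planar([[r.lon, r.lat] for r in retained], zone=zone)

    rows = []
    for r, (x, y) in zip(retained, planar):
        sg, tg = assign_groups(r, subgroups)
        rows.append(
            {
                "record_id": r.record_id,
                "date": r.report_date,
                "x": x,
                "y": y,
                "comment": r.comment,
                "subgroup": sg.value if sg else None,
                "temporal": tg.value if tg else None,
            }
        )
    df = pd.DataFrame(rows)

    active = df[df["temporal"] == TemporalGroup.ACTIVE.value]
    attr = (
        _attribute_records(active, presences, config)
        if len(active)
        else pd.DataFrame(columns=["record_id", "label", "same_day_min_distance_m", "date", "response_related"])
    )
    tally = (
        tally_attribution([AttributionLabel(v) for v in attr["label"]], list(attr["date"]))
        if len(attr)
        else None
    )
    removed_ids = set(attr.loc[attr["response_related"], "record_id"]) if len(attr) else set()

    rates_rows, charts, gof_rows, comp_rows = [], [], [], []
    from .records import PRE_SPILL_WINDOW

    for sg_def in subgroups:
        name = sg_def.name.value
        sub = df[df["subgroup"] == name]
        if sub.empty:
            continue
        pre = sub[sub["temporal"] == TemporalGroup.PRE_SPILL.value]
        act = sub[sub["temporal"] == TemporalGroup.ACTIVE.value]
        post = sub[sub["temporal"] == TemporalGroup.POST_RADC.value]
        kept = act[~act["record_id"].isin(removed_ids)]
        try:
            row, chart, gofs, comps = _rate_block(
                name,
                list(pre["date"]),
                list(act["date"]),
                list(post["date"]),
                list(kept["date"]),
                (PRE_SPILL_WINDOW, sg_def.active_window, sg_def.post_radc_window),
                config,
                warnings,
            )
        except ValueError as exc:
            warnings.append(f"rate block failed for {name}: {exc}")
            continue
        rates_rows.append(row)
        charts.append(chart)
        gof_rows.extend(gofs)
        comp_rows.extend(comps)

    summaries, frames = [], []
    pts_all = df[["x", "y"]].to_numpy()
    pts_removed = df[~df["record_id"].isin(removed_ids)][["x", "y"]].to_numpy()
    for variant, pts in (("ALL_RECORDS", pts_all), ("RESPONSE_REMOVED", pts_removed)):
        if len(pts) < 4:
            warnings.append(f"hotspot variant {variant}: too few records, skipped")
            continue
        try:
            summary, frame, _ = _hotspot_variant(pts, config, variant)
        except ValueError as exc:
            warnings.append(f"hotspot variant {variant} failed: {exc}")
            continue
        summaries.append(summary)
        frames.append(frame)

    return ReportBundle(
        filter_report=filt,
        attribution_tally=tally,
        attribution=attr,
        rates_table=pd.DataFrame(rates_rows),
        comparisons=pd.DataFrame(comp_rows),
        gof_table=pd.DataFrame(gof_rows),
        u_chart_table=pd.concat(charts, ignore_index=True) if charts else pd.DataFrame(),
        hotspot_summary=pd.DataFrame(summaries),
        gi_scores=pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(),
        manifest=manifest,
        warnings=warnings,
    )
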