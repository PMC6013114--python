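"""Synthetic-study generator: determinism, moments, detection model."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import LineString

from strandeffort.linkage import nearest_responder_distance
from strandeffort.records import TemporalWindow
from strandeffort.synthetic import (
    ACTIVE_WINDOW,
    DetectionConfig,
    InjectedCluster,
    MortalityConfig,
    ResponderScheduleConfig,
    apply_detection,
    default_configs,
    default_study,
    simulate_responders,
    simulate_strandings,
    truth_report,
)

WINDOW = TemporalWindow("2010-05", "2013-12")  # 44 months
SHORE = LineString([(0.0, 0.0), (120000.0, 0.0)])


def mortality(lam=4.2, clusters=()):
    return MortalityConfig(rates={"A": lam}, shorelines={"A": SHORE}, clusters=clusters)


class TestSimulateStrandings:
    def test_zero_rate_empty(self):
        df = simulate_strandings(mortality(0.0), WINDOW, seed=1)
        assert df.empty

    def test_poisson_moments(self):
        totals = [len(simulate_strandings(mortality(), WINDOW, seed=s)) for s in range(100)]
        expected = 4.2 * 44
        se_mean = np.sqrt(expected / len(totals))
        assert np.mean(totals) == pytest.approx(expected, abs=3 * se_mean)

    def test_locations_on_shoreline_and_dates_in_window(self):
        df = simulate_strandings(mortality(), WINDOW, seed=2)
        assert (df["y"] == 0.0).all()
        assert df["x"].between(0, 120000).all()
        assert all(WINDOW.contains(d) for d in df["date"])

    def test_cluster_adds_alongshore_density(self):
        cl = InjectedCluster("A", (60000.0, 0.0), sigma_m=3000.0, extra_rate=5.0)
        df = simulate_strandings(mortality(1.0, clusters=(cl,)), WINDOW, seed=3)
        clustered = df[df["cluster"] == 0]
        assert len(clustered) > 100  # ~5/month over 44 months
        assert clustered["x"].std() == pytest.approx(3000.0, rel=0.2)
        assert (clustered["y"] == 0.0).all()  # carcasses beach on shore

    def test_deterministic_under_seed(self):
        a = simulate_strandings(mortality(), WINDOW, seed=7)
        b = simulate_strandings(mortality(), WINDOW, seed=7)
        pd.testing.assert_frame_equal(a, b)


def segments(n=24, length=5000.0):
    return tuple(
        (f"s{i:02d}", LineString([(i * length, 0.0), ((i + 1) * length, 0.0)])) for i in range(n)
    )


class TestSimulateResponders:
    def test_zero_fraction_no_presences(self):
        cfg = ResponderScheduleConfig(segments=segments(), fraction_start=0.0, fraction_end=0.0)
        assert simulate_responders(cfg, WINDOW, seed=1) == []

    def test_full_coverage_every_segment_every_day(self):
        cfg = ResponderScheduleConfig(segments=segments(4), fraction_start=1.0, fraction_end=1.0)
        presences = simulate_responders(cfg, TemporalWindow("2011-01", "2011-02"), seed=1)
        assert len(presences) == 4 * (31 + 28)
        per_day = pd.Series([p.date for p in presences]).value_counts()
        assert (per_day == 4).all()

    def test_ramp_decline_is_monotone(self):
        cfg = ResponderScheduleConfig(segments=segments(), fraction_start=1.0, fraction_end=0.1)
        presences = simulate_responders(cfg, WINDOW, seed=1)
        df = pd.DataFrame({"date": [p.date for p in presences]})
        df["month"] = [f"{d.year}-{d.month:02d}" for d in df["date"]]
        df["day"] = df["date"]
        per_day = df.groupby(["month", "day"]).size().groupby("month").mean()
        per_day = per_day.reindex(sorted(per_day.index))
        assert (per_day.diff().dropna() <= 0).all()

    def test_survey_days_per_week_limits_weekdays(self):
        cfg = ResponderScheduleConfig(
            segments=segments(4), fraction_start=1.0, fraction_end=1.0, survey_days_per_week=5
        )
        presences = simulate_responders(cfg, TemporalWindow("2011-03", "2011-03"), seed=1)
        assert all(p.date.weekday() < 5 for p in presences)


class TestApplyDetection:
    def test_certain_responder_zero_public(self):
        """With p_public = 0 and p_responder = 1, the reported set is exactly
        the carcasses with a same-day team within the radius."""
        true_df = simulate_strandings(mortality(), WINDOW, seed=4)
        cfg = ResponderScheduleConfig(segments=segments(), fraction_start=0.3, fraction_end=0.3)
        presences = simulate_responders(cfg, WINDOW, seed=5)
        det = DetectionConfig(p_public=0.0, p_responder=1.0)
        study = apply_detection(true_df, presences, det, seed=6)

        by_date = {}
        for p in presences:
            by_date.setdefault(p.date, []).append(p)
        covered_ids = set()
        for row in true_df.itertuples(index=False):
            d = nearest_responder_distance((row.x, row.y), row.date, by_date.get(row.date, []))
            if d is not None and d <= det.radius_m:
                covered_ids.add(row.carcass_id)
        assert set(study.records["carcass_id"]) == covered_ids
        assert study.truth["was_response_detected"].all()

    def test_equal_probabilities_make_coverage_irrelevant(self):
        """When responders report no better than the public, reporting is
        independent of responder coverage (chi-square on the 2x2 table)."""
        true_df = simulate_strandings(mortality(12.0), WINDOW, seed=7)
        cfg = ResponderScheduleConfig(segments=segments(), fraction_start=0.4, fraction_end=0.4)
        presences = simulate_responders(cfg, WINDOW, seed=8)
        det = DetectionConfig(p_public=0.4, p_responder=0.4)
        study = apply_detection(true_df, presences, det, seed=9)

        by_date = {}
        for p in presences:
            by_date.setdefault(p.date, []).append(p)
        covered, reported = [], []
        reported_ids = set(study.records["carcass_id"])
        for row in true_df.itertuples(index=False):
            d = nearest_responder_distance((row.x, row.y), row.date, by_date.get(row.date, []))
            covered.append(d is not None and d <= det.radius_m)
            reported.append(row.carcass_id in reported_ids)
        table = pd.crosstab(pd.Series(covered), pd.Series(reported))
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_truth_report_consistency(self):
        study = default_study(seed=11)
        rep = truth_report(study)
        assert rep["n_reported"] == len(study.records) == len(study.truth)
        assert rep["n_response_detected"] + rep["n_public"] == rep["n_reported"]
        assert 0.0 < rep["carcass_detection_rate"] < 1.0

    def test_default_study_active_share_near_58_percent(self):
        """The default conditions put the response-attributable share of
        active-window reports near the published headline level."""
        shares = []
        for seed in (1, 2, 3, 4):
            study = default_study(seed)
            merged = study.records.merge(study.truth, on="record_id")
            active = merged[merged["date"].map(ACTIVE_WINDOW.contains)]
            shares.append(active["was_response_detected"].mean())
        assert np.mean(shares) == pytest.approx(0.58, abs=0.10)

    def test_unspecified_comments_exist_among_response_records(self):
        """Some responder-detected records stay textually silent, so only
        the proximity rule can recover them."""
        study = default_study(seed=13)
        merged = study.records.merge(study.truth, on="record_id")
        resp = merged[merged["was_response_detected"]]
        assert (resp["comment"].str.strip() == "").any() or (
            ~resp["comment"].str.contains("SCAT|crew|Task Force|response", regex=True)
        ).any()

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(p_public=0.5, p_responder=0.2).validate()
        with pytest.raises(ValueError):
            DetectionConfig(p_public=1.5).validate()


class TestRecoveryInvariants:
    def test_attribution_recovery_at_large_n(self):
        """With >= 2,000 reports, the linkage estimate of the
        response-related fraction recovers the detection-model truth
        within two binomial standard errors."""
        from strandeffort.pipeline import StudyConfig, _attribute_records

        mort, sched, det = default_configs()
        mort = MortalityConfig(
            rates={k: v * 45 for k, v in mort.rates.items()}, shorelines=mort.shorelines
        )
        true_df = simulate_strandings(mort, ACTIVE_WINDOW, seed=21)
        presences = simulate_responders(sched, ACTIVE_WINDOW, seed=22)
        study = apply_detection(true_df, presences, det, seed=23)
        assert len(study.records) >= 2000

        attr = _attribute_records(study.records, study.presences, StudyConfig())
        est = attr["response_related"].mean()
        truth = study.truth["was_response_detected"].mean()
        se = np.sqrt(truth * (1 - truth) / len(attr))
        assert abs(est - truth) <= 2 * se
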