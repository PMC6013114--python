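"""Monthly stranding-rate analytics.

Monthly stranding counts are modelled as homogeneous Poisson within each
(geographic subgroup, temporal group) cell.  The module provides:

* zero-filled monthly count series per subgroup/window;
* staged U-charts (counts-per-unit control charts with a one-month
  subgroup size): centre line at the stage mean rate ū and control
  limits ū ± 3·sqrt(ū), each stage computed independently;
* a Pearson chi-square goodness-of-fit test against the Poisson
  distribution with the mean estimated from the series;
* an exact two-sample comparison of Poisson rates.  Conditional on the
  total count N = x1 + x2, x1 ~ Binomial(N, T1/(T1+T2)) under
  H0: lambda1 = lambda2; the two-sided p sums all outcomes whose null
  probability does not exceed the observed one (minimum-likelihood
  two-sided definition).  The 95% CI on the rate ratio is the
  Clopper-Pearson interval for the conditional proportion transformed by
  r = p/(1-p) * T2/T1;
* the Bonferroni family-wise alpha adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
import datetime as _dt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import Subgroup, TemporalWindow, months_in_window

__all__ = [
    "MonthlyCountSeries",
    "UChartStage",
    "PoissonGOFResult",
    "RateComparison",
    "monthly_series",
    "monthly_rate",
    "u_chart",
    "poisson_gof",
    "compare_rates",
    "bonferroni_alpha",
]


@dataclass
class MonthlyCountSeries:
    """Zero-filled per-calendar-month counts for one subgroup and window."""

    subgroup: Subgroup | str | None
    window: TemporalWindow
    counts: np.ndarray  # int, length == months_in_window(window)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != months_in_window(self.window):
            raise ValueError(
                f"series length {len(self.counts)} != window months {months_in_window(self.window)}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def months(self) -> list[str]:
        return self.window.month_labels()

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def monthly_series(
    dates: Sequence[_dt.date],
    window: TemporalWindow,
    subgroup: Subgroup | str | None = None,
) -> MonthlyCountSeries:
    """Bin record dates into zero-filled monthly counts over ``window``.

    Dates outside the window raise: callers are expected to have grouped
    records first, so a stray date signals a bookkeeping error.
    """
    labels = window.month_labels()
    index = {m: i for i, m in enumerate(labels)}
    counts = np.zeros(len(labels), dtype=int)
    for d in dates:
        key = f"{d.year:04d}-{d.month:02d}"
        if key not in index:
            raise ValueError(f"date {d} outside window {window.start}..{window.end}")
        counts[index[key]] += 1
    return MonthlyCountSeries(subgroup=subgroup, window=window, counts=counts)


def monthly_rate(series: MonthlyCountSeries) -> float:
    """Mean strandings per month: total count over inclusive month base."""
    return series.total / len(series.counts)


@dataclass(frozen=True)
class UChartStage:
    """One stage of a staged U-chart (subgroup size = one month)."""

    label: str
    start_index: int
    end_index: int  # exclusive
    u_bar: float
    ucl: float
    lcl: float


def u_chart(
    series: MonthlyCountSeries,
    stage_bounds: Sequence[tuple[str, int, int]],
) -> list[UChartStage]:
    """Compute staged U-chart centre lines and 3-sigma control limits.

    ``stage_bounds`` is a list of (label, start, end) index ranges that
    must partition the series in order.  Each stage's mean and limits are
    computed from that stage's months only.
    """
    n = len(series.counts)
    expected = 0
    for _, s, e in stage_bounds:
        if s != expected or e <= s:
            raise ValueError(f"stage bounds must partition the series; got {stage_bounds}")
        expected = e
    if expected != n:
        raise ValueError(f"stage bounds cover {expected} of {n} months")

    stages = []
    for label, s, e in stage_bounds:
        u_bar = float(series.counts[s:e].mean())
        sd = np.sqrt(u_bar)  # Poisson counts per one-month unit
        stages.append(
            UChartStage(
                label=label,
                start_index=s,
                end_index=e,
                u_bar=u_bar,
                ucl=u_bar + 3.0 * sd,
                lcl=max(0.0, u_bar - 3.0 * sd),
            )
        )
    return stages


def u_chart_frame(series: MonthlyCountSeries, stages: Sequence[UChartStage]) -> pd.DataFrame:
    """Tidy (month, count, stage, u_bar, ucl, lcl) frame for plotting/export."""
    rows = []
    months = series.months
    for st in stages:
        for i in range(st.start_index, st.end_index):
            rows.append(
                {
                    "month": months[i],
                    "count": int(series.counts[i]),
                    "stage": st.label,
                    "u_bar": st.u_bar,
                    "ucl": st.ucl,
                    "lcl": st.lcl,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PoissonGOFResult:
    chi_square: float
    df: int
    p_value: float
    bin_edges: tuple[int, ...]  # observed-value classes 0..m-1 plus tail >= m
    cochran_ok: bool


def poisson_gof(series: MonthlyCountSeries | np.ndarray, min_months: int = 10) -> PoissonGOFResult:
    """Pearson chi-square goodness of fit of monthly counts to a Poisson law.

    Observations are classed by their count value (0, 1, 2, ..., m-1,
    and a merged right tail >= m).  Expected class frequencies come from
    Poisson(mean of the series).  The tail is merged leftward until every
    expected frequency is >= 1 and at least 80% of classes have expected
    frequency >= 5 (Cochran's rule); if no m satisfies Cochran, the
    largest m with all expectations >= 1 is used and flagged.  One degree
    of freedom is lost to the estimated mean: df = classes - 2.

    Raises for series shorter than ``min_months`` months — with so little
    data an exact multinomial method should be used instead.
    """
    counts = series.counts if isinstance(series, MonthlyCountSeries) else np.asarray(series, int)
    n = len(counts)
    if n < min_months:
        raise ValueError(
            f"series has {n} < {min_months} months; use an exact goodness-of-fit method"
        )
    mean = counts.mean()
    if mean == 0:
        raise ValueError("all-zero series: Poisson fit is degenerate")

    max_m = int(counts.max()) + 1

    def expected_bins(m: int) -> np.ndarray:
        body = stats.poisson.pmf(np.arange(m), mean) * n
        tail = stats.poisson.sf(m - 1, mean) * n
        return np.append(body, tail)

    chosen = None
    cochran_ok = True
    for m in range(max_m, 1, -1):
        exp = expected_bins(m)
        if exp.min() >= 1.0 and (exp >= 5.0).mean() >= 0.8:
            chosen = m
            break
    if chosen is None:
        cochran_ok = False
        for m in range(max_m, 1, -1):
            if expected_bins(m).min() >= 1.0:
                chosen = m
                break
    if chosen is None or chosen + 1 < 3:
        raise ValueError("too few usable classes for a chi-square fit")

    m = chosen
    exp = expected_bins(m)
    obs = np.append(np.bincount(np.minimum(counts, m), minlength=m + 1)[:m], (counts >= m).sum())
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = (m + 1) - 2
    p = float(stats.chi2.sf(chi2, df))
    return PoissonGOFResult(
        chi_square=chi2, df=df, p_value=p, bin_edges=tuple(range(m + 1)), cochran_ok=cochran_ok
    )


@dataclass(frozen=True)
class RateComparison:
    """Exact two-sample Poisson rate comparison (H0: true rate ratio = 1)."""

    x1: int
    x2: int
    T1: float
    T2: float
    rate1: float
    rate2: float
    sample_rate_ratio: float
    p_value: float
    ci95_low: float
    ci95_high: float


def compare_rates(x1: int, T1: float, x2: int, T2: float) -> RateComparison:
    """Exact conditional-binomial comparison of two Poisson rates.

    Under H0 the first count given the total is Binomial(x1+x2,
    T1/(T1+T2)); the two-sided p-value sums the probabilities of all
    outcomes no more likely than the observed one.  The 95% CI on the
    rate ratio transforms the Clopper-Pearson interval for the
    conditional proportion.  Matches the classical exact rate-ratio test
    (R's ``poisson.test``) to numerical precision.
    """
    if x1 < 0 or x2 < 0 or int(x1) != x1 or int(x2) != x2:
        raise ValueError("event counts must be non-negative integers")
    if T1 <= 0 or T2 <= 0:
        raise ValueError("time bases must be positive")
    x1, x2 = int(x1), int(x2)
    N = x1 + x2
    if N == 0:
        raise ValueError("no events in either arm: rate ratio undefined")

    p0 = T1 / (T1 + T2)
    pmf = stats.binom.pmf(np.arange(N + 1), N, p0)
    # relative tolerance guards against ties broken by floating-point noise
    p_value = float(min(1.0, pmf[pmf <= pmf[x1] * (1 + 1e-7)].sum()))

    lo_p = 0.0 if x1 == 0 else float(stats.beta.ppf(0.025, x1, N - x1 + 1))
    hi_p = 1.0 if x1 == N else float(stats.beta.ppf(0.975, x1 + 1, N - x1))

    def ratio_from_prop(q: float) -> float:
        if q >= 1.0:
            return float("inf")
        return (q / (1.0 - q)) * (T2 / T1)

    rate1 = x1 / T1
    rate2 = x2 / T2
    return RateComparison(
        x1=x1,
        x2=x2,
        T1=T1,
        T2=T2,
        rate1=rate1,
        rate2=rate2,
        sample_rate_ratio=(rate1 / rate2) if x2 > 0 else float("inf"),
        p_value=p_value,
        ci95_low=ratio_from_prop(lo_p),
        ci95_high=ratio_from_prop(hi_p),
    )


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise alpha adjustment: alpha' = alpha / m for m hypotheses."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m
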