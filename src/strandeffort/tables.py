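"""Published summary tables from the Deepwater Horizon stranding study area.

These are the printed surveillance summaries for bottlenose dolphin
strandings in the northern Gulf of Mexico (1996-2015): record counts per
geographic subgroup and response period, monthly rates, the
reporting-party tally during Active Response, and the published exact
rate-comparison results.  They serve as worked-example inputs and as
cross-checks for the analytics in :mod:`strandeffort.rates` — the raw
record-level data behind them are not bundled.

Month bases: the published Post-RADC and Active rates divide by a base
one month larger than the printed date ranges imply in several cells
(e.g. Jan 2014 - Apr 2015 is 16 inclusive months, yet 29 strandings at a
printed 1.71/month implies 17).  ``RECONCILED_MONTHS`` records the bases
that reproduce the printed rates; the honest inclusive counts live in
``records.DEFAULT_WINDOWS``.  Where responder-removed or five-year
pre-spill raw counts were not published, they are reconstructed as
round(printed rate × base).
"""

from __future__ import annotations

import pandas as pd

from .records import Subgroup

__all__ = [
    "SUBGROUP_COUNTS",
    "MONTHLY_RATES",
    "ATTRIBUTION_TALLY_BY_YEAR",
    "RECONCILED_MONTHS",
    "reconstructed_count",
    "rate_comparison_inputs_active_vs_post",
    "rate_comparison_inputs_active_vs_prespill5",
    "PUBLISHED_ACTIVE_VS_POST",
    "PUBLISHED_ACTIVE_VS_PRESPILL5",
    "flag_inconsistent_ratios",
]

#: Stranding record counts by subgroup and period (Pre-Spill, Active, Post-RADC).
SUBGROUP_COUNTS: dict[Subgroup, dict[str, int]] = {
    Subgroup.LA_PUBLIC_PRIVATE: {"PRE_SPILL": 123, "ACTIVE": 149, "POST_RADC": 22},
    Subgroup.LA_REMOTE: {"PRE_SPILL": 109, "ACTIVE": 185, "POST_RADC": 29},
    Subgroup.MS_BARRIER_ISLANDS: {"PRE_SPILL": 109, "ACTIVE": 75, "POST_RADC": 11},
    Subgroup.AL_MOBILE: {"PRE_SPILL": 82, "ACTIVE": 56, "POST_RADC": 14},
    Subgroup.AL_BSNWR_ORANGE_BEACH: {"PRE_SPILL": 51, "ACTIVE": 23, "POST_RADC": 21},
}

#: Published monthly stranding rates (per month): Pre-Spill (full), Active
#: (all records), Active with responder-influenced records removed, Post-RADC,
#: plus the five-year Pre-Spill (May 2005 - Apr 2010) rate.
MONTHLY_RATES: dict[Subgroup, dict[str, float]] = {
    Subgroup.AL_BSNWR_ORANGE_BEACH: {
        "PRE_SPILL": 0.30, "ACTIVE_ALL": 0.62, "ACTIVE_REMOVED": 0.43, "POST_RADC": 0.88,
        "PRE_SPILL_5YR": 0.17,
    },
    Subgroup.AL_MOBILE: {
        "PRE_SPILL": 0.48, "ACTIVE_ALL": 1.51, "ACTIVE_REMOVED": 0.76, "POST_RADC": 0.58,
        "PRE_SPILL_5YR": 0.37,
    },
    Subgroup.MS_BARRIER_ISLANDS: {
        "PRE_SPILL": 0.63, "ACTIVE_ALL": 2.08, "ACTIVE_REMOVED": 0.78, "POST_RADC": 0.44,
        "PRE_SPILL_5YR": 0.25,
    },
    Subgroup.LA_PUBLIC_PRIVATE: {
        "PRE_SPILL": 0.72, "ACTIVE_ALL": 3.17, "ACTIVE_REMOVED": 1.17, "POST_RADC": 1.57,
        "PRE_SPILL_5YR": 0.32,
    },
    Subgroup.LA_REMOTE: {
        "PRE_SPILL": 0.63, "ACTIVE_ALL": 4.20, "ACTIVE_REMOVED": 1.82, "POST_RADC": 1.71,
        "PRE_SPILL_5YR": 0.42,
    },
}

#: Reporting-party tally of the 488 Active Response records by calendar year.
#: Rows: comment says not response related / comment says response related /
#: responder within 161 m on the report day / unknown relation.
ATTRIBUTION_TALLY_BY_YEAR: pd.DataFrame = pd.DataFrame(
    {
        2010: [1, 27, 24, 22],
        2011: [22, 79, 59, 39],
        2012: [8, 22, 23, 41],
        2013: [15, 25, 16, 47],
        2014: [2, 6, 0, 10],
    },
    index=["NOT_RESPONSE", "RESPONSE_COMMENT", "PROXIMITY_161M", "UNKNOWN"],
)

#: Month bases that reconcile the printed rates with the printed/derived
#: counts.  ACTIVE bases equal the inclusive month counts of the printed
#: Active windows; POST_RADC bases are one month larger than the printed
#: windows imply; the five-year Pre-Spill base is 60.
RECONCILED_MONTHS: dict[Subgroup, dict[str, int]] = {
    Subgroup.LA_PUBLIC_PRIVATE: {"ACTIVE": 47, "POST_RADC": 14, "PRE_SPILL_5YR": 60},
    Subgroup.LA_REMOTE: {"ACTIVE": 44, "POST_RADC": 17, "PRE_SPILL_5YR": 60},
    Subgroup.MS_BARRIER_ISLANDS: {"ACTIVE": 36, "POST_RADC": 25, "PRE_SPILL_5YR": 60},
    Subgroup.AL_MOBILE: {"ACTIVE": 37, "POST_RADC": 24, "PRE_SPILL_5YR": 60},
    Subgroup.AL_BSNWR_ORANGE_BEACH: {"ACTIVE": 37, "POST_RADC": 24, "PRE_SPILL_5YR": 60},
}


def reconstructed_count(rate: float, months: int) -> int:
    """Recover an unpublished raw count from a printed rate and month base."""
    return round(rate * months)


def rate_comparison_inputs_active_vs_post(subgroup: Subgroup) -> tuple[int, int, int, int]:
    """(x1, T1, x2, T2) for responder-removed Active vs Post-RADC.

    x1 is reconstructed from the printed responder-removed rate; x2 is
    the printed Post-RADC count; bases are the reconciled ones.
    """
    months = RECONCILED_MONTHS[subgroup]
    x1 = reconstructed_count(MONTHLY_RATES[subgroup]["ACTIVE_REMOVED"], months["ACTIVE"])
    x2 = SUBGROUP_COUNTS[subgroup]["POST_RADC"]
    return x1, months["ACTIVE"], x2, months["POST_RADC"]


def rate_comparison_inputs_active_vs_prespill5(subgroup: Subgroup) -> tuple[int, int, int, int]:
    """(x1, T1, x2, T2) for responder-removed Active vs five-year Pre-Spill."""
    months = RECONCILED_MONTHS[subgroup]
    x1 = reconstructed_count(MONTHLY_RATES[subgroup]["ACTIVE_REMOVED"], months["ACTIVE"])
    x2 = reconstructed_count(MONTHLY_RATES[subgroup]["PRE_SPILL_5YR"], months["PRE_SPILL_5YR"])
    return x1, months["ACTIVE"], x2, months["PRE_SPILL_5YR"]


#: Published exact-rate-comparison results, responder-removed Active vs
#: Post-RADC: (p, 95% LCI, 95% UCI, sample rate ratio).
PUBLISHED_ACTIVE_VS_POST: dict[Subgroup, tuple[float, float, float, float]] = {
    Subgroup.AL_BSNWR_ORANGE_BEACH: (0.042, 0.24, 0.99, 0.49),
    Subgroup.AL_MOBILE: (0.528, 0.66, 2.67, 1.30),
    Subgroup.MS_BARRIER_ISLANDS: (0.142, 0.85, 3.93, 1.77),
    Subgroup.LA_PUBLIC_PRIVATE: (0.277, 0.45, 1.28, 0.74),
    Subgroup.LA_REMOTE: (0.831, 0.69, 1.69, 1.07),
}

#: Published responder-removed Active vs five-year Pre-Spill results:
#: (pre rate, active rate, p, 95% LCI, 95% UCI, ratio).  The Bon Secour
#: and MS Barrier Islands ratios are not reconcilable with their own
#: printed rates (0.43/0.17 = 2.53, 0.77/0.25 = 3.08); see
#: :func:`flag_inconsistent_ratios`.
PUBLISHED_ACTIVE_VS_PRESPILL5: dict[Subgroup, tuple[float, float, float, float, float, float]] = {
    Subgroup.AL_BSNWR_ORANGE_BEACH: (0.17, 0.43, 0.140, 0.80, 3.76, 1.73),
    Subgroup.AL_MOBILE: (0.37, 0.76, 0.013, 1.14, 3.79, 2.06),
    Subgroup.MS_BARRIER_ISLANDS: (0.25, 0.77, 0.0099, 2.20, 10.77, 4.67),
}


def flag_inconsistent_ratios(tolerance: float = 0.05) -> dict[Subgroup, dict[str, float]]:
    """Find published ratio rows inconsistent with their own printed rates.

    Returns, per flagged subgroup, the printed ratio and the ratio
    recomputed from the printed rates.  A row is flagged when the two
    disagree by more than ``tolerance`` (relative).
    """
    flags: dict[Subgroup, dict[str, float]] = {}
    for sg, (pre, active, _p, _lo, _hi, ratio) in PUBLISHED_ACTIVE_VS_PRESPILL5.items():
        recomputed = active / pre
        if abs(recomputed - ratio) / ratio > tolerance:
            flags[sg] = {"printed_ratio": ratio, "ratio_from_printed_rates": recomputed}
    return flags
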