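# Methods

## The problem and the model

Stranding reports are an observation process layered on a mortality
process: a dolphin carcass becomes a Level A record only if somebody
finds it and phones it in.  The package treats the monthly count of
reports in a (geographic subgroup, response period) cell as homogeneous
Poisson, and asks whether the elevated rate during an oil-spill clean-up
persists once records attributable to the response workforce are
removed.  Two complementary analyses are implemented: a temporal one
(exact comparison of monthly Poisson rates between periods) and a
spatial one (change in Getis-Ord Gi* hotspot area when attributed
records are dropped).

## Record filtering

Filtering is a four-stage pipeline with an audited tally per stage:
(1) records with missing or unparseable coordinates or dates, or
coordinates outside [−180, 180] × [−90, 90], are dropped; (2) only dead
bottlenose dolphins are kept (live strandings and other species removed
in one stage, as the upstream curation did); (3) points must fall
inside the area-of-response polygon (boundary inclusive); (4) records
on a supplied coordinate/description mismatch list are dropped — that
judgement is inherently manual (e.g. a point plotting offshore while
the text names a beach), so the package takes it as an input rather
than re-deriving it.  Coordinate parsing accepts decimal degrees,
degrees decimal-minutes and degrees-minutes-seconds with hemisphere
letters; minutes or seconds ≥ 60, extra numeric fields, or
contradictory signs are parse failures returned as values (`None`) so
the filter can count them.  Slash dates are read strictly as US
m/d/yyyy; a date readable only day-first is rejected rather than
guessed.

## Temporal windows and month bases

Calendar-month windows are inclusive of both endpoint months.  The
Pre-Spill window (Jan 1996 – Apr 2010) is shared by all subgroups; the
Active Response → Post-RADC transition varies by subgroup as removal
actions were declared complete.  The published post-period rates divide
by a base one month larger than the printed ranges imply in several
cells (e.g. Jan 2014 – Apr 2015 is 16 inclusive months, but 29
strandings at the printed 1.71/month requires 17).  `months_in_window`
always returns the honest inclusive count; the bases that reconcile the
printed rates are recorded separately (`tables.RECONCILED_MONTHS`) and
used, explicitly, only when reproducing published rows.  Where raw
counts behind a printed rate were not published (responder-removed and
five-year pre-spill columns), they are reconstructed as round(rate ×
base); with those inputs every arithmetically consistent published
comparison row reproduces exactly, which validates the reconstruction.

## Responder attribution

Each clean-up-period record receives exactly one label with precedence
comment-positive > comment-negative > proximity > unknown: the
responder activity databases were only consulted for records whose
comments named no reporting party, so text evidence always wins.  The
comment lexicon is a configurable pair of case-insensitive regex sets;
the default is conservative (explicit response-organisation phrases
such as "SCAT team", "Task Force", "BP work crew") and is logged in
every run manifest.  One subtlety: a bare "oil spill response"
substring also occurs inside negations ("not related to the oil spill
response"), so the default response patterns anchor that phrase to an
agentive verb ("found/reported by …").  Proximity uses the minimum
perpendicular point-to-polyline distance to any survey segment present
on the *same calendar date*, compared inclusively against 161 m
(1/10 mile); there is no ±1-day window.  Enlarging the radius can only
move records from unknown to proximity-attributed, a monotonicity the
tests check.

## Exact comparison of Poisson rates

For counts x₁, x₂ over exposure bases T₁, T₂, conditioning on
N = x₁ + x₂ gives x₁ ~ Binomial(N, T₁/(T₁+T₂)) under H₀: λ₁ = λ₂.  The
two-sided p-value is the minimum-likelihood definition — the sum of
probabilities of all outcomes no more probable than the observed one —
with a 1 + 1e-7 relative guard on the tie comparison so floating-point
noise cannot split exact ties (the behaviour of the classical reference
implementation).  The 95% CI on the rate ratio is the Clopper–Pearson
interval for the conditional proportion mapped through
r = p/(1−p) · T₂/T₁.  The implementation is validated against a
brute-force enumeration oracle in exact rational arithmetic (agreement
to 1e-12 for all N ≤ 200 scanned) and is conservative by construction:
simulated type-I error at α = 0.05 with ~30 events per arm is about
0.037.  Degenerate input x₁ = x₂ = 0 raises.  Five subgroup hypotheses
form a family; the Bonferroni-adjusted threshold α′ = 0.05/5 = 0.01 is
used when declaring significance.

## Goodness of fit and U-charts

The Pearson χ² fit to the Poisson law classes months by their count
value (0, 1, …, m−1, tail ≥ m), with expectations from Poisson(sample
mean).  The named test leaves the binning open, so a rule had to be
fixed: the tail is merged leftward until every expected class frequency
is ≥ 1 and at least 80% are ≥ 5 (Cochran's criterion); if no m
satisfies Cochran the largest m with all expectations ≥ 1 is used and
flagged.  One degree of freedom is charged for the estimated mean
(df = classes − 2).  Series shorter than 10 months raise with advice to
use exact methods.  Under a simulated null (Poisson(1.0), 60 months)
the empirical rejection rate at α = 0.05 is ≈ 0.048.  Because the
binning is a package choice, published GOF p-values are treated as
qualitative (fit / no fit), not as exact targets.

U-charts use a one-month subgroup size: centre line ū (the stage's mean
monthly rate, identical to `monthly_rate` of the stage sub-series) and
limits ū ± 3√ū clipped at zero, each stage (Pre-Spill / Active /
Post-RADC) computed from its own months only.  No run rules beyond the
3σ lines are applied.

## Spatial pipeline

**Projection.** Coordinates are projected to UTM (zone 15 N by default)
with an in-package transverse-Mercator implementation (Krüger series in
the third flattening to n⁴; errors ≪ 1 mm inside a zone, verified
against an independent series formulation and a numerically integrated
meridian arc).  Synthetic planar inputs bypass projection.

**Aggregation.** Integrate/Collect-style snapping is order-dependent in
the GIS tools it emulates and undocumented there; here it is made
deterministic: points are processed in ascending index order and each
joins the cluster of the first earlier point within the tolerance
(25 km for basin-wide runs), clusters sitting at the weighted centroid
of their members.  Total record count is conserved.  Exact replication
of a GIS run is declared out of reach; real-data event fields are
therefore approximate.

**Scale selection.** Incremental spatial autocorrelation computes global
Moran's I with binary distance-band weights over growing bands
(default: start at the smallest distance giving every event a
neighbour, step = start/2, 10 bands).  Expectation −1/(n−1) and the
randomization-null variance use the standard formulas (checked against
permutation nulls).  The peak is the smallest band whose Z is both a
local maximum and a running maximum; with a monotone profile the last
band is used and flagged.  Ties break to the smaller distance.

**Gi\*.** Self-weight wᵢᵢ = 1 (the starred statistic), zone-of-
indifference kernel w(d) = 1 for d ≤ d₀, d₀/d beyond, with d₀ the ISA
peak.  Two degenerate cases are defined as score 0 and flagged rather
than NaN: a constant field (S = 0) and a saturated neighbourhood (all
weights equal, where both the numerator and the variance bracket vanish
identically).  Note the per-event numerators do not generally sum to
zero: their total is Σⱼ cⱼ(xⱼ − x̄) with cⱼ the weight column sums,
vanishing only when the cⱼ are equal (e.g. regular configurations);
the tests check the correct identity.

**Surface and area.** Z-scores are interpolated by inverse distance
weighting (power 2; exact at event cells), on 2 km cells for basin-wide
runs and 500 m cells for subgroup-scale runs; the raster is clipped to
the union of ISA-peak-radius buffers around events, and the significant
area is (cells with Z > 1.96) × cell². Areas are always reported with
their cell size, since the number depends on it; raw |Z| > 1.96 is used
with no multiple-testing correction, matching the hotspot-class maps
this emulates.  Published areas (311 → 150.8 km², a 48% drop) depend on
unpublished raster parameters and snapping order, so the package
targets the qualitative result — a ≥ 30% shrink when attributed records
are removed — which the synthetic recovery test demonstrates.

## Synthetic studies

The generator emulates what the pipeline assumes, with known truth:

* **Mortality**: true carcass arrivals are monthly Poisson per subgroup
  (default 4.2/month on a 120 km remote shoreline — the published
  pre-spill reported rate of ~0.63/month divided by the default public
  reporting probability 0.15), beached arc-length-uniform along the
  shoreline polyline.  Injected clusters add Poisson intensity spread
  along-shore (Gaussian in arc length) around a centre; there is no
  drift model — drift is folded into the spatial distribution, since
  only beached records exist upstream.
* **Responders**: daily presences on 5 km shoreline segments, with the
  fraction of segments surveyed ramping linearly across the clean-up
  window (default 0.35 → 0.02, emulating the workforce drawdown from
  tens of thousands to roughly a thousand responders), optional
  always-surveyed segments, and a survey-days-per-week cap.
* **Detection**: a carcass with a same-day team within 161 m is
  reported with p_responder = 0.95 (party: responder), otherwise with
  the public baseline p_public = 0.15 (party: public).  Responder
  reports carry a response-naming comment with probability 0.57, else a
  silent comment that only the proximity rule can recover; public
  reports name a non-response party with probability 0.23 (both rates
  follow the published tally's comment/proximity split).  Under these
  defaults ~58% of clean-up-window reports are response-attributable,
  the published headline share.
* **Seeding**: one root seed spawns independent named streams per
  sub-generator, so stages are reproducible in isolation.

Because attribution recomputes the same same-day distances the
detection model used, the estimator of the response-related fraction is
exactly consistent with the generator truth; recovery tests at ≥ 2,000
reports confirm agreement within two binomial standard errors.  What
the generator does *not* emulate — comment free-text diversity beyond
the template mixes, geocoding error, drifting carcasses, day-to-day
correlation in survey coverage, non-homogeneous seasonal mortality —
bounds what passing tests say about real data: they validate the
machinery and its statistical calibration, not the field realism of any
particular parameter value.

## Problem sizes and determinism

Default analysis runs use the study's own constants (161 m radius,
25 km aggregation, Z > 1.96, α′ = 0.01).  Simulation-based checks use
10,000 replicates for test calibration and permutation nulls, 60-month
series for GOF calibration, and single-seed default studies (~500 true
carcasses; ~2,000+ reports for large-n recovery checks) — sizes chosen
so the whole suite gives stable Monte-Carlo verdicts at seeded
reproducibility.  All pipeline outputs are deterministic given config
and seed; floating-point text output is rendered at fixed precision.

## Known limitations

* Real record-level data are not bundled; published-table reproductions
  rest on reconstructed counts (exact where the tables are internally
  consistent; two published ratio rows are not and are flagged and
  excluded rather than reverse-engineered).
* The aggregation step cannot replicate a specific GIS run's snapping
  order; ISA peak distances and absolute hotspot areas on real data are
  approximate by design.
* The GOF binning rule is a package choice among defensible options;
  p-values near a decision boundary can differ from other
  implementations' binnings.
* Hotspot significance is per-event with no field-wise multiplicity
  control, as in the maps it reproduces.
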