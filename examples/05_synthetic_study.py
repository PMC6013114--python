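"""Simulate a study with known ground truth and recover it.

The default synthetic study emulates a remote shoreline: true carcass
arrivals at 4.2/month, a public reporting probability of 0.15, and a
responder survey schedule over the 44-month clean-up window with
near-certain reporting inside 161 m.  The attribution pipeline is then
scored against the generator's truth labels.
"""

import strandeffort.synthetic as syn
from strandeffort.pipeline import StudyConfig, _attribute_records

study = syn.default_study(seed=1)
report = syn.truth_report(study)
print(f"true strandings: {report['n_true_strandings']}, "
      f"reported: {report['n_reported']} "
      f"(detection rate {report['carcass_detection_rate']:.2f})")

active = study.records[study.records["date"].map(syn.ACTIVE_WINDOW.contains)]
merged = active.merge(study.truth, on="record_id")
truth_frac = merged["was_response_detected"].mean()

attr = _attribute_records(active, study.presences, StudyConfig())
est_frac = attr["response_related"].mean()
print(f"active-window reports: {len(active)}")
print(f"true response-detected fraction: {truth_frac:.2f}")
print(f"estimated response-related fraction: {est_frac:.2f}")
print(attr["label"].value_counts().to_string())

# The estimate combines comment evidence with the 161 m same-day rule;
# under the default conditions (~58% of clean-up-period reports made by
# responders) it recovers the generator's truth because silent responder
# reports are exactly the records with a same-day team within radius.
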