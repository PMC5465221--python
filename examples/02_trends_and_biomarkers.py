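"""Identify consistent biomarkers and classify dose/time responsiveness.

Re-runs the simulation of example 01, then: overlaps DEM sets across
conditions, keeps miRNAs called DEM in at least half of the 12 conditions
(a cross-condition replication filter), and classifies each candidate's
fold-change profile as time-responsive (strictly monotone along the four
timepoints in >= 2 doses) and/or dose-responsive (monotone along the three
doses in >= 2 timepoints).
"""

import toxmir as tm
from toxmir import simulate, trends

design = tm.generate_design()
conditions = tm.treated_conditions(design)
ids = simulate.make_mirna_ids(664)
truths = simulate.plant_effects(ids, n_planted=50, seed=2, conditions=conditions)
counts, _ = tm.generate_counts(design, tm.SimulationParams(seed=1), truths)
dems = tm.call_dems(counts, design)

sets = trends.dem_sets(dems)
print(f"DEM union {len(sets.global_union)}, "
      f"intersection across all 12 conditions {len(sets.global_intersection)}")

consistent = trends.common_dems(dems, min_conditions=6)
planted = {t.mirna_id for t in truths}
hits = set(consistent["mirna_id"])
print(f"consistent DEMs (>= 6 of 12 conditions): {len(consistent)}; "
      f"sensitivity {len(hits & planted) / 50:.2f}, "
      f"false discoveries {len(hits - planted)}")

calls = trends.trend_calls(dems, mirnas=list(consistent["mirna_id"]))
both = calls[calls["time_responsive"] & calls["dose_responsive"]]
print(f"time-responsive {calls['time_responsive'].sum()}, "
      f"dose-responsive {calls['dose_responsive'].sum()}, both {len(both)}")

biomarker = truths[0].mirna_id
top = consistent.iloc[0]
print(f"top-ranked candidate: {top['mirna_id']} "
      f"(planted biomarker = {biomarker}), DEM in {top['n_conditions_dem']}/12 "
      f"conditions, mean |log2FC| {top['mean_abs_log2fc']:.2f}, "
      f"sign-consistent: {top['sign_consistent']}")
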