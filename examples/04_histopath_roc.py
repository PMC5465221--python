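"""Relate miRNA expression profiles to histopathological findings by ROC.

Builds a condition x feature presence table in which "single cell
necrosis" is driven by a planted miRNA's |log2FC| through a logistic link,
drops the low-dose early timepoints (no findings there), and scores each
(miRNA, feature) pair by the Mann-Whitney AUC of the |log2FC| confidence
scores against the feature labels.
"""

import pandas as pd

from toxmir import histopath, simulate

conds = [(d, t) for d in ("low", "middle", "high") for t in (3, 7, 14, 28)]
biomarker = simulate.biomarker_effect("rno-miR-s0001")
bystander = simulate.transient_effect("rno-miR-s0002", peak_log2fc=1.5)

histo = simulate.generate_histopath(
    [biomarker, bystander],
    drivers={"single cell necrosis": "rno-miR-s0001"},
    link_strength=8.0,
    lfc_threshold=3.0,
    conditions=conds,
    seed=11,
)
print("histopathology table (1 = feature present):")
print(histo["single cell necrosis"].to_string())

fc = pd.DataFrame(
    {c: [2.0 ** biomarker.log2fc[c], 2.0 ** bystander.log2fc.get(c, 0.0)] for c in conds},
    index=["rno-miR-s0001", "rno-miR-s0002"],
)
fc.columns = pd.MultiIndex.from_tuples(conds, names=["dose_level", "timepoint_days"])

out = histopath.biomarker_feature_auc(fc, histo)
necrosis = out[out["feature"] == "single cell necrosis"].set_index("mirna_id")
print(f"\nAUC over the {int(necrosis['n_conditions'].iloc[0])} retained conditions "
      "(low-dose 3/7/14-day points excluded):")
for mid, row in necrosis.iterrows():
    print(f"  {mid}: AUC = {row['auc']:.2f} "
          f"({row['n_pos']} positive / {row['n_neg']} negative conditions)")
print("the driving miRNA separates feature-positive conditions perfectly; "
      "the early transient responder is anti-correlated with this late-onset "
      "feature (AUC near 0; 0.5 would be chance)")
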