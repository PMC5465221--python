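"""Expression-vs-histopathology ROC analysis.

Fold changes per treated condition are turned into a confidence matrix
(continuous score = |log2FC|, with a binary companion thresholded at
1.5-fold), conditions without histopathological findings in the source
study (low dose at 3, 7 and 14 days) are excluded, and each
(miRNA, feature) pair is scored by the area under the ROC curve — the
Mann-Whitney concordance between feature-positive and feature-negative
conditions.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

#: conditions removed by default: no histopathological changes observed there
DEFAULT_EXCLUSIONS: tuple[tuple[str, int], ...] = (
    ("low", 3),
    ("low", 7),
    ("low", 14),
)


def build_confidence_matrix(
    fc_table: pd.DataFrame,
    fc_cutoff: float = 1.5,
    exclude: Sequence[tuple[str, int]] = DEFAULT_EXCLUSIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score and binary matrices from a miRNA x condition fold-change table.

    ``fc_table`` columns are (dose_level, timepoint_days) tuples or a
    MultiIndex; values are fold changes.  Returns (scores, binary) over the
    retained conditions: score = |log2 FC|, binary = 1 iff FC > cutoff or
    FC < 1/cutoff (strictly).
    """
    cols = list(fc_table.columns)
    exclude = [(d, int(t)) for d, t in exclude]
    missing = [c for c in exclude if tuple(c) not in {tuple(col) for col in cols}]
    if missing:
        warnings.warn(f"excluded condition(s) absent from table: {missing}")
    keep = [c for c in cols if tuple(c) not in {tuple(e) for e in exclude}]
    fc = fc_table[keep].astype(float)
    scores = np.abs(np.log2(fc))
    binary = ((fc > fc_cutoff) | (fc < 1.0 / fc_cutoff)).astype(int)
    return scores, binary


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as Mann-Whitney concordance.

    (#(s+ > s-) + 0.5 * #(s+ = s-)) / (n_pos * n_neg).  Requires at least
    one positive and one negative label.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("single class: AUC undefined")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def biomarker_feature_auc(
    fc_table: pd.DataFrame,
    histopath: pd.DataFrame,
    mirnas: Sequence[str] | None = None,
    fc_cutoff: float = 1.5,
    exclude: Sequence[tuple[str, int]] = DEFAULT_EXCLUSIONS,
) -> pd.DataFrame:
    """AUC of |log2FC| scores against each histopathological feature.

    ``histopath`` rows are (dose_level, timepoint_days) conditions, columns
    are feature names, values binary presence.  Returns one row per
    (miRNA, feature), sorted by AUC descending within miRNA; pairs whose
    labels are single-class get a missing AUC with a reason.
    """
    scores, _binary = build_confidence_matrix(fc_table, fc_cutoff, exclude)
    conditions = [tuple(c) for c in scores.columns]
    histo_index = {tuple(ix): ix for ix in histopath.index}
    usable = [c for c in conditions if c in histo_index]
    if not usable:
        raise ValueError("no overlap between fold-change conditions and histopathology rows")
    if mirnas is None:
        mirnas = list(scores.index)
    rows = []
    for mid in mirnas:
        svec = scores.loc[mid, [c for c in scores.columns if tuple(c) in set(usable)]].to_numpy()
        for feature in histopath.columns:
            labels = np.asarray(
                [int(histopath.loc[histo_index[c], feature]) for c in usable]
            )
            n_pos = int(labels.sum())
            n_neg = int(len(labels) - n_pos)
            if n_pos == 0 or n_neg == 0:
                auc, reason = float("nan"), "single class"
            else:
                auc, reason = roc_auc(svec, labels), ""
            rows.append(
                {
                    "mirna_id": mid,
                    "feature": feature,
                    "auc": auc,
                    "n_pos": n_pos,
                    "n_neg": n_neg,
                    "n_conditions": len(usable),
                    "reason": reason,
                }
            )
    df = pd.DataFrame(rows)
    return (
        df.sort_values(["mirna_id", "auc"], ascending=[True, False], na_position="last")
        .reset_index(drop=True)
    )
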