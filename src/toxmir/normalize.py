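"""Count normalization and abundance filtering.

Reads-per-million scaling followed by upper-quartile normalization adjusts
for library depth and RNA composition; miRNAs below 5 normalized RPM in
every sample are removed to avoid artifacts from species absent in one or
more libraries.  Replicate consistency is assessed by pairwise Pearson
correlation of log2(value + 1) within each condition.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .design import treated_conditions


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    return counts.sum(axis=0)


def rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads per million: count * 1e6 / library size (column sum)."""
    libs = library_sizes(counts)
    zero = libs[libs <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts * 1e6 / libs


def upper_quartile_normalize(
    norm: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample upper-quartile scaling preserving the grand scale.

    The per-sample factor is the 75th percentile (linear interpolation)
    of that sample's values over miRNAs with a nonzero row total; each
    column is divided by its factor and multiplied by the geometric mean
    of all factors.  Returns (normalized matrix, factors).
    """
    expressed = norm.index[norm.sum(axis=1) > 0]
    if len(expressed) == 0:
        raise ValueError("no miRNA with nonzero total; cannot normalize")
    pool = norm.loc[expressed]
    factors = pool.quantile(0.75, axis=0, interpolation="linear")
    zero = factors[factors <= 0]
    if len(zero):
        raise ValueError(f"upper quartile is zero for sample(s): {list(zero.index)}")
    geo_mean = float(np.exp(np.log(factors).mean()))
    out = norm / factors * geo_mean
    return out, factors


def filter_low_abundance(
    norm: pd.DataFrame, threshold: float = 5.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop miRNAs below ``threshold`` in every sample.

    A miRNA is retained iff its normalized value is >= threshold in at
    least one sample.  Returns (filtered matrix, removed ids).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = (norm >= threshold).any(axis=1)
    removed = norm.index[~keep].tolist()
    return norm.loc[keep], removed


def normalize_counts(
    counts: pd.DataFrame, rpm_threshold: float = 5.0
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """RPM -> upper-quartile -> abundance filter convenience wrapper."""
    uq, factors = upper_quartile_normalize(rpm(counts))
    filtered, removed = filter_low_abundance(uq, rpm_threshold)
    return filtered, factors, removed


def replicate_correlation(norm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r of log2(value+1) between replicates per condition.

    Conditions (including control groups) with fewer than two replicates
    are skipped with a warning; degenerate pairs (zero variance) yield NaN.
    """
    log_norm = np.log2(norm + 1.0)
    rows = []
    groups = design.groupby(["dose_level", "timepoint_days"], sort=True)
    for (dose, tp), sub in groups:
        samples = [s for s in sub["sample_id"] if s in norm.columns]
        if len(samples) < 2:
            warnings.warn(
                f"condition ({dose}, {tp}d) has fewer than 2 replicates; skipped"
            )
            continue
        for a, b in itertools.combinations(samples, 2):
            x, y = log_norm[a].to_numpy(), log_norm[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {
                    "dose_level": dose,
                    "timepoint_days": int(tp),
                    "sample_a": a,
                    "sample_b": b,
                    "pearson_r": r,
                }
            )
    return pd.DataFrame(
        rows, columns=["dose_level", "timepoint_days", "sample_a", "sample_b", "pearson_r"]
    )
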