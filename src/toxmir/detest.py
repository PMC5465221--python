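"""Per-condition differential expression against time-matched controls.

Each treated (dose, timepoint) group is compared with its time-matched
control using an exact conditional negative-binomial test: after
equalizing counts to the geometric-mean library depth, the group-A sum of
i.i.d. NB draws with common dispersion phi, conditional on the two-group
total, follows a closed-form (negative-hypergeometric) law that is free of
the unknown mean.  Two-sided p-values sum the probabilities of all
outcomes no more likely than the observed one.  phi = 0 reduces to the
Poisson/binomial case.

A miRNA is called differentially expressed (DEM) when its fold change
(on upper-quartile-normalized values, with a pseudocount) exceeds 1.5 in
either direction and the exact-test p-value is < 0.05 — raw p-values, no
multiplicity correction, matching the per-condition call rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import normalize
from .design import control_samples, condition_samples, treated_conditions

_TIE_REL_TOL = 1e-12  # relative tolerance for probability ties in the two-sided sum


@dataclass
class DispersionEstimate:
    phi: float
    n_features_used: int


def estimate_common_dispersion(counts: pd.DataFrame, design: pd.DataFrame) -> DispersionEstimate:
    """Method-of-moments common NB dispersion pooled over miRNAs.

    Counts are equalized to the geometric-mean library size; for each
    miRNA and each replicate group, phi is estimated as (v - m) / m^2 from
    the group sample mean m and variance v.  Per-miRNA estimates average
    over groups, are clipped at zero, and the pooled estimate is their
    median.  Equidispersed (Poisson) data yield ~0.
    """
    libs = counts.sum(axis=0).astype(float)
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValueError(f"zero library size for sample(s): {bad}")
    ref = float(np.exp(np.log(libs).mean()))
    eq = counts * (ref / libs)

    groups = []
    for (dose, tp), sub in design.groupby(["dose_level", "timepoint_days"], sort=True):
        samples = [s for s in sub["sample_id"] if s in counts.columns]
        if len(samples) >= 2:
            groups.append(samples)
    if not groups:
        raise ValueError("no group with >= 2 replicates; cannot estimate dispersion")

    per_group = []
    for samples in groups:
        block = eq[samples].to_numpy()
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            est = np.where(m > 0, (v - m) / np.square(m), np.nan)
        per_group.append(est)
    stacked = np.vstack(per_group)
    with np.errstate(invalid="ignore"):
        per_feature = np.nanmean(stacked, axis=0)
    valid = ~np.isnan(per_feature)
    if not valid.any():
        raise ValueError("no feature with positive mean in any group")
    phi = float(np.median(np.maximum(0.0, per_feature[valid])))
    return DispersionEstimate(phi=phi, n_features_used=int(valid.sum()))


def _conditional_log_pmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log pmf of the group-A equalized sum conditional on the total.

    For i.i.d. NB(mu, phi) counts the group sums are NB with sizes
    n_a/phi and n_b/phi and a shared success probability, so the
    conditional law is negative-hypergeometric and parameter-free given
    phi.  phi = 0 gives Binomial(total, n_a / (n_a + n_b)).
    """
    k = np.arange(total + 1)
    if phi == 0:
        logp = math.log(n_a / (n_a + n_b))
        log1mp = math.log(n_b / (n_a + n_b))
        lp = (
            gammaln(total + 1)
            - gammaln(k + 1)
            - gammaln(total - k + 1)
            + k * logp
            + (total - k) * log1mp
        )
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        lp = (
            gammaln(k + r_a)
            - gammaln(k + 1)
            + gammaln(total - k + r_b)
            - gammaln(total - k + 1)
        )
    return lp - logsumexp(lp)


def equalize_to_common_depth(
    counts: np.ndarray, libs: np.ndarray, common_depth: float
) -> np.ndarray:
    """Rescale raw counts to a common library depth and round to integers."""
    return np.rint(np.asarray(counts, dtype=float) * common_depth / libs).astype(np.int64)


def exact_nb_test(
    counts_a,
    counts_b,
    lib_a,
    lib_b,
    phi: float,
) -> float:
    """Two-sided exact conditional NB test for a difference in abundance.

    counts_a/counts_b are the raw per-replicate counts of one miRNA in the
    two groups; lib_a/lib_b the corresponding library sizes.  Counts are
    rescaled to the geometric-mean depth and rounded; the p-value sums the
    conditional probabilities of all group-A sums whose probability does
    not exceed the observed one (ties included with relative tolerance
    1e-12).  Returns p in (0, 1].
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    la = np.asarray(lib_a, dtype=float)
    lb = np.asarray(lib_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if (la <= 0).any() or (lb <= 0).any():
        raise ValueError("library sizes must be positive")
    if a.size != la.size or b.size != lb.size:
        raise ValueError("counts and library sizes must align")

    common = float(np.exp(np.mean(np.log(np.concatenate([la, lb])))))
    a_eq = equalize_to_common_depth(a, la, common)
    b_eq = equalize_to_common_depth(b, lb, common)
    total = int(a_eq.sum() + b_eq.sum())
    if total == 0:
        return 1.0
    lp = _conditional_log_pmf(total, a.size, b.size, phi)
    lp_obs = lp[int(a_eq.sum())]
    mask = lp <= lp_obs + math.log1p(_TIE_REL_TOL)
    if mask.all():
        return 1.0
    p = float(np.exp(logsumexp(lp[mask])))
    return min(max(p, np.exp(lp_obs)), 1.0)


def fold_change(
    norm_treated, norm_control, pseudocount: float = 0.5
) -> tuple[float, float]:
    """Group-mean fold change with a pseudocount guarding zero controls.

    FC = (mean(treated) + pseudocount) / (mean(control) + pseudocount);
    returns (FC, log2 FC).
    """
    t = np.asarray(norm_treated, dtype=float)
    c = np.asarray(norm_control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    fc = (t.mean() + pseudocount) / (c.mean() + pseudocount)
    return float(fc), float(np.log2(fc))


def classify_call(
    fc: float, p_value: float, fc_threshold: float = 1.5, p_threshold: float = 0.05
) -> tuple[bool, str]:
    """Apply the DEM rule: |FC| beyond the threshold (strictly) and p below cutoff."""
    is_dem = (fc > fc_threshold or fc < 1.0 / fc_threshold) and p_value < p_threshold
    if not is_dem:
        return False, "none"
    return True, ("up" if fc > 1 else "down")


def call_dems(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    norm: pd.DataFrame | None = None,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    rpm_threshold: float = 5.0,
    pseudocount: float = 0.5,
    phi: float | None = None,
) -> pd.DataFrame:
    """One DEM record per retained miRNA x treated condition.

    Fold changes use the normalized, abundance-filtered matrix (computed
    from ``counts`` when ``norm`` is not supplied); the exact test uses
    raw counts.  phi defaults to the pooled common-dispersion estimate.
    """
    if norm is None:
        norm, _factors, _removed = normalize.normalize_counts(counts, rpm_threshold)
    if phi is None:
        phi = estimate_common_dispersion(counts, design).phi

    libs = counts.sum(axis=0).astype(float)
    mirnas = [m for m in norm.index if m in counts.index]
    records = []
    for dose, tp in treated_conditions(design):
        t_samples = condition_samples(design, dose, tp)
        c_samples = control_samples(design, tp)
        if not c_samples:
            raise ValueError(f"condition ({dose}, {tp}d) has no time-matched control")
        raw_t = counts.loc[mirnas, t_samples].to_numpy()
        raw_c = counts.loc[mirnas, c_samples].to_numpy()
        norm_t = norm.loc[mirnas, t_samples].to_numpy()
        norm_c = norm.loc[mirnas, c_samples].to_numpy()
        lib_t = libs[t_samples].to_numpy()
        lib_c = libs[c_samples].to_numpy()
        for i, mid in enumerate(mirnas):
            fc, lfc = fold_change(norm_t[i], norm_c[i], pseudocount)
            p = exact_nb_test(raw_t[i], raw_c[i], lib_t, lib_c, phi)
            is_dem, direction = classify_call(fc, p, fc_threshold, p_threshold)
            records.append(
                {
                    "mirna_id": mid,
                    "dose_level": dose,
                    "timepoint_days": tp,
                    "log2fc": lfc,
                    "fold_change": fc,
                    "p_value": p,
                    "is_dem": is_dem,
                    "direction": direction,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "mirna_id",
            "dose_level",
            "timepoint_days",
            "log2fc",
            "fold_change",
            "p_value",
            "is_dem",
            "direction",
        ],
    )
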