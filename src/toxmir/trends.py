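"""Set algebra over DEM calls and dose/time-responsiveness classification.

Venn-style overlap accounting of per-condition DEM sets, identification of
miRNAs called DEM consistently across conditions ("common DEMs"), and the
trend classifiers: a miRNA is time-responsive when its fold-change profile
is strictly monotone along the ordered timepoints in at least two dose
levels, and dose-responsive when it is strictly monotone along the ordered
doses in at least two timepoints.  Ties (relative tolerance 1e-9) break a
pattern under the default strict rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DEFAULT_TIMEPOINTS, TREATED_DOSE_LEVELS

_REL_TOL = 1e-9


@dataclass
class DemSets:
    """Per-condition DEM id sets and their overlap structure."""

    per_condition: dict[tuple[str, int], set[str]]
    by_dose: dict[str, dict[int, set[str]]]
    by_timepoint: dict[int, dict[str, set[str]]]
    time_regions: dict[str, dict[frozenset[int], int]]
    dose_regions: dict[int, dict[frozenset[str], int]]
    global_intersection: set[str]
    global_union: set[str]
    updown: pd.DataFrame = field(default_factory=pd.DataFrame)


def _regions(sets: Mapping) -> dict[frozenset, int]:
    """Venn region counts: members keyed by the exact subset of sets they fall in."""
    union = set().union(*sets.values()) if sets else set()
    counts: dict[frozenset, int] = {}
    for item in union:
        key = frozenset(k for k, s in sets.items() if item in s)
        counts[key] = counts.get(key, 0) + 1
    return counts


def dem_sets(dems: pd.DataFrame) -> DemSets:
    """Build DEM id sets per condition / dose / timepoint plus overlap counts."""
    flagged = dems[dems["is_dem"]]
    per_condition: dict[tuple[str, int], set[str]] = {}
    for (dose, tp), sub in dems.groupby(["dose_level", "timepoint_days"], sort=False):
        key = (str(dose), int(tp))
        per_condition[key] = set(
            sub.loc[sub["is_dem"], "mirna_id"]
        )
    by_dose: dict[str, dict[int, set[str]]] = {}
    by_timepoint: dict[int, dict[str, set[str]]] = {}
    for (dose, tp), ids in per_condition.items():
        by_dose.setdefault(dose, {})[tp] = ids
        by_timepoint.setdefault(tp, {})[dose] = ids
    time_regions = {dose: _regions(tps) for dose, tps in by_dose.items()}
    dose_regions = {tp: _regions(doses) for tp, doses in by_timepoint.items()}
    sets = list(per_condition.values())
    global_union = set().union(*sets) if sets else set()
    global_intersection = set.intersection(*sets) if sets else set()
    updown = (
        flagged.groupby(["dose_level", "timepoint_days", "direction"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
        .reset_index()
    )
    return DemSets(
        per_condition=per_condition,
        by_dose=by_dose,
        by_timepoint=by_timepoint,
        time_regions=time_regions,
        dose_regions=dose_regions,
        global_intersection=global_intersection,
        global_union=global_union,
        updown=updown,
    )


def series_direction(
    values: Sequence[float],
    strict: bool = True,
    rel_tol: float = _REL_TOL,
) -> str:
    """'increasing', 'decreasing' or 'none' for one ordered fold-change series.

    Strict mode requires every consecutive step to move in the same
    direction; a tie (relative difference below ``rel_tol``) or a missing
    value breaks the pattern.  Non-strict mode tolerates ties but still
    rejects reversals.
    """
    vals = [float(v) if v is not None else float("nan") for v in values]
    if len(vals) < 2 or any(np.isnan(v) for v in vals):
        return "none"
    ups = downs = ties = 0
    for a, b in zip(vals, vals[1:]):
        if abs(b - a) <= rel_tol * max(abs(a), abs(b)):
            ties += 1
        elif b > a:
            ups += 1
        else:
            downs += 1
    if strict:
        if ties == 0 and downs == 0:
            return "increasing"
        if ties == 0 and ups == 0:
            return "decreasing"
        return "none"
    if downs == 0 and ups > 0:
        return "increasing"
    if ups == 0 and downs > 0:
        return "decreasing"
    return "none"


def classify_time_responsive(
    fc_by_condition: Mapping[tuple[str, int], float],
    doses: Sequence[str] = TREATED_DOSE_LEVELS,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
    min_series: int = 2,
    strict: bool = True,
    require_same_direction: bool = False,
) -> tuple[dict[str, str], bool]:
    """Per-dose monotone direction along timepoints + responsiveness flag.

    Responsive iff at least ``min_series`` dose series are monotone
    (any direction by default; optionally the same direction).
    """
    timepoints = sorted(int(t) for t in timepoints)
    directions = {
        dose: series_direction(
            [fc_by_condition.get((dose, t), float("nan")) for t in timepoints],
            strict=strict,
        )
        for dose in doses
    }
    flag = _responsive(directions.values(), min_series, require_same_direction)
    return directions, flag


def classify_dose_responsive(
    fc_by_condition: Mapping[tuple[str, int], float],
    doses: Sequence[str] = TREATED_DOSE_LEVELS,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
    min_series: int = 2,
    strict: bool = True,
    require_same_direction: bool = False,
) -> tuple[dict[int, str], bool]:
    """Per-timepoint monotone direction along ordered doses + flag."""
    timepoints = sorted(int(t) for t in timepoints)
    directions = {
        t: series_direction(
            [fc_by_condition.get((dose, t), float("nan")) for dose in doses],
            strict=strict,
        )
        for t in timepoints
    }
    flag = _responsive(directions.values(), min_series, require_same_direction)
    return directions, flag


def _responsive(directions, min_series: int, require_same_direction: bool) -> bool:
    hits = [d for d in directions if d != "none"]
    if require_same_direction:
        return len(hits) >= min_series and len(set(hits)) == 1
    return len(hits) >= min_series


def trend_calls(
    dems: pd.DataFrame,
    doses: Sequence[str] = TREATED_DOSE_LEVELS,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
    mirnas: Sequence[str] | None = None,
    strict: bool = True,
    require_same_direction: bool = False,
) -> pd.DataFrame:
    """Per-miRNA trend classification from the full fold-change profile.

    Uses fold changes from ALL conditions (not only DEM-flagged ones);
    restrict ``mirnas`` to e.g. the common-DEM set to reproduce the
    narrowed workflow.
    """
    if mirnas is None:
        mirnas = sorted(dems["mirna_id"].unique())
    fc_lookup = {
        (r.mirna_id, (str(r.dose_level), int(r.timepoint_days))): float(r.fold_change)
        for r in dems.itertuples()
    }
    ndem = dems.groupby("mirna_id")["is_dem"].sum().to_dict()
    rows = []
    for mid in mirnas:
        prof = {
            cond: fc_lookup.get((mid, cond), float("nan"))
            for cond in [(d, int(t)) for d in doses for t in timepoints]
        }
        tdir, tflag = classify_time_responsive(
            prof, doses, timepoints, strict=strict,
            require_same_direction=require_same_direction,
        )
        ddir, dflag = classify_dose_responsive(
            prof, doses, timepoints, strict=strict,
            require_same_direction=require_same_direction,
        )
        rows.append(
            {
                "mirna_id": mid,
                "time_responsive": tflag,
                "dose_responsive": dflag,
                "time_directions": tdir,
                "dose_directions": ddir,
                "n_conditions_dem": int(ndem.get(mid, 0)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "time_responsive",
            "dose_responsive",
            "time_directions",
            "dose_directions",
            "n_conditions_dem",
        ],
    )


def common_dems(dems: pd.DataFrame, min_conditions: int = 12) -> pd.DataFrame:
    """miRNAs called DEM in at least ``min_conditions`` conditions.

    Ranked by (number of DEM conditions, mean |log2FC|) descending, with a
    sign-consistency flag (all DEM directions agree).
    """
    if dems.empty:
        return pd.DataFrame(
            columns=["mirna_id", "n_conditions_dem", "mean_abs_log2fc", "sign_consistent"]
        )
    n_conditions = dems.groupby(["dose_level", "timepoint_days"]).ngroups
    if min_conditions > n_conditions:
        raise ValueError(
            f"min_conditions={min_conditions} exceeds the {n_conditions} tested conditions"
        )
    flagged = dems[dems["is_dem"]]
    if flagged.empty:
        return pd.DataFrame(
            columns=["mirna_id", "n_conditions_dem", "mean_abs_log2fc", "sign_consistent"]
        )
    grouped = flagged.groupby("mirna_id")
    summary = pd.DataFrame(
        {
            "n_conditions_dem": grouped.size(),
            "mean_abs_log2fc": grouped["log2fc"].apply(lambda s: s.abs().mean()),
            "sign_consistent": grouped["direction"].nunique() == 1,
        }
    )
    summary = summary[summary["n_conditions_dem"] >= min_conditions]
    summary = summary.sort_values(
        ["n_conditions_dem", "mean_abs_log2fc"], ascending=[False, False]
    ).reset_index()
    return summary[["mirna_id", "n_conditions_dem", "mean_abs_log2fc", "sign_consistent"]]
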