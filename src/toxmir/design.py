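"""Experimental design of the multi-dose, multi-timepoint toxicity study.

The default design mirrors a repeat-dose rodent hepatotoxicity experiment:
three dose levels of the test compound (low 4.5, middle 15, high 45 mg/kg)
administered for 3, 7, 14 or 28 days, three profiled replicates per group,
plus one time-matched vehicle control group per timepoint.  That yields
12 treated conditions and 48 sequencing libraries in total.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

#: dose level -> administered dose in mg/kg body weight
DOSE_MG_PER_KG: dict[str, float] = {
    "control": 0.0,
    "low": 4.5,
    "middle": 15.0,
    "high": 45.0,
}

TREATED_DOSE_LEVELS: tuple[str, ...] = ("low", "middle", "high")
DEFAULT_TIMEPOINTS: tuple[int, ...] = (3, 7, 14, 28)

#: canonical ordering used for sorting dose levels
_DOSE_ORDER = {"control": 0, "low": 1, "middle": 2, "high": 3}

DESIGN_COLUMNS = [
    "sample_id",
    "dose_level",
    "dose_mg_per_kg",
    "timepoint_days",
    "replicate",
]


def generate_design(
    n_replicates: int = 3,
    doses: Sequence[str] = TREATED_DOSE_LEVELS,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
) -> pd.DataFrame:
    """Build the sample design table.

    One row per library: every (treated dose, timepoint) cell gets
    ``n_replicates`` rows, and each timepoint additionally gets a
    time-matched control group with the same replicate count.  Rows are
    ordered deterministically by (timepoint, dose, replicate).

    Returns a DataFrame with columns ``sample_id, dose_level,
    dose_mg_per_kg, timepoint_days, replicate``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    doses = list(doses)
    timepoints = [int(t) for t in timepoints]
    if not doses or not timepoints:
        raise ValueError("doses and timepoints must be non-empty")
    if len(set(doses)) != len(doses):
        raise ValueError("duplicate dose levels in design")
    if len(set(timepoints)) != len(timepoints):
        raise ValueError("duplicate timepoints in design")
    unknown = [d for d in doses if d not in TREATED_DOSE_LEVELS]
    if unknown:
        raise ValueError(f"unknown dose levels: {unknown}")

    rows = []
    for tp in sorted(timepoints):
        for dose in sorted(["control"] + doses, key=_DOSE_ORDER.__getitem__):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{dose}_d{tp}_r{rep}",
                        "dose_level": dose,
                        "dose_mg_per_kg": DOSE_MG_PER_KG[dose],
                        "timepoint_days": tp,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def treated_conditions(design: pd.DataFrame) -> list[tuple[str, int]]:
    """Treated (dose_level, timepoint_days) pairs in canonical order."""
    pairs = {
        (str(r.dose_level), int(r.timepoint_days))
        for r in design.itertuples()
        if r.dose_level != "control"
    }
    return sorted(pairs, key=lambda p: (p[1], _DOSE_ORDER[p[0]]))


def condition_samples(design: pd.DataFrame, dose_level: str, timepoint_days: int) -> list[str]:
    """Sample ids belonging to one (dose level, timepoint) group."""
    mask = (design["dose_level"] == dose_level) & (
        design["timepoint_days"] == int(timepoint_days)
    )
    return design.loc[mask, "sample_id"].tolist()


def control_samples(design: pd.DataFrame, timepoint_days: int) -> list[str]:
    """Sample ids of the time-matched control group."""
    return condition_samples(design, "control", timepoint_days)


def condition_label(dose_level: str, timepoint_days: int) -> str:
    return f"{dose_level}:{int(timepoint_days)}d"


def parse_condition_label(label: str) -> tuple[str, int]:
    dose, tp = label.split(":")
    return dose, int(tp.rstrip("d"))
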