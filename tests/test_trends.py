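import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxmir.trends import (
    classify_dose_responsive,
    classify_time_responsive,
    common_dems,
    dem_sets,
    series_direction,
    trend_calls,
)

DOSES = ("low", "middle", "high")
TPS = (3, 7, 14, 28)


def _dem_frame(flags, log2fc=1.0):
    """flags: {(mirna, dose, tp): is_dem}; builds a minimal DEMRecord table."""
    rows = []
    for (mid, dose, tp), flag in flags.items():
        rows.append(
            {
                "mirna_id": mid,
                "dose_level": dose,
                "timepoint_days": tp,
                "log2fc": log2fc if flag else 0.0,
                "fold_change": 2.0**log2fc if flag else 1.0,
                "p_value": 0.01 if flag else 0.9,
                "is_dem": flag,
                "direction": "up" if flag else "none",
            }
        )
    return pd.DataFrame(rows)


def _full_grid(dem_ids_by_condition):
    flags = {}
    universe = set(itertools.chain.from_iterable(dem_ids_by_condition.values()))
    for dose in DOSES:
        for tp in TPS:
            members = dem_ids_by_condition.get((dose, tp), set())
            for mid in universe:
                flags[(mid, dose, tp)] = mid in members
    return _dem_frame(flags)


class TestSeriesDirection:
    def test_strict_directions(self):
        assert series_direction([1, 2, 3, 4]) == "increasing"
        assert series_direction([4, 3, 2, 1]) == "decreasing"
        assert series_direction([2.0, 2.0, 3.0, 4.0]) == "none"  # tie breaks
        assert series_direction([1, 3, 2, 4]) == "none"
        assert series_direction([1, float("nan"), 2, 3]) == "none"

    def test_non_strict_allows_ties(self):
        assert series_direction([2.0, 2.0, 3.0, 4.0], strict=False) == "increasing"
        assert series_direction([2.0, 2.0, 2.0], strict=False) == "none"

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=6))
    def test_reversal_antisymmetry(self, values):
        fwd = series_direction(values)
        rev = series_direction(values[::-1])
        flip = {"increasing": "decreasing", "decreasing": "increasing", "none": "none"}
        assert rev == flip[fwd]


class TestResponsivenessClassifiers:
    def test_two_monotone_dose_series_make_time_responsive(self):
        fc = {}
        fc.update({("low", t): v for t, v in zip(TPS, [2.0, 2.5, 3.0, 4.0])})
        fc.update({("middle", t): v for t, v in zip(TPS, [1.2, 1.5, 2.0, 2.2])})
        fc.update({("high", t): 1.0 for t in TPS})
        directions, flag = classify_time_responsive(fc)
        assert flag and directions == {
            "low": "increasing",
            "middle": "increasing",
            "high": "none",
        }

    def test_single_monotone_series_is_not_enough(self):
        fc = {("low", t): v for t, v in zip(TPS, [2.0, 2.5, 3.0, 4.0])}
        fc.update({(d, t): 1.0 for d in ("middle", "high") for t in TPS})
        _, flag = classify_time_responsive(fc)
        assert not flag

    def test_dose_responsive_needs_two_timepoints(self):
        fc = {(d, t): 1.0 for d in DOSES for t in TPS}
        fc.update({(d, 3): v for d, v in zip(DOSES, [1.0, 2.0, 3.0])})
        fc.update({(d, 7): v for d, v in zip(DOSES, [1.0, 1.5, 2.5])})
        directions, flag = classify_dose_responsive(fc)
        assert flag and directions[3] == "increasing" and directions[7] == "increasing"
        # only one monotone timepoint -> not responsive
        fc.update({(d, 7): 1.0 for d in DOSES})
        _, flag = classify_dose_responsive(fc)
        assert not flag

    def test_constant_profile_is_unresponsive(self):
        fc = {(d, t): 2.0 for d in DOSES for t in TPS}
        assert not classify_time_responsive(fc)[1]
        assert not classify_dose_responsive(fc)[1]

    def test_same_direction_mode_rejects_mixed_directions(self):
        fc = {("low", t): v for t, v in zip(TPS, [1.0, 2.0, 3.0, 4.0])}
        fc.update({("middle", t): v for t, v in zip(TPS, [4.0, 3.0, 2.0, 1.0])})
        fc.update({("high", t): 1.0 for t in TPS})
        assert classify_time_responsive(fc)[1]
        assert not classify_time_responsive(fc, require_same_direction=True)[1]


class TestDemSets:
    def test_disjoint_and_identical_sets(self):
        ids = {("low", 3): {"a", "b"}, ("low", 7): {"c"}}
        sets = dem_sets(_full_grid(ids))
        assert sets.time_regions["low"][frozenset({3})] == 2
        assert sets.time_regions["low"][frozenset({7})] == 1
        same = {("low", t): {"x", "y"} for t in TPS}
        sets = dem_sets(_full_grid(same))
        assert sets.time_regions["low"][frozenset(TPS)] == 2

    def test_region_counts_match_membership_enumeration(self):
        rng = np.random.default_rng(3)
        universe = [f"m{i}" for i in range(30)]
        ids = {
            (d, t): {m for m in universe if rng.random() < 0.3}
            for d in DOSES
            for t in TPS
        }
        sets = dem_sets(_full_grid(ids))
        for dose in DOSES:
            # oracle: assign each union member to its exact membership region
            union = set().union(*(ids[(dose, t)] for t in TPS))
            expected = {}
            for m in union:
                key = frozenset(t for t in TPS if m in ids[(dose, t)])
                expected[key] = expected.get(key, 0) + 1
            assert sets.time_regions[dose] == expected
            # partition property
            assert sum(sets.time_regions[dose].values()) == len(union)

    def test_global_union_intersection_and_updown(self):
        ids = {(d, t): {"a"} for d in DOSES for t in TPS}
        ids[("low", 3)] = {"a", "b"}
        sets = dem_sets(_full_grid(ids))
        assert sets.global_intersection == {"a"}
        assert sets.global_union == {"a", "b"}
        row = sets.updown[
            (sets.updown["dose_level"] == "low") & (sets.updown["timepoint_days"] == 3)
        ]
        assert int(row["up"].iloc[0]) == 2 and int(row["down"].iloc[0]) == 0


class TestCommonDems:
    def test_min_conditions_one_equals_union(self):
        ids = {("low", 3): {"a", "b"}, ("high", 28): {"b", "c"}}
        dems = _full_grid(ids)
        out = common_dems(dems, min_conditions=1)
        assert set(out["mirna_id"]) == {"a", "b", "c"}
        assert out.iloc[0]["mirna_id"] == "b"  # most conditions first

    def test_no_dems_yields_empty(self):
        dems = _full_grid({})
        assert common_dems(dems, min_conditions=1).empty

    def test_excessive_min_conditions_rejected(self):
        dems = _full_grid({("low", 3): {"a"}})
        with pytest.raises(ValueError):
            common_dems(dems, min_conditions=13)

    def test_trend_calls_report_dem_condition_counts(self):
        ids = {(d, t): {"a"} for d in DOSES for t in TPS}
        calls = trend_calls(_full_grid(ids))
        row = calls[calls["mirna_id"] == "a"].iloc[0]
        assert row["n_conditions_dem"] == 12
        # constant fold changes: not trend-responsive under the strict rule
        assert not row["time_responsive"] and not row["dose_responsive"]
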