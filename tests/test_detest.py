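import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom, poisson

import toxmir as tm
from toxmir import simulate
from toxmir.design import generate_design
from toxmir.detest import (
    call_dems,
    classify_call,
    estimate_common_dispersion,
    exact_nb_test,
    fold_change,
)


def conditional_enumeration_p(counts_a, counts_b, phi, mu=3.0):
    """Independent oracle: convolve per-replicate pmfs and condition on the total.

    The conditional law must not depend on mu; any positive value works.
    """
    total = int(sum(counts_a) + sum(counts_b))
    support = np.arange(total + 1)

    def group_pmf(n_reps):
        pmf = np.zeros(total + 1)
        pmf[0] = 1.0
        if phi == 0:
            single = poisson.pmf(support, mu)
        else:
            r = 1 / phi
            single = nbinom.pmf(support, r, r / (r + mu))
        for _ in range(n_reps):
            pmf = np.convolve(pmf, single)[: total + 1]
        return pmf

    joint = group_pmf(len(counts_a)) * group_pmf(len(counts_b))[::-1]
    joint /= joint.sum()
    p_obs = joint[int(sum(counts_a))]
    return float(joint[joint <= p_obs * (1 + 1e-12)].sum())


class TestExactNBTest:
    def test_identical_groups_give_p_one(self):
        libs = [1e6] * 3
        assert exact_nb_test([5, 5, 5], [5, 5, 5], libs, libs, 0.1) == 1.0

    def test_binomial_special_case_0_vs_10(self):
        # phi=0, equal libraries, 1 vs 1: conditional law Binomial(10, 1/2)
        p = exact_nb_test([0], [10], [1e6], [1e6], 0.0)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, phi):
        rng = np.random.default_rng(23)
        for _ in range(40):
            n_a, n_b = rng.integers(1, 4, size=2)
            total = int(rng.integers(1, 31))
            a_sum = int(rng.integers(0, total + 1))
            a = [a_sum] + [0] * (n_a - 1)
            b = [total - a_sum] + [0] * (n_b - 1)
            p = exact_nb_test(a, b, [1e6] * n_a, [1e6] * n_b, phi)
            p_oracle = conditional_enumeration_p(a, b, phi)
            assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_symmetry_under_group_swap(self):
        a, b = [3, 9, 1], [12, 20, 7]
        la, lb = [9e5, 1.1e6, 1e6], [1e6, 8e5, 1.2e6]
        assert exact_nb_test(a, b, la, lb, 0.1) == pytest.approx(
            exact_nb_test(b, a, lb, la, 0.1), rel=1e-12
        )

    def test_equalization_absorbs_depth_differences(self):
        # counts proportional to library sizes carry no signal
        p = exact_nb_test([10], [20], [1e6], [2e6], 0.1)
        assert p == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test([1], [1], [1e6], [1e6], -0.1)
        with pytest.raises(ValueError):
            exact_nb_test([-1], [1], [1e6], [1e6], 0.1)
        with pytest.raises(ValueError):
            exact_nb_test([], [1], [], [1e6], 0.1)


class TestDispersionEstimate:
    def test_poisson_counts_estimate_near_zero(self):
        design = generate_design(3, ["low", "middle", "high"], [3, 7])
        params = tm.SimulationParams(
            n_mirnas=300, dispersion=0.0, lib_size_mean=100_000, seed=19
        )
        counts, _ = tm.generate_counts(design, params, [])
        est = estimate_common_dispersion(counts, design)
        assert est.phi < 0.02
        assert est.n_features_used == 300

    def test_nb_dispersion_recovered_within_band(self):
        design = generate_design(3)
        params = tm.SimulationParams(n_mirnas=664, dispersion=0.1, seed=29)
        counts, _ = tm.generate_counts(design, params, [])
        est = estimate_common_dispersion(counts, design)
        assert 0.05 <= est.phi <= 0.2

    def test_identical_replicates_contribute_zero(self):
        design = generate_design(2, ["low"], [3])
        counts = pd.DataFrame(
            [[7, 7, 7, 7]], columns=design["sample_id"], index=["m1"]
        )
        est = estimate_common_dispersion(counts, design)
        assert est.phi == 0.0

    def test_unreplicated_design_rejected(self):
        design = generate_design(1, ["low"], [3])
        counts = pd.DataFrame([[5, 6]], columns=design["sample_id"], index=["m1"])
        # drop one column so no group has 2 replicates
        with pytest.raises(ValueError):
            estimate_common_dispersion(counts[[design["sample_id"][0]]], design)


class TestFoldChange:
    def test_pseudocount_arithmetic(self):
        fc, lfc = fold_change([40.0], [10.0])
        assert fc == pytest.approx(40.5 / 10.5)
        assert lfc == pytest.approx(np.log2(40.5 / 10.5))

    def test_equal_means_give_unity(self):
        fc, lfc = fold_change([10, 20], [15, 15])
        assert (fc, lfc) == (1.0, 0.0)

    def test_zero_control_stays_finite(self):
        fc, _ = fold_change([10.0], [0.0])
        assert fc == pytest.approx(21.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fold_change([], [1.0])


class TestDemCall:
    @pytest.mark.parametrize(
        "fc, p, is_dem, direction",
        [
            (1.5, 0.01, False, "none"),  # threshold is strict
            (4.0, 0.04, True, "up"),
            (0.5, 0.001, True, "down"),
            (2.0, 0.05, False, "none"),  # p cutoff is strict too
            (1.0 / 1.5, 0.01, False, "none"),
        ],
    )
    def test_rule_boundaries(self, fc, p, is_dem, direction):
        assert classify_call(fc, p) == (is_dem, direction)

    def test_call_dems_flags_follow_rule(self, small_sim):
        dems = call_dems(small_sim["counts"], small_sim["design"])
        rule = (
            (dems["fold_change"] > 1.5) | (dems["fold_change"] < 1 / 1.5)
        ) & (dems["p_value"] < 0.05)
        assert (dems["is_dem"] == rule).all()
        up = dems[dems["direction"] == "up"]
        assert (up["log2fc"] > 0).all()
        # planted consistent effects are found in most conditions
        bm = small_sim["truths"][0].mirna_id
        assert dems.loc[dems["mirna_id"] == bm, "is_dem"].sum() >= 10

    def test_missing_control_is_an_error(self, small_sim):
        design = small_sim["design"]
        broken = design[design["dose_level"] != "control"]
        with pytest.raises(ValueError, match="control"):
            call_dems(small_sim["counts"], broken)

    def test_planted_signal_increases_rejection_rate(self):
        # rejection among planted miRNAs grows with the planted effect size
        design = generate_design(3, ["low"], [3])
        ids = simulate.make_mirna_ids(150)
        planted = ids[:30]
        rates = []
        for lfc in (0.0, 1.0, 2.0):
            truths = (
                [simulate.constant_effect(m, lfc, [("low", 3)]) for m in planted]
                if lfc > 0
                else []
            )
            params = tm.SimulationParams(
                n_mirnas=150, dispersion=0.1, lib_size_mean=100_000, seed=31
            )
            counts, _ = tm.generate_counts(design, params, truths)
            dems = call_dems(counts, design, phi=0.1)
            rates.append(dems[dems["mirna_id"].isin(planted)]["is_dem"].mean())
        assert rates[0] < rates[1] < rates[2]
        assert rates[0] < 0.15 and rates[2] > 0.8
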