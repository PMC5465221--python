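import math

import numpy as np
import pytest

import toxmir as tm
from toxmir import simulate
from toxmir.design import generate_design


def test_counts_are_reproducible_given_seed(small_sim):
    params = tm.SimulationParams(n_mirnas=40, lib_size_mean=100_000, seed=7)
    again, _ = tm.generate_counts(small_sim["design"], params, small_sim["truths"])
    assert again.equals(small_sim["counts"])


def test_null_poisson_column_sums_track_library_sizes():
    design = generate_design(3, ["low"], [3, 7])
    params = tm.SimulationParams(
        n_mirnas=50, dispersion=0.0, lib_size_mean=100_000, lib_size_cv=0.0, seed=3
    )
    counts, truth = tm.generate_counts(design, params, [])
    assert truth.empty
    # column sum ~ Poisson(1e5): sd ~ 316, allow 6 sd
    assert np.all(np.abs(counts.sum(axis=0) - 100_000) < 2000)


def test_nb_marginal_moments_match_dispersion():
    # single condition, many replicates -> i.i.d. columns per miRNA
    design = generate_design(1000, ["low"], [3])
    phi = 0.3
    params = tm.SimulationParams(
        n_mirnas=5,
        dispersion=phi,
        lib_size_mean=50_000,
        lib_size_cv=0.0,
        baseline_logmean_sd=0.5,
        seed=11,
    )
    counts, _ = tm.generate_counts(design, params, [])
    x = counts.to_numpy(dtype=float)
    m = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)
    expected = m + phi * m**2
    assert np.all(np.abs(v / expected - 1) < 0.2)


def test_planted_constant_effect_scales_treated_means():
    # log2fc = 2 -> treated/control mean ratio ~ 4
    design = generate_design(400, ["low"], [3])
    ids = simulate.make_mirna_ids(10)
    truths = [simulate.constant_effect(ids[0], 2.0, [("low", 3)])]
    params = tm.SimulationParams(
        n_mirnas=10, dispersion=0.1, lib_size_mean=50_000, lib_size_cv=0.0, seed=5
    )
    counts, _ = tm.generate_counts(design, params, truths)
    treated = [s for s in counts.columns if s.startswith("low")]
    control = [s for s in counts.columns if s.startswith("control")]
    ratio = counts.loc[ids[0], treated].mean() / counts.loc[ids[0], control].mean()
    assert ratio == pytest.approx(4.0, rel=0.06)
    null_ratio = counts.loc[ids[5], treated].mean() / counts.loc[ids[5], control].mean()
    assert null_ratio == pytest.approx(1.0, rel=0.06)


def test_truth_builders_respect_pattern_invariants():
    conds = [(d, t) for d in ("low", "middle", "high") for t in (3, 7, 14, 28)]
    bm = simulate.biomarker_effect("m1")
    assert all(v >= math.log2(1.5) for v in bm.log2fc.values())
    up = simulate.constant_effect("m2", 1.0, conds)
    assert up.pattern == "constant_up"
    down = simulate.constant_effect("m3", -1.0, conds)
    assert down.pattern == "constant_down"
    mono = simulate.monotone_effect("m4", "time")
    for d in ("low", "middle", "high"):
        series = [mono.log2fc[(d, t)] for t in (3, 7, 14, 28)]
        assert series == sorted(series) and len(set(series)) == 4
    with pytest.raises(ValueError):
        simulate.constant_effect("m5", 0.2, conds)  # below the 1.5-fold floor
    with pytest.raises(ValueError):
        tm.SimulationParams(n_mirnas=10, dispersion=-0.1)


def test_counts_reject_unknown_truth_ids():
    design = generate_design(1, ["low"], [3])
    params = tm.SimulationParams(n_mirnas=5, seed=0)
    stray = simulate.constant_effect("not-a-mirna", 1.0, [("low", 3)])
    with pytest.raises(ValueError, match="not-a-mirna"):
        tm.generate_counts(design, params, [stray])


# ---------------------------------------------------------------------------
# read emission


def test_reads_exact_emission_and_empty_counts():
    ref = {"mirA": "ACGTACGTACGTACGTAC", "mirB": "TTTTAAAACCCCGGGGTT"}
    reads = simulate.generate_reads({"mirA": 3}, ref, error_rate=0.0, seed=1)
    assert len(reads) == 3
    for _name, seq, quals in reads:
        assert seq.startswith(ref["mirA"])
        assert len(seq) == len(quals) == 50
    assert simulate.generate_reads({}, ref, seed=1) == []
    with pytest.raises(KeyError, match="mirX"):
        simulate.generate_reads({"mirX": 1}, ref, seed=1)


def test_read_error_rate_produces_matching_mismatch_fraction():
    ref = {"mirA": "ACGTACGTACGTACGTACGTA"}
    n_reads, err = 2000, 0.01
    reads = simulate.generate_reads({"mirA": n_reads}, ref, error_rate=err, seed=9)
    template = (ref["mirA"] + simulate.DEFAULT_ADAPTER).ljust(50, "A")[:50]
    mismatches = sum(
        sum(a != b for a, b in zip(seq, template)) for _n, seq, _q in reads
    )
    frac = mismatches / (n_reads * 50)
    assert frac == pytest.approx(err, abs=0.002)


def test_reference_sequences_unique_and_length_bounded():
    ref = simulate.generate_reference(simulate.make_mirna_ids(200), seed=4)
    seqs = list(ref.values())
    assert len(set(seqs)) == 200
    assert all(18 <= len(s) <= 25 for s in seqs)


# ---------------------------------------------------------------------------
# target map / pathways / histopathology


def test_target_map_support_distribution():
    ids = simulate.make_mirna_ids(200)
    zero = simulate.generate_target_map(ids, 100, support_prob=0.0, seed=2)
    assert zero.empty
    full = simulate.generate_target_map(ids[:10], 50, support_prob=1.0, seed=2)
    assert (full["support"] == 7).all() and len(full) == 500
    tm_df = simulate.generate_target_map(ids, 500, support_prob=0.2, seed=2)
    # P(Binomial(7, 0.2) >= 2) = 1 - 0.8^7 - 7*0.2*0.8^6 = 0.42328...
    frac = (tm_df["support"] >= 2).sum() / tm_df.attrs["n_pairs"]
    expected = 1 - 0.8**7 - 7 * 0.2 * 0.8**6
    assert frac == pytest.approx(expected, abs=0.01)
    with pytest.raises(ValueError):
        simulate.generate_target_map(ids, 10, n_algorithms=0)


def test_pathway_collection_contains_planted_genes():
    genes = simulate.gene_ids(300)
    planted = {"hit_set": genes[:20]}
    coll = simulate.generate_pathways(genes, n_pathways=10, set_size=40, planted=planted, seed=3)
    assert set(genes[:20]) <= coll["hit_set"]
    assert len(coll["hit_set"]) == 40
    assert len(coll) == 11
    with pytest.raises(ValueError):
        simulate.generate_pathways([], 5)
    with pytest.raises(ValueError, match="unknown genes"):
        simulate.generate_pathways(genes, 5, planted={"bad": ["nope"]})


def test_histopath_step_link_is_deterministic_threshold(small_sim):
    bm = small_sim["truths"][0]
    histo = simulate.generate_histopath(
        small_sim["truths"],
        drivers={"single cell necrosis": bm.mirna_id},
        link_strength=float("inf"),
        lfc_threshold=4.0,
        conditions=small_sim["conditions"],
        seed=1,
    )
    for cond in small_sim["conditions"]:
        expected = int(abs(bm.log2fc[cond]) >= 4.0)
        assert histo.loc[cond, "single cell necrosis"] == expected
    # both classes occur for this threshold on the ramped biomarker profile
    assert 0 < histo["single cell necrosis"].sum() < len(histo)
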