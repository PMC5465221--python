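"""Synthetic data generators for every pipeline input.

The generators emulate the statistical structure of a rat-liver small-RNA
sequencing study: ~664 detected miRNAs across 48 libraries (12 treated
dose x time conditions with 3 replicates each plus time-matched controls),
negative-binomially distributed counts with a heavy-tailed abundance
profile, planted dose/time fold-change patterns, a miRNA->gene target
support table emulating the consensus of 7 prediction algorithms,
KEGG-style gene-set collections, and a condition x histopathology-feature
presence table linked to the expression of designated driver miRNAs.

All generators are deterministic given their seed; sub-streams are derived
from a single :class:`numpy.random.SeedSequence` per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_TIMEPOINTS,
    TREATED_DOSE_LEVELS,
    condition_label,
    generate_design,
    treated_conditions,
)

PATTERNS = (
    "null",
    "constant_up",
    "constant_down",
    "monotone_time",
    "monotone_dose",
    "transient",
)

#: histopathology features scored by pathologists in repeat-dose liver studies
HISTOPATH_FEATURES = (
    "nuclear alteration",
    "cellular foci",
    "cellular infiltration",
    "eosinophilic change",
    "granular eosinophilic degeneration",
    "fibrosis",
    "hypertrophy",
    "bile duct proliferation",
    "oval cell proliferation",
    "single cell necrosis",
)

#: 3' sequencing adapter ligated to mature miRNAs (TruSeq small RNA)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

MIN_FC = 1.5  # planted "consistent" patterns never drop below this fold change


@dataclass
class SimulationParams:
    """Knobs of the count simulator.

    dispersion is the negative-binomial overdispersion phi in
    Var = mu + phi * mu^2; 0 means Poisson.  lib_size_mean is the expected
    library depth (reads per library); the study-scale 1e7 is configurable
    but the default is desk-scale.  baseline_logmean_sd controls how
    heavy-tailed the per-miRNA abundance profile is (a few dominant
    species, like hepatic miR-122, at sd ~ 1.8).
    """

    n_mirnas: int = 664
    dispersion: float = 0.1
    lib_size_mean: int = 500_000
    lib_size_cv: float = 0.3
    baseline_logmean_sd: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.lib_size_mean < 1000:
            raise ValueError("lib_size_mean must be >= 1000")
        if self.lib_size_cv < 0:
            raise ValueError("lib_size_cv must be >= 0")


@dataclass
class EffectTruth:
    """Planted ground-truth effect for one miRNA.

    log2fc maps every treated (dose_level, timepoint_days) condition to the
    planted log2 fold change versus the time-matched control.
    """

    mirna_id: str
    pattern: str
    log2fc: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


def make_mirna_ids(n: int) -> list[str]:
    return [f"rno-miR-s{i:04d}" for i in range(1, n + 1)]


def _dose_time_grid(
    doses: Sequence[str] = TREATED_DOSE_LEVELS,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
) -> list[tuple[str, int]]:
    return [(d, int(t)) for t in timepoints for d in doses]


def constant_effect(
    mirna_id: str,
    log2fc: float,
    conditions: Sequence[tuple[str, int]] | None = None,
) -> EffectTruth:
    """Same planted log2FC in every treated condition (up or down)."""
    conditions = conditions or _dose_time_grid()
    pattern = "constant_up" if log2fc >= 0 else "constant_down"
    if abs(log2fc) < math.log2(MIN_FC):
        raise ValueError("constant patterns require |log2fc| >= log2(1.5)")
    return EffectTruth(mirna_id, pattern, {c: float(log2fc) for c in conditions})


def biomarker_effect(
    mirna_id: str,
    base_log2fc: float = 1.5,
    dose_step: float = 0.8,
    time_step: float = 1.2,
    doses: Sequence[str] = TREATED_DOSE_LEVELS,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
) -> EffectTruth:
    """A consistently overexpressed biomarker profile.

    Up-regulated beyond the 1.5-fold threshold in every condition, with a
    strictly monotone ramp along both the dose and the time axis — the
    profile of an early, sensitive and consistent biomarker.  The default
    step sizes exceed the fold-change estimation noise at phi = 0.1 with
    triplicates (sd ~ 0.5 log2 units per increment) by about two standard
    deviations, so the monotone profile survives estimation.
    """
    if base_log2fc < math.log2(MIN_FC):
        raise ValueError("biomarker base log2fc must be >= log2(1.5)")
    lfc = {
        (d, int(t)): base_log2fc + dose_step * di + time_step * ti
        for di, d in enumerate(doses)
        for ti, t in enumerate(sorted(timepoints))
    }
    return EffectTruth(mirna_id, "constant_up", lfc)


def monotone_effect(
    mirna_id: str,
    axis: str,
    peak_log2fc: float = 2.0,
    doses: Sequence[str] = TREATED_DOSE_LEVELS,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
) -> EffectTruth:
    """Effect strictly ordered along one axis (time or dose), flat in the other."""
    if axis not in ("time", "dose"):
        raise ValueError("axis must be 'time' or 'dose'")
    timepoints = sorted(int(t) for t in timepoints)
    lfc: dict[tuple[str, int], float] = {}
    if axis == "time":
        steps = np.linspace(peak_log2fc / len(timepoints), peak_log2fc, len(timepoints))
        for d in doses:
            for ti, t in enumerate(timepoints):
                lfc[(d, t)] = float(steps[ti])
        pattern = "monotone_time"
    else:
        steps = np.linspace(peak_log2fc / len(doses), peak_log2fc, len(doses))
        for di, d in enumerate(doses):
            for t in timepoints:
                lfc[(d, t)] = float(steps[di])
        pattern = "monotone_dose"
    return EffectTruth(mirna_id, pattern, lfc)


def transient_effect(
    mirna_id: str,
    peak_log2fc: float = 2.0,
    doses: Sequence[str] = TREATED_DOSE_LEVELS,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
) -> EffectTruth:
    """Early response that decays back to baseline at late timepoints."""
    timepoints = sorted(int(t) for t in timepoints)
    weights = np.linspace(1.0, 0.0, len(timepoints))
    lfc = {
        (d, t): float(peak_log2fc * weights[ti])
        for d in doses
        for ti, t in enumerate(timepoints)
    }
    return EffectTruth(mirna_id, "transient", lfc)


def plant_effects(
    mirna_ids: Sequence[str],
    n_planted: int = 50,
    seed: int = 0,
    lfc_range: tuple[float, float] = (1.0, 2.0),
    frac_down: float = 0.5,
    biomarker: bool = True,
    conditions: Sequence[tuple[str, int]] | None = None,
) -> list[EffectTruth]:
    """Plant constant up/down effects on a random subset of miRNAs.

    The first planted miRNA (when ``biomarker`` is true) receives the
    consistently-up biomarker ramp; the rest get constant effects with
    |log2FC| drawn uniformly from ``lfc_range`` (at least 1 by default, so
    every planted effect exceeds the 1.5-fold call threshold) and sign
    down with probability ``frac_down``.
    """
    if n_planted > len(mirna_ids):
        raise ValueError("cannot plant more effects than miRNAs")
    if lfc_range[0] < math.log2(MIN_FC):
        raise ValueError("planted |log2fc| must be >= log2(1.5)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    chosen = rng.choice(len(mirna_ids), size=n_planted, replace=False)
    truths: list[EffectTruth] = []
    for j, idx in enumerate(chosen):
        mid = mirna_ids[idx]
        if biomarker and j == 0:
            truths.append(biomarker_effect(mid))
            continue
        mag = rng.uniform(*lfc_range)
        sign = -1.0 if rng.random() < frac_down else 1.0
        truths.append(constant_effect(mid, sign * mag, conditions))
    return truths


def truth_table(truths: Iterable[EffectTruth]) -> pd.DataFrame:
    """Long-format truth table: mirna_id, pattern, dose_level, timepoint_days, log2fc."""
    rows = []
    for t in truths:
        for (dose, tp), lfc in sorted(t.log2fc.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            rows.append(
                {
                    "mirna_id": t.mirna_id,
                    "pattern": t.pattern,
                    "dose_level": dose,
                    "timepoint_days": tp,
                    "log2fc": lfc,
                }
            )
    return pd.DataFrame(
        rows, columns=["mirna_id", "pattern", "dose_level", "timepoint_days", "log2fc"]
    )


def generate_counts(
    design: pd.DataFrame,
    params: SimulationParams,
    truths: Sequence[EffectTruth] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the miRNA x sample count matrix.

    Per-miRNA relative abundances come from a normalized log-normal profile
    (heavy-tailed: a handful of dominant species).  Library sizes are
    log-normal around ``lib_size_mean``.  Counts are NB with
    mean = abundance_i * libsize_j * 2**log2fc(i, condition_j) and
    Var = mu + phi * mu^2; control columns always use log2fc = 0.

    Returns (counts DataFrame, long-format truth table).
    """
    ss = np.random.SeedSequence(params.seed)
    rng_base, rng_lib, rng_counts = (np.random.default_rng(s) for s in ss.spawn(3))

    mirna_ids = make_mirna_ids(params.n_mirnas)
    known = [t.mirna_id for t in truths]
    missing = set(known) - set(mirna_ids)
    if missing:
        raise ValueError(f"truth names miRNAs outside the simulated set: {sorted(missing)}")
    if len(set(known)) != len(known):
        raise ValueError("duplicate miRNA ids in truth")

    z = rng_base.normal(0.0, params.baseline_logmean_sd, params.n_mirnas)
    abundance = np.exp(z)
    abundance /= abundance.sum()

    n_samples = len(design)
    if params.lib_size_cv > 0:
        sigma2 = math.log1p(params.lib_size_cv**2)
        mu = math.log(params.lib_size_mean) - sigma2 / 2
        lib_sizes = rng_lib.lognormal(mu, math.sqrt(sigma2), n_samples)
    else:
        lib_sizes = np.full(n_samples, float(params.lib_size_mean))

    lfc_by_mirna = {t.mirna_id: t.log2fc for t in truths}
    idx_of = {m: i for i, m in enumerate(mirna_ids)}

    counts = np.zeros((params.n_mirnas, n_samples), dtype=np.int64)
    for j, row in enumerate(design.itertuples()):
        fold = np.ones(params.n_mirnas)
        if row.dose_level != "control":
            cond = (str(row.dose_level), int(row.timepoint_days))
            for mid, table in lfc_by_mirna.items():
                fold[idx_of[mid]] = 2.0 ** table.get(cond, 0.0)
        mu_col = abundance * lib_sizes[j] * fold
        if params.dispersion == 0:
            counts[:, j] = rng_counts.poisson(mu_col)
        else:
            r = 1.0 / params.dispersion
            p = r / (r + mu_col)
            counts[:, j] = rng_counts.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=mirna_ids, columns=design["sample_id"].tolist())
    counts_df.index.name = "mirna_id"
    return counts_df, truth_table(truths)


# ---------------------------------------------------------------------------
# read-level simulation


def generate_reference(
    mirna_ids: Sequence[str],
    seed: int = 0,
    min_len: int = 18,
    max_len: int = 25,
) -> dict[str, str]:
    """Random unique mature sequences, 18-25 nt, one per miRNA."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    seen: set[str] = set()
    for mid in mirna_ids:
        while True:
            length = int(rng.integers(min_len, max_len + 1))
            seq = "".join(bases[rng.integers(0, 4, length)])
            if seq not in seen:
                seen.add(seq)
                seqs[mid] = seq
                break
    return seqs


def generate_reads(
    counts: Mapping[str, int] | pd.Series,
    reference: Mapping[str, str],
    adapter: str = DEFAULT_ADAPTER,
    read_length: int = 50,
    error_rate: float = 0.0,
    mean_quality: int = 38,
    quality_sd: float = 2.0,
    seed: int = 0,
) -> list[tuple[str, str, list[int]]]:
    """Emit sequencing reads for one library column.

    Each miRNA i yields exactly counts[i] reads whose sequence is the
    mature sequence followed by the 3' adapter, padded with 'A' / truncated
    to ``read_length``.  Substitution errors are applied uniformly at
    ``error_rate``; per-base qualities are Phred values around
    ``mean_quality``.  Returns (name, sequence, phred_qualities) tuples in
    deterministic order; write with :func:`toxmir.io.write_fastq`.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if isinstance(counts, pd.Series):
        counts = counts.to_dict()
    for mid in counts:
        if mid not in reference:
            raise KeyError(f"miRNA {mid!r} absent from reference")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    bases = "ACGT"
    reads: list[tuple[str, str, list[int]]] = []
    for mid in sorted(counts):
        n = int(counts[mid])
        if n < 0:
            raise ValueError(f"negative count for {mid!r}")
        template = (reference[mid] + adapter).ljust(read_length, "A")[:read_length]
        for k in range(n):
            seq = list(template)
            if error_rate > 0:
                hits = np.flatnonzero(rng.random(read_length) < error_rate)
                for pos in hits:
                    alternatives = bases.replace(seq[pos], "")
                    seq[pos] = alternatives[int(rng.integers(0, 3))]
            quals = np.clip(
                np.rint(rng.normal(mean_quality, quality_sd, read_length)), 2, 41
            ).astype(int)
            reads.append((f"{mid}_read{k + 1}", "".join(seq), quals.tolist()))
    return reads


# ---------------------------------------------------------------------------
# target map, pathways, histopathology


def generate_target_map(
    mirna_ids: Sequence[str],
    n_genes: int,
    n_algorithms: int = 7,
    support_prob: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """miRNA->gene prediction-support table.

    For every (miRNA, gene) pair the number of supporting prediction
    algorithms is Binomial(n_algorithms, support_prob); only pairs with
    support >= 1 are materialized.  Gene universe is ``gene_ids``
    g0001..gN; retrieve it with :func:`target_universe`.
    """
    if n_algorithms < 1:
        raise ValueError("n_algorithms must be >= 1")
    if not 0 <= support_prob <= 1:
        raise ValueError("support_prob must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    genes = gene_ids(n_genes)
    support = rng.binomial(n_algorithms, support_prob, size=(len(mirna_ids), n_genes))
    mi, gi = np.nonzero(support)
    df = pd.DataFrame(
        {
            "mirna_id": np.asarray(mirna_ids, dtype=object)[mi],
            "gene_id": np.asarray(genes, dtype=object)[gi],
            "support": support[mi, gi],
        }
    )
    df.attrs["n_algorithms"] = n_algorithms
    df.attrs["n_pairs"] = len(mirna_ids) * n_genes
    df.attrs["genes"] = genes
    return df


def gene_ids(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(1, n_genes + 1)]


def generate_pathways(
    genes: Sequence[str],
    n_pathways: int = 50,
    set_size: int = 40,
    planted: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """KEGG-style gene-set collection: random sets plus optional planted sets.

    ``planted`` maps set name -> member genes (must exist in ``genes``);
    planted sets are topped up with random genes to ``set_size`` when
    smaller.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene universe")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    collection: dict[str, set[str]] = {}
    planted = dict(planted or {})
    universe = set(genes)
    for name, members in planted.items():
        members = set(members)
        stray = members - universe
        if stray:
            raise ValueError(f"planted set {name!r} names unknown genes: {sorted(stray)[:5]}")
        if len(members) < set_size:
            pool = [g for g in genes if g not in members]
            extra = rng.choice(len(pool), size=set_size - len(members), replace=False)
            members |= {pool[i] for i in extra}
        collection[name] = members
    for i in range(1, n_pathways + 1):
        name = f"pathway_{i:03d}"
        if name in collection:
            continue
        idx = rng.choice(len(genes), size=min(set_size, len(genes)), replace=False)
        collection[name] = {genes[j] for j in idx}
    return collection


def generate_histopath(
    truths: Sequence[EffectTruth],
    drivers: Mapping[str, str],
    link_strength: float = 4.0,
    lfc_threshold: float = 1.0,
    conditions: Sequence[tuple[str, int]] | None = None,
    features: Sequence[str] = HISTOPATH_FEATURES,
    seed: int = 0,
) -> pd.DataFrame:
    """Condition x feature binary histopathology table.

    Each feature is driven by one designated miRNA: presence is Bernoulli
    with logit = link_strength * (|log2fc_driver(condition)| - lfc_threshold).
    link_strength 0 makes features independent of expression (AUC 0.5);
    link_strength = inf gives a deterministic step at |log2fc| >=
    lfc_threshold (AUC 1 for the driver).  Undriven features are Bernoulli(0.5).
    """
    conditions = list(conditions or _dose_time_grid())
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    lfc_by_mirna = {t.mirna_id: t.log2fc for t in truths}
    for feat, mid in drivers.items():
        if feat not in features:
            raise ValueError(f"unknown feature {feat!r}")
        if mid not in lfc_by_mirna:
            raise ValueError(f"driver miRNA {mid!r} has no planted truth")
    data = np.zeros((len(conditions), len(features)), dtype=int)
    for fi, feat in enumerate(features):
        driver = drivers.get(feat)
        for ci, cond in enumerate(conditions):
            if driver is None:
                p = 0.5
            else:
                x = abs(lfc_by_mirna[driver].get(cond, 0.0)) - lfc_threshold
                if math.isinf(link_strength):
                    p = 1.0 if x >= 0 else 0.0
                else:
                    p = 1.0 / (1.0 + math.exp(-link_strength * x))
            data[ci, fi] = int(rng.random() < p)
    index = pd.MultiIndex.from_tuples(conditions, names=["dose_level", "timepoint_days"])
    return pd.DataFrame(data, index=index, columns=list(features))
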