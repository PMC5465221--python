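# Methods

This note documents the models behind `toxmir`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical decisions that pin down bit-reproducibility.

## Study design

The default design emulates a repeat-dose rodent hepatotoxicity study:
three dose levels (low 4.5, middle 15, high 45 mg/kg) × four treatment
durations (3, 7, 14, 28 days) × three profiled replicates, plus one
time-matched vehicle control group of three replicates per timepoint —
48 libraries, 12 treated conditions. Every treated group is compared only
against its time-matched control, never against a pooled control, because
control expression drifts with animal age. The control-group replicate
count defaults to the treated count (three), the structure consistent
with 48 total libraries.

## Count simulation

Counts are negative-binomial: `count_ij ~ NB(mean μ_ij, Var μ + φμ²)`
with

```
μ_ij = a_i · L_j · 2^{Δ_i(c_j)}
```

where `a` is a per-miRNA relative-abundance profile (normalized
exp-normal with log-sd `baseline_logmean_sd`, default 1.8 — heavy-tailed,
so a few species dominate the library the way hepatic miR-122 does),
`L_j` a log-normal library size (default mean 5·10⁵ reads, CV 0.3; study
scale, ~10⁷, is configurable but desk-scale keeps simulations fast at
identical statistical structure since inference is dispersion-limited,
not depth-limited, at these counts), and `Δ_i(c)` the planted log2
fold-change of miRNA i in treated condition c (0 for controls and null
miRNAs). The dispersion default φ = 0.1 corresponds to a biological
coefficient of variation of ~0.32 between replicate animals, typical for
bulk tissue. With 664 simulated miRNAs the defaults mirror the size of a
detected rat-liver miRNA complement.

Planted effect patterns: `null`, `constant_up`/`constant_down` (same
log2FC, magnitude ≥ log2 1.5, in every condition; recovery experiments
draw |log2FC| ~ U[1, 2]), `monotone_time`, `monotone_dose` (strictly
ordered along one axis), and `transient` (early response decaying to
baseline). The designated biomarker is a `constant_up` profile with a
strictly monotone ramp along both axes: base log2FC 1.5, +0.8 per dose
step, +1.2 per time step. The ramp steps were sized against the
fold-change estimation noise: at φ = 0.1 with triplicates the estimated
log2FC has sd ≈ 0.4, so a consecutive-condition increment has sd ≈ 0.5–0.6
and each planted step clears it by roughly two standard deviations,
making strict-monotone trend classification of the biomarker reliable
(Monte-Carlo success ≈ 0.99). Flat or shallow ramps are destroyed by
estimation noise and classified unresponsive — which is correct behaviour
of the classifier, not a bug. The resulting maximum log2FC (6.7) is
larger than typical reported biomarker inductions (~4.7) but of the same
order.

Read-level simulation emits, per miRNA, exactly `count` reads of the
mature sequence plus the 3′ TruSeq small-RNA adapter, padded to 50 nt,
with uniform substitution errors and Gaussian Phred qualities (mean 38).
Not emulated: indels, machine-specific error profiles, multiplex
barcodes, unmappable genomic background reads, isomiR length variants.
Passing round-trip tests therefore demonstrate the correctness of the
trim → filter → assign bookkeeping, not robustness to real base-caller
artifacts.

## Read processing

Adapter trimming truncates at the leftmost occurrence of the adapter
prefix with minimum overlap 5. Kept reads satisfy 18 ≤ length ≤ 25 and
mean Phred ≥ 30; the quality rule is applied per read (the sample-level
QC of sequencing practice reduced to an executable per-read rule).
Assignment is full-length matching against the mature reference with a
configurable substitution allowance (default 0); reads with two or more
equally good best hits are dropped as ambiguous rather than fractionally
assigned. Genome-level mapping as a contamination check is out of scope.

## Normalization

RPM then upper-quartile: the per-sample factor is the 75th percentile
(linear interpolation, the numpy/R type-7 definition — pinned for
reproducibility) over miRNAs with a nonzero row total; columns are
divided by their factor and rescaled by the geometric mean of all factors
so the grand scale stays in RPM-equivalent units. The 5-RPM abundance
filter removes a miRNA only when it is below threshold in **every**
library: the filter's purpose is to eliminate normalization artifacts
from species absent in one or more samples, which only globally-absent
species can cause. (Per-sample or per-group variants of this rule exist;
all-samples is this package's documented choice.)

## Differential expression

The exact test conditions on the two-group total of depth-equalized
counts. For i.i.d. NB replicates with common mean and dispersion φ, group
sums are NB with sizes n_A/φ, n_B/φ and a shared success probability, so
the conditional law of the group-A sum is negative-hypergeometric —
closed-form and free of the mean. Equalization rounds each count to the
geometric-mean library depth. Two-sided p-values sum all outcome
probabilities ≤ the observed probability, with a relative tie tolerance
of 10⁻¹² to stabilise floating-point equality; p is clamped to (0, 1] and
returns exactly 1 when the observed outcome is modal. φ = 0 is handled as
the conditional binomial.

The common dispersion is a pooled method-of-moments estimate: per miRNA
and replicate group, φ̂ = (v − m)/m² on depth-equalized counts, averaged
over groups, clipped at 0, median across miRNAs. It recovers φ = 0.1 to
within [0.05, 0.2] on the default design and returns ~0 for Poisson
data. Limitation: with only 2–3 replicates per group the estimate is
biased slightly downward (φ̂ ≈ 0.08 at φ = 0.1), which makes the
estimated-φ test mildly anticonservative (null rejection ≈ 0.07 at
nominal 0.05); given the true φ the test is calibrated (≈ 0.050). No
tagwise/empirical-Bayes shrinkage is attempted — common dispersion is the
smallest faithful implementation, and the DEM call rule is
fold-change-dominated anyway.

DEM rule: FC > 1.5 or FC < 1/1.5 (strict) **and** p < 0.05, on raw
p-values with no multiplicity correction — deliberately mirroring the
per-condition call rule of the source workflow; adjustment is reserved
for enrichment. Fold changes use group means of normalized values with a
pseudocount of 0.5 (unstated in the source; 0.5 keeps FC finite for
zero-count controls without swamping small means).

### Consistency filtering and error control

Because per-condition calls are uncorrected, the 12-condition DEM union
accumulates false positives (~0.05 × 614 null miRNAs × 12 conditions in
the default simulation — a pair-level FDR near 0.4). Specificity comes
from the replication step of the workflow, not from the per-condition
rule: biomarker recovery keeps miRNAs called DEM in at least **half** the
treated conditions (6 of 12). Correlated false calls are possible because
the three doses at a timepoint share one control group, so a
one-timepoint threshold is insufficient; the majority rule yields
sensitivity ≥ 0.9 and FDR ≤ 0.05 for planted effects with |log2FC| ≥ 1 at
φ = 0.1. `common_dems(min_conditions=12)` is the strictest variant
(DEM in every condition).

## Trend classification

A dose-series (fold change across the four ordered timepoints) is
*increasing*/*decreasing* only when strictly monotone; ties — relative
tolerance 10⁻⁹ — break the pattern (a non-strict mode tolerates ties but
still rejects reversals). Time-responsive ⇔ ≥ 2 of 3 dose series are
monotone; dose-responsive ⇔ ≥ 2 of 4 timepoint series are monotone along
the three ordered doses. Directions may differ between qualifying series
(the literal reading); `require_same_direction=True` restricts to
coherent trends. Classification uses fold changes from **all**
conditions, not only DEM-flagged ones; restricting to a candidate list is
available through the `mirnas` argument. Note that with only three doses
a random profile is monotone per series with probability 1/3, so ~40% of
unselected miRNAs are "dose-responsive" by chance — the classifier is a
descriptive label for already-selected candidates, not a test.

## Enrichment

Consensus targets keep (miRNA, gene) pairs supported by ≥ 2 of 7
prediction algorithms. Overrepresentation is the one-sided hypergeometric
tail P(X ≥ k) (equivalent to one-tailed Fisher's exact on the 2×2
table), with N = |universe|, K = pathway size in the universe, n = query
size, k = overlap. The universe defaults to all genes in the target map;
the collection union is available as an alternative policy. Adjustment is
Benjamini–Hochberg step-up by default ("BH"); Holm step-down is a switch.
The significance cutoff (5%) applies to adjusted p-values. Curated
(experimentally-observed) target sets run through the same engine with
`n_algorithms=1, min_support=1`.

## Histopathology ROC

Fold changes per treated condition become a confidence matrix: continuous
score |log2FC| plus a binary companion thresholded at 1.5-fold (strict).
The continuous score is what ROC ranking uses — a purely binary score
degenerates to a single operating point; the binary matrix is emitted for
transparency. The low-dose 3-, 7- and 14-day conditions are excluded by
default (no histopathological findings there), leaving 9 condition
observations. AUC is the Mann–Whitney concordance with half-credit ties;
pairs whose feature labels are single-class over the retained conditions
get a missing AUC with a reason rather than a number. Observations are
conditions, not animals; a per-animal mode simply requires replicate-level
fold changes as input. The synthetic histopathology table links each
feature to one designated driver miRNA through a logistic function of
|log2FC| (link strength 0 ⇒ independence, AUC 0.5; ∞ ⇒ deterministic
step, AUC 1 for the driver), which makes ROC recovery well-posed.

## Reproducibility and problem sizes

Every generator and the pipeline derive all randomness from one seed via
`numpy.random.SeedSequence` sub-streams, so a (config, seed) pair is
bit-reproducible. Test and acceptance problem sizes are the package's
defaults: 664 miRNAs × 48 libraries at 5·10⁵ reads/library for recovery
experiments, 5000 feature-tests for type-I calibration, exhaustive
enumeration up to totals of 30 (exact test) and universes of 25
(hypergeometric), ≥ 1000 (miRNA, feature) pairs for null-link ROC — sizes
at which the Monte-Carlo bands quoted above are sharp while a full run
completes in well under a minute per stage.

## Known limitations

- Common (not tagwise) dispersion; no GLM/covariates; slight downward
  MoM bias at triplicate scale (see above).
- The simulator plants multiplicative effects only; no composition
  shifts, batch structure, or correlated miRNA programs. Recovery results
  therefore bound performance under the model's own assumptions.
- Trend classification is descriptive (no monotone-trend test such as
  Jonckheere–Terpstra, no benchmark-dose modelling).
- Enrichment treats gene sets as unstructured; no topology or
  redundancy correction.
- ROC on 9 condition-level observations has coarse (1/n₊n₋) AUC
  granularity; per-animal scoring is preferable when replicate-level
  fold changes are available.
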