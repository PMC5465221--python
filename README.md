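# toxmir

Dose–time toxicogenomic miRNA biomarker discovery from small-RNA
sequencing counts.

`toxmir` is a reusable, tested implementation of a biomarker-discovery
workflow for repeat-dose rodent toxicity studies: liver miRNA expression
is profiled at several doses of a hepatotoxicant (low / middle / high,
e.g. 4.5 / 15 / 45 mg/kg) over several treatment durations (3, 7, 14, 28
days) with time-matched vehicle controls, and the goal is to find miRNAs
that respond early, sensitively and consistently — candidates for
carcinogenicity biomarkers that precede visible histopathology. The
package takes raw reads (FASTQ) or a miRNA × library count table and
carries the analysis through differential expression, trend
classification, consistent-biomarker selection, target-set enrichment and
expression-vs-histopathology ROC. A first-class synthetic-data module
generates every input with the statistical structure the analysis
assumes, so the whole pipeline is testable without any data download.

## The statistics at the core

**Differential expression.** For each treated condition (dose, timepoint)
versus its time-matched control, counts are compared with an exact
conditional negative-binomial test. Counts are NB with mean μ and
variance μ + φμ² (common dispersion φ, method-of-moments estimate pooled
over miRNAs). After equalizing replicates to the geometric-mean library
depth, the sums of the two groups are NB with sizes n_A/φ and n_B/φ and a
shared success probability, so conditional on the total the group-A sum
follows a closed-form negative-hypergeometric law that does not depend on
the unknown mean; the two-sided p-value sums the probabilities of all
outcomes no more likely than the one observed. φ = 0 reduces to the
classical conditional binomial test. A miRNA is a DEM in a condition when
FC > 1.5 or FC < 1/1.5 (fold change on RPM + upper-quartile-normalized
values, pseudocount 0.5) and p < 0.05.

**Normalization.** Reads per million (count·10⁶ / library size) followed
by upper-quartile scaling: each library is divided by the 75th percentile
of its expressed-miRNA values and rescaled by the geometric mean of all
factors; miRNAs below 5 RPM in every library are removed.

**Trends and biomarkers.** A miRNA is *time-responsive* when its
fold-change profile is strictly monotone along the four timepoints in at
least two dose levels, and *dose-responsive* when monotone along the
three doses in at least two timepoints. Consistent biomarkers are miRNAs
called DEM in many conditions (`common_dems`), ranked by breadth and
mean |log2FC|.

**Enrichment.** Predicted miRNA→gene interactions are kept when supported
by ≥ 2 of 7 prediction algorithms; the target union of a DEM list is
tested against each gene set with the one-sided hypergeometric tail
P(X ≥ k) and Benjamini–Hochberg adjustment (Holm available).

**Histopathology ROC.** Per-condition |log2FC| scores (conditions without
any findings excluded) are scored against binary histopathological
features with the Mann–Whitney AUC,
(#{s⁺ > s⁻} + ½·#{s⁺ = s⁻}) / (n₊ n₋).

## Worked example

`examples/01_simulate_and_call_dems.py` simulates the default study (664
miRNAs, 48 libraries, 50 planted effects, φ = 0.1) and calls DEMs:

```
48 libraries, 12 treated conditions
count matrix: 664 miRNAs x 48 libraries, median depth 460288
common NB dispersion estimate: phi = 0.096 (true 0.1, 664 features)
    high  3d:  37 up /  35 down DEMs
    ...
  middle 28d:  53 up /  25 down DEMs
unique DEMs across all conditions: 324
```

Per-condition calls use raw p-values, so the 324-miRNA union contains
one-off false positives. `examples/02_trends_and_biomarkers.py` applies
the cross-condition replication filter and the trend classifiers:

```
consistent DEMs (>= 6 of 12 conditions): 50; sensitivity 1.00, false discoveries 0
time-responsive 4, dose-responsive 21, both 2
top-ranked candidate: rno-miR-s0006 (planted biomarker = rno-miR-s0006),
DEM in 12/12 conditions, mean |log2FC| 4.12, sign-consistent: True
```

All 50 planted effects are recovered with no false discovery, and the
planted consistently-up biomarker ranks first and is classified both
time- and dose-responsive. The remaining examples demonstrate target-set
enrichment (the planted pathway dominates at p ≈ 10⁻¹¹⁷), the
histopathology ROC (AUC 1.0 for the driving miRNA), and the end-to-end
pipeline (`toxmir run --outdir out --seed 1` from a shell, or
`run_pipeline(PipelineConfig(seed=1))` from Python).

## Layout

- `src/toxmir/design.py` — dose/timepoint/replicate design tables
- `src/toxmir/simulate.py` — generators: counts, reads, reference,
  target map, pathways, histopathology
- `src/toxmir/readproc.py` — adapter trimming, length/quality filters,
  read assignment
- `src/toxmir/normalize.py` — RPM, upper-quartile, abundance filter,
  replicate correlation
- `src/toxmir/detest.py` — dispersion estimation, exact NB test, DEM calls
- `src/toxmir/trends.py` — DEM set algebra, trend classifiers, common DEMs
- `src/toxmir/enrichment.py` — target filtering, hypergeometric
  overrepresentation, BH/Holm
- `src/toxmir/histopath.py` — confidence matrix, Mann–Whitney AUC
- `src/toxmir/pipeline.py`, `src/toxmir/cli.py` — orchestration and the
  thin `toxmir` command (`simulate`, `quantify`, `run`, `report`)

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
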