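# Methods

## The assay model

The pipeline consumes long-format concentration tables from a bead-based
multiplex immunoassay: one row per (tumor, stimulation condition, analyte)
with a concentration in pg/ml and a censoring flag. Conditions are the
unstimulated medium control, an isotype-antibody control, anti-CD3/anti-CD28
TCR cross-linking, anti-PD-1 alone, and anti-PD-1-based combinations. All
scores are built from fold ratios FR = c_stim / c_medium per tumor and
analyte, because multiplicative changes are the natural effect scale for
positive, right-skewed secretion data.

### Censoring policy

Below-LLOQ values are stored as the reported LLOQ with a flag, never as
zero. When the *reference* (medium) value is below the LLOQ and the
stimulated value is quantifiable, the reference is replaced by LLOQ/2
before division — the standard half-LLOQ substitution, which avoids
spuriously infinite fold ratios while preserving the direction of a real
induction. When both operands are censored low, or either is missing, the
fold ratio is missing and the applied policy is recorded per cell. A
`strict` policy that discards any censored operand is available.

### Scores

* **TCR-dependent selection.** An analyte is TCR-dependent when its cohort
  median FR under TCR cross-linking strictly exceeds 1.5. Medians are
  taken over non-missing tumors; analytes observed in fewer than two
  tumors are skipped with a warning.
* **IRS.** Count of TCR-dependent analytes with FR ≥ 1.5 under anti-PD-1,
  transformed to a percent of the panel size and rounded to two decimals.
  With the canonical 17-analyte panel the positivity cutoff 41.18 is
  identical to "at least 7 positives" — asserted in tests over all 18
  achievable counts. The comparison is ≥ by default (a `strict_positivity`
  flag gives >; the 7/17 arithmetic is unaffected either way). Missing
  analytes count as non-positive under the fixed-denominator convention,
  so missingness can only lower a score; a `denominator="evaluable"`
  option is provided and logged when used.
* **HRS.** Count of all panel analytes with FR < 0.1 under anti-PD-1.
  Classification is strict `> median` against the cohort median by
  default; the published fixed threshold is quoted both as 5.5 and 5.55,
  so a user-supplied fixed threshold near that pair triggers a warning
  and both conventions (`strict` flag) are retained.
* **Cutoff optimization.** Candidates are the achievable IRS values
  k·100/17 (the score is discrete; continuous candidates add nothing).
  For each candidate: sensitivity and specificity of IRS_high against the
  cluster labels, and the positive likelihood ratio sens/(1−spec) with a
  Haldane +0.5 correction on all four confusion cells whenever
  specificity is exactly 1 (otherwise every perfectly-specific candidate
  would be infinite and incomparable). The maximizer wins; ties go to the
  larger Youden J, then the smaller cutoff. An exhaustive independent
  search validates the optimizer on 200 random instances in the tests.
* **Rescue.** A tumor below the cutoff on anti-PD-1 alone is rescued when
  any *tested* combination reaches the cutoff; untested combinations stay
  untested and never count as failures. Best-condition ties break by a
  documented fixed condition order (sorted names unless supplied).

## Cluster classifier

Anti-PD-1 fold ratios are log2-transformed and z-scored per analyte across
tumors. The z-score uses the population (n) denominator — a convention
fixed for exact reproducibility; sample (n−1) is available by flag.
Analytes with fewer than two observations or zero variance are dropped
with a warning. Tumors and analytes are clustered agglomeratively and the
tumor tree is cut at k = 2; the group with the higher grand-mean z is
R_clus (an exact tie is an error demanding manual assignment). Two
distance/linkage pairs are first-class — Euclidean/Ward and
correlation/average — because the protocol this reproduces is documented
both ways; reports record which was used, and neither is silently
preferred. Missing cells are never imputed: pairwise distances use
pairwise-complete coordinates rescaled by the fraction observed
(d² · p/p_obs), which reduces exactly to the ordinary distance on
complete data.

## Biomarker statistics

Two-sided Wilcoxon rank-sum per feature between IRS classes: exact when
the combined sample is ≤ 25 without ties, normal approximation with tie
and continuity correction otherwise; Benjamini–Hochberg correction within
each analysis family (supernatant factors and phenotype features
separately, matching how such screens are reported). Volcano ratio uses
the group mean by default (median by flag — which central the original
figures used is not stated, so both are computed); a zero central is
replaced by half the smallest positive central in the family and flagged.
Flow-phenotype features acquired on fewer than 500 events are retained
but flagged unusable and excluded from statistics by default. Spearman
matrices use midranks and a t-approximation for p, with a minimum pair
count (default 5) below which an entry stays missing.

## Survival validation

Kaplan–Meier, log-rank and Cox (Efron ties, Wald CI) delegate to
lifelines. The maximally selected rank-statistic scan is implemented
directly: for every distinct biomarker value whose low/high split keeps
the low-group fraction within quantile bounds (default 0.1–0.9 — the
bounds used by canonical implementations; the source protocol does not
state them), the signed standardized log-rank statistic Z = (O−E)/√V is
computed, and the cutpoint maximizing |Z| is selected (ties → lower
value). Significance is by permutation of the biomarker across patients
with add-one correction, p = (1 + #{max|Z|ᵖᵉʳᵐ ≥ max|Z|}) / (B+1) —
exactly reproducible at desk scale and assumption-free, in place of the
asymptotic improved-Bonferroni approximation. Note that under complete
survival separation the standardized statistic can peak at a small, pure
low group rather than the visual center of a biomarker gap; this is a
known property of maximally selected statistics and the reason the
quantile bounds exist. The median-split analysis is the fixed-split
special case of the same machinery.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the summary level the pipeline consumes (no bead fluorescence, standard
curves, or cytometry events):

    conc[t, c, a] = baseline[t, a] · effect[t, c, a] · noise[t, c, a]

* **Baselines** are lognormal per analyte (log-means staggered over
  ~3–6.2 log-pg/ml to mimic the orders-of-magnitude spread of cytokine
  abundances; log-SD 1.0).
* **Effects.** Medium and isotype have effect 1 (the isotype control is
  the medium condition plus independent noise — no systematic effect).
  TCR cross-linking multiplies every inducible analyte by
  exp(N(log 3, 0.45)), so cohort medians sit well above the 1.5 selection
  threshold while non-inducible analytes stay near 1. Responders
  re-engage the program under anti-PD-1: a strong subset of ≥ 9 inducible
  analytes (effects clipped at ≥ 2.0, keeping every designed responder
  comfortably past the 7-positive classification bar under 20%
  measurement noise) plus a mild 1.1–1.8× lift on the rest of the panel —
  responder tumors show most analytes elevated, which is what lets the
  unsupervised classifier find them.
* **Suppression.** PD-1 engagement suppresses scattered analytes below
  0.1 in most non-responding tumors (background rate 0.18 per analyte), so
  the cohort-median hypo-responsive count is nonzero, as observed in such
  assays. Hypo-responders carry a dedicated block of ≥ 9 suppressed
  analytes whose depth is tied to the tumor's CCR5⁺CTLA4⁺ Treg fraction
  through a logistic link (Treg fractions: Beta(6,18) for hypo-responders,
  Beta(2,38) otherwise). An earlier design that confined suppression to
  the hypo-responder class made those tumors geometric outliers that
  captured the k = 2 dendrogram cut; spreading suppression across the
  cohort is both more faithful and restores the responder/non-responder
  structure as the dominant axis.
* **Rescue.** Half of non-responders (configurable) draw 1–3 rescuing
  combination conditions, which receive responder-like boosts on a
  tumor-specific subset — reproducing a variegated rescue profile.
* **Noise and censoring.** Mean-1 lognormal noise with CV 0.2 by default;
  LLOQ 2 pg/ml and ULOQ 50,000 pg/ml clamp reported values with flags;
  2% of cells go missing at random. With CV 0, no missingness and
  degenerate bounds, realized fold ratios equal the designed effects
  exactly (asserted in tests).
* **Classes and reproducibility.** Class counts are deterministic,
  round(fraction · n) — a responder fraction of 7/42 yields exactly seven
  responders — with random assignment to tumors. One root seed sequence
  is split up front into per-tumor streams plus cohort and survival
  streams, so identical (config, seed) pairs are bit-identical and
  per-tumor draws are independent of generation order.
* **Survival.** A separate 90-patient cohort with standardized log
  expression of the designated prognostic analyte (CXCL10 by default),
  hazard h₀·exp(β·z) with β = −0.8 (higher expression protective),
  12-month baseline median PFS, administrative censoring uniform on 6–36
  months.

### What the generator does not emulate

Histotype-specific secretion profiles, batch/plate effects, correlated
analyte noise within biological pathways, informative missingness, and
any coupling between the tumor cohort and the survival cohort (the
survival stage validates one expression value per patient, as in the
analysis it reproduces). Passing recovery tests therefore demonstrates
that the pipeline's inference machinery is correct under the assumed
generative structure — not that the structure captures every property of
real assay data.

## Problem sizes and test design

The test suite exercises cohorts of 20–42 tumors and recovery sweeps of
12–25 seeds, with survival cohorts of 90 patients and permutation counts
of 49–2,000; these sizes give stable Monte-Carlo margins for every
asserted rate (e.g. label-recovery ≥ 90%, CI coverage 85–100%) while
keeping the whole suite fast. Property-based suites run 100–120 generated
cases per invariant. Oracle checks pit each bespoke optimizer against an
independent exhaustive implementation: the cutoff optimizer against full
candidate enumeration, exact Wilcoxon p against complete rank-partition
enumeration (combined n ≤ 10), the maxstat scan against brute-force split
evaluation, and the Cox coefficient against a grid search of the partial
likelihood.

## Known limitations

* The identity of the 17 TCR-dependent analytes is a configurable
  convention in the generator (the selection stage derives it from data,
  as intended); real panels may select a different membership.
* The clustering recovery property holds in aggregate (mean per-tumor
  accuracy ≈ 0.96 over seeds); occasional seeds still split the
  hypo-responder block first, which is an honest property of k = 2 cuts
  on three-class structure.
* Combination-condition IRS uses the medium reference (the same as the
  single-agent score); referencing anti-PD-1-alone instead is exposed as
  an option, since the original convention is not documented.
* The maxstat permutation p replaces, and is not numerically identical
  to, the asymptotic selection-adjusted approximation used by canonical
  implementations.
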