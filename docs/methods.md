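# Methods

This note documents the statistical models, defaults and numerical choices
behind `methpanel`, what the synthetic generators do and do not emulate, and
the design decisions taken where the procedure was genuinely open.

## The screening cascade (array_selection)

The cascade looks for CpG sites usable as plasma markers of liver cancer.
Its stages, in order:

1. **Imputation.** Missing β values are filled by the k-nearest-neighbour
   rule over sites: a missing (site, sample) entry becomes the mean of that
   sample's values at the k sites closest in nan-aware Euclidean distance
   (k = 10 by default). Observed entries are never altered; imputed values
   are clipped to [0, 1]. Backed by `sklearn.impute.KNNImputer`, whose
   nan-Euclidean distance rescales by the fraction of shared observed
   coordinates; with moderate missingness this preserves the neighbour
   ranking of the plain shared-coordinate distance.
2. **Differential test + fold change.** Per site, a two-sided Wilcoxon
   rank-sum test (exact enumeration when both groups have ≤ 6 samples,
   tie-corrected normal approximation otherwise, via
   `scipy.stats.mannwhitneyu`) plus the ratio rule
   β̄_tumour / max(β̄_normal, ε) ≥ 2 with ε = 10⁻³ guarding the
   zero-denominator case. Retention uses raw P < 0.05; Benjamini–Hochberg
   q-values are attached for reporting only. The ratio rule as stated
   selects hypermethylated sites; the symmetric rule
   β̄_normal/β̄_tumour ≥ 2 identifies hypomethylated sites for reporting,
   but only hypermethylated candidates continue, because every later filter
   assumes hypermethylation.
3. **Cross-dataset intersection.** Sites present in both candidate lists
   with the same direction; annotation kept from the first list.
4. **Leukocyte filter.** Candidates ranked by mean β in healthy whole
   blood, ascending (lower blood background = cleaner plasma signal); the
   lowest 30 are kept, ties broken by site ID.
5. **Pan-cancer specificity.** Per cancer type, a site is "hypermethylated"
   when its mean β exceeds 0.3. A candidate is kept iff it is
   hypermethylated in at most two cancer types and one of them is LIHC.

**Batch integration.** When multiple array datasets are merged before
screening, per-batch per-site values are standardised on the logit scale to
the pooled per-site mean and SD, then transformed back. The integration
method used upstream of published 450k meta-analyses is rarely stated;
location–scale standardisation was chosen because it is simple, invertible,
and exactly removes constant logit shifts. A batch with zero per-site
variance maps to the pooled mean.

## WGBS analysis (wgbs)

The pipeline starts at per-CpG cytosine counts (Bismark CpG-report dialect;
1-based positions, both strands). Alignment, trimming and deduplication are
upstream concerns.

- **Conversion rate** = Σu / Σ(m+u) over the unmethylated lambda spike-in's
  CpGs; every methylated lambda call is a bisulfite-conversion failure.
- **Methylation calling** merges the + strand cytosine at p with the −
  strand cytosine at p+1 into one dyad anchored at p;
  β = (m₊+m₋)/(m₊+m₋+u₊+u₋). An orphaned − strand record is emitted as its
  own dyad anchored at p−1 and logged, never dropped. Default coverage
  floor: 5 reads per dyad per group pool (standard WGBS practice; not a
  published parameter).
- **DMC testing** pools counts across samples per group and applies a
  two-sided Fisher exact test to the 2×2 (m, u) table. The test behind the
  published "P < 0.05" is unnamed; pooled-count testing was chosen because
  DMC counts in the millions from 12 pairs imply site-level count testing
  rather than per-sample rank statistics. Dyads covered in only one group
  are skipped and tallied in a skip report.
- **DMR calling**: within one chromosome and direction, consecutive DMCs
  chain while the inter-DMC gap is ≤ 150 bp; chains of ≥ 2 DMCs are
  regions. The "within 50–150 bp" span phrase is ambiguous (gap vs window
  vs total span); this implementation treats 150 bp as the clustering gap
  and 50 bp as a minimum reporting span — shorter regions are flagged
  `short_span`, not removed, and both bounds are configurable, so every
  plausible reading remains available.
- **Context classification** is strand-aware around the TSS: downstream =
  0–200 bp 3′ of the TSS, upstream = 0–2000 bp 5′ of it, with precedence
  intragenic > downstream > upstream > intergenic when genes conflict.

## MSP quantification (msp)

Relative methylation is 2^(−ΔΔCt) with
ΔΔCt = (Ct_target − Ct_ACTB)_sample − (Ct_target − Ct_ACTB)_positive-control,
the calibrator being the methylated HepG2 control on the same plate
(per-plate calibration; whether published assays calibrated per plate or
against a fixed calibrator is unstated). Gates:

- sample valid iff ACTB Ct determined and strictly below 35 cycles;
- plate valid iff every no-template control stays undetermined and every
  positive-control target amplifies; samples on a failed plate are refused;
- replicate wells are averaged on the Ct scale before ΔΔCt (the qPCR norm);
- an undetermined target Ct in a valid sample maps to level 0 with an
  `undetected` flag rather than imputing the cycle cap: monotone,
  threshold-free, and ROC-compatible;
- standard curves regress Ct on log10(copies); efficiency
  (10^(−1/slope) − 1) × 100 must fall in [90%, 110%], and a non-negative
  slope is rejected outright. Cycle caps (45 tissue / 50 plasma) are
  treated as input-validation metadata only.

## Panel evaluation (panel_eval)

- **ROC**: empirical curve over all distinct thresholds with the inclusive
  positive rule (score ≥ cutoff, matching the "AFP ≥ 20 ng/ml" convention).
  The trapezoid AUC equals the Mann–Whitney concordant-pair fraction with
  ties counted half — an identity the tests assert exactly. The 95% CI uses
  the DeLong structural-component variance, symmetric on the AUC scale and
  clipped to [0, 100] (the behaviour of the common R implementation, and
  the only form consistent with a degenerate 100 (100–100) CI on perfectly
  separated cohorts). The Youden cutoff maximises J = sens + spec − 1; ties
  resolve to the smallest threshold, favouring sensitivity in a screening
  context.
- **Marker combination**: published dual-marker results improve both
  sensitivity and specificity over each single marker, which an
  either-positive OR rule cannot do; the default combiner is therefore a
  logistic model on log2(level + 10⁻⁶), fitted on the training split only
  and applied unchanged to validation. On linearly separable training data
  the unpenalised fit is degenerate and the estimator falls back to a
  rank-average score (logged, `fallback_` attribute). An OR-rule mode
  (per-marker Youden cutoffs, score = max level/cutoff ratio) is provided
  for comparison. The estimator follows the scikit-learn fit/predict API.
- **Cohort split**: stratified by group only (per-group ⌈2n/3⌉ training),
  seeded; stage balance is not forced, matching the observed per-group 2:1
  counts (173 → 116/57, 199 → 133/66, 98 → 66/32).
- **Subgroup tables** report numerator and denominator beside each rounded
  percentage so every figure recomputes from its own counts; empty strata
  are NA, never 0. Both single-tumour size strata readings are emitted
  (size recorded only for single-tumour cases), since published
  small-tumour denominators are ambiguous between definitions.
- **AFP comparison**: performance at fixed clinical cutoffs plus the
  smallest AFP threshold whose specificity (compared at the 2-decimal
  reporting precision) reaches a matched target; if unattainable the
  threshold is +∞ with zero sensitivity.
- **Group tests** dispatch as is conventional: rank-sum for two groups,
  Kruskal–Wallis for more, chi-square for categorical variables.

## Association analyses (assoc)

Methylation–expression correlation uses Spearman's rank coefficient with
average ranks for ties (Pearson available as an option; the rank statistic
is primary because it is the one actually reported in this literature and
is robust to the β-value scale). Constant vectors yield NA. Survival uses a
median split of the methylation value — strictly above the median is
"high", ties at the median go low, a deterministic rule — with per-group
Kaplan–Meier curves and a two-sided log-rank test via `lifelines`.

## Synthetic data: what it emulates, and what it does not

Array β values are drawn from Beta distributions parameterised by
(mean, concentration = 30), respecting the [0, 1] support; planted DMCs use
tumour mean 0.5 vs normal mean 0.05 against a 0.2 background, the strong
separation regime the screening stage assumes. Missingness is injected
completely at random (no informative-missingness mechanism is modelled).
Blood matrices give marker sites mean 0.05 and other sites 0.2; pan-cancer
matrices use 0.5 (hyper) vs 0.1 per assignment. WGBS counts are per-strand
Poisson coverage with Bernoulli methylation per read; the lambda spike-in
is unmethylated except for the configured conversion-failure rate
(default 0.5%). Plasma ΔCt values are Gaussian per group and gene — no
published ΔCt distributions exist, so the defaults (HCC means 8–9.5 with
SD 3–3.5; controls 13.5–15.5 with SD 2–2.5 cycles) were chosen once to
produce qualitative HCC / CLD / healthy separation of the magnitude a
strong plasma assay shows, and are not calibrated to reproduce any
published AUC. Samples are assigned to plates in seeded random order so
plate-calibrator noise is not confounded with group. AFP is log-normal per
group with a heavy HCC tail (a substantial AFP-negative HCC fraction).

Consequences: passing tests demonstrate the pipeline's correctness and its
behaviour under the assumed statistical structure — they do not certify
performance on real cohorts, where β distributions are bimodal with probe
effects, WGBS errors are not purely binomial, qPCR has plate-to-plate
efficiency drift beyond a location shift, and clinical confounders
correlate with marker levels. Published patient-cohort AUCs are therefore
not reproduction targets; the worked-example layer instead recomputes the
published percentages from their printed denominators and counts through
the same formula code paths used for synthetic data.

## Problem sizes and numerics

Tests and the acceptance script run on deliberately small instances chosen
to keep the whole suite fast while leaving each statistical check
well-powered: screening cascades on 300 sites × 50+50 samples over 10–20
seeds, WGBS on 3–4 pairs × a few hundred CpG dyads per chromosome at depth
30–50, plasma cohorts of 200–470 samples, and oracle comparisons on
hundreds to a thousand random micro-instances. Exact identities (AUC =
pair fraction, Fisher p = hypergeometric enumeration, DMR = window
enumeration) are asserted at 10⁻⁹–10⁻¹² tolerance; sampled quantities use
3-standard-error binomial bands. Logit transforms clip β to
[10⁻⁶, 1 − 10⁻⁶]. All randomness flows through `numpy.random.default_rng`
with explicit seeds; derived stage seeds are SHA-256 hashes of
(seed, stage-name) reduced below 2³¹.

## Known limitations

- The batch-integration standardisation is a stand-in for an unnamed
  published procedure; it removes location/scale batch structure only.
- The rank-sum screen is unpaired; partly matched tumour/normal designs
  would gain power from a paired test.
- DeLong CIs undercover near AUC = 1 (variance degenerates); a bootstrap
  alternative is not implemented.
- The WGBS DMC test on pooled counts ignores between-sample
  overdispersion; a per-sample paired mode would be more conservative.
- Survival analysis is univariate Kaplan–Meier/log-rank only; no Cox
  adjustment.
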