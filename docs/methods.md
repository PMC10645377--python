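# Methods

This package re-implements, as a tested pipeline over synthetic data,
the computational analysis by which a panel of metastatic prostate
cancer (mPC) organoid/PDX models is stratified into response classes
for a B7H3-targeted antibody–drug conjugate carrying a
pyrrolobenzodiazepine (PBD) payload. PBD dimers form DNA inter-strand
crosslinks that arrest replication forks, so sensitivity tracks
replication-stress biology (RB1/TP53 loss, SLFN11 expression, select
DNA-repair lesions) rather than target-antigen density alone.

## Dose–response summarization

Viability titrations are summarized per model from paired curves: the
targeted ADC and a non-binding isotype-control ADC carrying the same
payload. For one experiment the area under mean percent viability is
taken over log10(dose) by the trapezoid rule and divided by
100 × (log10-dose span), so a curve pinned at 100% viability
integrates to exactly 1 and the statistic is invariant to rescaling
all doses by a common factor (the AUC definition is the package's own;
only the ratio below is externally specified). The normalized AUC is

    nAUC = AUC(targeted) / AUC(control)

computed per experiment pair, then summarized as the median and IQR
over independent experiments; the median is the per-model response
statistic. Replicates are averaged per dose before integration, and
viability is used as supplied (values above 100% are legitimate since
viability is relative to an untreated control).

IC50 and MaxR come from a four-parameter logistic fit of mean
viability against log10(dose) (relative, curve-midpoint IC50). A flat
or non-convergent curve returns `converged=False` rather than raising,
and a fitted midpoint outside the tested dose range is flagged
out-of-range instead of being reported as a numeric IC50. MaxR is the
mean viability at the top dose (4 μg/mL under the default grid).

Responder status is called as R iff median nAUC < 0.75 (strict, ties
are NR). The threshold is a reproduction aid: the published response
classes separate cleanly around it (responders ≤ ~0.7, nonresponders
→ 1), but when observed labels are supplied they always take
precedence. It is configurable and recorded in output provenance.

## Expression normalization

Raw counts are normalized between samples by the trimmed mean of
M-values (TMM) with the canonical trim fractions: the reference sample
is the one whose upper-quartile count fraction is closest to the mean
upper quartile; per sample, genes zero in either member are excluded,
the top and bottom 30% by M-value and 5% by A-value are trimmed, and
the scaling factor is the weighted mean of the surviving M-values with
inverse delta-method variance weights, exponentiated. Factors are
renormalized to geometric mean 1 and applied through effective library
sizes; log2 CPM uses a 0.5 pseudo-count.

`ordered_quantile_normalize` is a rank-based inverse-normal transform,
Φ⁻¹((rank − 0.5)/n) with average ranks for ties (this offset
convention is the implemented definition; some implementations use
rank/(n + 1)). It is strictly rank-preserving for untied values.

## SLFN11 expressor calling

The published positivity rule lives in supplementary material that is
not reproduced here, so the caller is pluggable and the default is the
package's own operational rule: a two-component Gaussian mixture is
fitted to the cohort's (log-scale) SLFN11 expression and a sample is
positive when its posterior for the higher-mean component exceeds 0.5.
The mixture is fitted on the supplied values directly — a rank
inverse-normal transform would map any cohort to an exact N(0,1) shape
and erase the bimodality the mixture needs — so the call is invariant
to affine, not arbitrary monotone, transforms. A fit is treated as
degenerate when a component weight falls below 0.02 or the component
means are separated by less than 2 pooled standard deviations; the
caller then falls back, with a warning, to a single cohort-wide status
(overall mean versus the configured threshold), since an effectively
unimodal cohort carries no per-sample information. Every call records
its method and fitted parameters.

## Signature scoring

Single-sample gene-set scores use the ssGSEA running sum: genes are
ranked within each sample (average ranks for ties) and the enrichment
score is the sum over the ranked list, walked from the highest
expressed gene down, of the difference between the weighted in-set
empirical CDF (weights |rank|^α, α = 0.25, the cited method's default)
and the unweighted out-of-set CDF. Raw scores are rescaled by the
cohort score range (max − min; the global range when several sets are
scored together), which makes scores comparable across signatures and
can be disabled. Scores are rank-based and therefore invariant to any
strictly increasing per-sample transform of expression. The KDE-based
scoring variant of the same package family is deliberately not
re-implemented; the ssGSEA estimator is used for both model and
cohort data.

Scores are z-scaled per signature across the cohort with the sample
standard deviation (ddof = 1). Phenotypes are called from AR and
neuroendocrine z-scores by quadrant with configurable cutoffs
(default 0): AR+/NE− ARPC, AR−/NE− DNPC, AR−/NE+ SCNPC, AR+/NE+
amphicrine. The true membership of the replication-stress, IFN, RB
and AR/NE signatures is supplied by the user as GMT files; the
packaged sets are synthetic placeholders for testing.

The response screen correlates each signature's z-scores with
per-model median nAUC (Spearman by default), adjusts two-sided
p-values across signatures by Benjamini–Hochberg, and sorts
significant hits (FDR ≤ 0.05) by |coefficient|. Constant score
vectors are reported with undefined coefficients and excluded from
the adjustment. Group comparisons use two-sided Wilcoxon rank-sum
tests with Holm adjustment across pairs.

## IHC H-scores

H = Σ_i pct_i × i over intensities 1–3, range 0–300; percentage
vectors must sum to 100 within ±0.5 (absorbing rounded tables).
Triplicate core scores are averaged per tumor over evaluable cores
only; a tumor with no evaluable core is marked not-analyzed rather
than erroring. A tumor is a B7H3 expressor iff its averaged H-score
is strictly greater than 20.

## Biomarker decision rules

A model is classified by an ordered rule list; exactly one rule fires
and is recorded with a rationale naming the triggering biomarker:

1. B7H3 not expressed → ineligible (target expression is necessary
   but not sufficient).
2. RB1 biallelic loss OR replication-stress z-score > 1 → responder.
3. SLFN11 expressed → responder.
4. ATR or CHD1 loss of function → responder.
5. TP53 wild type (or monoallelic) → nonresponder.
6. Otherwise indeterminate.

RB1/replication stress precedes SLFN11 because RB1-deficient models
respond independently of SLFN11 status. The replication-stress
fallback threshold of z > +1 is a conservative default for the
RB1-wild-type responders whose scores sit above the cohort average,
and is configurable. BRCA2 loss is carried but deliberately inert: the
observed BRCA2-deficient, TP53-wild-type model was nonresponsive, and
the TP53 rule dominates. TP53-altered models with no positive
biomarker are left indeterminate rather than forced to nonresponder,
since that cell of the decision table is not observed. The ordering of
the SLFN11 and DNA-repair rules is an interpretation of a schematic;
with the panel's annotations the two orderings give identical calls.

## Clinical cohort funnel

PolyA and capture assay tables are merged to unique samples (polyA
rows win on overlap; priority configurable, disagreements in tumor
content above 0.05 warn). Samples with at least 30% tumor content
(inclusive ≥) are kept. The funnel then partitions sequentially: RB1
homozygous alteration; SLFN11 call among RB1-intact samples (caller
injectable, default the mixture rule above); ATR/CHD1 loss among the
RB1-wt/SLFN11-negative remainder; TP53 status among the rest.
Eligible = RB1-altered ∪ SLFN11+ ∪ ATR/CHD1-loss, reported over the
filtered cohort. Branch counts at every stage sum to the stage input.
Counting is sample-level throughout, including the stage the source
phrases per patient.

## Synthetic-data generator

The generator's defaults are the study conditions, fixed once:

- Expression: 2,000 genes × 26 samples; per-gene log2 means N(5, 2);
  negative-binomial counts with dispersion 0.1 (the standard bulk
  RNA-seq noise assumption; no published noise model exists for these
  data). Planted sets shift member-gene means by δ log2 units in a
  configured fraction of samples and are recorded in a truth table.
- Dose–response: 10-point 1:4 serial dilution from 4 μg/mL, 5
  replicates, 3 independent experiment pairs, additive Gaussian noise
  of 5 viability points truncated at 0 only (viability may exceed
  100). Replicate-to-replicate variance is not published; 5% is a
  nominal, configurable choice. Per-model 4PL parameters are fixed so
  each response class jointly satisfies the printed constraints
  (non-ARPC IC50 0.03–2.08 ng/mL with nAUC 0.2–0.5 and steep slopes;
  ARPC responders shallower with nAUC below 0.75; nonresponders
  near-flat, nAUC → 1). The control curve is near-flat (~99% at the
  top dose).
- Cohort: independent Bernoulli genotype alterations at marginal
  frequencies RB1 0.10, TP53 0.40, ATR 0.02, CHD1 0.02; tumor content
  Beta(3, 2), giving ~92% of samples at ≥ 30% content; SLFN11
  expression from a two-component Gaussian mixture (means 2 and 6,
  sd 1, positive fraction 0.40).
- IHC: triplicate cores per tumor from fixed intensity profiles,
  optionally Dirichlet-perturbed on the profile's support; rows always
  sum to 100.

One global seed is split into fixed named substreams
(`numpy.random.SeedSequence` spawn keys), so adding a generator never
perturbs existing draws and per-model dose-response streams are
independent.

The generator emulates the statistical structure the analysis assumes
— bimodal SLFN11, planted set shifts, Hill-curve viability, marginal
genotype frequencies — but not features of real data such as gene–gene
correlation, batch effects, GC/length bias, genotype co-occurrence, or
phenotype-dependent expression programs. Passing tests therefore
demonstrate correctness of the computations and calibration under the
assumed model, not performance on real cohorts.

## The 26-model panel

The shipped annotation table (`model_annotations_synthetic.tsv`) is a
synthetic reconstruction: a published table of 26 models is available
only as a figure, so rows were constructed to jointly satisfy every
printed tally (phenotype counts 19/2/5; 8/8 SLFN11+ ARPC responders;
3 of 11 SLFN11− ARPC models responding; 8 ARPC nonresponders, 7 of 8
TP53-wt; 9 RB1-deficient models, 6 SLFN11+; all non-ARPC models
RB1-null/TP53-altered responders). Individual rows must not be read as
measured values for the named models. One published RB1-null ARPC line
evaluable only in vivo is excluded, as including it cannot be
reconciled with the printed in-vitro response counts.

## Numerical choices and degenerate inputs

- 4PL fitting: `scipy.optimize.curve_fit` with a midpoint-crossing
  initial guess, slope bounded to [0.01, 50], midpoint bounded to ±6
  decades beyond the grid; failure → `converged=False`, never an
  exception.
- nAUC with a zero control AUC is an error (degenerate control), as
  are unpaired experiment identifiers (reported by name).
- Tie handling uses average ranks everywhere (ssGSEA, rank-sum tests,
  quantile normalization).
- z-transforms raise on zero-variance signatures, except inside the
  correlation screen where constants are reported with NaN
  coefficients so one flat signature cannot fail a whole screen.
- Writers are atomic (temp-then-rename); no partial output survives a
  failure. Every pipeline run writes a provenance JSON with package
  versions, seed, thresholds and input digests.

## Problem sizes

Test and driver problem sizes are chosen as the smallest at which the
checked statistical properties are stable: oracle agreement on 200
random 10×6 matrices; 20-seed simulation studies for IC50 recovery;
n = 1,000 rule-labelled cohorts for classifier accuracy; n = 10,000
for funnel composition and marginal checks; 50-seed null calibrations
for the correlation screen.

## Known limitations

- The ssGSEA variant is used for all data; the KDE-based scoring used
  for part of the original model-data analysis is out of scope, so
  score values (not ranks) can differ from that pipeline.
- The published correlation between RB-signature score and nAUC
  (r = −0.64) is reproducible only with the real deposited expression
  data and true gene lists, which users must supply.
- The SLFN11 mixture rule is operational, not the published
  supplementary rule.
- Clinical funnel results on the real SU2C/PCF cohort require
  user-supplied tables; nothing is downloaded.
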