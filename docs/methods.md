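# Methods

## Futility monitoring

The clinical-benefit probability *p* is modelled with a conjugate Beta prior.
The default rule uses Beta(0.5, 9.5) — prior mean 0.05 carried by an
effective sample size of 10 — a reference rate p_ref = 0.05, a posterior
threshold of 0.95, an interim look at 29 patients and a 50-patient total.
Stopping is declared when P(*p* < p_ref | data) exceeds the threshold with a
strict inequality. The tail probability is the regularized incomplete beta
function evaluated by `scipy.special.betainc`; at the zero-success interim
the value is 0.952402, within 2.5 × 10⁻³ of the threshold, so the evaluator
must be accurate well beyond quadrature tolerances — the test suite checks
agreement with an adaptive-quadrature oracle to 10⁻⁸ and relies on the
strict monotonic decrease of the tail probability in the success count to
justify the boundary's run-length search. A boundary of −1 is the sentinel
for "no futility boundary" (the criterion fails even at zero successes),
reported by the CLI in those words. The interim decision accepts any
observed *n*, not just the planned interim size, because real conduct can
over-enroll a stage; the computed posterior probability is always reported
alongside the decision rather than asserting a margin. Operating
characteristics treat the interim success count as Binomial(interim_n,
true_p): exact mode sums the binomial CDF at the boundary, Monte-Carlo mode
draws seeded replicates (PCG64, one explicit integer seed, recorded in run
metadata).

## RECIST endpoints

Timepoint classification uses the sum of target-lesion diameters with the
standard precedence: progression first (new lesion, or ≥ 20 % **and** ≥ 5 mm
above the nadir, the nadir including baseline and all prior timepoints),
then complete response (all diameters zero), then partial response (≥ 30 %
below baseline), else stable disease. Only target lesions are modelled; a
boolean new-lesion flag stands in for non-target assessment. Best overall
response requires a confirmatory assessment of equal-or-better category at
least 28 days later for CR/PR; a response seen only once is downgraded to SD
with an unconfirmed-response flag. "Four months" of stable disease is
interpreted as four 28-day protocol cycles — 112 days — for determinism; the
SD clock runs from enrollment (day 0) to the last non-PD assessment day, and
an SD seen only once (say at day 56) is still category SD with that
duration. The clinical-benefit denominator keeps non-evaluable patients
(intent-to-treat). The cohort rate carries an exact Clopper–Pearson 95 %
interval. PHQ-9 (0–27) and GAD-7 (0–21) severity uses the fixed bands 0–4
normal, 5–9 grade 1, 10–14 grade 2, ≥ 15 grade 3; the bands partition each
score range exactly.

## Survival

PFS events occur at the earlier of progression and death; patients alive
and progression-free are censored at the last radiographic assessment. OS
events occur at death, censoring at the last date known alive. Times are
internally in days (must be ≥ 1); months are reported at 1 month = 30.4375
days. The Kaplan–Meier estimator is computed directly: at each distinct
event time the curve multiplies by 1 − d/n with events preceding censorings
at ties, and Greenwood's sum gives the variance. The median is the smallest
event time with S(t) ≤ 0.5; its 95 % interval inverts the pointwise
complementary-log-log (Brookmeyer–Crowley) band — the interval bounds are
the first event times at which the band's lower and upper limits cross 0.5,
with an unbounded upper limit reported as undefined when the upper band
never crosses. The log-log transform was chosen as the standard
clinical-trials default; the method name is recorded in output metadata.
The implementation is cross-checked against lifelines (curve values to
machine precision, medians and median CIs exactly) but does not depend on
it at run time for the estimate.

## RPPA

Rows (antibodies) are median-centered across samples and scaled to unit
standard deviation with the n − 1 denominator (the scaling convention is
otherwise ambiguous); zero-spread rows become all-zero rather than NaN, and
normalization is idempotent. Files with missing cells are rejected at the
reader — the composite score is undefined under missingness and no
imputation rule is assumed. The PI3K score sums the six positive-arm nodes
(pAkt, pmTOR, pGSK3, pS6K, pS6, p4EBP1) and subtracts INPP4B and PTEN, each
node the mean of its mapped antibodies. The default node map takes pAkt
from the S473 site (the site in the downmodulation panel), pS6 from both
S235/S236 and S240/S244, p4EBP1 from both S65 and T37/T46; where the exact
antibody identities are ambiguous (pGSK3, pS6K isoform/site) the mapping is
explicit configuration (YAML) rather than a guess. Integral downmodulation
requires a strictly negative on-treatment delta at all five key antibodies.
Clustering is agglomerative centroid linkage with 1 − Pearson correlation
by default (Euclidean available), deterministic smallest-index tie-break;
centroid linkage can invert merge heights, which is flagged with a warning
and never repaired. Dendrograms export to Newick with branch lengths as
clamped height differences.

## Genomics

The qualifying-event rules are: PIK3CA/AKT1 — any non-synonymous small
variant (missense, truncating, frameshift, splice) or amplification
(log ratio ≥ 1.0 when derived from raw ratios); PTEN — any non-synonymous
small variant or deep deletion at log ratio ≤ −2.0. The deep-deletion
cutoff is set so that the canonical −2.87 homozygous loss qualifies while
shallow single-copy losses do not, and is configurable. Pathogenicity is
not adjudicated — any non-synonymous event in the three-gene set counts,
matching inclusive clinical reporting. The gene set itself is configurable.
Crosstabs count samples present in both the variant and response tables;
collapsing the SD duration subgroups preserves totals.

## Synthetic data

`simulate_trial` draws each patient's best-response category from a mixture
(default: 12 % prolonged SD, 22 % short SD, 40 % PD, 26 % non-evaluable, no
objective responses — the published cohort's distribution) and constructs
lesion-diameter trajectories backward from the intended category as
piecewise-linear multiples of the baseline sum, with baseline sums kept
≥ 30 mm so the 5 mm absolute progression rule never blocks a planted ≥ 20 %
increase. Re-classifying the generated assessments recovers the planted
category exactly (a tested contract) provided the follow-up horizon covers
the trajectory. PFS and OS times are exponential at the configured medians
(defaults 54.75 and 340.9 days, i.e. 1.8 and 11.2 months) — exponential
because only medians are specified and the closed form makes recovery tests
exact; the two endpoints are independent draws and OS is not constrained to
exceed PFS, which real data would satisfy. Assessments are scheduled every
56 days (two 28-day cycles). `simulate_rppa` plants an activation factor
with loading +1 on the positive-arm antibodies and −1 on PTEN/INPP4B, plus
a mean shift on the key downstream antibodies of on-treatment samples;
`simulate_variants` plants pathway alterations at a configured prevalence
from the canonical event templates. All generators are pure functions of
(config, seed), with per-patient/per-sample sub-streams spawned
deterministically from the global seed, so outputs are byte-identical
across calls.

What the generators do **not** emulate: measurement error and reader
variability in lesion diameters, non-exponential hazards, correlation
between response category and survival time, informative censoring,
antibody-specific RPPA noise scales, and panel-specific variant-calling
artifacts. Passing tests therefore demonstrate the correctness of the
analysis arithmetic and classification logic under clean, well-specified
inputs — not robustness to real-data messiness.

## Problem sizes and numerics

Stochastic tests use fixed seeds throughout; the survival recovery tests
use 2000–5000 patients (binomial/KM sampling error comfortably inside the
5 % tolerance), the mixture-calibration test 200 cohorts of 50, the
Monte-Carlo operating-characteristic check 10⁵ replicates against a 3-SE
band. Clustering oracle comparisons use 5–6 items, where exhaustive O(n³)
recomputation is trivial. Floating-point ties in the clustering distance
search are resolved with a 10⁻¹⁵ slack toward the earlier pair; the
height-inversion flag uses a 10⁻¹² slack.

## Known limitations

Single-arm machinery only: no comparative statistics (log-rank, Cox), no
competing risks, no frequentist two-stage design optimization, no
irRECIST/PERCIST variants, no lymph-node special-casing, no external
reference-cohort joint clustering, and no adverse-event coding beyond the
questionnaire severity bands. The Brookmeyer–Crowley interval is one of
several defensible median-CI constructions; published intervals computed
under a different transform will differ slightly.
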