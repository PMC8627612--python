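# Methods

## Instruments and the AMSTAR-2 rating algorithm

AMSTAR-2 is encoded as 16 items with response alphabet {Y, N}, extended by
PY for items 2, 4, 7, 8, 9. Items 11, 12 and 15 are answered only when the
review performed a meta-analysis (otherwise they must be NA), and items 9
and 11 may carry separate RCT and NRSI judgments when the review includes
both study designs. Seven items (2, 4, 7, 9, 11, 13, 15) are critical.
ROBIS is encoded as 21 items in four domains, each answered on
{Y, PY, PN, N, NI}.

The overall-confidence algorithm counts *flaws* (response N; for
stratified items, N in any stratum) separately over critical and
non-critical items, excluding NA items from both counts:

| critical flaws | non-critical flaws | rating |
|---|---|---|
| 0 | ≤ 1 | HIGH |
| 0 | > 1 | MODERATE |
| 1 | any | LOW |
| > 1 | any | CRITICALLY_LOW |

PY is treated as "no flaw" by default: the rule counts *major* flaws and
PY is affirmative partial credit. Published guidance is ambiguous about PY
on critical items, so a strict mode (`strict_py_critical=True`) that
counts critical-item PY as a flaw is exposed rather than silently chosen.
For stratified items the flaw criterion is conjunctive (any negative
stratum is a flaw), mirroring the harmonization convention that a positive
verdict requires positives for both RCTs and NRSI.

ROBIS's domain-concern and overall risk-of-bias judgments are assessor
judgments with no published mechanical algorithm; they are deliberately
not modelled. A clearly-labelled triage heuristic
(`robis_overall_heuristic`) exists for convenience and is excluded from
the reliability pipeline.

## Harmonization

The canonical table maps 12 AMSTAR-2 items and 14 ROBIS items into 11
comparisons over four domains; ROBIS 4.4 serves two comparisons. Ten
comparisons are fully overlapping; the publication-bias-vs-robustness
comparison is only partial. Coverage: 26/37 items = 70.3%.

The general conversion treats ROBIS Y/PY as positive and N/PN/NI as
negative, against AMSTAR-2 Y vs N. Refinements per comparison:

- **PY-collapse (items 2, 8):** AMSTAR Y/PY merge with ROBIS Y/PY,
  leaving two effective categories; scored unweighted. Collapsing rather
  than keeping a 3-level scale follows from the rule itself: once Y and PY
  are declared equal on both sides there is no residual ordering.
- **Search strategy (item 4 vs ROBIS 2.1–2.4):** three ordered categories
  N < PY < Y (coded 1, 2, 3). ROBIS side: Y if all four sub-items
  positive; PY if 2.3 and 2.4 both positive; else N. Scored with
  quadratic weights.
- **Design-conditional (item 9 vs 3.4):** with both designs present, the
  AMSTAR side is positive only when both strata are Y/PY.
- **Meta-analysis-gated (items 11 and 15 comparisons):** skipped entirely
  for reviews without a meta-analysis; counted as excluded, so applicable
  + excluded = cohort size for every comparison.
- **Item 11 vs 4.3 + 4.4:** the published convention does not state how
  the two ROBIS items combine. Default: positive iff **both** are Y/PY
  (consistent with the all-positive clause of the search rule and the
  conjunctive stratum rule); `rule_e_mode="ANY"` is available because the
  choice is genuinely open.
- **Items 12 + 13 vs 4.6:** with a meta-analysis, positive iff both 12
  and 13 are Y; without one, item 13 alone carries the comparison. The
  comparison itself is never skipped.
- The heterogeneity comparison (item 14 vs 4.4) is implemented ungated:
  nothing in the convention restricts it to meta-analyses.

Reviews failing validation are dropped from all comparisons with a logged
warning — never imputed. Category sets are design-fixed (q = 2 or 3) even
when a category is unobserved, so unobserved categories contribute zero
propensity to the chance term rather than shrinking q.

## Agreement estimation

Gwet's coefficient AC = (pa − pe)/(1 − pe) with
pa = (1/n) Σ w[aᵢ,bᵢ], πₖ = (1/2n) Σ [1(aᵢ=k)+1(bᵢ=k)], and
pe = (T_w/(q(q−1))) Σ πₖ(1−πₖ), T_w = Σ wₖₗ. Identity weights give the
unweighted AC1 (T_w = q); quadratic weights wₖₗ = 1 − (k−l)²/(q−1)² give
the weighted AC2 used for the one ordered 3-level comparison.

Uncertainty: delete-one jackknife,
se = sqrt(((n−1)/n) Σ (AC₍₋ᵢ₎ − mean)²), with a Wald interval at
z = 1.959964 (normal, not t — large-sample practice for agreement
coefficients). The upper bound is truncated at 1; the lower bound is not
truncated, since slightly negative lower bounds are meaningful for
near-zero coefficients. The jackknife was chosen as a deterministic,
assumption-light variance estimator; published agreement tables rarely
state their variance method, so digit-for-digit CI reproduction of any
particular published table is explicitly not a goal. A paired
nonparametric bootstrap (`bootstrap_se`) is provided as a cross-check; on
the four-pair worked example the two agree within 25%, and simulated
coverage of the nominal 95% interval at n = 101 is ≈ 94%.

Leave-one-out replicates are grouped by the removed pair's category
combination, making the jackknife O(q²) after the O(n) sufficient
statistics — exact, not approximate.

Degenerate samples where pe reaches 1 raise a structured
`DegenerateSampleError` (with identity or quadratic weights this cannot
occur, since Σ πₖ(1−πₖ) is bounded away from its maximum; it is reachable
with user-supplied weight matrices). Fewer than 2 pairs is an error;
between 2 and 3 the point estimate is available without a CI, and the
pipeline reports comparisons with n < 2 as NOT_ESTIMABLE rather than
dropping the row.

Report rounding is half-up to 2 decimals (se to 4), applied only at the
reporting layer; library results keep full precision.

## Synthetic cohorts

The generator emulates a consensus-appraisal study: paired AMSTAR-2/ROBIS
assessments of n reviews (default 101) with

- latent quality u ~ Beta(1.2, 6.0) — strongly left-skewed; under the
  defaults fewer than 1% of simulated reviews rate HIGH on AMSTAR-2 and
  all-positive ROBIS profiles are similarly rare, matching the rarity of
  high-quality verdicts in published appraisal cohorts;
- has_ma ~ Bernoulli(0.8) and design mix RCT-only/NRSI-only/both with
  probabilities 0.15/0.55/0.30 (nutrition evidence is mostly
  observational);
- one latent state per methodological concept — one concept per
  comparison, plus one per instrument-unique item — met with probability
  u, with a "partially met" level carved out with probability
  py_prob = 0.25 where the AMSTAR-2 item admits PY;
- each instrument observes each concept with probability
  `concordance` (default 0.9, reflecting calibrated consensus raters);
  otherwise it records an independent uniform draw over the comparison's
  harmonized categories, emitted back through canonical item responses.
  This makes the two limiting cases exact: at concordance 1 every
  comparison is perfectly concordant, and at concordance 0 both sides
  have uniform category marginals, so the population coefficient is 0 for
  every comparison. (A redraw uniform over the *raw* response alphabets
  would not have this null property: unequal induced marginals between
  instruments push AC1 away from 0 even under independence.) An
  `adjacent` discordance model (off-by-one category errors) is available
  for exercising the weighted coefficient;
- ROBIS unmet states are emitted as PN/N/NI with probabilities
  0.3/0.5/0.2; met → Y, partial → PY.

Because ROBIS 4.4 serves two comparisons, one shared "synthesis" latent
state drives AMSTAR items 11 and 14 and the ROBIS 4.3 + 4.4 unit; the
joint unit is redrawn as a block under discordance so both comparisons
keep uniform null marginals. A side effect is that simulated 4.3 and 4.4
always agree with each other; real assessments need not.

What the simulator does **not** model: per-item response distributions of
any real cohort, correlations between concepts beyond the single quality
factor, rater psychology, or systematic instrument bias. Passing
simulation tests therefore demonstrates correctness of the pipeline and
the estimator's statistical behaviour under a controlled truth — not that
any particular real-world agreement level will be reproduced.

All draws flow through a single seeded numpy Generator in a fixed concept
order, so cohorts are byte-identical across runs for a given config.

## Problem sizes used in checks

Exhaustive enumerations are used wherever alphabets permit (625 tuples for
the search rule, 2⁸ rating configurations for the coefficient oracle, all
flaw-count combinations for the rating rule, 2¹³ assignments for the
NA-equivalence property). Statistical checks use n = 10⁵ reviews for the
zero-concordance null (tolerance ±0.02), 12 replicate cohorts of 101 for
concordance monotonicity, 2,000 samples of 101 pairs for CI coverage
(expected within [0.92, 0.98]), and 10⁴ reviews for prevalence
calibration.

## Known limitations

- The harmonization conventions are encoded for the canonical 11-
  comparison scheme; alternative matchings (e.g. 12-comparison variants
  that pair AMSTAR-2 item 3 with ROBIS 1.4, or fold ROBIS 3.5 into the
  data-extraction comparison) are documented here but not implemented.
- Only two-rater, complete-data designs are supported: the input is one
  consensus assessment per instrument per review. Cohen's κ,
  Krippendorff's α, multi-rater and missing-data designs are out of
  scope.
- ROBIS Phase 1 (relevance) and Phase 3 (overall RoB judgment) are not
  modelled.
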