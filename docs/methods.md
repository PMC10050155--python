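# Methods

This note documents the models, defaults and design choices behind
`dualsub`, and what the synthetic-cohort tests do and do not demonstrate
about real data.

## Single-sample enrichment scoring

`enrichment.ssgsea_score` implements the rank-weighted running-sum
single-sample GSEA statistic. Per sample, genes receive ranks 1..N (ties
get average ranks; a constant profile is rejected as carrying no
ordering). Ordered by decreasing rank, the enrichment score of set S is
the sum over positions of the difference between the cumulative
`r^alpha`-weighted mass of in-set genes (normalised to 1) and the
cumulative uniform mass `1/(N−|S|)` of out-of-set genes. Closed forms
used as exact tests: a singleton set at the top (bottom) of the ranking
scores exactly `+N/2` (`−N/2`), and a {top, bottom} pair at `alpha = 0`
scores exactly 0.

Defaults: `alpha = 0.25` and division of the final score matrix by its
global max−min, matching the GSVA `ssgsea` defaults; both are exposed
because published template scores depend on them. A set member absent
from the matrix is dropped; coverage below 80% warns and below 30% is an
error, since cross-species translation erodes sets and a heavily eroded
set no longer measures its pathway. A set covering *all* matrix features
is rejected (the out-of-set mass is undefined).

Because the statistic is purely rank-based, scores — and therefore all
pathway-level classification results — are invariant to any strictly
increasing per-sample transform. This is the precise, provable form of
the claim that pathway-level classifiers resist normalisation
differences; it does **not** extend to gene-level (option A)
classification, which is only empirically reported.

## Nearest-template prediction

Templates are binary indicators over their feature universe; a feature
may belong to one class only (enforced), since a marker present in two
templates is uninformative. Features are mean-centered across the cohort
before distance computation (median available): on uncentered positive
data, cosine distance to any non-negative indicator is dominated by the
profile's overall level and classification degenerates toward the
largest template. Cohort centering implies a sample's call depends on the
cohort it is classified with; single-sample classification without a
centering reference is rejected rather than silently miscomputed.
Optional per-feature unit-variance scaling is off by default.

Distances are `d = 1 − cos(x, t_k) ∈ [0, 2]`; the call is the argmin.
Exact ties (within 1e-12) and zero centered profiles are reported
`unclassified` with a reason.

**Permutation null.** The sample's own centered values are permuted
across the template features B times (default 1000), preserving the
sample's value distribution, and `p = (1 + #{d* ≤ d_obs})/(B + 1)`. Two
null statistics are supported:

* `nearest` (default): `d*` is the minimum distance over all class
  templates of the permuted profile — the same functional as the
  observed statistic. This null is calibrated: on signal-free data the
  p-values are uniform up to permutation discreteness (KS ≈ 0.04–0.07 at
  B = 1000 on a 200-sample null cohort), so the downstream FDR has its
  nominal meaning.
* `predicted`: `d*` is the distance to the predicted template only, the
  classical NTP formulation. Because the observed statistic is a minimum
  over K templates while this null is not, null p-values concentrate
  near `Beta(1, K)` rather than uniform (KS ≈ 0.5–0.6 with K = 4) — an
  anti-conservative behaviour inherited by published NTP
  implementations. It is retained for comparability; exhaustive
  enumeration oracles for both schemes are part of the test suite.

Each sample's permutation stream is seeded by (run seed, CRC32 of the
sample id), so p-values do not depend on the order samples appear in the
matrix. BH adjustment is across samples within one run (not across
classes), and calls with q ≥ 0.05 are `unclassified`.

The classifier is exposed statsmodels-style: `NearestTemplateModel(matrix,
template, params).fit()` returns a `ClassificationResult` holding calls,
per-class distances, p, FDR and a `summary()` table; `ntp_classify()` is
the functional shorthand.

## Ortholog translation

Translation is driven entirely by a supplied two-column symbol map; no
synonym or case folding is attempted (silent case-folding fabricates
ortholog hits between human upper-case and mouse title-case symbols).
One-to-many mappings keep *all* targets, so translated templates can grow
even while some symbols drop out — the behaviour seen when human CMS
marker templates are carried into mouse. Unmapped symbols are dropped and
itemised in a `TranslationReport` (`n_input = n_mapped + n_dropped` is an
enforced invariant). A target symbol reached from two different classes
is removed from both and logged. At matrix level, many-to-one collisions
collapse by maximum variance by default (the most informative row), with
`mean` and `first` as alternatives.

## Template derivation

* **z-score selection (option B).** Per-class mean ssGSEA scores are
  standardised per set using the sample SD (ddof = 1) over the class
  means; a set is assigned to a class iff its z is > 0 there and < 0 in
  every other class (strict). Sets with identical class means are
  degenerate and excluded. This is a *selection rule, not a test*: it
  carries no significance threshold, so on a signal-free cohort it will
  still assign sets whose z pattern happens to be single-positive
  (probability ≈ 0.3 per set for four exchangeable classes). Only the
  requirement that every class receive at least one set can block a
  noise-only template. Use it, as intended, on cohorts with genuine
  class structure, or prefer the pairwise-test filter when false
  selection matters.
* **Pairwise Welch filter (options C steps 1–3).** A set is kept for the
  class with the highest mean iff every pairwise comparison against each
  other class is significant (two-sided Welch, p < 0.01 by default, with
  the direction checked). Welch rather than pooled-variance, since
  enrichment-score variances differ across classes and nothing in the
  procedure justifies equal variances. Classes need ≥ 3 samples.
* **L1 multinomial grouping (option C step 4).** Candidate genes are
  standardised and an L1-penalised multinomial logistic model is fitted
  over a geometric 20-point λ path from the data-derived λ_max.
  10-fold class-stratified cross-validated multinomial deviance selects
  λ by the one-standard-error rule (largest λ within one SE of the
  minimum); the path is truncated early once deviance has clearly blown
  past its minimum. A gene joins the class with a positive coefficient
  at the chosen λ; multi-positive genes go to the largest coefficient
  (logged); constant genes are excluded with a warning. Stratified folds
  tighten the fold-to-fold deviance SE relative to unstratified folds,
  so the one-SE rule sits slightly deeper along the path than an
  unstratified implementation would put it. Each class's surviving group
  is wrapped as one gene set, ssGSEA-scored and re-filtered for that
  same class before entering the option C union; every template member
  is traced to exactly one of the four steps in the derivation report.
* **Meta-signature diagnostic.** Per called class, up to 20 genes with
  linear fold change > 4 (log2 input assumed, so FC = 2^Δmean) and Welch
  p < 0.05 form a meta-signature; the class-by-class matrix of median
  signature scores should be diagonal-dominant when gene-level markers
  travel — and its off-diagonal failures are exactly the evidence that
  they often do not.
* **Cross-cohort concordance.** Per-class Pearson correlation between
  two cohorts' sets-by-classes mean score matrices over a shared set
  universe (≥ 3 sets required).

## Synthetic cohorts

`simulate.simulate_cohort` draws gene baselines μ_g ~ U(4, 10) and values
N(μ_g, σ) on a log2-like scale, then shifts each class's planted marker
genes by +δ in that class's samples. Defaults — 4 classes × 25 samples,
2000 genes, 5 disjoint planted sets of 20 genes per class, δ = 1.5,
σ = 1, plus 20% signal-free samples (truth label `unclassified`) — are
the cohort scale at which recovery and calibration are evaluated
throughout the tests; the derivation tests use δ = 2 with n = 25/class
and the LASSO tests δ = 3, σ = 0.5 with n = 20/class. A second-species
namespace is generated with 5% ortholog dropout and 5% one-to-many
expansion.

Gaussian log-expression is used rather than negative-binomial counts:
the classifier consumes normalised data and its scoring is rank-based,
so the marginal family is immaterial to what these tests exercise. The
generator does not emulate batch effects, correlated co-expression
within sets, compositional library-size artefacts, or tumour purity
gradients; passing recovery tests therefore demonstrates correctness of
the algorithms under clean planted structure, not classification
accuracy on real tumours, where effect sizes are smaller and gene sets
overlap.

## Numerical choices and degenerate inputs

Distance ties use a 1e-12 tolerance; permutation counts use
`d* ≤ d_obs + 1e-12` so exactly-equal rearrangements count as extreme.
p-values live in [1/(B+1), 1] by construction. B ≥ 19 is enforced so the
smallest attainable p can clear a 0.05 threshold. Duplicate identifiers,
non-finite values, empty sets, all-constant profiles and zero vectors
are rejected with named offenders rather than imputed; missing
expression values are likewise rejected (the upstream normalisation is
expected to have resolved them). Expression input is assumed normalised;
a maximum value above 50 triggers a raw-counts warning.

## Known limitations

* Calls depend on the classified cohort through feature centering;
  classifying a sample inside different cohorts can change its call.
* The `nearest` null corrects the calibration of the classical NTP
  p-value but both schemes share its permutation framework; p-values
  remain conditional on the template and cohort at hand.
* The z-score selection rule will select spurious sets on cohorts
  without real class structure (see above).
* Option A inherits every weakness of gene-level cross-species
  classification that motivates options B/C; it is provided as the
  baseline, not the recommendation.
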