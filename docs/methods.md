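# Methods

This note documents the models implemented in `newsworthy`, the choices
made where the procedures admit more than one reasonable reading, and what
the synthetic-data experiments do and do not establish.

## Problem setting

Given citation records (title, abstract, MeSH headings) labeled by whether
the article attracted a press release (PR) or news coverage (NC), the
package asks two questions: *how predictable* is that attention from the
article's content (cross-validated AUC), and *which content features and
topics* carry the signal (bootstrap-ranked n-grams; supervised topics).
Negatives are constructed by matched sampling so that the answer reflects
content rather than journal prestige or publication date.

## Matched sampling

For each positive article, up to `max_per_positive` controls are drawn
uniformly without replacement from pool articles agreeing on all match
keys (journal/issue/year; strings trimmed and casefolded before
comparison). Positives are processed in corpus order and claimed controls
are removed from later eligible sets, which is how the combined corpus is
kept duplicate-free. A positive with no eligible controls contributes
nothing and is logged. The uniform draw is the minimal assumption; no
covariate-distance matching is attempted.

## Featurization

Tokens are lowercase `[a-z0-9]+` runs; digits survive ("95% CI" →
`95`, `ci`). Stop words (the classic 318-word Glasgow IR list, shipped in
the source) are removed *before* bigram formation, so a bigram may bridge
a removed stop word. Field provenance is encoded in the feature string:

* title terms emit both `TI-`-prefixed and unprefixed uni-/bigrams —
  published predictor lists contain both plain words and `TI-` variants,
  and double emission is the minimal scheme consistent with that;
  the unprefixed copy can be disabled (`emit_unprefixed_title=False`);
* abstract terms are the unprefixed stream;
* each MeSH heading is one `MH-` feature (lowercased, spaces → hyphens,
  qualifiers like `england/epidemiology` kept verbatim), with bigrams over
  adjacent headings.

"Appeared in at least two instances" is read as document frequency ≥ 2,
since instances are articles. The 50,000-feature cap keeps the highest
*total corpus counts*, ties broken lexicographically; the retained
vocabulary is sorted lexicographically so the feature index is a pure
function of (corpus, config).

## Discriminative model

The classifier minimizes ½‖w‖² + λ Σᵢ log(1 + exp(−ỹᵢ(wᵀXᵢ + w₀))) with
ỹ ∈ {−1, +1}: λ multiplies the loss, so smaller λ means stronger
regularization, and the intercept is unpenalized (penalizing it would bias
toward the majority class under the heavy imbalance of these corpora).
The fit is delegated to scikit-learn's LBFGS solver, whose objective is
exactly this form with C = λ; tests verify agreement with an independent
high-precision optimizer to 1e−4 in the weights.

Evaluation is stratified five-fold cross-validated AUC (Mann–Whitney rank
form; ties get half credit). λ is selected *inside* each training split by
(k−1)-fold inner CV over the logarithmic grid 1e−5 … 1e2 (8 points),
maximizing mean inner AUC with ties going to the smaller λ (stronger
regularization). Folds are stratified by label — unstratified folds
degenerate at ~5–14% positive rates — and all splits derive from a stored
seed. Inner selection fits use a looser optimizer tolerance (1e−4) than
final refits: AUC is a rank statistic and is insensitive to the last
digits of the weights.

## Bootstrap feature ranking

B resamples of the documents (with replacement, B = 1000 by default)
refit the model at a fixed λ — the full-data cross-validated choice; the
pipeline uses the modal fold-selected value.  Re-tuning λ inside every
replicate is available behind a flag but disproportionate at B = 1000.
Per-feature replicate means and SDs give normal-approximation 95%
intervals (mean ± 1.96 SD). Positive features rank by descending CI lower
bound, negative by ascending upper bound, ties by mean then
lexicographically. Replicates drawing a single class are redrawn (logged);
more than 10% redraws aborts. Density summaries are Gaussian KDEs with
Silverman bandwidth, renormalized to trapezoid integral 1; an optimizer
tolerance of 1e−4 per replicate fit suffices because between-replicate
variation dominates.

Note an honest limitation: these intervals measure *within-sample
estimator stability*. On a null corpus with thousands of features, a few
percent of features will exclude zero by chance; what a null run does not
produce is a robust feature of planted-signal magnitude. The tests check
exactly that.

## Supervised topic model

The sLDA generative story (K topics β, symmetric Dirichlet(α) proportions,
per-word topic assignments, and a label drawn from softmax(η_cᵀz̄) where z̄
holds the document's empirical topic frequencies) is fit by variational
EM with a fully factorized posterior. C = 2 with the negative class as
reference (η_neg ≡ 0): per-class softmax coefficients are unidentifiable
and fixing a reference is the standard remedy. The intractable softmax
normalizer is handled with Jensen's inequality (expectation inside the
log, factorizing over word positions) plus the first-order bound
log x ≤ x/ζ + log ζ − 1, tight at the current iterate — both are
minorize–maximize steps, so the reported ELBO is non-decreasing (tests
allow 1e−6 relative slack for the β-smoothing and floating point).
The per-document E-step is a numba kernel (sequential per-position φ
updates with an incrementally maintained Jensen factor); the M-step
updates β in closed form from expected topic-word counts (additive 1e−8
smoothing, renormalized) and η by L-BFGS on the concave response term.

Defaults: K = 20, α = 1 for corpus analysis; convergence at relative ELBO
change < 1e−5 or 200 EM iterations, per-document E-step at mean |Δφ| <
1e−6 or 100 sweeps. Initialization (β from randomly chosen documents'
word counts with seeded perturbation; φ from perturbed uniform) is fully
seed-determined; restarts are the caller's loop over seeds. Documents
enter as raw token counts, untruncated. Prediction for unlabeled
documents runs the E-step without the label term (plain variational LDA)
and applies the softmax to the inferred z̄.

## Synthetic data

The discriminative generator emulates a matched PR corpus: 800 documents
at 12.5% positive (within the 5–14% range of real corpora), titles of
13 ± 5 words, abstracts of 214 ± 67 (truncated normal, minimum 1),
5–15 MeSH headings from a 200-heading controlled vocabulary, background
words Zipf(1.1) so the min-df and cap filters see a realistic long tail.
Three planted words (one per field) are each present in half the
documents with +4.5 log-odds effect; a present word is written four times
into its field (documents repeat the terms they are about — a single
planted token would leave the realized signal far weaker than the
construction's analytic Bayes AUC of ≈0.95 implies). The label is
Bernoulli with logit b₀ + Σ effects, b₀ calibrated by bisection so the
expected positive rate equals the quota; documents are then collected
until both class quotas fill exactly (case–control collection preserves
the logistic form up to the intercept).

The sLDA generator plants K near-disjoint block topics (98% of each
topic's mass uniform on its own V/K-word block) and one discriminative
topic (η = +3); the recovery fixture is K = 5, V = 200, 500 documents of
60 words.

What passing these tests shows: the estimators recover signals they are
built for, at realistic imbalance and dimensionality, and degrade to
chance under the null. What they do not show: behavior on real English
text (synthetic words carry no morphology, no topical correlation between
title and abstract, no journal style), nor calibration of class
probabilities, nor that real press-release signals are as clean as
planted ones.

## Problem sizes in the standard runs

The shipped test and acceptance runs use the generator defaults above
(800-document corpora; the null-behavior runs shorten abstracts to 60 ± 20
words over smaller vocabularies, which leaves the chance level untouched
while keeping the feature space at ~10⁴), B = 200 bootstrap replicates for
ranking demonstrations and 60–100 repetitions for coverage, and 20 seeded
sLDA refits for sign-recovery rates. These sizes are the package's chosen
demonstration scale; all of them are parameters.

## Known limitations

* Bootstrap CIs are normal-approximation only; percentile/BCa intervals
  are out of scope, as are stability selection and p-values.
* The sLDA bound is a lower-bound surrogate; ELBO values are comparable
  across iterations of one run, not across models.
* Matched sampling trusts the caller's pool: it cannot verify that a pool
  article truly lacked a press release.
* The vocabulary sizes reported for the original corpora are not
  reproducible without the exact original tokenizer and stop list; the
  implementation treats them as non-binding.
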