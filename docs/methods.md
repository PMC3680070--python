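# Methods

This note documents the models and procedures `ppidiag` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish about real data.

## Data model and formats

Corpora follow the unified PPI interchange layout
(`corpus > document > sentence > entity / pair`), with inclusive
`charOffset="a-b"` entity spans in the XML converted to 0-based half-open
spans internally (a single internal convention keeps round-trips
lossless). Candidate pairs are unordered, self-pairs are rejected, and
ids follow the `Corpus.dX.sY.pZ` scheme with the one-letter prefixes
A/B/H/I/L for the five benchmarks. The original resources do not publish
a schema for tokenization/parse layers; the dialect used here
(`tokenization`, `dependencies`, `bracketing` sub-elements, with leaves of
the bracketed tree carrying token indices) is self-defined and preserved
byte-stably through write→parse→write. Unknown XML elements are carried
as opaque payload. Predictions are label-only TSVs — the analysis is
label-level throughout; no margins or scores are used.

## Difficulty stratification

The success level of a pair is the count of roster classifiers predicting
its gold label. Cutoffs operate on the success-level histogram:

* difficult side (default `closest`): the non-empty level prefix whose
  size is closest to `fraction × corpus size` (default fraction 0.10),
  ties broken toward the smaller, more stringent set;
* easy side (default `at_least`): the smallest non-empty suffix whose
  size reaches at least the target.

The asymmetric default pairing is the one that reproduces all twenty
published per-corpus set sizes from the published histograms; both rules
are available on both sides, and `extract_difficulty_sets` flags any
corpus/setting where the two rules disagree rather than guessing intent.
Success levels are never rescaled across rosters of different size
(CV max 13, CL max 12).

Overlap significance uses the Pearson χ² on the 2×2 membership table,
without continuity correction, declared significant only when p < 0.001
*and* the observed overlap exceeds |A||B|/N (a one-sided enrichment
reading). In small universes the uncorrected one-sided p is
anti-conservative relative to the exact hypergeometric tail by roughly a
factor of three at N ≈ 20; the `correction=True` variant (Yates) tracks
the exact tail closely and is what the small-universe validation tests
exercise quantitatively. Degenerate tables (empty sets, sets equal to the
universe) are rejected rather than assigned a p-value.

## Expected-correctness bookkeeping

For a classifier with positive-prediction rate r (percent) on a stratum
of n same-gold pairs, the expected number of correct labels is
e = round(r n/100) (positive stratum) or round((1 − r/100) n) (negative),
with halves rounded away from zero. r is computed over all pairs the
prediction set covers, pooled per setting — the population is not
specified by convention elsewhere, so reports state it explicitly.
Published reference tables occasionally derive e from unrounded rates
(one row differs by 1 from the one-decimal arithmetic); the ratio columns
are insensitive to this.

P/R/F use the standard percentage definitions with all zero-denominator
cases defined as 0 (needed for degenerate strata). Three-class (D/N/E)
reports compute one-vs-rest P/R/F per class and a support-weighted
average of the unrounded per-class metrics as the total row — weighted,
not micro, averaging: micro-averaging cannot reproduce the reference
total-precision value from its own confusion matrix, weighted averaging
reproduces all three totals.

Relabel-and-rescore inverts the gold labels of a curated list of pairs
and re-scores fixed predictions; no retraining is modeled. The shipped
list (`ppidiag/data/flagged_pairs.tsv`) contains the 51 benchmark pairs
flagged as likely annotation errors (23 positives, 28 negatives).

## Agreement and clustering

Agreement between two classifiers is the fraction of commonly covered
pairs with identical predicted labels, computed per setting (CV by
default; the settings are never pooled) and irrespective of gold.
Clustering agglomerates on 1 − agreement, which need not satisfy the
triangle inequality, so only metric-free criteria are offered: complete
linkage by default (the referenced clustering tool's default), average
and single by option. Classifiers are sorted lexicographically before
linkage so ties resolve deterministically. Dendrograms serialize to
Newick with height-difference branch lengths; labels containing
structural characters are quoted.

## Feature space

Features are extracted on an entity-blinded tokenization (ENT1/ENT2 for
the pair, PROT for other mentions; whitespace/punctuation tokens whose
spans partition the non-space characters). Clue lexicons (interaction,
negation, hedge; plain-text, user-overridable) are evaluated in four
scopes: s = whole sentence, b = before the earlier entity, w = strictly
between, a = after the later entity. The scope letters are an
interpretation of the conventional "before/between/after entities"
phrasing. "-ing word after first entity" is read as a modifier: the token
immediately following the earlier entity ends in "ing". The entity head
token is the last token overlapping the entity span.

Dependency features use BFS shortest paths on the undirected view of the
labeled dependency graph (unit weights, neighbors explored in ascending
token order so tied paths resolve to the lexicographically smallest).
Syntax-tree paths run leaf → lowest common ancestor → leaf. Label
distributions (whole structure and path) yield counts, relative
frequencies and Shannon entropies in bits; a Kullback–Leibler mode
computes divergence of each sentence's label distribution from the
corpus-wide background (the reference distribution is this package's
choice; the background is the natural null here). Missing layers and
disconnected entity pairs produce absent (NaN) features, never zeros.

Information gain discretizes continuous features by a supervised binary
split maximizing IG, recursing once per side (≤ 4 bins) — deterministic
and C4.5-flavored; no specific rule is canonical for this analysis. Signs
come from the Pearson/point-biserial correlation between the raw feature
and the binary class indicator. Difficulty prediction uses a CART
decision tree (entropy criterion, minimum leaf 25, depth cap 12 — chosen
for stability, no canonical hyperparameters exist) under document-level
10-fold cross-validation with a pooled confusion matrix by default;
training-set resubstitution is available since the reference protocol is
not stated. The interaction baselines cover five learner kinds (decision
tree, shallow "rule-list" tree, naive Bayes, logistic regression,
k-nearest-neighbor) with equivalent inductive biases to the usual
toolkit menu; document-level fold discipline is enforced with a hard
error on any train/test document overlap.

## Synthetic benchmark generator

The generator emulates study conditions, not English. Per sentence:

1. protein count k ~ categorical {2: 0.55, 3: 0.25, 4: 0.12, 5: 0.08};
   all C(k,2) pairs are enumerated;
2. a latent sentence type (positive-bearing / negative-only) is assigned
   by per-k-stratum quota; type odds decay with k as 1/(1 + 0.35(k−2)),
   and the quota scale q₀ solves the configured corpus positive ratio in
   closed form (infeasible targets raise an error stating the achievable
   range). Quota assignment rather than i.i.d. sampling keeps realized
   ratios within a fraction of a point of target at n ≥ 2000;
3. sentence length in words ~ N(27.6, 6) for positive-type and
   N(37.2, 8) for negative-type sentences — the published per-class mean
   lengths; within a type, pairs are positive with probability 0.95
   (positive-type) or 0.02 (floor);
4. entities are equally spaced with gap g = 3(d̄ + 1)/(k + 1), where d̄ is
   the class entity-distance target (7.15 positive / 9.67 negative) —
   the mean index gap over all pairs of k equally spaced entities is
   g(k+1)/3, so per-class distances are recovered by construction;
5. interaction / negation / hedge words and commas are inserted at
   class-conditioned rates, giving the baseline learners recoverable
   signal;
6. parse layers: a chain dependency graph over tokens whose edge labels
   are the fallback `dep` with probability 0.8 − 0.62·clarity and
   otherwise drawn from the standard label alphabet (nsubj, dobj, nn,
   appos, conj_and, det, amod, prep_with, prep_in, nsubjpass), plus a
   shallow constituency tree with an `X` fallback constituent — where
   clarity ~ U(0,1) is a per-sentence parse-quality variable.

Predictions: pair difficulty δ_p blends Beta(2,2) noise with the
sentence's realized parse opacity (1 − normalized dependency-label
entropy) at weight 0.5, so difficulty is partially recoverable from the
extracted features — difficult pairs sit in low-entropy, fallback-heavy
parses. Classifier correctness is
clamp(b_c − λ_c δ_p + ρ_c u_f(p) − [CL]·0.12 ± bias/2) with
u_f(p) ~ N(0, 0.15) shared within a representation family (inducing the
family-level agreement structure), clamping to [0.02, 0.98], and a bias
term (+ on gold-positive, − on gold-negative pairs) that steers the
realized positive-prediction rate; `positive_bias_for_rate` gives the
closed-form bias for a target rate. The CL penalty of 0.12 is the
midpoint of the reported 10–15 point CV→CL gap. δ and u depend only on
the prediction seed, so CV and CL matrices over the same corpus share
their latent difficulty, as the CV×CL crosstab analysis requires.

The five-corpus suite reproduces the benchmark pair counts
{5834, 9666, 433, 817, 330} (scaled by a size factor, built to exact pair
budgets) and positive ratios {0.171, 0.262, 0.376, 0.410, 0.497}, with a
13-classifier CV roster and a 12-classifier CL roster.

**What passing tests show, and what they do not.** The generator
reproduces the *aggregate couplings* the analyses consume (length/class,
distance/class, ratio/protein-count, difficulty/parse-opacity,
family-correlated errors, CV→CL degradation). It does not model real
syntax, lexical semantics, annotation-guideline artifacts, or the actual
error processes of kernel classifiers; test results on synthetic data
validate the *pipeline arithmetic and statistical machinery*, not claims
about any particular real corpus.

## Numerical conventions and degenerate inputs

Rounding for presentation is half-away-from-zero at the stated precision;
internal computation is unrounded. Empty difficulty classes are reported
absent rather than zero. Even vote committees require an explicit tie
rule (default is to error). Frequency distributions sum to 1 ± 1e−9 or
are absent. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical configuration and seed give
byte-identical corpora, predictions and report bundles.

## Problem sizes used in the shipped checks

The regression suite exercises the pipeline on synthetic corpora of
roughly 200–2200 pairs (the five-corpus suite at 5% scale, a single
2200-pair corpus for parameter-recovery and feature-analysis checks, and
10-replicate loops at 250–2000 pairs for stochastic properties), sizes at
which every targeted effect is comfortably resolvable. The acceptance
script operates on the published success-level histograms themselves and
is deterministic.

## Known limitations

* Sentence text is template-based token filler; features that depend on
  real lexical variety (e.g. character-level length in chars vs words)
  are only weakly distinguishable on synthetic data.
* The easy-side/difficult-side cutoff asymmetry is reverse-engineered
  from published set sizes; the original single-rule description does not
  reproduce two of the ten easy-side sizes, and the discrepancy is
  surfaced, not resolved.
* χ² overlap p-values in very small universes should be read through the
  corrected variant or an exact test; the default matches the reference
  methodology instead.
* No AUC, no score-level analysis, no model retraining: predictions are
  consumed as fixed label tables.
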