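# Methods

## The pipeline

The package implements a cascaded text-classification design for
drug-related microblog posts. Stage one assigns each tweet a *source/type*:
personal communication, official/media content, or retail promotion. Stage
two assigns *sentiment* (positive / negative / neutral-or-unidentifiable),
optionally restricted to the tweets stage one labels personal. The cascade
rests on one structural assumption, enforced by the corpus validator and
exploited by the classifier: **every media and retail tweet carries at least
one URL**, so a tweet with no URL is classified personal without consulting
any model. Trained source models therefore only ever see URL-bearing
tweets, both at training and at prediction time.

"Neutral" and "unidentifiable" are deliberately one label value. Separating
truly neutral statements from uninterpretable ones is out of scope here;
binary sentiment tasks simply exclude the neutral class.

## Featurization

* Tokenization: lowercase; maximal runs of letters/digits/apostrophes;
  stop words retained and no stemming (function words and inflected forms
  carry signal in 140-character texts); `#` stripped so hashtag words count
  as words; user mentions collapsed to the single placeholder `@user`;
  URLs removed from the token stream and handled separately.
* Features: unigrams plus adjacent bigrams, with multiplicity.
* URL features (source tasks only): the expanded URL is lowercased, its
  scheme dropped, host and path split on non-alphanumerics; pure-numeric
  tokens and tokens under 2 characters are discarded; the resulting
  unigrams/bigrams are prefixed `url:` so they can never collide with text
  features and feature provenance stays auditable. Approach 1 uses the
  short URL's host tokens (the shortener itself, weak but honest signal);
  approach 2 uses the expansion, falling back to short-host tokens when a
  link does not resolve. Sentiment tasks use text features only.
* Selection: per feature, a 2×2 presence/absence × class/rest contingency
  chi-square statistic (no continuity correction), maximized over classes
  for multiclass tasks; the top *k* = 500 features are kept, ties at the
  boundary broken by ascending feature string. Degenerate tables (a zero
  margin) score 0. Selection is re-fit inside every training fold — never
  on held-out data — which is the leakage-safe reading of selection-inside-CV.
* Weighting: `w(i,j) = tf(i,j) · ln(N/df(i))` with raw counts. The log base
  is natural; base choice only rescales all weights by a constant and
  cannot change any trained decision boundary beyond regularization
  scaling. No sublinear tf damping, no idf smoothing, no vector
  normalization. `df = 0` is impossible for selected features by
  construction and is treated as an invariant breach.

## Classifiers

scikit-learn estimators behind a uniform contract:

| algorithm | estimator | settings |
|---|---|---|
| `nb` | multinomial naive Bayes | Laplace α = 1.0; tf-idf weights as fractional counts |
| `lr` | logistic regression (liblinear) | L2, C = 1.0, tol = 1e-6, one-vs-rest |
| `svm` | linear SVC | hinge loss, C = 1.0, one-vs-rest |

None of these hyperparameters is prescribed by the underlying study design;
all are the field's standard defaults for ~500-dimensional sparse text and
every one can be overridden per task. Prediction is the argmax of per-class
scores (log-posteriors for NB, decision functions for LR/SVM); exact ties
break to the first class in sorted class order, making prediction
deterministic. A trained model refuses vectors from any other feature
space. Models serialize to a versioned JSON bundle carrying
hyperparameters, class list, learned parameters and the feature-space hash.

## Evaluation

5-fold cross-validation on an unstratified seeded random partition (fold
sizes differ by at most one; a stratified option exists but is off by
default, matching a plain random-partition protocol). Metrics: per-class
precision, recall and F1 with macro averages as unweighted means of the
per-class values (not pooled counts). Zero-denominator conventions: P, R
and F are defined as 0 and the class flagged in the report.

Classifier comparison uses a **paired** one-tailed t-test on per-fold
F-scores (df = n−1, H1: mean(a−b) > 0): pairing by shared folds is the
standard, more powerful choice when both classifiers were evaluated on
identical folds; an unpaired Welch variant is available behind a flag.
t = 0 yields p = 0.5; a zero-variance nonzero difference is reported as the
degenerate limit (p = 0 or 1) and flagged rather than surfacing NaN. No
multiple-testing correction is applied across pairwise comparisons.

## Lexicon baseline

The comparison baseline scores tokens from a valence dictionary
(values in [−4, 4]) with a negation rule (a negator within the 3 preceding
tokens multiplies the valence by −0.74) and booster increments applied
toward the valence's sign, then squashes the summed valence S to
`S/√(S² + 15)` and thresholds at ±0.05 (neutral in between, so a tweet with
no lexicon words is neutral). These constants follow the published
lexicon-and-rule method's defaults and are configurable.
Capitalization emphasis, punctuation amplification and emoji handling are
deliberately omitted — the tokenizer lowercases — because the baseline's
role here is the comparison contract, not bit-compatibility with any
particular release. Absolute baseline scores on real tweets are therefore
not a claim this package makes.

## Reliability

Krippendorff's alpha for nominal data, computed from the coincidence
matrix: α = 1 − Do/De, units with fewer than two codings excluded, missing
data handled naturally by the formulation. When all codings fall in one
category De = 0 and the result is flagged undefined rather than raised.
Per-category alphas collapse codings to {category, other} and rerun the
same routine, matching how agreement is conventionally reported per label.

## Synthetic corpus generator

The generator produces labeled corpora with the statistical skeleton the
pipeline assumes, not linguistically realistic tweets. Design:

* **Latent structure.** Each tweet gets a source and/or sentiment label
  with exact class counts (seeded permutation). The canonical fixtures use
  the compositions 330 media / 340 retail / 330 personal (N = 1000, all
  URL-bearing), 1292 / 921 / 787 positive/negative/neutral (N = 3000, with
  a latent source mix of 2633 personal + 367 media/retail), and
  1157 / 850 / 626 (N = 2633, all personal).
* **Text.** Background chatter is drawn Zipf-weighted from 200 synthetic
  tokens (`w000`…); length ~ Poisson(12) clipped to ≥3 tokens and trimmed
  to the classic 140-character limit. A tweet *expresses* its class through
  Binomial(3, `signal_strength`) expressive tokens per labeled axis,
  inserted at random positions — mirroring how a real tweet carries its
  sentiment in a short phrase rather than in every word. Ten percent of
  expressive tokens are hashtagged and 10% of tweets open with a mention,
  exercising tokenizer edge cases. Default `signal_strength` is 0.8;
  at 0 the corpus is pure noise and classifiers sit at chance.
* **Source noise vs URL signal.** Source-expressive *text* tokens are
  confusable: with probability `source_confusion` = 0.25 a tweet borrows
  another class's vocabulary, capping text-only source accuracy well below
  ceiling. URL signal is gated per slot by the same `signal_strength`:
  host and each path word come from the class's pools (news-like,
  shop-like, photo-sharing-like) with probability `signal_strength`, else
  from generic filler pools. Media/retail tweets always carry a URL;
  personal tweets link out with probability `url_rate_personal`
  (default 0.3; 1.0 in the URL-bearing source fixture). Every generated
  short URL maps to its expansion in the accompanying resolver table. This
  is what makes expanded-URL features (approach 2) strictly more
  informative than short-URL features (approach 1) whenever URL-borne
  signal exists — and equally uninformative when signal_strength is 0.
* **Domain inversion.** With probability `inversion_rate` (default 0.3) a
  positive tweet expresses itself exclusively through conventionally
  negative slang ("faded", "wasted", "fucked", "dead", "lit", "zooted").
  The accompanying valence lexicon covers conventional sentiment words and
  part of that slang but misses most domain argot (4 of 10 positive-pool
  words, 5 of 10 negative-pool, 4 of 6 inverted-pool are covered) — the
  coverage profile that makes real lexicon baselines underperform on
  slang-heavy drug talk. Consequently the baseline's macro F degrades
  monotonically in the inversion rate while trained classifiers, which
  simply learn the inverted tokens as positive features, stay flat.
* Determinism: one `numpy` Generator seeded from the `SyntheticSpec`; the manifest
  records every parameter and each tweet's latent assignment, so corpora
  are exactly regenerable.

### What the generator does *not* emulate

Real tweets have grammar, topic drift, sarcasm, creative orthography,
retweet duplication, bots, and class-correlated length; the generator has
none of these. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its qualitative mechanisms (URL expansion
helps source classification; supervised learning survives domain-inverted
sentiment where lexicons fail; the cascade never mislabels URL-less tweets)
operate as designed — not that any particular F-score would be achieved on
real data. Published F-scores from real labeled corpora are context, not
reproduction targets, because no such corpus is publicly deposited.

## Problem sizes and numerical choices

The standard runs use the canonical fixture sizes (1000 source / 3000
sentiment tweets, 5-fold CV) and a 10,000-tweet corpus for the cascade
soundness sweep; these sizes keep every check fast on a single CPU while
leaving thousands of candidate n-grams so the 500-feature cap genuinely
binds. Oracles (contingency-table chi-square, pairwise-disagreement alpha,
hand Bayes posteriors, t statistics) are checked to 1e-9 on small
instances. All stochastic components — the generator, fold assignment,
liblinear/SVC seeds — take explicit seeds, and a fixed (corpus, task, seed,
resolver) quadruple reproduces reports byte-identically.

## Known limitations

* The shipped keyword/blacklist configuration is illustrative; production
  keyword lists for drug-trend monitoring are curated continuously and are
  not reproduced here.
* Live URL resolution (bounded redirect following) exists but is
  network-dependent; all tests and standard runs use offline resolver
  tables.
* The relevance filter does not attempt language identification: tweets
  with a non-English tag are dropped, untagged tweets pass through.
* Binary source tasks introduce the synthetic complement label `rest`;
  it is a task artifact and not accepted in corpus files.
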