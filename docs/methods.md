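# Methods

## Scope and units

The package compares discussion forums by their content. One document is
one post: the downstream statistics ("proportion of posts containing a
term", document-topic counts per post) are defined at post level, so
thread-level aggregation is deliberately not offered. Crawling, HTML
scraping and database storage are out of scope; corpora enter as JSONL or
CSV files of post records.

## Tokenization

Unicode-aware lowercasing; apostrophes are deleted before splitting so
contractions collapse to the forms stop lists carry ("I'll" → "ill",
"don't" → "dont"); the text is split on non-alphanumeric characters; pure
numbers and single-character tokens are dropped; stop words are removed.
No stemming is applied — unstemmed topics are substantially easier to
label, and stemmed and unstemmed runs are known to give comparable
models. The packaged stop list is a standard English list augmented with
apostrophe-stripped contraction fragments; forum-member usernames should
be appended per site by the user (username detection is site-specific and
not attempted). The exact rule set is a declared convention of this
package: tokenizers of common topic-modeling toolkits behave similarly
but are not specified to this level of detail.

## Lexicon prevalence

Each contextual-factor category is a set of lowercase terms, possibly
multiword. A post matches a category if any term occurs in the lowercased
raw text on word boundaries; multiword terms match as contiguous word
sequences separated by arbitrary non-word material. Matching runs on raw
text, not the stop-filtered token stream, so stop-like terms ("hit")
still count — the stop list serves topic modeling only. A post counts
once per category no matter how many terms match. Prevalence of category
c in forum f is

    cell(f, c) = #{posts in f matching c} / #{posts in f},

undefined (an error) for empty forums. The heat map shows categories ×
forums on a sequential palette scaled on [0, max cell], so the darkest
hue is anchored at the largest observed value and cells are comparable
across forums.

The packaged lexicons carry the published example terms per category plus
natural inflectional variants; they are a starter set meant to be
extended per study. The iterative lexicon-development process (adding
keywords until forums stop differentiating) is a human procedure and not
code.

## Topic model

Standard LDA with symmetric priors: θ_d ~ Dir(α), φ_k ~ Dir(β), tokens
drawn topic-then-word. Inference is collapsed Gibbs sampling over token
assignments with the conditional

    p(z_i = k | z₋ᵢ, w) ∝ (n_dk^{-i} + α)(n_kw^{-i} + β) / (n_k^{-i} + Vβ).

Estimators are posterior-predictive means from the count tables,

    θ[d,k] = (n_dk + α)/(N_d + Kα),    φ[k,w] = (n_kw + β)/(n_k + Vβ),

averaged over thinned post-burn-in samples. Empty posts are retained with
a uniform prior θ row so every post keeps a row in the document-topic
matrix.

Defaults: α = 50/K, β = 0.01, 1000 sweeps, burn-in 500, samples every 10
sweeps — the common defaults of the Gibbs-sampling toolkits used in this
literature, stated explicitly so runs are reproducible. K is the one
modeling choice the user must make per forum (20 is a typical value for a
few-thousand-post forum; larger, shorter-post corpora may need 40);
held-out model selection is not implemented because K in this kind of
study is chosen by interpretability. Hyperparameter optimization
(asymmetric α) is likewise not implemented: symmetric priors keep the
enumeration oracle exact.

### Numerical and inference choices

* The per-token resampling loop is JIT-compiled (numba). Uniform variates
  are drawn outside the kernel from a single seeded generator, one per
  token per sweep, tokens visited in document order then token order —
  identical seed and input give bit-identical assignments.
* Initialization is incremental: tokens are assigned one at a time from
  the collapsed conditional given the tokens assigned so far. This starts
  chains near coherent modes and is markedly less prone to merged-topic
  local optima than uniform random assignment.
* `n_chains` (default 3) independent chains are run with seeds derived
  from the master seed; the returned state is the chain with the highest
  *mean* collapsed log p(z, w) over its retained sampling window. The
  window mean, rather than the final-sweep value, also demotes chains
  that were still converging while samples were being taken.
* Ties in top-word ranking break toward the lower word id, making reports
  deterministic.
* Topic labels are arbitrary (the posterior is invariant under label
  permutation); all recovery metrics first match fitted to reference
  topics greedily by per-topic L1 distance.

For toy corpora an exact reference is available: the posterior mean of θ
computed by summing the collapsed joint over all K^N assignment vectors.
The sampler is validated against it in the tests; with symmetric priors
the exact posterior mean is uniform by label exchangeability, so this
check verifies that the chain mixes across modes without bias.

## Document-topics and Topic Bars

A topic is a major constituent of a post when θ[d,k] ≥ T (the closed
inequality is a fixed convention of this package). The threshold T is
calibrated per forum by scanning a candidate grid — default 0.05 to 0.95
in steps of 0.05 — for the value minimizing |#document-topics(T) − N|,
ties broken toward the larger (stricter) threshold; nearest, not exact,
matching is intended (a forum can legitimately settle at, say, 2368
document-topics for 2092 posts). The fixed grid makes calibration
deterministic and auditable from the persisted θ. Posts whose θ never
reaches T contribute no pairs: they hold trace amounts of many topics and
are not representative of any one.

Per-topic shares are document-topic counts over the total; category
shares sum member topics' shares (the grouping of topics into categories
is a human judgment supplied as a CSV map; any topic with nonzero share
must be mapped). Both sum to 1, so each forum's Topic Bar spans the same
width and forums are directly comparable. Whether denominators are
computed per topic then summed or per category directly is immaterial
under these definitions.

## Synthetic data generator

The generator emulates the *scale and statistical structure* of real
forum corpora, not their language: posts are token sequences from the LDA
generative process over an abstract vocabulary ("w0001", …), with
log-normal token counts (default mean 189, SD 378, matching the
shortest-post forums of the motivating studies' scale; minimum 1) and
defaults n_posts = 2092, K_true = 20, V = 2000, α_true = 0.1,
β_true = 0.05. Small β_true yields sparse, well-separated topics so
parameter recovery is meaningful; small α_true makes each post dominated
by few topics, as real posts are. Lexicon terms are injected by exact
count: round(p·n) distinct posts get one uniformly chosen term appended,
with naturally occurring matches counted into the quota — so the
prevalence estimator must return p *exactly*, an equality test rather
than a statistical one.

What passing tests on this generator do **not** show: robustness to real
language (morphology, spelling variation, named entities, quoting),
burstiness within posts beyond LDA's assumptions, thread structure, or
temporal signal. They do show that each statistic computes what it claims
on data whose ground truth is known.

## Experiment sizes

The validation experiments use deliberately moderate sizes chosen to
exercise each property clearly: sampler-vs-enumeration on a 2-document,
6-token, V=3, K=2 corpus (the enumeration space, 2⁶ states, is exact);
parameter recovery on 500 posts × ~60 tokens, K=5, V=200; prevalence
recovery on 2000 posts; the end-to-end Topic Bars run on 400 posts with
one dominant topic per post (α_true = 0.05), K=4. Larger corpora only
sharpen these results.

## Known limitations

* Matching is surface-level: no negation handling, no disambiguation
  ("patch" the cessation aid vs software patch), no misspelling
  tolerance. Lexicons must be curated per domain and will age as slang
  evolves.
* The sampler is serial; very large corpora (10⁵+ posts) will want
  longer wall-clock budgets or fewer chains.
* Asymmetric priors and hyperparameter optimization are unsupported.
* Calibration assumes a unimodal-enough document-topic count curve over
  the grid; it is exact for what it claims (grid minimization) but the
  grid resolution bounds how close |D − N| can get.
* The topic→category grouping is input, not inference; automatic
  thematic grouping is a non-goal.
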