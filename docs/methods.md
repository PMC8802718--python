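# Methods

`opinionpulse` implements a complete opinion-mining and utilization-attribution
chain on synthetic data with known ground truth. This note documents the models,
the generator that defines the study conditions, the defaults that matter, and
what the package's tests do and do not establish.

## The analysis chain

The pipeline mirrors a public-health infodemiology design: a decade-long
social-media stream is searched for posts about a single health topic
(traditional Chinese medicine in the motivating setting), each on-topic post is
classified as positive / negative / neutral, the yearly **Opinion Polarity
Ratio** (OPR) summarizes criticism intensity, topics are mined separately from
positive and negative posts, and in parallel a region-year panel of health-care
utilization is attributed to candidate socio-economic factors.

### Opinion Polarity Ratio

For a period with `n+` positive and `n−` negative posts,

    OPR = n− / n+                    if n+ ≠ 0
    OPR = (n− + δ) / (n+ + δ)        if n+ = 0,  0 < δ ≤ 1.

The smoothing δ (default 1.0) exists only to keep the statistic finite when no
positive posts occur; the formula is implemented exactly as printed, with an
`always_smooth` flag for the variant that smooths both branches. Neutral posts
enter neither count. Binning is by calendar year. The headline quantity is the
trend ratio OPR(last year) / OPR(first year).

### Topic tracking (pool-based active learning)

A binary linear SVM (scikit-learn `LinearSVC`, balanced class weights, Platt-style
probability calibration fitted on the training decision values) is trained on a
small labeled seed set, scores the unlabeled pool, and the highest-scoring batch
is sent to the labeling oracle; the loop repeats for a fixed budget. The
selection score defaults to **uncertainty** (|p − 0.5| smallest): with on-topic
posts at ~25% of the stream, querying the decision boundary is what makes the
loop beat random labeling — exploitation sampling (largest positive probability),
appropriate when positives are rare, underperforms random here and is kept as a
config option together with a seeded random baseline. Defaults: batch 15,
budget 40 (600 oracle labels, ~3% of the default stream), threshold 0.5. The
loop, not the SVM solver, is the implemented contribution; the classifier is a
pluggable `fit`/`predict_proba` contract.

### Sentiment classification

Three stages:

1. **Lexicon bootstrap.** Nouns with document frequency ≥ `f_min` (2) become
   entity candidates; adjectives/verbs within a `window` (3 tokens) of an entity
   in ≥ `c_min` (2) posts become opinion-word candidates. This deterministic
   POS/co-occurrence rule replaces a joint topic model whose only role was
   speeding up expert labeling.
2. **Maximum-entropy expansion.** The conditional exponential model
   p(c|d,λ) ∝ exp(Σᵢ λᵢ,c fᵢ(d)) over counts of opinion words, entities, signed
   emoticons and !/? marks is trained by iterative scaling on a stratified
   expert-labeled seed sample (default 50 posts/class). A slack feature pads
   every instance to a constant feature total, giving the closed-form scaling
   update and a provably non-decreasing log-likelihood (asserted every
   iteration; updates at zero empirical expectation are capped so the guarantee
   survives separable data). The trained model labels the full on-topic set.
3. **Opinion-aware knowledge graph (OKG).** Nodes are lexicon tokens with
   polarity (n⁺ − n⁻)/(n⁺ + n⁻ + γ) over the machine-labeled posts containing
   them (γ = 1); undirected edges carry within-post co-occurrence counts. A
   post's score sums, over its matched nodes, the node polarity blended with one
   round of neighbor-weighted averaging (damping 1.0); the label is positive
   above τ, negative below −τ, else neutral.

Two numerical choices matter and were fixed by construction-level reasoning:

* **Class-balanced OKG input.** Because the corpus carries more negative than
  positive posts overall, raw counts shift *every* node polarity off zero and
  summed entity votes push genuinely neutral posts past the band. The OKG is
  therefore built from a confidence-ranked, pos/neg-balanced subset of the
  expansion set (all neutral-labeled posts are kept; deterministic, no extra
  randomness). This centers neutral scores at zero.
* **Neutral band τ = 0.35.** With summed node votes the band must sit between
  the neutral score spread (entity-node noise, sd ≈ 0.2) and the opinion-word
  mass of polar posts (≥ 0.5). A narrow band (e.g. 0.1) misroutes roughly half
  of the neutral class regardless of classifier quality.

One propagation round keeps the contract deterministic and bounded; iterating to
a fixpoint is deliberately not done (no convergence theory for the signed,
damped update is claimed). A `maxent_only` switch supports ablation.

### Topic mining (online LDA, dynamic vocabulary)

Stochastic variational LDA in the online style: per-minibatch document E-step,
then λ ← (1 − ρ_t) λ + ρ_t (η + (D/|batch|)·sstats) with ρ_t = (τ₀ + t)^(−κ).
Words never seen before are appended to the vocabulary with prior weight η
(plus a 1% seeded perturbation to break topic symmetry) before the update.
Defaults: K = 10, α = 1/K, η = 0.01, κ = 0.7, τ₀ = 64, minibatch 256. With
κ = 0 and one full-corpus batch the update reduces to a single batch variational
EM step (tested against an independent reference implementation, and recovery is
cross-checked against scikit-learn's online LDA). Positive and negative subsets
are scored against one shared model so their co-occurrence graphs are
comparable; per-polarity models are a flag. Topics are ranked by expected
assignment mass Σ_d (γ_dj − α); co-occurrence counts documents whose topic
proportions exceed θ = 0.2 for both topics.

### Factor analysis

The dependent variable is log(visits) on standardized factors, so Lasso
coefficients are comparable impact coefficients.

* **Lasso.** Cyclic coordinate descent with soft thresholding minimizing
  (1/2n)‖y − Xβ‖² + λ‖β‖₁, warm-started down a 50-point geometric λ-grid from
  λ_max = max|Xᵀ(y − ȳ)|/n. λ is chosen at the minimum mean error of seeded
  10-fold CV (not the one-SE rule). λ = 0 reproduces OLS to 1e-6 and the
  orthogonal-design closed form holds to 1e-8; scikit-learn's Lasso is used as
  an independent cross-check, never as the implementation.
* **Bayesian network.** Variables (30 factors + visits) are tertile-discretized;
  visits are first detrended by the yearly mean, since the deterministic growth
  component otherwise masks weaker factor dependencies in the contingency
  tables. Structure search is greedy hill-climbing over add/delete/reverse
  single-edge moves under the BDeu score (equivalent sample size 1.0, max 2
  parents, optional naive-Bayes initialization around visits). The score
  trajectory is non-decreasing by construction and the result is a DAG. The
  influential-factor set is the Markov blanket of visits.
* **Descriptive views.** Mean visits by factor-quantile level (4 levels), and an
  age histogram over bands 0–8, 9–15, 16–24, 25–35, 36–50, 51–65, 66+ chosen to
  expose the age groups of interest.

## The synthetic-data generator

The generator defines the study conditions; its defaults are the shipped
"headline-trend" calibration (`src/opinionpulse/data/headline_trend.yaml` — the
constants live in the config file, not in code).

**Post stream.** 10 years × 2,000 posts/year from 2004; 25% on-topic. The
synthetic language is a space-delimited token stream over four disjoint
vocabularies (120 topic entities tagged NOUN, 40 + 40 signed opinion words
tagged ADJ, 300 topic-neutral filler words); no attempt is made to imitate
Chinese orthography — the analysis logic, not segmentation, is the subject, so
an exact tag lexicon stands in for a statistical tagger. On-topic posts carry
1–3 entities; polar posts add 1 + Poisson(1.2) own-polarity words, an
opposite-polarity word with probability 0.1, a matching signed emoticon with
probability 0.3 and "!" with probability 0.4; neutral posts carry neither
polarity lexicon. Timestamps are uniform within the year; user IDs are
generated but unused. Yearly sentiment proportions keep the neutral share at
0.30 while the true OPR ramps log-linearly from 0.600 to 1.398 — an end-to-start
ratio of exactly 2.33.

**Region-year panel.** 34 regions × 2004–2014 × 30 named factors. Log visits =
region baseline (sd 0.2 around log-mean 11) + yearly growth with
growth = 2.41^(1/10) + 0.4·gdp + 0.25·education + N(0, 0.02). Factors emulate
within-year standardized indices: a persistent regional trait plus a yearly
innovation (sd 0.3) centered across regions within each year. National yearly
totals are normalized onto the deterministic growth path (flag
`normalize_totals`), so the configured 2.41-fold visits rise holds exactly;
this adds only a year-level constant on the log scale and is invisible to the
cross-sectional factor stages. Visits are kept as positive reals so the
zero-noise growth identity is exact.

**Visit-age records.** 50,000 records; ages are integers drawn uniformly within
bands under the mixture 25–35: 0.32, 0–8: 0.18, 36–50: 0.16, 16–24: 0.12,
51–65: 0.10, 9–15: 0.06, 66–90: 0.06 — a dominant young-adult mode and a
secondary early-childhood mode.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: natural-language ambiguity (sarcasm, negation scope,
out-of-lexicon sentiment), topic drift and vocabulary change inside the tracked
topic, user-level correlation and bursts, factor collinearity structures of real
national statistics (factors are generated independently), measurement error in
visit counts, and any real hospital's case mix. Results on this corpus
demonstrate that the chain recovers structure it is designed to detect when its
assumptions hold, not that it would attain the same accuracy on field data.

## Problem sizes and determinism

Default experiment scales were chosen to keep a full replication on one CPU in
tens of seconds: trend replication uses the full 10 × 2,000-post stream per
seed with ten seeds; factor-recovery checks use ten seeded 374-row panels;
topic-recovery uses 2,000 single-topic documents. Every stochastic component
(generators, fold shuffling, LDA initialization, the SVM's dual solver, seed
sampling) is driven by explicit seeds; rerunning the pipeline with an identical
configuration reproduces a byte-identical report, which the test suite asserts.

## Known limitations

* The OKG interaction between classifier confidence and propagation is
  heuristic; only one propagation round is supported.
* Iterative scaling is slow near the optimum compared with quasi-Newton
  methods; `max_iter` (500) bounds training rather than a gradient criterion.
* The BDeu hill-climber finds a local optimum; no restarts are performed
  (recovery on the default panel does not need them).
* `lasso_cv` refits on the CV-minimizing λ, which is known to over-select;
  coefficient *ranking* (the quantity used downstream) is stable, support size
  is not.
* The trend-ratio estimate divides two yearly OPRs each built from a few
  hundred posts, so single-seed replicates scatter by ±20%; the reported
  quantity is the ten-seed median.
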