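# opinionpulse

Opinion-polarity trend mining and health-utilization factor analysis, end to
end, on synthetic data with known ground truth.

## The problem

Public discussion of a health practice and actual use of it can move in
opposite directions. Measuring that requires an inference chain over two very
different data sources: a decade of social-media posts (find the on-topic
posts, classify each one's stance, track the yearly balance of criticism) and
a region-year panel of utilization statistics (attribute visit growth to
socio-economic factors). `opinionpulse` implements that chain for researchers
who want to study, test or teach the methodology without access to the
proprietary corpora such studies run on: every input is generated synthetically
with known ground truth, so every stage's output can be checked against what
was planted.

## The methods

* **Opinion Polarity Ratio (OPR)** per year: `n−/n+` when `n+ ≠ 0`, else the
  smoothed `(n− + δ)/(n+ + δ)` with `0 < δ ≤ 1`; the headline statistic is
  OPR(last year)/OPR(first year).
* **Topic tracking** by pool-based active learning around a linear SVM with
  probability calibration (uncertainty sampling by default; exploitation and
  random baselines available).
* **Sentiment classification**: a POS/co-occurrence lexicon bootstrap, a
  maximum-entropy classifier `p(c|d,λ) ∝ exp(Σᵢ λᵢ,c fᵢ(d))` trained by
  iterative scaling (monotone log-likelihood, asserted), and an opinion-aware
  knowledge graph whose polarity propagation assigns the final
  positive/negative/neutral stances.
* **Topic mining** with online variational LDA supporting a growable
  vocabulary; top-5 topics per polarity plus topic co-occurrence graphs.
* **Factor analysis** of log-visits on 30 standardized factors: hand-written
  Lasso coordinate descent with seeded 10-fold cross-validation, and BDeu
  hill-climbing Bayesian-network structure learning with Markov-blanket
  extraction; stratified-visit and age-distribution views.
* **Synthetic generators** for the labeled post stream, the 34-region ×
  2004–2014 panel and the visit-age records. The shipped "headline-trend"
  calibration plants a 2.33-fold rise in the true OPR and a 2.41-fold rise in
  national visits.

Model details, defaults and limitations: [`docs/methods.md`](docs/methods.md).

## Worked example

Run the opinion half of the pipeline (generate the default 20,000-post stream,
track the topic, classify stances, compute the yearly OPR) for one seed:

```python
>>> from opinionpulse import pipeline
>>> from opinionpulse.metrics import OprInput, opr
>>> opr(OprInput(n_pos=10, n_neg=20))
2.0
>>> opr(OprInput(n_pos=0, n_neg=5, delta=1.0))
6.0
>>> res = pipeline.headline_opr_trend(seed=1)
>>> res["series"]
 year  n_pos  n_neg      opr
 2004    226    108 0.477876
 2005    198    133 0.671717
 2006    213    125 0.586854
 2007    205    144 0.702439
 2008    205    165 0.804878
 2009    211    169 0.800948
 2010    181    185 1.022099
 2011    166    174 1.048193
 2012    163    177 1.085890
 2013    174    213 1.224138
>>> res["trend_ratio"]
2.5616219667943803
>>> res["n_on_topic"], res["n_posts"]
(4766, 20000)
```

The tracker retrieved 4,766 of the 20,000 posts as on-topic (the generator
plants ~25%); the classified stance counts yield a rising OPR whose
end-to-start ratio for this seed is 2.56 against the planted 2.33 — single
seeds scatter, which is why the headline figure is a ten-seed median. The
full pipeline, including topic mining and the panel stages, runs from the
shell:

```bash
pulse run --seed 1 --out out/      # writes out/report.json + CSV artifacts
pulse report --dir out/            # renders the summary figures
```

`pulse gen | track | classify | opr | factors` expose the individual stages.

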