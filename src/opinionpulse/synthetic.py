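"""Synthetic-data generators with known ground truth.

Three generators feed the pipeline: a labeled social-media post stream
(:func:`gen_corpus`), a region-year utilization panel (:func:`gen_panel`)
and hospital visit-age records (:func:`gen_visit_records`).  All are
deterministic under a fixed seed; the post generator is byte-reproducible
through :func:`write_posts_jsonl`.

The synthetic "language" is a stream of space-delimited tokens drawn from
four pairwise disjoint vocabularies: topic entities (``entity_*``, nouns),
positive and negative opinion words (``good_*`` / ``bad_*``, adjectives)
and topic-neutral filler (``fill_*``).  On-topic posts mix entities,
opinion words matching their true sentiment and filler; off-topic posts are
filler only.  Polar posts may carry a signed emoticon and an exclamation
mark; neutral posts carry neither polarity lexicon.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, CorpusConfig, PanelConfig, VisitConfig

__all__ = [
    "Post",
    "POSITIVE_EMOTICONS",
    "NEGATIVE_EMOTICONS",
    "gen_corpus",
    "gen_panel",
    "gen_visit_records",
    "gen_topic_corpus",
    "write_posts_jsonl",
    "read_posts_jsonl",
    "tag_lexicon",
    "FACTOR_NAMES",
    "factor_names",
]

POSITIVE_EMOTICONS: tuple[str, ...] = (":)", ":-)", ":D")
NEGATIVE_EMOTICONS: tuple[str, ...] = (":(", ":-(", ":'(")

#: thematic names for the default 30 candidate factors; the first two carry
#: the true effect in the default configuration.
FACTOR_NAMES: tuple[str, ...] = (
    "gdp", "education", "hospital_beds", "physicians", "medical_consumption",
    "insurance_coverage", "urbanization", "population", "income_per_capita",
    "pollution_pm", "pollution_so2", "temperature", "humidity", "rainfall",
    "road_density", "internet_penetration", "aging_ratio", "birth_rate",
    "unemployment", "pension_coverage", "retail_sales", "housing_price",
    "green_space", "water_quality", "literacy_rate", "college_density",
    "public_transport", "social_security_spend", "tourism", "energy_use",
)


@dataclass
class Post:
    """One synthetic social-media message with its ground truth."""

    id: str
    user: str
    timestamp: str  # ISO-8601
    text: str
    on_topic: bool
    sentiment: str | None  # "pos" | "neg" | "neu" for on-topic posts

    @property
    def year(self) -> int:
        return int(self.timestamp[:4])

    @property
    def tokens(self) -> list[str]:
        return self.text.split()

    def to_record(self) -> dict:
        truth: dict = {"on_topic": self.on_topic}
        if self.sentiment is not None:
            truth["sentiment"] = self.sentiment
        return {
            "id": self.id,
            "user": self.user,
            "timestamp": self.timestamp,
            "text": self.text,
            "truth": truth,
        }


def _vocab(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:03d}" for i in range(1, n + 1)]


def corpus_vocabularies(config: CorpusConfig) -> dict[str, list[str]]:
    """The four disjoint vocabularies implied by a corpus config."""
    return {
        "entity": _vocab("entity", config.n_entities),
        "positive": _vocab("good", config.n_positive),
        "negative": _vocab("bad", config.n_negative),
        "filler": _vocab("fill", config.n_filler),
    }


def tag_lexicon(config: CorpusConfig) -> dict[str, str]:
    """Exact POS lexicon of the synthetic language (entity→NOUN, opinion→ADJ).

    Filler words map to OTHER; the lexicon never reveals opinion-word
    polarity, only the word class a tagger would supply.
    """
    vocab = corpus_vocabularies(config)
    lex: dict[str, str] = {}
    for word in vocab["entity"]:
        lex[word] = "NOUN"
    for word in vocab["positive"] + vocab["negative"]:
        lex[word] = "ADJ"
    for word in vocab["filler"]:
        lex[word] = "OTHER"
    return lex


_SENTIMENTS = ("pos", "neg", "neu")


def gen_corpus(config: CorpusConfig) -> list[Post]:
    """Generate the labeled post stream described by ``config``.

    Post counts are exact (``n_years * posts_per_year``); the on-topic flag
    and per-year sentiment labels are sampled at the configured rates, and
    token emission follows the label: polar posts carry 1+Poisson opinion
    words of their own polarity (plus, with probability ``opposite_noise``,
    one of the opposite polarity), neutral posts carry none.
    """
    rng = np.random.default_rng(config.seed)
    vocab = corpus_vocabularies(config)
    entities = np.array(vocab["entity"])
    pos_words = np.array(vocab["positive"])
    neg_words = np.array(vocab["negative"])
    filler = np.array(vocab["filler"])
    trend = config.trend()
    n_users = max(2, config.posts_per_year // 4)

    posts: list[Post] = []
    pid = 0
    for y in range(config.n_years):
        year = config.start_year + y
        p_pos, p_neg, p_neu = trend[y]
        year_start = _dt.datetime(year, 1, 1)
        year_seconds = int((_dt.datetime(year + 1, 1, 1) - year_start).total_seconds())
        for _ in range(config.posts_per_year):
            pid += 1
            on_topic = bool(rng.random() < config.frac_on_topic)
            toks: list[str] = []
            sentiment: str | None = None
            if on_topic:
                sentiment = _SENTIMENTS[rng.choice(3, p=[p_pos, p_neg, p_neu])]
                n_ent = int(rng.integers(1, 4))
                toks.extend(rng.choice(entities, size=n_ent))
                if sentiment == "pos":
                    own, other = pos_words, neg_words
                elif sentiment == "neg":
                    own, other = neg_words, pos_words
                else:
                    own = other = None
                if own is not None:
                    n_own = 1 + int(rng.poisson(1.2))
                    toks.extend(rng.choice(own, size=n_own))
                    if rng.random() < config.opposite_noise:
                        toks.append(str(rng.choice(other)))
                    toks.extend(rng.choice(filler, size=int(rng.integers(3, 9))))
                else:
                    toks.extend(rng.choice(filler, size=int(rng.integers(4, 10))))
            else:
                toks.extend(rng.choice(filler, size=int(rng.integers(6, 13))))
            toks = [str(t) for t in rng.permutation(toks)]
            if sentiment == "pos" and rng.random() < config.emoticon_rate:
                toks.append(str(rng.choice(POSITIVE_EMOTICONS)))
            elif sentiment == "neg" and rng.random() < config.emoticon_rate:
                toks.append(str(rng.choice(NEGATIVE_EMOTICONS)))
            if sentiment in ("pos", "neg"):
                if rng.random() < config.punct_rate:
                    toks.append("!")
            elif rng.random() < config.punct_rate / 2:
                toks.append("?")
            ts = year_start + _dt.timedelta(seconds=int(rng.integers(year_seconds)))
            posts.append(
                Post(
                    id=f"p{pid:07d}",
                    user=f"u{int(rng.integers(n_users)):05d}",
                    timestamp=ts.isoformat(),
                    text=" ".join(toks),
                    on_topic=on_topic,
                    sentiment=sentiment,
                )
            )
    return posts


def write_posts_jsonl(posts: Iterable[Post], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps(post.to_record(), sort_keys=True, ensure_ascii=False))
            fh.write("\n")


def read_posts_jsonl(path: str | Path) -> list[Post]:
    posts = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            truth = rec.get("truth", {})
            posts.append(
                Post(
                    id=rec["id"],
                    user=rec["user"],
                    timestamp=rec["timestamp"],
                    text=rec["text"],
                    on_topic=bool(truth.get("on_topic", False)),
                    sentiment=truth.get("sentiment"),
                )
            )
    return posts


def factor_names(n_factors: int) -> list[str]:
    if n_factors <= len(FACTOR_NAMES):
        return list(FACTOR_NAMES[:n_factors])
    extra = [f"factor_{i:02d}" for i in range(len(FACTOR_NAMES) + 1, n_factors + 1)]
    return list(FACTOR_NAMES) + extra


def gen_panel(config: PanelConfig) -> pd.DataFrame:
    """Generate the region-year utilization panel.

    ``visits[r, y] = base_r * growth**(y - y0) * exp(sum_j beta_j x[r,y,j] + eps)``
    with ``eps ~ N(0, noise_sd)``.  Factor columns emulate within-year
    standardized indices (deviation of a region from the national mean):
    a persistent regional trait plus a yearly innovation that is centered
    across regions within each year, so national visit totals track the
    configured growth while regions move relative to each other.  The
    ground-truth coefficients are attached as ``DataFrame.attrs['true_beta']``.
    """
    rng = np.random.default_rng(config.seed)
    names = factor_names(config.n_factors)
    missing = set(config.beta) - set(names)
    if missing:
        raise ConfigError(f"beta names {sorted(missing)} not among factor columns")
    years = np.array(list(config.years))
    n_r, n_y, n_f = config.n_regions, len(years), config.n_factors

    base_log = config.base_log_mean + config.region_sd * rng.standard_normal(n_r)
    x_base = rng.standard_normal((n_r, n_f))
    innov = rng.standard_normal((n_r, n_y, n_f))
    if n_r > 1:
        innov = innov - innov.mean(axis=0, keepdims=True)  # relative-to-national index
    x = x_base[:, None, :] + config.factor_drift * innov
    beta = np.array([config.beta.get(name, 0.0) for name in names])
    eps = config.noise_sd * rng.standard_normal((n_r, n_y))
    log_growth = np.log(config.visits_growth) * (years - config.start_year)
    log_visits = base_log[:, None] + log_growth[None, :] + x @ beta + eps
    visits = np.exp(log_visits)
    if config.normalize_totals:
        # pin each year's national total to the deterministic growth path so
        # the configured end-to-start visits ratio holds exactly; this only
        # adds a year-level constant on the log scale and leaves the
        # cross-sectional factor structure untouched
        target = np.exp(base_log).sum() * np.exp(log_growth)
        visits = visits * (target / visits.sum(axis=0))[None, :]

    rows = []
    for r in range(n_r):
        region = f"region_{r + 1:02d}"
        for yi, year in enumerate(years):
            row = {"region": region, "year": int(year), "visits": visits[r, yi]}
            row.update({name: x[r, yi, j] for j, name in enumerate(names)})
            rows.append(row)
    panel = pd.DataFrame(rows)
    panel.attrs["true_beta"] = {name: config.beta.get(name, 0.0) for name in names}
    panel.attrs["visits_growth"] = config.visits_growth
    return panel


def gen_visit_records(config: VisitConfig) -> pd.DataFrame:
    """Generate visit records with ages drawn from the configured band mixture."""
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    if n == 0:
        return pd.DataFrame(columns=["visit_id", "year", "age"])
    weights = np.array([w for _, _, w in config.age_mixture])
    comps = rng.choice(len(weights), size=n, p=weights / weights.sum())
    lows = np.array([lo for lo, _, _ in config.age_mixture])
    highs = np.array([hi for _, hi, _ in config.age_mixture])
    # uniform integer age on the closed band of the drawn component
    ages = lows[comps] + (rng.random(n) * (highs[comps] - lows[comps] + 1)).astype(int)
    years = config.start_year + rng.integers(config.n_years, size=n)
    return pd.DataFrame(
        {
            "visit_id": [f"v{i + 1:07d}" for i in range(n)],
            "year": years,
            "age": ages,
        }
    )


def gen_topic_corpus(
    n_docs: int = 2000,
    n_topics: int = 2,
    vocab_per_topic: int = 30,
    doc_len: int = 20,
    seed: int = 11,
) -> tuple[list[list[str]], np.ndarray, list[list[str]]]:
    """Corpus of single-topic documents over disjoint per-topic vocabularies.

    Returns (documents, true topic index per document, per-topic vocabulary).
    Used to probe topic-model recovery: with disjoint vocabularies the true
    topics are identifiable up to permutation.
    """
    rng = np.random.default_rng(seed)
    vocabs = [
        [f"t{k}_w{i:03d}" for i in range(vocab_per_topic)] for k in range(n_topics)
    ]
    truth = rng.integers(n_topics, size=n_docs)
    docs = []
    for k in truth:
        words = rng.choice(vocabs[k], size=doc_len)
        docs.append([str(w) for w in words])
    return docs, truth, vocabs
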