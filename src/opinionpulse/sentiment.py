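"""Sentiment classification chain: lexicon bootstrap → maximum-entropy
classifier → opinion-aware knowledge graph (OKG) stance propagation.

The maximum-entropy model is the standard conditional exponential family

    p(c | d, λ) = exp(Σ_i λ_{i,c} f_i(d)) / Σ_{c'} exp(Σ_i λ_{i,c'} f_i(d))

trained by improved iterative scaling: a slack feature pads every instance
so the feature total is constant, under which the IIS update has the closed
form δ_{i,c} = (1/C) log(Ẽ[f_i 1_c] / E_λ[f_i 1_c]) and the training
log-likelihood is provably non-decreasing.  Features are non-negative
counts of bootstrapped opinion words and entities plus signed emoticon and
punctuation counts.

The trained model labels an expansion set from which the OKG is built:
nodes are entity/opinion/emoticon tokens with empirical polarity
(n⁺ − n⁻)/(n⁺ + n⁻ + γ), edges are within-post co-occurrence counts.  A
post's stance is the sum over matched nodes of their polarity blended with
one round of neighbor-weighted averaging, thresholded by the neutral band τ.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .preprocess import TokenizedPost
from .synthetic import NEGATIVE_EMOTICONS, POSITIVE_EMOTICONS

__all__ = [
    "SentimentError",
    "SentimentConfig",
    "Lexicons",
    "MaxEntModel",
    "bootstrap_lexicon",
    "extract_features",
    "maxent_prob",
    "train_maxent_iis",
    "build_okg",
    "propagate_stance",
    "classify_corpus",
    "stratified_seed_labels",
]

logger = logging.getLogger(__name__)

CLASSES = ("pos", "neg", "neu")
_POS_EMO = frozenset(POSITIVE_EMOTICONS)
_NEG_EMO = frozenset(NEGATIVE_EMOTICONS)


class SentimentError(ValueError):
    pass


@dataclass(frozen=True)
class SentimentConfig:
    """Knobs of the classification chain (none dictated by theory; see docs)."""

    window: int = 3          # co-occurrence window for the lexicon bootstrap
    f_min: int = 2           # min document frequency for entity candidates
    c_min: int = 2           # min co-occurring posts for opinion-word candidates
    smoothing: float = 1.0   # γ in the node-polarity denominator
    damping: float = 1.0     # weight of the neighbor average in propagation
    tau: float = 0.35        # neutral band on the propagated score
    tol: float = 1e-6
    max_iter: int = 500
    seeds_per_class: int = 50
    balance_okg: bool = True   # build the OKG from a class-balanced expansion
    maxent_only: bool = False  # ablation: skip the OKG, use MaxEnt labels


@dataclass
class Lexicons:
    entities: frozenset[str]
    sentiment_words: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.entities & self.sentiment_words
        if overlap:
            raise SentimentError(f"lexicons must be disjoint, share {sorted(overlap)[:3]}")


def bootstrap_lexicon(
    corpus: Sequence[TokenizedPost],
    window: int = 3,
    f_min: int = 2,
    c_min: int = 2,
) -> Lexicons:
    """POS/co-occurrence bootstrap of entity and opinion-word candidates.

    Nouns with document frequency ≥ ``f_min`` become entity candidates;
    adjectives/verbs found within ``window`` tokens of an entity candidate
    in at least ``c_min`` distinct posts become opinion-word candidates.
    """
    df: Counter[str] = Counter()
    for post in corpus:
        nouns = {t for t, g in zip(post.tokens, post.pos_tags) if g == "NOUN"}
        df.update(nouns)
    entities = {t for t, n in df.items() if n >= f_min}

    near_entity_posts: Counter[str] = Counter()
    for post in corpus:
        hits: set[str] = set()
        toks, tags = post.tokens, post.pos_tags
        ent_idx = [i for i, t in enumerate(toks) if t in entities]
        if not ent_idx:
            continue
        ent_pos = np.array(ent_idx)
        for i, (tok, tag) in enumerate(zip(toks, tags)):
            if tag in ("ADJ", "VERB") and np.abs(ent_pos - i).min() <= window:
                hits.add(tok)
        near_entity_posts.update(hits)
    sentiment_words = {t for t, n in near_entity_posts.items() if n >= c_min}
    return Lexicons(
        entities=frozenset(entities - sentiment_words),
        sentiment_words=frozenset(sentiment_words),
    )


def extract_features(post: TokenizedPost, lexicons: Lexicons) -> dict[str, float]:
    """Sparse non-negative count features for one post.

    One feature per opinion word (``sw=<token>``) and entity (``ent=<token>``)
    occurrence count, plus pooled signed emoticon counts and
    exclamation/question-mark counts.
    """
    fv: dict[str, float] = defaultdict(float)
    for tok in post.tokens:
        if tok in lexicons.sentiment_words:
            fv[f"sw={tok}"] += 1.0
        elif tok in lexicons.entities:
            fv[f"ent={tok}"] += 1.0
        elif tok in _POS_EMO:
            fv["emo_pos"] += 1.0
        elif tok in _NEG_EMO:
            fv["emo_neg"] += 1.0
        elif tok == "!":
            fv["punct_excl"] += 1.0
        elif tok == "?":
            fv["punct_quest"] += 1.0
    return dict(fv)


@dataclass
class MaxEntModel:
    """Fitted conditional exponential model over the three stance classes."""

    classes: tuple[str, ...]
    feature_index: dict[str, int]
    weights: np.ndarray           # (n_classes, n_features + 1); last col = slack
    feature_total: float          # the constant C the slack pads up to
    ll_history: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.feature_index)

    def design_row(self, fv: Mapping[str, float]) -> np.ndarray:
        row = np.zeros(self.n_features + 1)
        for name, val in fv.items():
            j = self.feature_index.get(name)
            if j is not None:
                row[j] = val
        row[-1] = max(self.feature_total - row[:-1].sum(), 0.0)
        return row

    def predict_log_proba(self, fv: Mapping[str, float]) -> np.ndarray:
        row = self.design_row(fv)
        logits = self.weights @ row
        return logits - logsumexp(logits)

    def predict_proba(self, fv: Mapping[str, float]) -> np.ndarray:
        return np.exp(self.predict_log_proba(fv))

    def predict(self, fv: Mapping[str, float]) -> str:
        return self.classes[int(np.argmax(self.predict_log_proba(fv)))]


def maxent_prob(fv: Mapping[str, float], model: MaxEntModel) -> dict[str, float]:
    """Class probabilities for one feature vector (unknown features ignored)."""
    p = model.predict_proba(fv)
    return {c: float(pi) for c, pi in zip(model.classes, p)}


def _design_matrix(
    fvs: Sequence[Mapping[str, float]], feature_index: Mapping[str, int]
) -> tuple[np.ndarray, float]:
    n, d = len(fvs), len(feature_index)
    F = np.zeros((n, d + 1))
    for i, fv in enumerate(fvs):
        for name, val in fv.items():
            j = feature_index.get(name)
            if j is not None:
                F[i, j] = val
    totals = F[:, :-1].sum(axis=1)
    C = float(totals.max()) if n else 1.0
    if C <= 0:
        C = 1.0
    F[:, -1] = C - totals
    return F, C


def train_maxent_iis(
    fvs: Sequence[Mapping[str, float]],
    labels: Sequence[str],
    classes: Sequence[str] = CLASSES,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MaxEntModel:
    """Fit λ by iterative scaling; log-likelihood is checked to be monotone.

    Instances are padded with a slack feature so the per-instance feature
    total is the constant ``C``; the scaling update is then exact.  Updates
    for coordinates with zero empirical expectation are capped (separable
    data drives them to −∞), which preserves the monotonicity guarantee.
    """
    if len(fvs) != len(labels):
        raise SentimentError("fvs and labels length mismatch")
    present = sorted(set(labels))
    if len(present) < 2:
        raise SentimentError("training labels contain a single class")
    classes = tuple(c for c in classes if c in present) or tuple(present)
    for fv in fvs:
        for v in fv.values():
            if not np.isfinite(v) or v < 0:
                raise SentimentError(f"feature values must be finite and >= 0, got {v}")

    names = sorted({name for fv in fvs for name in fv})
    feature_index = {name: j for j, name in enumerate(names)}
    F, C = _design_matrix(fvs, feature_index)
    n, d1 = F.shape
    y = np.array([classes.index(lab) for lab in labels])
    Y = np.zeros((n, len(classes)))
    Y[np.arange(n), y] = 1.0

    emp = (Y.T @ F) / n                       # empirical E[f_i 1_c]
    lam = np.zeros((len(classes), d1))
    cap = 10.0 / C
    ll_history: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        logits = F @ lam.T
        lse = logsumexp(logits, axis=1)
        ll = float((logits[np.arange(n), y] - lse).sum() / n)
        if ll_history and ll < ll_history[-1] - 1e-9:
            raise SentimentError("log-likelihood decreased during IIS")
        ll_history.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
        P = np.exp(logits - lse[:, None])
        model_exp = (P.T @ F) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.log(emp / model_exp) / C
        delta = np.where(emp <= 0, -cap, delta)
        delta = np.clip(delta, -cap, cap)
        delta[:, model_exp.sum(axis=0) <= 0] = 0.0  # features absent from data
        lam = lam + delta
    return MaxEntModel(
        classes=classes,
        feature_index=feature_index,
        weights=lam,
        feature_total=C,
        ll_history=ll_history,
    )


def _okg_tokens(post: TokenizedPost, lexicons: Lexicons) -> set[str]:
    keep = lexicons.entities | lexicons.sentiment_words | _POS_EMO | _NEG_EMO
    return {t for t in post.tokens if t in keep}


def build_okg(
    posts: Sequence[TokenizedPost],
    labels: Sequence[str],
    lexicons: Lexicons,
    smoothing: float = 1.0,
) -> nx.Graph:
    """Opinion-aware knowledge graph from stance-labeled posts.

    Node polarity is ``(n_pos - n_neg) / (n_pos + n_neg + smoothing)`` over
    labeled posts containing the token; undirected edges carry within-post
    co-occurrence counts.  No labeled posts → empty graph.
    """
    if len(posts) != len(labels):
        raise SentimentError("posts and labels length mismatch")
    n_pos: Counter[str] = Counter()
    n_neg: Counter[str] = Counter()
    edge_w: Counter[tuple[str, str]] = Counter()
    seen: set[str] = set()
    for post, lab in zip(posts, labels):
        toks = _okg_tokens(post, lexicons)
        seen.update(toks)
        if lab == "pos":
            n_pos.update(toks)
        elif lab == "neg":
            n_neg.update(toks)
        for a, b in combinations(sorted(toks), 2):
            edge_w[(a, b)] += 1
    graph = nx.Graph()
    for tok in sorted(seen):
        p, m = n_pos[tok], n_neg[tok]
        polarity = (p - m) / (p + m + smoothing) if (p + m + smoothing) > 0 else 0.0
        graph.add_node(tok, polarity=float(polarity), n_pos=p, n_neg=m)
    for (a, b), w in edge_w.items():
        graph.add_edge(a, b, weight=float(w))
    return graph


def propagate_stance(
    graph: nx.Graph,
    post: TokenizedPost,
    lexicons: Lexicons,
    tau: float = 0.35,
    damping: float = 1.0,
) -> tuple[str, float]:
    """One-round polarity propagation; returns (label, score).

    Each matched node's polarity is blended with the weighted mean polarity
    of its neighbors (``(pol + damping * nbr_mean) / (1 + damping)``); the
    post score is the sum over matched nodes, thresholded at ±τ.
    """
    matched = sorted(_okg_tokens(post, lexicons) & set(graph.nodes))
    if not matched:
        return "neu", 0.0
    score = 0.0
    for v in matched:
        pol = graph.nodes[v]["polarity"]
        nbrs = list(graph[v])
        if nbrs:
            w = np.array([graph[v][u]["weight"] for u in nbrs])
            pols = np.array([graph.nodes[u]["polarity"] for u in nbrs])
            nbr_mean = float((w * pols).sum() / w.sum())
        else:
            nbr_mean = pol
        score += (pol + damping * nbr_mean) / (1.0 + damping)
    if score > tau:
        return "pos", float(score)
    if score < -tau:
        return "neg", float(score)
    return "neu", float(score)


def stratified_seed_labels(
    posts: Sequence[TokenizedPost],
    truth: Mapping[str, str],
    per_class: int,
    seed: int = 0,
) -> dict[str, str]:
    """Small stratified ground-truth sample emulating expert seed labeling."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = defaultdict(list)
    for post in posts:
        lab = truth.get(post.post_id)
        if lab is not None:
            by_class[lab].append(post.post_id)
    seeds: dict[str, str] = {}
    for lab in sorted(by_class):
        ids = sorted(by_class[lab])
        take = min(per_class, len(ids))
        for pid in rng.choice(ids, size=take, replace=False):
            seeds[str(pid)] = lab
    return seeds


def classify_corpus(
    posts: Sequence[TokenizedPost],
    seed_labels: Mapping[str, str],
    config: SentimentConfig = SentimentConfig(),
) -> tuple[dict[str, tuple[str, float]], dict]:
    """Run the full chain on an on-topic corpus.

    bootstrap lexicons → train MaxEnt on the seed labels → MaxEnt labels the
    expansion set (all posts) → build the OKG from those labels → the OKG
    assigns the final stance of every post (MaxEnt-only ablation via
    ``config.maxent_only``).  Returns ``{post_id: (stance, score)}`` plus a
    dict of fitted artifacts (lexicons, model, graph).
    """
    if not posts:
        return {}, {"lexicons": None, "model": None, "graph": None}
    lexicons = bootstrap_lexicon(posts, config.window, config.f_min, config.c_min)
    seed_classes = sorted(set(seed_labels.values()))
    if len(seed_classes) < 2:
        lab = seed_classes[0] if seed_classes else "neu"
        logger.warning(
            "seed labels contain a single class (%s); degenerating to a constant classifier",
            lab,
        )
        return {p.post_id: (lab, 0.0) for p in posts}, {
            "lexicons": lexicons,
            "model": None,
            "graph": None,
        }
    by_id = {p.post_id: p for p in posts}
    fvs_seed = [extract_features(by_id[pid], lexicons) for pid in sorted(seed_labels)]
    labs_seed = [seed_labels[pid] for pid in sorted(seed_labels)]
    model = train_maxent_iis(
        fvs_seed, labs_seed, tol=config.tol, max_iter=config.max_iter
    )
    expansion: list[tuple[str, float]] = []
    for p in posts:
        proba = model.predict_proba(extract_features(p, lexicons))
        j = int(np.argmax(proba))
        expansion.append((model.classes[j], float(proba[j])))
    expansion_labels = [lab for lab, _ in expansion]
    if config.maxent_only:
        out = {
            p.post_id: (lab, conf) for p, (lab, conf) in zip(posts, expansion)
        }
        return out, {"lexicons": lexicons, "model": model, "graph": None}
    build_posts, build_labels = posts, expansion_labels
    if config.balance_okg:
        # equalize pos/neg mass entering the graph so class imbalance does not
        # shift every node polarity off zero; keep the most confident posts
        pos_i = [i for i, (lab, _) in enumerate(expansion) if lab == "pos"]
        neg_i = [i for i, (lab, _) in enumerate(expansion) if lab == "neg"]
        m = min(len(pos_i), len(neg_i))
        by_conf = lambda i: (-expansion[i][1], posts[i].post_id)  # noqa: E731
        keep = set(sorted(pos_i, key=by_conf)[:m]) | set(sorted(neg_i, key=by_conf)[:m])
        keep |= {i for i, (lab, _) in enumerate(expansion) if lab == "neu"}
        idx = sorted(keep)
        build_posts = [posts[i] for i in idx]
        build_labels = [expansion_labels[i] for i in idx]
    graph = build_okg(build_posts, build_labels, lexicons, smoothing=config.smoothing)
    out = {
        p.post_id: propagate_stance(graph, p, lexicons, config.tau, config.damping)
        for p in posts
    }
    return out, {"lexicons": lexicons, "model": model, "graph": graph}
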