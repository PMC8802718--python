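"""Lexicon bootstrap, maximum-entropy training and OKG stance propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import logsumexp

from opinionpulse import sentiment
from opinionpulse.preprocess import TokenizedPost
from opinionpulse.sentiment import (
    Lexicons,
    SentimentConfig,
    SentimentError,
    bootstrap_lexicon,
    build_okg,
    classify_corpus,
    extract_features,
    maxent_prob,
    propagate_stance,
    train_maxent_iis,
)


def _tp(pid, tokens, tags=None):
    tags = tags or ["OTHER"] * len(tokens)
    return TokenizedPost(post_id=pid, tokens=list(tokens), pos_tags=list(tags))


class TestBootstrapLexicon:
    def test_empty_corpus_gives_empty_sets(self):
        lex = bootstrap_lexicon([])
        assert lex.entities == frozenset() and lex.sentiment_words == frozenset()

    def test_adjacent_adjectives_all_become_sentiment_words(self):
        posts = [
            _tp(f"p{i}", ["herb", "fine"], ["NOUN", "ADJ"]) for i in range(3)
        ] + [_tp(f"q{i}", ["herb", "grim"], ["NOUN", "ADJ"]) for i in range(3)]
        lex = bootstrap_lexicon(posts, f_min=2, c_min=2)
        assert lex.entities == frozenset({"herb"})
        assert lex.sentiment_words == frozenset({"fine", "grim"})

    def test_rare_noun_excluded_by_frequency_threshold(self):
        posts = [_tp("p0", ["herb"], ["NOUN"])]
        lex = bootstrap_lexicon(posts, f_min=2)
        assert "herb" not in lex.entities

    def test_window_limits_cooccurrence(self):
        far = ["herb"] + ["x"] * 5 + ["fine"]
        tags = ["NOUN"] + ["OTHER"] * 5 + ["ADJ"]
        posts = [_tp(f"p{i}", far, tags) for i in range(3)]
        lex = bootstrap_lexicon(posts, window=3, f_min=2, c_min=2)
        assert "fine" not in lex.sentiment_words


class TestExtractFeatures:
    LEX = Lexicons(entities=frozenset({"herb"}), sentiment_words=frozenset({"fine"}))

    def test_no_matching_tokens_empty_support(self):
        fv = extract_features(_tp("p", ["plain", "words"]), self.LEX)
        assert fv == {}

    def test_single_sentiment_word(self):
        fv = extract_features(_tp("p", ["fine"]), self.LEX)
        assert fv == {"sw=fine": 1.0}

    def test_counts_match_brute_force_on_random_posts(self, rng):
        vocab = ["herb", "fine", "plain", ":)", ":(", "!", "?"]
        for i in range(100):
            toks = [str(t) for t in rng.choice(vocab, size=rng.integers(1, 12))]
            fv = extract_features(_tp(f"p{i}", toks), self.LEX)
            assert fv.get("sw=fine", 0) == toks.count("fine")
            assert fv.get("ent=herb", 0) == toks.count("herb")
            assert fv.get("emo_pos", 0) == toks.count(":)")
            assert fv.get("emo_neg", 0) == toks.count(":(")
            assert fv.get("punct_excl", 0) == toks.count("!")
            assert fv.get("punct_quest", 0) == toks.count("?")


class TestMaxEntProb:
    def test_zero_weights_give_uniform(self):
        model = train_maxent_iis(
            [{"a": 1.0}, {"b": 1.0}, {"c": 1.0}], ["pos", "neg", "neu"], max_iter=0
        )
        p = maxent_prob({"a": 1.0}, model)
        assert p == pytest.approx({"pos": 1 / 3, "neg": 1 / 3, "neu": 1 / 3})

    def test_log3_weight_gives_three_quarters(self):
        # two classes, one feature active for class A with weight ln 3
        model = train_maxent_iis(
            [{"f": 1.0}, {"f": 1.0}], ["A", "B"], classes=("A", "B"), max_iter=0
        )
        model.weights[0, model.feature_index["f"]] = np.log(3.0)
        p = maxent_prob({"f": 1.0}, model)
        assert p["A"] == pytest.approx(0.75)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.data())
    def test_probabilities_normalize(self, data):
        n_feat = data.draw(st.integers(1, 5))
        names = [f"f{j}" for j in range(n_feat)]
        fvs = [
            {n: data.draw(st.floats(0, 5)) for n in names},
            {n: data.draw(st.floats(0, 5)) for n in names},
        ]
        model = train_maxent_iis(fvs, ["pos", "neg"], max_iter=0)
        model.weights = data.draw(
            st.lists(
                st.floats(-3, 3), min_size=model.weights.size, max_size=model.weights.size
            )
        )
        model.weights = np.reshape(model.weights, (2, -1))
        p = model.predict_proba(fvs[0])
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p > 0).all()


def _nll_oracle(F, y, n_classes):
    """Negative conditional log-likelihood of the same design, for L-BFGS."""

    def f(lam_flat):
        lam = lam_flat.reshape(n_classes, F.shape[1])
        logits = F @ lam.T
        lse = logsumexp(logits, axis=1)
        return -(logits[np.arange(len(y)), y] - lse).sum() / len(y)

    return f


class TestTrainMaxEntIIS:
    def test_separable_toy_corpus_reaches_training_accuracy_one(self):
        fvs = [{"g": 2.0}, {"g": 1.0}, {"b": 1.0}, {"b": 3.0}]
        labels = ["pos", "pos", "neg", "neg"]
        model = train_maxent_iis(fvs, labels, max_iter=300)
        assert [model.predict(fv) for fv in fvs] == labels

    def test_identical_features_yield_empirical_priors(self):
        fvs = [{"x": 1.0}] * 4
        model = train_maxent_iis(fvs, ["pos", "neg", "pos", "neg"], max_iter=200)
        p = model.predict_proba({"x": 1.0})
        assert p == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_log_likelihood_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        fvs = [
            {f"f{j}": float(rng.poisson(1)) for j in range(6)} for _ in range(80)
        ]
        labels = [("pos", "neg", "neu")[i % 3] for i in range(80)]
        model = train_maxent_iis(fvs, labels, max_iter=200)
        diffs = np.diff(model.ll_history)
        assert (diffs >= -1e-9).all()

    def test_single_class_rejected(self):
        with pytest.raises(SentimentError):
            train_maxent_iis([{"a": 1.0}], ["pos"])

    def test_nonfinite_feature_rejected(self):
        with pytest.raises(SentimentError):
            train_maxent_iis([{"a": np.nan}, {"b": 1.0}], ["pos", "neg"])

    def test_converged_weights_match_gradient_ascent_oracle(self, rng):
        # 200 random non-separable instances; compare predictions, not raw λ
        # (the softmax parameterization is only identified up to shifts)
        n, d = 200, 5
        names = [f"f{j}" for j in range(d)]
        raw = rng.poisson(1.0, size=(n, d)).astype(float)
        logits = raw[:, 0] - raw[:, 1] + 0.5 * rng.standard_normal(n)
        labels = np.where(logits > 1, "pos", np.where(logits < -1, "neg", "neu"))
        if len(set(labels)) < 2:  # pragma: no cover
            pytest.skip("degenerate draw")
        fvs = [dict(zip(names, row)) for row in raw]
        model = train_maxent_iis(fvs, list(labels), tol=1e-12, max_iter=5000)

        F = np.vstack([model.design_row(fv) for fv in fvs])
        y = np.array([model.classes.index(lab) for lab in labels])
        res = minimize(
            _nll_oracle(F, y, len(model.classes)),
            np.zeros(model.weights.size),
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        lam_oracle = res.x.reshape(model.weights.shape)
        P_iis = np.exp(F @ model.weights.T - logsumexp(F @ model.weights.T, axis=1, keepdims=True))
        P_ora = np.exp(F @ lam_oracle.T - logsumexp(F @ lam_oracle.T, axis=1, keepdims=True))
        assert np.abs(P_iis - P_ora).max() < 1e-3


class TestOkg:
    LEX = Lexicons(
        entities=frozenset({"herb", "clinic"}),
        sentiment_words=frozenset({"fine", "grim"}),
    )

    def test_token_only_in_positive_posts_has_polarity_one(self):
        posts = [_tp("a", ["fine"]), _tp("b", ["fine"])]
        g = build_okg(posts, ["pos", "pos"], self.LEX, smoothing=0.0)
        assert g.nodes["fine"]["polarity"] == 1.0

    def test_balanced_token_has_polarity_zero(self):
        posts = [_tp(str(i), ["herb"]) for i in range(6)]
        g = build_okg(posts, ["pos"] * 3 + ["neg"] * 3, self.LEX)
        assert g.nodes["herb"]["polarity"] == 0.0

    def test_polarity_and_edges_match_counting_oracle(self, rng):
        vocab = ["herb", "clinic", "fine", "grim", "other"]
        posts, labels = [], []
        for i in range(50):
            toks = [str(t) for t in rng.choice(vocab, size=rng.integers(1, 6))]
            posts.append(_tp(f"p{i}", toks))
            labels.append(("pos", "neg", "neu")[rng.integers(3)])
        g = build_okg(posts, labels, self.LEX, smoothing=1.0)
        keep = {"herb", "clinic", "fine", "grim"}
        for tok in keep:
            n_pos = sum(1 for p, l in zip(posts, labels) if l == "pos" and tok in p.tokens)
            n_neg = sum(1 for p, l in zip(posts, labels) if l == "neg" and tok in p.tokens)
            if tok in g:
                assert g.nodes[tok]["polarity"] == pytest.approx(
                    (n_pos - n_neg) / (n_pos + n_neg + 1.0)
                )
        for a in keep:
            for b in keep:
                if a < b and g.has_edge(a, b):
                    w = sum(1 for p in posts if a in p.tokens and b in p.tokens)
                    assert g[a][b]["weight"] == w

    def test_polarity_bounded(self, rng):
        posts = [_tp(str(i), ["fine", "grim"]) for i in range(30)]
        labels = [("pos", "neg")[rng.integers(2)] for _ in range(30)]
        g = build_okg(posts, labels, self.LEX, smoothing=1.0)
        for _, attrs in g.nodes(data=True):
            assert -1.0 <= attrs["polarity"] <= 1.0

    def test_no_posts_gives_empty_graph(self):
        g = build_okg([], [], self.LEX)
        assert len(g) == 0


class TestPropagateStance:
    LEX = TestOkg.LEX

    def _graph(self, polarity):
        posts = [_tp("a", ["fine"]), _tp("b", ["grim"])]
        g = build_okg(posts, ["pos", "neg"], self.LEX, smoothing=0.0)
        return g

    def test_all_positive_nodes_give_positive(self):
        g = self._graph(1.0)
        label, score = propagate_stance(g, _tp("q", ["fine"]), self.LEX)
        assert label == "pos" and score > 0

    def test_no_overlap_gives_neutral(self):
        g = self._graph(1.0)
        assert propagate_stance(g, _tp("q", ["unrelated"]), self.LEX)[0] == "neu"

    def test_mirror_symmetric_post_is_neutral(self):
        g = self._graph(1.0)
        label, score = propagate_stance(g, _tp("q", ["fine", "grim"]), self.LEX)
        assert label == "neu" and score == pytest.approx(0.0)


class TestClassifyCorpus:
    def test_empty_corpus(self):
        out, artifacts = classify_corpus([], {}, SentimentConfig())
        assert out == {} and artifacts["model"] is None

    def test_neutral_only_corpus_stays_neutral(self, rng):
        posts = []
        for i in range(200):
            toks = [f"fill_{int(j):03d}" for j in rng.integers(0, 50, size=6)]
            posts.append(_tp(f"p{i}", toks))
        seeds = {f"p{i}": "neu" for i in range(5)}
        out, _ = classify_corpus(posts, seeds, SentimentConfig())
        frac_neu = sum(1 for lab, _ in out.values() if lab == "neu") / len(out)
        assert frac_neu >= 0.95

    def test_yearly_label_proportions_recover_generator_trend(
        self, small_on_topic, small_corpus, sentiment_truth
    ):
        seeds = sentiment.stratified_seed_labels(small_on_topic, sentiment_truth, 50, 0)
        out, _ = classify_corpus(small_on_topic, seeds, SentimentConfig())
        truth_labels = [sentiment_truth[pid] for pid in out]
        pred_labels = [out[pid][0] for pid in out]
        for lab in ("pos", "neg", "neu"):
            t = truth_labels.count(lab) / len(out)
            p = pred_labels.count(lab) / len(out)
            assert abs(t - p) < 0.07  # small corpus; the full-scale band is tighter
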