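"""Online variational LDA with a growable vocabulary.

Stochastic variational inference for latent Dirichlet allocation in the
style of Hoffman et al.'s online algorithm: each minibatch gets a
document-level variational E-step (optimizing γ_d and φ_dwk), the
topic-word variational parameters λ are then blended toward the minibatch's
sufficient statistics with step size ρ_t = (τ₀ + t)^(−κ).  Words never seen
before are appended to the vocabulary with prior weight η (plus a tiny
seeded perturbation to break topic symmetry) before the update — the
"dynamic vocabulary" adaptation needed for an open-ended post stream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import psi

__all__ = ["TopicsError", "OnlineLda", "top_topics", "topic_cooccurrence"]


class TopicsError(ValueError):
    pass


def _dirichlet_expectation(alpha: np.ndarray) -> np.ndarray:
    """E[log θ] for θ ~ Dirichlet(alpha), rows independent."""
    if alpha.ndim == 1:
        return psi(alpha) - psi(alpha.sum())
    return psi(alpha) - psi(alpha.sum(axis=1))[:, None]


@dataclass
class _Batch:
    word_ids: list[np.ndarray]
    word_counts: list[np.ndarray]


class OnlineLda:
    """Online-learning LDA over token-list documents.

    Parameters
    ----------
    n_topics : number of topics K.
    alpha : symmetric document-topic prior (default 1/K).
    eta : topic-word prior.
    kappa, tau0 : learning-rate decay, ρ_t = (τ₀ + t)^(−κ); κ=0 makes every
        update a full replacement (one full-corpus batch then equals a single
        batch variational EM step).
    total_docs : corpus-size scale D of the stochastic update; defaults to
        the number of documents seen so far when not given to ``update``.
    """

    def __init__(
        self,
        n_topics: int = 10,
        alpha: float | None = None,
        eta: float = 0.01,
        kappa: float = 0.7,
        tau0: float = 64.0,
        total_docs: int | None = None,
        seed: int = 0,
        e_step_iters: int = 100,
        e_step_tol: float = 1e-4,
    ):
        if n_topics < 1:
            raise TopicsError("n_topics must be >= 1")
        self.K = n_topics
        self.alpha = alpha if alpha is not None else 1.0 / n_topics
        self.eta = eta
        self.kappa = kappa
        self.tau0 = tau0
        self.total_docs = total_docs
        self.e_step_iters = e_step_iters
        self.e_step_tol = e_step_tol
        self._rng = np.random.default_rng(seed)
        self.vocab: dict[str, int] = {}
        self.lambda_ = np.zeros((self.K, 0))
        self.t = 0
        self.docs_seen = 0

    # ---------------------------------------------------------------- vocab

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    def _extend_vocab(self, docs: Sequence[Sequence[str]]) -> None:
        new = []
        for doc in docs:
            for w in doc:
                if w not in self.vocab:
                    self.vocab[w] = len(self.vocab)
                    new.append(w)
        if new:
            cols = self.eta * (
                1.0 + 0.01 * self._rng.random((self.K, len(new)))
            )
            self.lambda_ = np.hstack([self.lambda_, cols])

    def _encode(self, docs: Sequence[Sequence[str]], grow: bool) -> _Batch:
        if grow:
            self._extend_vocab(docs)
        ids, cts = [], []
        for doc in docs:
            counter = Counter(w for w in doc if w in self.vocab)
            keys = np.array(sorted(counter, key=self.vocab.get), dtype=object)
            ids.append(np.array([self.vocab[w] for w in keys], dtype=int))
            cts.append(np.array([counter[w] for w in keys], dtype=float))
        return _Batch(ids, cts)

    # --------------------------------------------------------------- E step

    def _e_step(self, batch: _Batch) -> tuple[np.ndarray, np.ndarray]:
        """Per-document variational optimization; returns (gamma, sstats)."""
        elog_beta = _dirichlet_expectation(self.lambda_)
        exp_elog_beta = np.exp(elog_beta)
        n_docs = len(batch.word_ids)
        gamma = np.full((n_docs, self.K), self.alpha)
        sstats = np.zeros_like(self.lambda_)
        for d in range(n_docs):
            ids, cts = batch.word_ids[d], batch.word_counts[d]
            if len(ids) == 0:
                continue
            gamma_d = self.alpha + cts.sum() / self.K * np.ones(self.K)
            exp_elog_beta_d = exp_elog_beta[:, ids]
            for _ in range(self.e_step_iters):
                exp_elog_theta = np.exp(_dirichlet_expectation(gamma_d))
                phi_norm = exp_elog_theta @ exp_elog_beta_d + 1e-100
                last = gamma_d
                gamma_d = self.alpha + exp_elog_theta * (
                    (cts / phi_norm) @ exp_elog_beta_d.T
                )
                if np.abs(gamma_d - last).mean() < self.e_step_tol:
                    break
            gamma[d] = gamma_d
            exp_elog_theta = np.exp(_dirichlet_expectation(gamma_d))
            phi_norm = exp_elog_theta @ exp_elog_beta_d + 1e-100
            sstats[:, ids] += np.outer(exp_elog_theta, cts / phi_norm) * exp_elog_beta_d
        return gamma, sstats

    # --------------------------------------------------------------- M step

    def update(
        self, minibatch: Sequence[Sequence[str]], total_docs: int | None = None
    ) -> np.ndarray:
        """One stochastic update; unseen words join the vocabulary first.

        Returns the minibatch's variational document-topic parameters γ.
        """
        if len(minibatch) == 0:
            raise TopicsError("minibatch must be non-empty")
        batch = self._encode(minibatch, grow=True)
        self.docs_seen += len(minibatch)
        D = total_docs or self.total_docs or self.docs_seen
        gamma, sstats = self._e_step(batch)
        rho = (self.tau0 + self.t) ** (-self.kappa)
        lambda_hat = self.eta + (D / len(minibatch)) * sstats
        self.lambda_ = (1.0 - rho) * self.lambda_ + rho * lambda_hat
        self.t += 1
        return gamma

    def fit(
        self,
        corpus: Sequence[Sequence[str]],
        batch_size: int = 256,
        passes: int = 1,
    ) -> "OnlineLda":
        if len(corpus) == 0:
            raise TopicsError("empty corpus")
        self.total_docs = self.total_docs or len(corpus)
        for _ in range(passes):
            for start in range(0, len(corpus), batch_size):
                self.update(corpus[start : start + batch_size])
        return self

    # ------------------------------------------------------------ inference

    @property
    def topic_word(self) -> np.ndarray:
        """Row-normalized topic-word distributions."""
        return self.lambda_ / self.lambda_.sum(axis=1, keepdims=True)

    def transform(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        """Variational γ for held-out documents (vocabulary frozen)."""
        batch = self._encode(docs, grow=False)
        gamma, _ = self._e_step(batch)
        return gamma

    def doc_topic(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        gamma = self.transform(docs)
        return gamma / gamma.sum(axis=1, keepdims=True)

    def top_words(self, topic: int, n: int = 10) -> list[str]:
        inv = {j: w for w, j in self.vocab.items()}
        order = np.argsort(self.lambda_[topic])[::-1][:n]
        return [inv[j] for j in order]


def top_topics(
    model: OnlineLda, docs: Sequence[Sequence[str]], k: int = 5, topn: int = 10
) -> list[dict]:
    """Topics ranked by total expected assignment mass over ``docs``.

    Mass of topic j is Σ_d (γ_dj − α), the expected token count assigned to
    the topic in the subset.
    """
    if k > model.K:
        raise TopicsError(f"k={k} exceeds model topic count {model.K}")
    if len(docs) == 0:
        raise TopicsError("empty document subset")
    gamma = model.transform(docs)
    mass = (gamma - model.alpha).sum(axis=0)
    order = np.argsort(-mass, kind="stable")[:k]
    return [
        {"topic": int(j), "mass": float(mass[j]), "top_words": model.top_words(int(j), topn)}
        for j in order
    ]


def topic_cooccurrence(
    model: OnlineLda, docs: Sequence[Sequence[str]], theta: float = 0.2
) -> np.ndarray:
    """Symmetric topic co-occurrence counts: documents where both topic
    proportions exceed ``theta``.  Diagonal is zero."""
    if not 0.0 < theta < 1.0:
        raise TopicsError(f"theta must lie in (0, 1), got {theta}")
    props = model.doc_topic(docs)
    present = (props > theta).astype(float)
    W = present.T @ present
    np.fill_diagonal(W, 0.0)
    return W
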