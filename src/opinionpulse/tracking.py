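"""Topic tracking by pool-based active learning with a linear max-margin model.

The loop follows the classic retrieval-oriented recipe: train a binary
classifier on the labeled set ``D_l``, score the unlabeled pool ``D_u``,
hand the ``batch_size`` highest-scoring posts to the labeling oracle, move
them into ``D_l``, retrain, and repeat for a fixed budget of iterations.
The selection score defaults to informativeness, i.e. uncertainty sampling
(smallest ``|p - 0.5|``): on corpora where on-topic posts are a sizable
minority, querying the decision boundary is what makes the loop beat random
labeling.  Exploitation sampling (largest positive-class probability, the
rare-positive retrieval variant) and a seeded random baseline are available
via ``strategy``.

The classifier is pluggable: anything with ``fit(X, y)`` and
``predict_proba(X) -> p(on-topic)`` works.  The default wraps a linear SVM
with Platt-style probability calibration on its decision values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .synthetic import Post

__all__ = [
    "TrackingError",
    "TrackingConfig",
    "ActiveLearningState",
    "CalibratedLinearSVM",
    "vectorize_corpus",
    "al_iteration",
    "track_topic",
]


class TrackingError(RuntimeError):
    pass


class ProbClassifier(Protocol):
    def fit(self, X, y) -> "ProbClassifier": ...
    def predict_proba(self, X) -> np.ndarray: ...


class CalibratedLinearSVM:
    """Linear SVM whose decision values are squashed by a fitted logistic map.

    ``predict_proba`` returns the positive-class probability only (shape
    ``(n,)``).  Calibration is fitted on the training data itself, which is
    adequate for ranking pool posts by score.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self._svm: LinearSVC | None = None
        self._platt: LogisticRegression | None = None

    def fit(self, X, y) -> "CalibratedLinearSVM":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise TrackingError(
                "training labels contain a single class; seed both classes"
            )
        # the labeled set grows heavily positive under exploitation sampling;
        # balanced class weights keep the margin from swallowing the pool.
        # random_state pins the dual solver's coordinate order (determinism)
        self._svm = LinearSVC(C=self.C, class_weight="balanced", random_state=0).fit(X, y)
        scores = self._svm.decision_function(X).reshape(-1, 1)
        self._platt = LogisticRegression(C=1e3, class_weight="balanced").fit(scores, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self._svm is None or self._platt is None:
            raise TrackingError("classifier not fitted")
        scores = self._svm.decision_function(X).reshape(-1, 1)
        return self._platt.predict_proba(scores)[:, 1]


@dataclass(frozen=True)
class TrackingConfig:
    batch_size: int = 15
    budget: int = 40
    threshold: float = 0.5
    strategy: str = "uncertainty"  # "uncertainty" | "exploit" | "random"
    seed: int = 0
    svm_C: float = 1.0

    def __post_init__(self) -> None:
        if self.strategy not in ("exploit", "uncertainty", "random"):
            raise TrackingError(f"unknown strategy {self.strategy!r}")


@dataclass
class ActiveLearningState:
    """Labeled set, unlabeled pool and the current classifier."""

    labeled: dict[str, int]
    pool: list[str]
    classifier: ProbClassifier
    iteration: int = 0
    budget: int = 20
    terminated: bool = False

    def __post_init__(self) -> None:
        overlap = set(self.labeled) & set(self.pool)
        if overlap:
            raise TrackingError(f"labeled set and pool overlap: {sorted(overlap)[:3]}")

    @property
    def n_total(self) -> int:
        return len(self.labeled) + len(self.pool)


def vectorize_corpus(
    token_lists: Mapping[str, Sequence[str]],
) -> tuple[sp.csr_matrix, dict[str, int]]:
    """Bag-of-words matrix over the whole corpus; returns (X, post_id→row)."""
    ids = sorted(token_lists)
    vec = CountVectorizer(analyzer=lambda toks: toks)
    X = vec.fit_transform([list(token_lists[i]) for i in ids])
    return X.tocsr(), {pid: row for row, pid in enumerate(ids)}


def _selection_order(
    scores: np.ndarray, pool: Sequence[str], strategy: str, rng: np.random.Generator
) -> np.ndarray:
    if strategy == "exploit":
        key = -scores
    elif strategy == "uncertainty":
        key = np.abs(scores - 0.5)
    else:  # random
        key = rng.random(len(pool))
    # ties broken by post id order (pool is kept sorted)
    return np.lexsort((np.arange(len(pool)), key))


def _fit(state: ActiveLearningState, X, rows: Mapping[str, int]) -> None:
    ids = sorted(state.labeled)
    Xl = X[[rows[i] for i in ids]]
    yl = np.array([state.labeled[i] for i in ids])
    state.classifier.fit(Xl, yl)


def al_iteration(
    state: ActiveLearningState,
    batch_size: int,
    oracle: Callable[[str], int],
    X,
    rows: Mapping[str, int],
    strategy: str = "exploit",
    rng: np.random.Generator | None = None,
) -> ActiveLearningState:
    """One query-label-retrain round; returns the updated state (in place).

    An empty pool terminates the loop without change; the classifier must
    already be fitted on the current labeled set.
    """
    if not state.pool:
        state.terminated = True
        return state
    if state.iteration >= state.budget:
        state.terminated = True
        return state
    rng = rng if rng is not None else np.random.default_rng(0)
    scores = state.classifier.predict_proba(X[[rows[i] for i in state.pool]])
    order = _selection_order(scores, state.pool, strategy, rng)
    chosen = [state.pool[i] for i in order[: min(batch_size, len(state.pool))]]
    for pid in chosen:
        state.labeled[pid] = int(oracle(pid))
    chosen_set = set(chosen)
    state.pool = [pid for pid in state.pool if pid not in chosen_set]
    state.iteration += 1
    _fit(state, X, rows)
    if not state.pool:
        state.terminated = True
    return state


def track_topic(
    posts_tokens: Mapping[str, Sequence[str]],
    seed_labels: Mapping[str, int],
    config: TrackingConfig = TrackingConfig(),
    oracle: Callable[[str], int] | None = None,
    truth: Mapping[str, int] | None = None,
) -> tuple[list[str], ProbClassifier, ActiveLearningState]:
    """Run the active-learning loop and classify the full corpus.

    ``seed_labels`` must contain at least one example per class.  The
    labeling oracle defaults to looking up ``truth`` (ground-truth labels in
    the synthetic setting).  Returns the post ids whose final on-topic
    probability reaches ``config.threshold``, the final classifier, and the
    terminal loop state.
    """
    if oracle is None:
        if truth is None:
            raise TrackingError("provide an oracle or ground-truth labels")
        oracle = lambda pid: int(truth[pid])  # noqa: E731
    if len(set(seed_labels.values())) < 2:
        raise TrackingError("seed_labels must contain both classes")
    X, rows = vectorize_corpus(posts_tokens)
    pool = sorted(set(posts_tokens) - set(seed_labels))
    state = ActiveLearningState(
        labeled=dict(seed_labels),
        pool=pool,
        classifier=CalibratedLinearSVM(C=config.svm_C),
        budget=config.budget,
    )
    _fit(state, X, rows)
    rng = np.random.default_rng(config.seed)
    while not state.terminated and state.iteration < state.budget:
        al_iteration(state, config.batch_size, oracle, X, rows, config.strategy, rng)
    all_ids = sorted(posts_tokens)
    probs = state.classifier.predict_proba(X[[rows[i] for i in all_ids]])
    selected = [pid for pid, p in zip(all_ids, probs) if p >= config.threshold]
    return selected, state.classifier, state
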