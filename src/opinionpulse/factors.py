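"""Utilization factor analysis: panel preprocessing, Lasso with 10-fold CV,
Bayesian-network structure learning, and the stratified-visit / age views.

The Lasso solver is cyclic coordinate descent with soft thresholding on the
standardized design, minimizing ``(1/2n)‖y − Xβ‖² + λ‖β‖₁``; the penalty is
chosen by seeded 10-fold cross validation at the minimum mean error.  The
Bayesian network is learned on quantile-discretized variables by greedy
hill-climbing (add / delete / reverse single-edge moves) under the BDeu
score with equivalent sample size ``ess``, optionally initialized as a
naive-Bayes star around the visits node; the factors reported as
influential are the Markov blanket of visits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "FactorError",
    "PanelTable",
    "LassoFit",
    "BnStructure",
    "preprocess_panel",
    "soft_threshold",
    "lasso_cd",
    "lasso_cv",
    "discretize",
    "learn_bn",
    "influential_factors",
    "stratified_visits",
    "age_distribution",
    "AGE_BIN_EDGES",
    "AGE_BIN_LABELS",
]

logger = logging.getLogger(__name__)


class FactorError(ValueError):
    pass


# ------------------------------------------------------------------ panel


@dataclass
class PanelTable:
    """Standardized region-year panel ready for regression/BN stages."""

    X: pd.DataFrame            # standardized factor columns, indexed (region, year)
    y: pd.Series               # log visits
    visits: pd.Series          # raw visits
    dropped: list[str] = field(default_factory=list)
    means: pd.Series | None = None
    scales: pd.Series | None = None

    @property
    def factor_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def y_detrended(self) -> pd.Series:
        """Log visits minus the yearly mean (removes the common growth trend).

        The cross-sectional structure the factor stages look for sits on top
        of a large deterministic year trend; removing the per-year mean
        before discretization keeps the trend from masking weaker factor
        dependencies in the Bayesian-network stage.
        """
        year = self.y.index.get_level_values("year")
        return self.y - self.y.groupby(year).transform("mean")


def preprocess_panel(
    raw: pd.DataFrame, start_year: int = 2004, end_year: int = 2014
) -> PanelTable:
    """Filter to the study window, standardize factors, log-transform visits.

    Zero-variance factor columns are dropped with a logged warning.  The
    dependent variable is log(visits) so factor coefficients act on relative
    utilization.
    """
    required = {"region", "year", "visits"}
    missing = required - set(raw.columns)
    if missing:
        raise FactorError(f"missing required columns: {sorted(missing)}")
    df = raw[(raw["year"] >= start_year) & (raw["year"] <= end_year)].copy()
    if len(df) < 2:
        raise FactorError("fewer than 2 rows remain after the year filter")
    if df.duplicated(["region", "year"]).any():
        raise FactorError("duplicate (region, year) rows")
    if (df["visits"] < 0).any():
        raise FactorError("visits must be non-negative")
    df = df.sort_values(["region", "year"]).set_index(["region", "year"])
    factors = [c for c in df.columns if c != "visits"]
    X = df[factors].astype(float)
    if not np.isfinite(X.to_numpy()).all():
        raise FactorError("non-finite factor values")
    stds = X.std(ddof=0)
    dropped = list(stds.index[stds == 0.0])
    for col in dropped:
        logger.warning("dropping zero-variance factor column %r", col)
    X = X.drop(columns=dropped)
    means, scales = X.mean(), X.std(ddof=0)
    Xs = (X - means) / scales
    return PanelTable(
        X=Xs,
        y=np.log(df["visits"].astype(float)),
        visits=df["visits"].astype(float),
        dropped=dropped,
        means=means,
        scales=scales,
    )


# ------------------------------------------------------------------ lasso


def soft_threshold(z: float | np.ndarray, lam: float):
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def lasso_cd(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Cyclic coordinate descent for (1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁.

    ``X`` is expected centered/standardized column-wise; the intercept is
    the mean of ``y``.  Converges when the largest coefficient change in a
    sweep falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise FactorError("non-finite entries in X or y")
    if lam < 0:
        raise FactorError("lambda must be non-negative")
    n, p = X.shape
    intercept = float(y.mean())
    yc = y - intercept
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    col_ss = (X**2).sum(axis=0) / n
    r = yc - X @ beta
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if col_ss[j] == 0.0:
                continue
            b_old = beta[j]
            rho = b_old * col_ss[j] + X[:, j] @ r / n
            b_new = soft_threshold(rho, lam) / col_ss[j]
            if b_new != b_old:
                r += X[:, j] * (b_old - b_new)
                beta[j] = b_new
                max_delta = max(max_delta, abs(b_new - b_old))
        if max_delta < tol:
            break
    return beta, intercept


@dataclass
class LassoFit:
    lambda_: float
    beta: pd.Series
    intercept: float
    cv_curve: pd.DataFrame     # columns: lambda, mean_error, sd_error, nonzero
    fold_seed: int

    def top_factors(self, k: int = 2) -> list[str]:
        return list(self.beta.abs().sort_values(ascending=False).index[:k])


def lasso_cv(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    n_folds: int = 10,
    lambda_grid: Sequence[float] | None = None,
    seed: int = 0,
    n_lambdas: int = 50,
) -> LassoFit:
    """Lasso path with seeded 10-fold CV; the penalty at minimum mean error wins."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    if n < n_folds:
        raise FactorError(f"n={n} smaller than n_folds={n_folds}")
    if lambda_grid is None:
        lam_max = np.abs(Xa.T @ (ya - ya.mean())).max() / n
        lam_max = max(lam_max, 1e-12)
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    logger.info("lasso_cv: %d folds, seed %d, %d lambdas", n_folds, seed, len(lambda_grid))

    errors = np.zeros((n_folds, len(lambda_grid)))
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = Xa[train_mask], ya[train_mask]
        Xte, yte = Xa[test_idx], ya[test_idx]
        beta = np.zeros(Xa.shape[1])
        for li, lam in enumerate(lambda_grid):
            beta, b0 = lasso_cd(Xtr, ytr, lam, beta0=beta)  # warm start down the path
            pred = b0 + Xte @ beta
            errors[f, li] = np.mean((yte - pred) ** 2)
    mean_err = errors.mean(axis=0)
    sd_err = errors.std(axis=0, ddof=1)
    best = int(np.argmin(mean_err))

    # full-data path for the sparsity curve and the final fit
    beta = np.zeros(Xa.shape[1])
    nonzero = []
    betas = []
    for lam in lambda_grid:
        beta, b0 = lasso_cd(Xa, ya, lam, beta0=beta)
        betas.append(beta.copy())
        nonzero.append(int(np.sum(np.abs(beta) > 1e-10)))
    final_beta, final_b0 = betas[best], float(ya.mean())
    curve = pd.DataFrame(
        {
            "lambda": lambda_grid,
            "mean_error": mean_err,
            "sd_error": sd_err,
            "nonzero": nonzero,
        }
    )
    return LassoFit(
        lambda_=float(lambda_grid[best]),
        beta=pd.Series(final_beta, index=names),
        intercept=final_b0,
        cv_curve=curve,
        fold_seed=seed,
    )


# ------------------------------------------------------------- discretize


def discretize(
    df: pd.DataFrame, n_bins: int = 3
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Quantile-cut every column into ordinal levels; returns (codes, edges).

    Columns with fewer distinct values than bins are coded by their distinct
    values; constant columns collapse to a single level.
    """
    out = {}
    edges: dict[str, np.ndarray] = {}
    for col in df.columns:
        x = df[col].astype(float)
        if x.nunique() < n_bins:
            codes, uniq = pd.factorize(x, sort=True)
            out[col] = codes
            edges[col] = np.asarray(uniq, dtype=float)
        else:
            binned, bin_edges = pd.qcut(x, n_bins, labels=False, retbins=True, duplicates="drop")
            out[col] = binned.astype(int).to_numpy()
            edges[col] = bin_edges
        logger.debug("discretize %s edges=%s", col, edges[col])
    return pd.DataFrame(out, index=df.index), edges


# ------------------------------------------------------------------- BN


@dataclass
class BnStructure:
    graph: nx.DiGraph
    score: float
    trajectory: list[float]
    params: dict

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)


class _BDeuScorer:
    """Decomposable BDeu family scores with caching."""

    def __init__(self, data: pd.DataFrame, ess: float = 1.0):
        self.names = list(data.columns)
        self.codes = {c: data[c].to_numpy(dtype=np.int64) for c in self.names}
        self.arity = {c: int(self.codes[c].max()) + 1 for c in self.names}
        self.n = len(data)
        self.ess = ess
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(self, node: str, parents: Sequence[str]) -> float:
        key = (node, tuple(sorted(parents)))
        if key in self._cache:
            return self._cache[key]
        r = self.arity[node]
        q = 1
        if parents:
            combo = np.zeros(self.n, dtype=np.int64)
            for p in sorted(parents):
                combo = combo * self.arity[p] + self.codes[p]
                q *= self.arity[p]
            joint = combo * r + self.codes[node]
        else:
            joint = self.codes[node].copy()
        a_j = self.ess / q
        a_jk = self.ess / (q * r)
        joint_counts = np.bincount(joint, minlength=q * r).reshape(q, r)
        parent_counts = joint_counts.sum(axis=1)
        score = float(
            np.sum(gammaln(a_j) - gammaln(a_j + parent_counts))
            + np.sum(gammaln(a_jk + joint_counts) - gammaln(a_jk))
        )
        self._cache[key] = score
        return score


def learn_bn(
    data: pd.DataFrame,
    max_parents: int = 2,
    init_as_naive_bayes: bool = False,
    ess: float = 1.0,
    target: str = "visits",
    max_iter: int = 1000,
) -> BnStructure:
    """Greedy hill-climbing structure search under the BDeu score.

    Moves are single-edge additions, deletions and reversals; candidates
    that would create a cycle or exceed ``max_parents`` are rejected.  The
    score trajectory is non-decreasing by construction and the final graph
    is acyclic.
    """
    names = list(data.columns)
    if len(names) < 1:
        raise FactorError("empty table")
    scorer = _BDeuScorer(data, ess=ess)
    graph = nx.DiGraph()
    graph.add_nodes_from(names)
    if init_as_naive_bayes and target in names and max_parents >= 1:
        for node in names:
            if node != target:
                graph.add_edge(target, node)

    def total_score() -> float:
        return sum(scorer.family(v, list(graph.predecessors(v))) for v in names)

    score = total_score()
    trajectory = [score]
    if len(names) == 1:
        return BnStructure(graph, score, trajectory, _bn_params(max_parents, init_as_naive_bayes, ess))

    for _ in range(max_iter):
        best_gain = 1e-9
        best_move = None
        for u in names:
            for v in names:
                if u == v:
                    continue
                parents_v = list(graph.predecessors(v))
                if graph.has_edge(u, v):
                    # delete u -> v
                    gain = scorer.family(v, [p for p in parents_v if p != u]) - scorer.family(
                        v, parents_v
                    )
                    if gain > best_gain:
                        best_gain, best_move = gain, ("del", u, v)
                    # reverse u -> v
                    if max_parents > graph.in_degree(u):
                        graph.remove_edge(u, v)
                        creates_cycle = nx.has_path(graph, u, v)
                        graph.add_edge(u, v)
                        if not creates_cycle:
                            parents_u = list(graph.predecessors(u))
                            gain = (
                                scorer.family(v, [p for p in parents_v if p != u])
                                - scorer.family(v, parents_v)
                                + scorer.family(u, parents_u + [v])
                                - scorer.family(u, parents_u)
                            )
                            if gain > best_gain:
                                best_gain, best_move = gain, ("rev", u, v)
                elif graph.in_degree(v) < max_parents and not nx.has_path(graph, v, u):
                    gain = scorer.family(v, parents_v + [u]) - scorer.family(v, parents_v)
                    if gain > best_gain:
                        best_gain, best_move = gain, ("add", u, v)
        if best_move is None:
            break
        op, u, v = best_move
        if op == "add":
            graph.add_edge(u, v)
        elif op == "del":
            graph.remove_edge(u, v)
        else:
            graph.remove_edge(u, v)
            graph.add_edge(v, u)
        score += best_gain
        trajectory.append(score)
    if not nx.is_directed_acyclic_graph(graph):  # pragma: no cover - guarded by moves
        raise FactorError("search produced a cyclic graph")
    return BnStructure(graph, score, trajectory, _bn_params(max_parents, init_as_naive_bayes, ess))


def _bn_params(max_parents: int, init_as_naive_bayes: bool, ess: float) -> dict:
    return {
        "max_parents": max_parents,
        "init_as_naive_bayes": init_as_naive_bayes,
        "ess": ess,
    }


def influential_factors(bn: BnStructure, target: str = "visits") -> set[str]:
    """Markov blanket of ``target``: parents, children, children's parents."""
    g = bn.graph
    if target not in g:
        raise FactorError(f"target {target!r} not in graph")
    parents = set(g.predecessors(target))
    children = set(g.successors(target))
    spouses = {p for c in children for p in g.predecessors(c)} - {target}
    return parents | children | spouses


# ------------------------------------------------------ descriptive views


def stratified_visits(
    panel: pd.DataFrame, factor: str, n_levels: int = 4
) -> pd.DataFrame:
    """Mean/sd of visits by quantile level of one factor."""
    if factor not in panel.columns:
        raise FactorError(f"factor {factor!r} not in panel")
    levels = pd.qcut(panel[factor].astype(float), n_levels, labels=False, duplicates="drop")
    grouped = panel.groupby(levels)["visits"]
    out = grouped.agg(mean_visits="mean", sd_visits="std", count="count").reset_index(
        names="level"
    )
    return out


AGE_BIN_EDGES: tuple[float, ...] = (0, 9, 16, 25, 36, 51, 66, math.inf)
AGE_BIN_LABELS: tuple[str, ...] = ("0-8", "9-15", "16-24", "25-35", "36-50", "51-65", "66+")


def age_distribution(
    ages: Sequence[float] | pd.Series,
    bin_edges: Sequence[float] = AGE_BIN_EDGES,
    labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Histogram over age bands plus the modal band label."""
    arr = np.asarray(ages, dtype=float)
    if arr.size and arr.min() < 0:
        raise FactorError("ages must be non-negative")
    counts, _ = np.histogram(arr, bins=np.asarray(bin_edges, dtype=float))
    if labels is None:
        if tuple(bin_edges) == AGE_BIN_EDGES:
            labels = AGE_BIN_LABELS
        else:
            labels = [
                f"{int(lo)}-{int(hi) - 1}" if np.isfinite(hi) else f"{int(lo)}+"
                for lo, hi in zip(bin_edges[:-1], bin_edges[1:])
            ]
    hist = pd.DataFrame({"band": list(labels), "count": counts})
    modal = str(hist.loc[hist["count"].idxmax(), "band"]) if arr.size else ""
    return hist, modal
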