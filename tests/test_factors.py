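"""Panel preprocessing, Lasso coordinate descent, BN structure learning, views."""

import logging

import numpy as np
import pandas as pd
import pytest

import opinionpulse as op
from opinionpulse import synthetic
from opinionpulse.factors import (
    BnStructure,
    FactorError,
    age_distribution,
    discretize,
    influential_factors,
    lasso_cd,
    lasso_cv,
    learn_bn,
    preprocess_panel,
    soft_threshold,
    stratified_visits,
)


@pytest.fixture(scope="module")
def panel_table(default_panel):
    return preprocess_panel(default_panel)


class TestPreprocessPanel:
    def test_years_outside_window_dropped(self, default_panel):
        wide = default_panel.copy()
        extra = wide[wide["year"] == 2004].assign(year=2000)
        extra2 = wide[wide["year"] == 2014].assign(year=2016)
        table = preprocess_panel(pd.concat([wide, extra, extra2], ignore_index=True))
        years = table.X.index.get_level_values("year")
        assert years.min() == 2004 and years.max() == 2014
        assert len(table.X) == 34 * 11

    def test_default_panel_dimensions(self, panel_table):
        assert panel_table.X.shape == (374, 30)
        np.testing.assert_allclose(panel_table.X.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(panel_table.X.std(ddof=0), 1.0, atol=1e-12)

    def test_constant_column_dropped_and_logged(self, default_panel, caplog):
        df = default_panel.copy()
        df["gdp"] = 1.0
        with caplog.at_level(logging.WARNING, logger="opinionpulse.factors"):
            table = preprocess_panel(df)
        assert "gdp" in table.dropped and "gdp" not in table.X.columns
        assert any("zero-variance" in rec.message for rec in caplog.records)

    def test_missing_columns_rejected(self):
        with pytest.raises(FactorError):
            preprocess_panel(pd.DataFrame({"region": ["a"], "year": [2005]}))

    def test_detrended_visits_have_zero_yearly_mean(self, panel_table):
        yd = panel_table.y_detrended
        years = yd.index.get_level_values("year")
        assert np.allclose(yd.groupby(years).mean(), 0.0, atol=1e-12)


class TestLassoCd:
    def test_lambda_zero_equals_ols_oracle(self, rng):
        for _ in range(5):
            n, p = 60, 8
            X = rng.standard_normal((n, p))
            X = X - X.mean(axis=0)
            y = rng.standard_normal(n)
            beta, b0 = lasso_cd(X, y, 0.0, tol=1e-12)
            ols, *_ = np.linalg.lstsq(X, y - y.mean(), rcond=None)
            np.testing.assert_allclose(beta, ols, atol=1e-6)

    def test_large_lambda_annihilates(self, rng):
        X = rng.standard_normal((40, 5))
        X = X - X.mean(axis=0)
        y = rng.standard_normal(40)
        lam_max = np.abs(X.T @ (y - y.mean())).max() / 40
        beta, _ = lasso_cd(X, y, lam_max * 1.0001)
        assert np.all(beta == 0.0)

    def test_orthonormal_design_matches_soft_threshold_closed_form(self, rng):
        n, p = 64, 6
        # orthogonalize against the constant vector so columns are centered
        # and mutually orthogonal, with X_j'X_j = n
        M = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        Q, _ = np.linalg.qr(M)
        X = Q[:, 1:] * np.sqrt(n)
        y = rng.standard_normal(n)
        lam = 0.07
        beta, _ = lasso_cd(X, y, lam, tol=1e-12)
        z = X.T @ (y - y.mean()) / n
        col_ss = (X**2).sum(axis=0) / n
        expected = soft_threshold(z, lam) / col_ss
        np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_matches_sklearn_lasso(self, rng):
        from sklearn.linear_model import Lasso

        X = rng.standard_normal((80, 10))
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        beta_true = np.zeros(10)
        beta_true[:2] = [1.0, -0.5]
        y = X @ beta_true + 0.1 * rng.standard_normal(80)
        lam = 0.05
        beta, b0 = lasso_cd(X, y, lam, tol=1e-12)
        sk = Lasso(alpha=lam, fit_intercept=True, tol=1e-12).fit(X, y)
        np.testing.assert_allclose(beta, sk.coef_, atol=1e-6)
        assert b0 == pytest.approx(sk.intercept_, abs=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(FactorError):
            lasso_cd(np.array([[np.nan]]), np.array([1.0]), 0.1)


class TestLassoCv:
    def test_fewer_rows_than_folds_rejected(self, rng):
        with pytest.raises(FactorError):
            lasso_cv(rng.standard_normal((5, 2)), rng.standard_normal(5), n_folds=10)

    def test_pure_noise_selects_near_zero_model(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.standard_normal((120, 10))
            X = (X - X.mean(axis=0)) / X.std(axis=0)
            y = r.standard_normal(120)
            fit = lasso_cv(X, y, seed=seed)
            if np.abs(fit.beta.to_numpy()).max() < 0.15:  # ~1.5 noise sd units
                hits += 1
        assert hits >= 8

    def test_duplicate_column_coefficients_sum_to_original(self, rng):
        n = 200
        X = rng.standard_normal((n, 6))
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        y = 1.0 * X[:, 0] + 0.05 * rng.standard_normal(n)
        fit_orig = lasso_cv(pd.DataFrame(X), pd.Series(y), seed=1)
        X_dup = np.column_stack([X, X[:, 0]])
        fit_dup = lasso_cv(pd.DataFrame(X_dup), pd.Series(y), seed=1)
        combined = fit_dup.beta.iloc[0] + fit_dup.beta.iloc[6]
        assert combined == pytest.approx(fit_orig.beta.iloc[0], rel=0.2)

    def test_path_sparsity_monotone_in_lambda(self, panel_table):
        fit = lasso_cv(panel_table.X, panel_table.y, seed=0)
        curve = fit.cv_curve.sort_values("lambda", ascending=False)
        nonzero = curve["nonzero"].to_numpy()
        assert np.all(np.diff(nonzero) >= 0)  # sparser at larger penalties


class TestDiscretize:
    def test_uniform_column_splits_into_even_tertiles(self, rng):
        df = pd.DataFrame({"u": rng.random(300)})
        codes, edges = discretize(df, n_bins=3)
        counts = codes["u"].value_counts()
        assert set(counts.index) == {0, 1, 2}
        assert counts.max() - counts.min() <= 2

    def test_constant_column_single_level(self):
        codes, _ = discretize(pd.DataFrame({"c": [5.0] * 10}), n_bins=3)
        assert set(codes["c"]) == {0}

    def test_bin_edges_reproduce_counts(self, rng):
        x = rng.standard_normal(200)
        codes, edges = discretize(pd.DataFrame({"x": x}), n_bins=3)
        e = edges["x"]
        for level in range(3):
            lo, hi = e[level], e[level + 1]
            if level == 0:
                mask = (x >= x.min()) & (x <= hi)
            else:
                mask = (x > lo) & (x <= hi)
            assert mask.sum() == (codes["x"] == level).sum()


def _simulate_chain(n, seed):
    """A -> B -> C over three 3-level variables with strong links."""
    rng = np.random.default_rng(seed)
    A = rng.integers(0, 3, size=n)
    flip = rng.random(n)
    B = np.where(flip < 0.8, A, rng.integers(0, 3, size=n))
    flip2 = rng.random(n)
    C = np.where(flip2 < 0.8, B, rng.integers(0, 3, size=n))
    return pd.DataFrame({"A": A, "B": B, "C": C})


class TestLearnBn:
    def test_max_parents_zero_gives_empty_graph(self):
        data = _simulate_chain(500, 0)
        bn = learn_bn(data, max_parents=0)
        assert bn.edges == []

    def test_single_variable_table(self):
        bn = learn_bn(pd.DataFrame({"A": [0, 1, 2, 0, 1]}))
        assert bn.edges == [] and len(bn.graph) == 1

    def test_score_trajectory_monotone_and_graph_acyclic(self):
        data = _simulate_chain(2000, 3)
        bn = learn_bn(data)
        assert all(b >= a - 1e-9 for a, b in zip(bn.trajectory, bn.trajectory[1:]))
        import networkx as nx

        assert nx.is_directed_acyclic_graph(bn.graph)

    def test_chain_skeleton_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            data = _simulate_chain(5000, seed)
            bn = learn_bn(data)
            skeleton = {frozenset(e) for e in bn.edges}
            good = (
                frozenset({"A", "B"}) in skeleton
                and frozenset({"B", "C"}) in skeleton
                and frozenset({"A", "C"}) not in skeleton
            )
            hits += good
        assert hits >= 8

    def test_naive_bayes_initialization_keeps_score_monotone(self):
        data = _simulate_chain(1000, 5).rename(columns={"C": "visits"})
        bn = learn_bn(data, init_as_naive_bayes=True, target="visits")
        assert all(b >= a - 1e-9 for a, b in zip(bn.trajectory, bn.trajectory[1:]))


class TestInfluentialFactors:
    def test_empty_graph_empty_blanket(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(["visits", "a"])
        bn = BnStructure(graph=g, score=0.0, trajectory=[0.0], params={})
        assert influential_factors(bn) == set()

    def test_star_graph_blanket_is_all_leaves(self):
        import networkx as nx

        g = nx.DiGraph()
        leaves = [f"f{i}" for i in range(4)]
        g.add_edges_from(("visits", leaf) for leaf in leaves)
        bn = BnStructure(graph=g, score=0.0, trajectory=[0.0], params={})
        assert influential_factors(bn) == set(leaves)

    def test_missing_target_rejected(self):
        import networkx as nx

        bn = BnStructure(graph=nx.DiGraph(), score=0.0, trajectory=[], params={})
        with pytest.raises(FactorError):
            influential_factors(bn)


class TestStratifiedVisits:
    def test_group_counts_sum_to_row_count(self, default_panel):
        out = stratified_visits(default_panel, "gdp")
        assert out["count"].sum() == len(default_panel)

    def test_independent_factor_gives_flat_means(self):
        # homogeneous regions isolate the stratification signal: a null
        # factor's level means stay within a few percent of each other while
        # the causal factor's spread spans multiples of the mean
        cfg = op.headline_panel_config(seed=11, region_sd=0.0, noise_sd=0.02)
        panel = synthetic.gen_panel(cfg)
        null = stratified_visits(panel, "temperature")  # true beta = 0
        null_spread = null["mean_visits"].max() - null["mean_visits"].min()
        gdp = stratified_visits(panel, "gdp")
        gdp_spread = gdp["mean_visits"].max() - gdp["mean_visits"].min()
        assert null_spread < 0.25 * gdp_spread
        assert null_spread < 0.2 * panel["visits"].mean()

    def test_gdp_levels_strictly_increasing(self, default_panel):
        out = stratified_visits(default_panel, "gdp")
        assert np.all(np.diff(out["mean_visits"].to_numpy()) > 0)

    def test_missing_factor_rejected(self, default_panel):
        with pytest.raises(FactorError):
            stratified_visits(default_panel, "no_such_factor")


class TestAgeDistribution:
    def test_point_mass_at_thirty(self):
        hist, modal = age_distribution([30.0] * 25)
        assert modal == "25-35"
        assert hist.set_index("band").loc["25-35", "count"] == 25
        assert hist["count"].sum() == 25

    def test_counts_conserve_records(self):
        cfg = op.headline_visit_config(seed=2, n_records=5000)
        ages = synthetic.gen_visit_records(cfg)["age"]
        hist, _ = age_distribution(ages)
        assert hist["count"].sum() == 5000

    def test_negative_age_rejected(self):
        with pytest.raises(FactorError):
            age_distribution([-1.0, 20.0])
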