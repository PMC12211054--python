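"""Lasso machinery, penalty selection, splitting inference, stability."""

import numpy as np
import pandas as pd
import pytest

from hepmicro import interaction_net as inet
from hepmicro import synthetic_data as sd


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(0)
    n, p = 60, 20
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    beta[3] = 1.0
    y = X @ beta + rng.normal(0, 0.1, n)
    return pd.Series(y), pd.DataFrame(X, columns=[f"t{j}" for j in range(p)])


class TestBuildTaxaMatrix:
    def test_concatenation_and_standardization(self, rng):
        profiles = {
            rank: pd.DataFrame(rng.standard_normal((10, 10)),
                               columns=[f"tax{j}" for j in range(10)])
            for rank in ("phylum", "class", "order", "family", "species")
        }
        m = inet.build_taxa_matrix(profiles)
        assert m.shape == (10, 50)
        assert np.abs(m.mean(0)).max() < 1e-9
        assert np.abs(m.std(0, ddof=0) - 1).max() < 1e-9
        for col in m.columns:
            rank = col.split("|")[0]
            assert rank in profiles


class TestLassoFit:
    def test_lambda_max_zeroes_solution(self, planted):
        y, X = planted
        lmax = inet.lambda_max(y.to_numpy(), X.to_numpy())
        fit = inet.lasso_path_fit(y, X, lmax * 1.001)
        assert (fit.beta == 0).all()
        fit2 = inet.lasso_path_fit(y, X, lmax * 0.5)
        assert (fit2.beta != 0).any()

    def test_lambda_zero_equals_ols(self, rng):
        n, p = 50, 8
        X = pd.DataFrame(rng.standard_normal((n, p)))
        y = pd.Series(rng.standard_normal(n))
        fit = inet.lasso_path_fit(y, X, 0.0)
        D = np.column_stack([np.ones(n), X.to_numpy()])
        ols, *_ = np.linalg.lstsq(D, y.to_numpy(), rcond=None)
        assert np.abs(fit.beta.to_numpy() - ols[1:]).max() < 1e-6

    def test_orthonormal_soft_threshold(self, rng):
        """On orthonormal columns the Lasso is coordinatewise soft-thresholding."""
        n = 64
        raw = rng.standard_normal((n, 6))
        q, _ = np.linalg.qr(raw - raw.mean(0))  # centered orthonormal columns
        X = q * np.sqrt(n)  # columns with X'X = n I
        beta = np.array([2.0, -1.0, 0.5, 0.0, 0.0, 0.0])
        y = X @ beta
        lam = 0.6
        fit = inet.lasso_path_fit(pd.Series(y), pd.DataFrame(X), lam)
        b_ols = X.T @ (y - y.mean()) / n
        expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0)
        assert np.abs(fit.beta.to_numpy() - expected).max() < 1e-5

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            inet.lasso_path_fit(pd.Series([1.0, np.nan, 2.0]),
                                pd.DataFrame(np.ones((3, 2))), 0.1)


class TestLambdaSelection:
    def test_deterministic(self, planted):
        y, X = planted
        assert inet.select_lambda_loocv(y, X) == inet.select_lambda_loocv(y, X)

    def test_strong_predictor_selected(self, planted):
        y, X = planted
        lam = inet.select_lambda_loocv(y, X)
        fit = inet.lasso_path_fit(y, X, lam)
        assert "t3" in fit.support

    def test_pure_noise_prefers_sparse_models(self, rng):
        hits = 0
        for r in range(10):
            n, p = 40, 15
            X = pd.DataFrame(rng.standard_normal((n, p)))
            X = (X - X.mean(0)) / X.std(0)
            y = pd.Series(rng.standard_normal(n))
            lam = inet.select_lambda_loocv(y, X)
            fit = inet.lasso_path_fit(y, X, lam)
            if len(fit.support) <= 3:
                hits += 1
        assert hits >= 8


class TestSplittingInference:
    def test_planted_signal_significant(self, planted):
        y, X = planted
        lam = inet.select_lambda_loocv(y, X)
        p = inet.interaction_pvalues(y, X, lam=lam, seed=1)
        assert p["t3"] < 1e-4
        assert (p.drop("t3") > 0.05).mean() > 0.9

    def test_reproducible_under_seed(self, planted):
        y, X = planted
        p1 = inet.interaction_pvalues(y, X, lam=0.1, seed=5)
        p2 = inet.interaction_pvalues(y, X, lam=0.1, seed=5)
        pd.testing.assert_series_equal(p1, p2)

    def test_null_conservative(self, rng):
        """Aggregated p-values under the null are stochastically >= uniform."""
        below = 0
        total = 0
        for r in range(30):
            n, p = 40, 10
            X = pd.DataFrame(rng.standard_normal((n, p)))
            X = (X - X.mean(0)) / X.std(0)
            y = pd.Series(rng.standard_normal(n))
            pv = inet.interaction_pvalues(y, X, lam=0.2, n_splits=20, seed=r)
            below += (pv < 0.1).sum()
            total += p
        assert below / total <= 0.1

    def test_small_n_errors(self, rng):
        with pytest.raises(ValueError):
            inet.interaction_pvalues(pd.Series(np.ones(10)),
                                     pd.DataFrame(np.ones((10, 2))), lam=0.1)


class TestStability:
    def test_planted_high_null_low(self, planted):
        # a moderate penalty separates the planted predictor from noise
        y, X = planted
        freq = inet.stability_selection(y, X, lam=0.1, seed=2)
        assert freq["t3"] >= 0.9
        assert (freq.drop("t3") <= 0.2).all()

    def test_reproducible(self, planted):
        y, X = planted
        f1 = inet.stability_selection(y, X, 0.1, n_iter=20, seed=9)
        f2 = inet.stability_selection(y, X, 0.1, n_iter=20, seed=9)
        pd.testing.assert_series_equal(f1, f2)

    def test_retained_set_monotone_in_cutoff(self, planted):
        y, X = planted
        freq = inet.stability_selection(y, X, 0.05, seed=3)
        prev = None
        for cut in np.linspace(0, 1, 11):
            cur = set(freq.index[freq >= cut])
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestConfounders:
    def test_no_covariates_equals_simple_regression(self, rng):
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        from scipy.stats import linregress
        p_simple = linregress(x, y).pvalue
        p_ours = inet.confounder_adjust(y, x, None)
        assert p_ours == pytest.approx(p_simple, rel=1e-9)

    def test_mediated_association_vanishes(self, rng):
        hits = 0
        for r in range(20):
            z = rng.standard_normal(80)  # confounder drives both
            x = z + rng.normal(0, 0.3, 80)
            y = z + rng.normal(0, 0.3, 80)
            cov = pd.DataFrame({"z": z})
            if inet.confounder_adjust(y, x, cov) > 0.05:
                hits += 1
        assert hits >= 16

    def test_collinear_covariates_error(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            inet.confounder_adjust(y, x, cov)


class TestNetworks:
    def test_summaries_and_intersections(self):
        e1 = pd.DataFrame({"gene": ["g1", "g2"], "taxon": ["t1", "t2"]})
        e2 = pd.DataFrame({"gene": ["g1", "g3"], "taxon": ["t1", "t3"]})
        net = inet.build_stage_networks({"A": e1, "B": e2})
        assert net["stages"]["A"]["n_edges"] == 2
        assert net["intersections"]["A&B"] == [["g1", "t1"]]
        degree = net["stages"]["A"]["degree"]
        assert sum(degree.values()) == 2 * 2  # handshake identity

    def test_disjoint_sets_empty_intersections(self):
        e1 = pd.DataFrame({"gene": ["g1"], "taxon": ["t1"]})
        e2 = pd.DataFrame({"gene": ["g2"], "taxon": ["t2"]})
        net = inet.build_stage_networks({"A": e1, "B": e2})
        assert net["intersections"]["A&B"] == []


def test_identify_interactions_small_chain():
    """End-to-end chain on a small planted stage recovers the edges."""
    Y, X, edges = sd.simulate_interaction_stage(
        n_samples=60, n_genes=8, n_taxa=15, n_edges=2, beta=0.8,
        noise_sd=0.3, seed=4)
    out = inet.identify_interactions(Y, X, stage="NAFL", seed=21)
    found = set(zip(out["gene"], out["taxon"]))
    truth = {(g, t) for g, t, _ in edges}
    assert truth <= found
    assert len(found - truth) == 0
    # strengths match the planted positive coupling
    assert (out.set_index(["gene", "taxon"]).loc[list(truth), "rho"] > 0.8).all()
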