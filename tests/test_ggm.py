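"""Graphical-lasso estimation, EBIC selection, and edge-table reporting."""

import numpy as np
import pandas as pd
import pytest

from panelnet.errors import ConfigurationError, EstimationError
from panelnet.ggm import (ContemporaneousNetwork, GaussianGraphicalModel,
                          average_edges, ebic_score, glasso_objective,
                          graphical_lasso, lambda_grid, precision_to_partial,
                          sample_correlation, select_network)


from _oracles import admm_glasso


class TestSampleCorrelation:
    def test_duplicated_column_correlates_perfectly(self, rng):
        x = rng.normal(size=1000)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=1000)})
        C = sample_correlation(df)
        assert C.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        df = pd.DataFrame(rng.normal(size=(100_000, 4)))
        C = sample_correlation(df).to_numpy()
        off = C[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_known_population_correlation(self, rng):
        n, r = 100_000, 0.5
        x = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r**2) * rng.normal(size=n)
        C = sample_correlation(pd.DataFrame({"x": x, "y": y}))
        assert C.loc["x", "y"] == pytest.approx(0.5, abs=0.01)

    def test_zero_variance_column_named_in_error(self, rng):
        df = pd.DataFrame({"ok": rng.normal(size=50), "flat": np.ones(50)})
        with pytest.raises(EstimationError, match="flat"):
            sample_correlation(df)

    def test_positive_semidefinite(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 6)))
        eig = np.linalg.eigvalsh(sample_correlation(df).to_numpy())
        assert eig.min() > -1e-10


class TestGraphicalLasso:
    def test_identity_input_gives_identity_precision(self):
        for lam in (0.01, 0.1, 0.5):
            np.testing.assert_allclose(graphical_lasso(np.eye(4), lam), np.eye(4),
                                       atol=1e-8)

    @pytest.mark.parametrize("s", [-0.6, -0.2, 0.1, 0.3, 0.7])
    @pytest.mark.parametrize("lam", [0.05, 0.25, 0.5])
    def test_p2_closed_form(self, s, lam):
        # For p=2 the solution covariance is S with the off-diagonal shrunk
        # toward zero by lam; the edge vanishes exactly when |s| <= lam.
        S = np.array([[1.0, s], [s, 1.0]])
        Theta = graphical_lasso(S, lam, tol=1e-10, max_iter=10_000)
        if abs(s) <= lam:
            np.testing.assert_allclose(Theta, np.eye(2), atol=1e-6)
        else:
            W = np.array([[1.0, s - np.sign(s) * lam],
                          [s - np.sign(s) * lam, 1.0]])
            np.testing.assert_allclose(Theta, np.linalg.inv(W), atol=1e-6)

    def test_p4_objective_matches_admm_oracle(self, rng):
        A = rng.normal(size=(60, 4))
        S = np.corrcoef(A.T)
        lam = 0.1
        ours = graphical_lasso(S, lam, tol=1e-10, max_iter=20_000)
        oracle = admm_glasso(S, lam)
        f_ours = glasso_objective(ours, S, lam)
        f_oracle = glasso_objective(oracle, S, lam)
        assert f_ours <= f_oracle + 1e-6

    def test_kkt_conditions(self, rng):
        A = rng.normal(size=(200, 4))
        S = np.corrcoef(A.T)
        lam = 0.1
        Theta = graphical_lasso(S, lam, tol=1e-12, max_iter=50_000)
        W = np.linalg.inv(Theta)
        resid = np.abs(W - S)
        np.fill_diagonal(resid, 0.0)
        assert resid.max() <= lam + 1e-6
        nz = (np.abs(Theta) > 1e-10) & ~np.eye(4, dtype=bool)
        if nz.any():
            np.testing.assert_allclose(resid[nz], lam, atol=1e-4)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            graphical_lasso(np.eye(3), -0.1)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self, rng):
        S = np.corrcoef(rng.normal(size=(100, 3)).T)
        Theta = graphical_lasso(S, 0.05)
        n = 100
        E = np.count_nonzero(np.triu(Theta, 1))
        sign, logdet = np.linalg.slogdet(Theta)
        ll = 0.5 * n * (logdet - np.trace(S @ Theta))
        assert ebic_score(Theta, S, n, gamma=0.0) == pytest.approx(-2 * ll + E * np.log(n))

    def test_empty_network_has_no_penalty(self, rng):
        S = np.eye(5)
        Theta = np.eye(5)
        n = 50
        ll = 0.5 * n * (np.linalg.slogdet(Theta)[1] - np.trace(S @ Theta))
        assert ebic_score(Theta, S, n, gamma=0.5) == pytest.approx(-2 * ll)

    def test_diagonal_model_beats_saturated_on_independent_data(self, rng):
        X = rng.normal(size=(2000, 5))
        S = np.corrcoef(X.T)
        diag = np.diag(1.0 / np.diag(S))
        saturated = np.linalg.inv(S)
        assert (ebic_score(diag, S, 2000, 0.5)
                < ebic_score(saturated, S, 2000, 0.5))


class TestSelectNetwork:
    def test_independent_data_give_empty_network(self, rng):
        X = rng.normal(size=(2000, 6))
        S = np.corrcoef(X.T)
        net = select_network(S, n=2000)
        assert np.count_nonzero(net.weights) == 0

    def test_chain_graph_recovery(self):
        # partial correlation 0.4 on consecutive pairs of a 6-node chain
        p, n, reps = 6, 2000, 20
        prec = np.eye(p)
        for i in range(p - 1):
            prec[i, i + 1] = prec[i + 1, i] = -0.4
        cov = np.linalg.inv(prec)
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        chol = np.linalg.cholesky(cov)
        true_edges = {(i, i + 1) for i in range(p - 1)}
        good = 0
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            X = rng.standard_normal((n, p)) @ chol.T
            net = select_network(np.corrcoef(X.T), n=n, n_lambdas=40)
            found = {(i, j) for i in range(p) for j in range(i + 1, p)
                     if net.weights[i, j] != 0}
            false_edges = found - true_edges
            # EBIC-glasso keeps all strong true edges; the spurious edges it
            # admits stay an order of magnitude below the true weight
            false_small = all(abs(net.weights[i, j]) < 0.05 for i, j in false_edges)
            if true_edges <= found and false_small:
                good += 1
        assert good >= 0.9 * reps

    def test_brute_force_lambda_selection_oracle(self, rng):
        X = rng.normal(size=(500, 4)) @ np.linalg.cholesky(
            np.array([[1, .5, .2, 0], [.5, 1, .3, 0], [.2, .3, 1, .1], [0, 0, .1, 1.0]])).T
        S = np.corrcoef(X.T)
        n = 500
        grid = lambda_grid(S, 30)
        net = select_network(S, n=n, lambdas=grid)
        # independent re-computation of the EBIC curve
        best_lam, best_val = None, np.inf
        for lam in sorted(grid)[::-1]:
            Theta = graphical_lasso(S, float(lam))
            val = ebic_score(Theta, S, n, 0.5)
            if val < best_val:
                best_lam, best_val = lam, val
        assert net.lambda_selected == pytest.approx(best_lam)

    def test_edge_count_monotone_along_path(self, rng):
        X = rng.normal(size=(800, 5)) + 0.5 * rng.normal(size=(800, 1))
        S = np.corrcoef(X.T)
        _, path = select_network(S, n=800, n_lambdas=40, return_path=True)
        counts = [pt.edge_count for pt in path]  # path ordered by decreasing lambda
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_unpenalized_partials_match_textbook(self, medium_scores):
        X = medium_scores[0].to_numpy()
        S = np.corrcoef(X.T)
        partial = precision_to_partial(graphical_lasso(S, 0.0))
        # textbook: invert the correlation matrix directly
        P = np.linalg.inv(S)
        expected = -P / np.sqrt(np.outer(np.diag(P), np.diag(P)))
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(partial, expected, atol=1e-8)

    def test_scale_invariance_of_network(self, rng):
        X = rng.normal(size=(500, 4)) + rng.normal(size=(500, 1))
        scales = np.array([1.0, 3.5, 0.2, 10.0])
        S1 = np.corrcoef(X.T)
        S2 = np.corrcoef((X * scales).T)
        n1 = select_network(S1, n=500)
        n2 = select_network(S2, n=500)
        np.testing.assert_allclose(n1.weights, n2.weights, atol=1e-10)

    def test_detected_edges_have_true_sign(self, spec, medium_scores):
        idx = {nd: i for i, nd in enumerate(spec.nodes)}
        X = medium_scores[0]
        net = GaussianGraphicalModel().fit(X).network_
        true = spec.true_partial
        for a, b in [("warmth", "inductive_reasoning"), ("hostility", "harshness"),
                     ("anxiety", "depression"), ("monitoring", "conduct_problems")]:
            w = net.weights[idx[a], idx[b]]
            assert np.sign(w) == np.sign(true[idx[a], idx[b]])


class TestNetworkContainer:
    def test_asymmetric_weights_rejected(self):
        w = np.zeros((2, 2))
        w[0, 1] = 0.5
        with pytest.raises(ConfigurationError):
            ContemporaneousNetwork(["a", "b"], w)

    def test_diagonal_forced_to_zero(self):
        w = np.eye(3) * 0.7
        net = ContemporaneousNetwork(["a", "b", "c"], w)
        assert np.all(np.diag(net.weights) == 0)


class TestAverageEdges:
    def _net(self, w12, labels=("anxiety", "depression")):
        w = np.array([[0.0, w12], [w12, 0.0]])
        return ContemporaneousNetwork(list(labels), w)

    @pytest.mark.parametrize("w1, w2, avg", [
        (0.39, 0.63, 0.51),
        (0.43, 0.46, 0.45),   # 0.445 rounds half away from zero
        (0.2, 0.2, 0.2),      # idempotence
    ])
    def test_printed_table_arithmetic(self, w1, w2, avg):
        table = average_edges(self._net(w1), self._net(w2))
        assert table["weight_avg"].iloc[0] == pytest.approx(avg)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            average_edges(self._net(0.2), self._net(0.2, labels=("x", "y")))

    def test_either_wave_filter_keeps_asymmetric_small_edges(self):
        # 0.00 at one wave, 0.03 at the other: kept despite average 0.015
        table = average_edges(self._net(0.0), self._net(0.03))
        assert len(table) == 1
        # but dropped when both waves are at or below the threshold
        table2 = average_edges(self._net(0.01), self._net(0.01))
        assert len(table2) == 0

    def test_average_filter_rule_option(self):
        table = average_edges(self._net(0.0), self._net(0.03), filter_rule="average")
        assert len(table) == 1
        table2 = average_edges(self._net(0.0), self._net(0.02), filter_rule="average")
        assert len(table2) == 0
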