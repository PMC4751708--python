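import numpy as np
import pytest
from scipy import integrate, stats

from netdiff import (
    DataError,
    LabeledDataset,
    NetworkSpec,
    ScoreDecomposition,
    SingularCovarianceError,
    UntestableVertexError,
    edge_scores,
    netdifm_statistic,
    netdifm_test,
    score_covariance,
    vertex_scores,
    vertex_subnetwork_test,
)
from netdiff.simulation import build_sigma, default_scenario, simulate_case_control

from conftest import random_dataset


# -- literal-formula oracles (kept deliberately loop-based and slow) -------


def oracle_vertex_scores(x, y):
    n, m = x.shape
    ybar = y.mean()
    return np.array([sum((y[l] - ybar) * x[l, i] for l in range(n)) for i in range(m)])


def oracle_edge_scores(x, y, edges):
    n = x.shape[0]
    ybar = y.mean()
    xbar = x.mean(axis=0)
    return np.array(
        [
            sum((y[l] - ybar) * (x[l, i] - xbar[i]) * (x[l, j] - xbar[j]) for l in range(n))
            for i, j in edges
        ]
    )


def oracle_sigma(x, y, edges):
    """Entry-by-entry evaluation of every σ_pq block formula."""
    n, m = x.shape
    ybar = y.mean()
    s = sum((y[l] - ybar) ** 2 for l in range(n))
    xbar = x.mean(axis=0)
    z = np.column_stack([(x[:, i] - xbar[i]) * (x[:, j] - xbar[j]) for i, j in edges])
    w = np.column_stack([x, z])
    p_tot = w.shape[1]
    sigma = np.empty((p_tot, p_tot))
    for p in range(p_tot):
        for q in range(p_tot):
            sigma[p, q] = s * np.cov(w[:, p], w[:, q], ddof=1)[0, 1]
    return sigma


# -- component examples ----------------------------------------------------


class TestVertexScores:
    def test_forced_arithmetic(self):
        data = LabeledDataset(
            np.array([[1.0], [1.0], [0.0], [0.0]]), np.array([1, 1, 0, 0]), ("A",)
        )
        assert vertex_scores(data) == pytest.approx([1.0])

    def test_constant_column_scores_zero(self):
        x = np.column_stack([np.full(6, 3.7), np.arange(6.0)])
        data = LabeledDataset(x, np.array([1, 0, 1, 0, 1, 0]), ("A", "B"))
        assert vertex_scores(data)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, dataset_30x4):
        data, net = dataset_30x4
        np.testing.assert_allclose(
            vertex_scores(data, net), oracle_vertex_scores(data.aligned(net), data.y)
        )

    def test_single_group_rejected(self):
        with pytest.raises(DataError, match="both labels"):
            LabeledDataset(np.ones((4, 1)), np.array([1, 1, 1, 1]), ("A",))


class TestEdgeScores:
    def test_constant_endpoint_gives_zero(self, triangle):
        rng = np.random.default_rng(0)
        x = np.column_stack([np.full(8, 2.0), rng.normal(size=8), rng.normal(size=8)])
        data = LabeledDataset(x, np.repeat([1, 0], 4), triangle.vertex_names)
        d_e = edge_scores(data, triangle)
        # edges (A,B) and (A,C) touch the constant column A
        assert d_e[list(triangle.edge_index[e] for e in [(0, 1), (0, 2)])] == pytest.approx(
            [0.0, 0.0], abs=1e-12
        )

    def test_two_sample_toy_by_hand(self):
        # Y=(1,0), x_i=x_j=(1,−1): centered labels ±1/2, centered x ±1,
        # so D^E = 1/2·(1·1) + (−1/2)·(−1·−1) = 0
        net = NetworkSpec(("A", "B"), ((0, 1),))
        data = LabeledDataset(
            np.array([[1.0, 1.0], [-1.0, -1.0]]), np.array([1, 0]), ("A", "B")
        )
        assert edge_scores(data, net) == pytest.approx([0.0], abs=1e-15)

    def test_matches_loop_oracle(self, dataset_30x4):
        data, net = dataset_30x4
        np.testing.assert_allclose(
            edge_scores(data, net), oracle_edge_scores(data.aligned(net), data.y, net.edges)
        )


class TestScoreCovariance:
    def test_single_vertex_no_edges(self):
        net = NetworkSpec(("A",), ())
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 1))
        y = np.repeat([1, 0], 6)
        dec = score_covariance(LabeledDataset(x, y, ("A",)), net)
        s = ((y - y.mean()) ** 2).sum()
        assert dec.Sigma.shape == (1, 1)
        assert dec.Sigma[0, 0] == pytest.approx(s * np.var(x, ddof=1))

    def test_matches_per_entry_oracle(self, dataset_30x4):
        data, net = dataset_30x4
        dec = score_covariance(data, net)
        np.testing.assert_allclose(
            dec.Sigma, oracle_sigma(data.aligned(net), data.y, net.edges), rtol=1e-10
        )

    def test_symmetric_and_psd(self, dataset_30x4):
        data, net = dataset_30x4
        sigma = score_covariance(data, net).Sigma
        np.testing.assert_allclose(sigma, sigma.T, rtol=1e-12)
        eig = np.linalg.eigvalsh(sigma)
        assert eig.min() >= -1e-10 * eig.max()

    def test_label_permutation_leaves_sigma_unchanged(self, dataset_30x4):
        # Σ factorizes as Σ(Y−Ȳ)² × a label-free pooled covariance, so any
        # relabeling with the same group sizes gives the same matrix
        data, net = dataset_30x4
        sigma = score_covariance(data, net).Sigma
        rng = np.random.default_rng(3)
        shuffled = data.with_labels(rng.permutation(data.y))
        np.testing.assert_allclose(score_covariance(shuffled, net).Sigma, sigma, rtol=1e-10)


class TestNetdifmStatistic:
    def test_zero_scores_give_zero(self):
        dec = ScoreDecomposition(
            np.zeros(2), np.zeros(1), np.eye(3), 1.0, working=np.zeros((4, 3))
        )
        assert netdifm_statistic(dec) == 0.0

    def test_identity_metric_is_squared_norm(self):
        d_v, d_e = np.array([1.0, 2.0]), np.array([-3.0])
        dec = ScoreDecomposition(d_v, d_e, np.eye(3), 1.0, working=np.zeros((4, 3)))
        assert netdifm_statistic(dec) == pytest.approx(14.0)

    def test_matches_explicit_inverse(self, dataset_30x4):
        data, net = dataset_30x4
        dec = score_covariance(data, net)
        expected = dec.D @ np.linalg.inv(dec.Sigma) @ dec.D
        assert netdifm_statistic(dec) == pytest.approx(expected, rel=1e-10)
        assert netdifm_statistic(dec, solver="pseudoinverse") == pytest.approx(
            expected, rel=1e-8
        )

    def test_singular_sigma_names_the_remedy(self):
        # a duplicated column makes two working variables collinear
        rng = np.random.default_rng(2)
        a = rng.normal(size=20)
        x = np.column_stack([a, a, rng.normal(size=20)])
        net = NetworkSpec(("A", "B", "C"), ((0, 1), (0, 2)))
        data = LabeledDataset(x, np.repeat([1, 0], 10), net.vertex_names)
        dec = score_covariance(data, net)
        with pytest.raises(SingularCovarianceError, match="prune_edges"):
            netdifm_statistic(dec)
        # the rank-deficient fallbacks still return a finite value
        assert np.isfinite(netdifm_statistic(dec, solver="pseudoinverse"))
        assert np.isfinite(netdifm_statistic(dec, solver="ridge", ridge=1e-6))


class TestNetdifmTest:
    def test_zero_statistic_p_is_one(self):
        assert stats.chi2.sf(0.0, 5) == 1.0

    def test_pvalue_matches_density_quadrature(self, dataset_30x4):
        data, net = dataset_30x4
        res = netdifm_test(data, net)
        assert res.df == net.n_vertices + net.n_edges
        quad, _ = integrate.quad(stats.chi2(res.df).pdf, res.statistic, np.inf)
        assert res.p_value == pytest.approx(quad, rel=1e-8)

    def test_statistic_at_df_matches_quadrature(self):
        df = 8
        quad, _ = integrate.quad(stats.chi2(df).pdf, df, np.inf)
        assert stats.chi2.sf(df, df) == pytest.approx(quad, rel=1e-10)


# -- invariance properties -------------------------------------------------


class TestInvariances:
    def test_label_swap_negates_scores_keeps_statistic(self, dataset_30x4):
        data, net = dataset_30x4
        swapped = data.with_labels(1 - data.y)
        dec, dec_s = score_covariance(data, net), score_covariance(swapped, net)
        np.testing.assert_allclose(dec_s.D, -dec.D, rtol=1e-10)
        assert netdifm_statistic(dec_s) == pytest.approx(netdifm_statistic(dec), rel=1e-10)

    def test_edge_order_permutation_invariance(self, dataset_30x4):
        # the quadratic form is invariant under any reordering of the score
        # vector (conjugation by a permutation matrix)
        data, net = dataset_30x4
        dec = score_covariance(data, net)
        rng = np.random.default_rng(11)
        perm = rng.permutation(dec.df)
        permuted = ScoreDecomposition(
            dec.D[perm][: net.n_vertices],
            dec.D[perm][net.n_vertices :],
            dec.Sigma[np.ix_(perm, perm)],
            dec.label_weight_sum,
            working=dec.working[:, perm],
        )
        assert netdifm_statistic(permuted) == pytest.approx(
            netdifm_statistic(dec), rel=1e-9
        )

    def test_column_scaling_invariance(self, dataset_30x4):
        data, net = dataset_30x4
        x = data.X.copy()
        x[:, 1] *= 17.0
        scaled = LabeledDataset(x, data.y, data.vertex_names)
        stat = netdifm_statistic(score_covariance(data, net))
        stat_scaled = netdifm_statistic(score_covariance(scaled, net))
        assert stat_scaled == pytest.approx(stat, rel=1e-8)
        # the D entry for the scaled vertex scales by the same factor
        assert vertex_scores(scaled, net)[1] == pytest.approx(
            17.0 * vertex_scores(data, net)[1], rel=1e-10
        )


# -- per-vertex subnetwork testing -----------------------------------------


class TestVertexSubnetworkTest:
    def test_df_is_one_plus_degree(self, small_net):
        data, _ = random_dataset(n=60, m=10, seed=4)
        data = LabeledDataset(data.X, data.y, small_net.vertex_names)
        for name in small_net.vertex_names[:3]:
            res = vertex_subnetwork_test(data, small_net, name)
            assert res.df == 1 + small_net.degree(name)

    def test_subnetwork_statistic_differs_from_whole_network(self):
        net = NetworkSpec(("H", "B", "C", "D"), ((0, 1), (0, 2), (0, 3)))
        data, _ = random_dataset(n=40, m=4, seed=5)
        data = LabeledDataset(data.X, data.y, net.vertex_names)
        whole = netdifm_test(data, net)
        sub = vertex_subnetwork_test(data, net, "H")
        assert sub.df < whole.df
        assert sub.statistic != pytest.approx(whole.statistic)

    def test_degree_zero_vertex_untestable(self):
        net = NetworkSpec(("A", "B", "C"), ((0, 1),))
        data, _ = random_dataset(n=20, m=3, seed=6)
        data = LabeledDataset(data.X, data.y, net.vertex_names)
        with pytest.raises(UntestableVertexError):
            vertex_subnetwork_test(data, net, "C")

    def test_shifted_vertex_attains_smallest_pvalue(self, small_net):
        # one vertex's mean differs between groups; over replicates that
        # vertex should usually win the per-vertex screen
        target = 4
        m = small_net.n_vertices
        mu_case = np.zeros(m)
        mu_case[target] = 0.6
        from netdiff import SimulationScenario

        scn = SimulationScenario(
            net=small_net,
            mu_case=mu_case,
            mu_control=np.zeros(m),
            beta_case=np.full(small_net.n_edges, 0.3),
            beta_control=np.full(small_net.n_edges, 0.3),
            n_case=100,
            n_control=100,
        )
        rng = np.random.default_rng(17)
        wins = 0
        n_rep = 15
        for _ in range(n_rep):
            data = simulate_case_control(scn, rng)
            pvals = [
                vertex_subnetwork_test(data, small_net, v).p_value for v in range(m)
            ]
            wins += int(np.argmin(pvals) == target)
        assert wins > n_rep / 2
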