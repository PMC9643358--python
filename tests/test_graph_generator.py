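"""Para-Learner, mixture-edge probabilities and Gumbel graph sampling."""

import numpy as np
import pytest
from scipy.special import expit

from ggn import _autodiff as ad
from ggn import graph_generator as gg
from ggn._autodiff import Tensor


def make_mix(means, log_vars=None, logits=None, n_nodes=2):
    means = np.atleast_2d(np.asarray(means, float))
    if log_vars is None:
        log_vars = np.full_like(means, -40.0)  # near point mass
    if logits is None:
        logits = np.zeros_like(means)
    return gg.MixtureEdgeParams(means=Tensor(means), log_vars=Tensor(log_vars),
                                logits=Tensor(logits), n_nodes=n_nodes)


class TestParaLearn:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.params = gg.init_para_learner(rng, in_dim=3, embed_dim=4,
                                           k_mix=2, rounds=2)

    def test_identical_features_complete_graph_identical_edges(self):
        n = 4
        x = np.tile(np.array([0.3, -0.2, 0.5]), (n, 1))
        a0 = np.ones((n, n)) - np.eye(n)
        mix = gg.para_learn(x, a0, self.params)
        for t in (mix.means, mix.log_vars, mix.logits):
            assert np.allclose(t.data, t.data[0], atol=1e-12)

    def test_node_relabeling_permutes_edge_parameters(self):
        n = 5
        rng = np.random.default_rng(1)
        x = rng.normal(size=(n, 3))
        a0 = np.abs(rng.normal(size=(n, n)))
        a0 = 0.5 * (a0 + a0.T)
        np.fill_diagonal(a0, 0)
        perm = np.array([2, 0, 4, 1, 3])
        m1 = gg.para_learn(x, a0, self.params)
        m2 = gg.para_learn(x[perm], a0[np.ix_(perm, perm)], self.params)
        p1 = gg.edges_to_matrix(m1.means[(Ellipsis, 0)], n).data
        p2 = gg.edges_to_matrix(m2.means[(Ellipsis, 0)], n).data
        assert np.allclose(p2, p1[np.ix_(perm, perm)], atol=1e-10)

    def test_three_node_hand_computed_message_passing(self):
        """Brute-force two-round aggregation with hand-set unit weights."""
        n, d = 3, 2
        params = {"rounds": 2, "k_mix": 1}
        net = {
            "W_in": ad.parameter(np.eye(2)),
            "b_in": ad.parameter(np.zeros(2)),
            "W_edge": ad.parameter(np.ones((4, 1))),
            "b_edge": ad.parameter(np.zeros(1)),
        }
        for r in range(2):
            net[f"W_self{r}"] = ad.parameter(np.eye(2))
            net[f"W_nei{r}"] = ad.parameter(np.eye(2))
            net[f"b{r}"] = ad.parameter(np.zeros(2))
        for g in ("means", "log_vars", "logits"):
            params[g] = net
        x = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        a0 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        mix = gg.para_learn(x, a0, params)
        # oracle: plain numpy unroll
        h = np.maximum(x, 0)
        for _ in range(2):
            h = np.maximum(h + a0 @ h, 0)
        iu, ju = gg.pair_indices(n)
        expected = (h[iu] * h[ju] + h[iu] + h[ju]).sum(axis=1)
        assert np.allclose(mix.means.data[:, 0], expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gg.para_learn(np.zeros((3, 3)), np.zeros((4, 4)), self.params)


class TestEdgeProbability:
    def test_large_mean_saturates(self):
        p = gg.edge_probability(make_mix([[20.0]]), n_draws=2, seed=0)
        assert p.p[0, 1] > 0.999

    def test_point_mass_at_zero_gives_half(self):
        p = gg.edge_probability(make_mix([[0.0]]), n_draws=2, seed=0)
        assert p.p[0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_monte_carlo_matches_logistic_of_mean(self):
        mix = make_mix([[1.0]], log_vars=[[2 * np.log(0.1)]])
        p = gg.edge_probability(mix, n_draws=10_000, seed=1)
        assert p.p[0, 1] == pytest.approx(expit(1.0), abs=0.02)

    def test_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(2)
        mix = make_mix(rng.normal(size=(6, 2)), log_vars=rng.normal(size=(6, 2)),
                       logits=rng.normal(size=(6, 2)), n_nodes=4)
        p = gg.edge_probability(mix, seed=3)
        assert np.allclose(p.p, p.p.T)
        assert np.all(np.diag(p.p) == 0)
        assert np.all((p.p >= 0) & (p.p <= 1))

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            gg.edge_probability(make_mix([[0.0]]), n_draws=0)

    def test_gradient_matches_finite_difference(self):
        """dp/d(mean) on a single edge: analytic vs central difference."""
        def p_of(mean):
            mix = make_mix([[mean, mean]], log_vars=[[-1.0, -0.5]],
                           logits=[[0.3, -0.2]])
            return gg.edge_probability(mix, n_draws=2, seed=7)

        mix = gg.MixtureEdgeParams(
            means=ad.parameter([[1.0, 1.0]]),
            log_vars=Tensor([[-1.0, -0.5]]),
            logits=Tensor([[0.3, -0.2]]), n_nodes=2)
        p = gg.edge_probability(mix, n_draws=2, seed=7)
        p.tensor[(0, 1)].backward()
        analytic = mix.means.grad.sum()
        eps = 1e-5
        numeric = (p_of(1.0 + eps).p[0, 1] - p_of(1.0 - eps).p[0, 1]) / (2 * eps)
        assert abs(analytic - numeric) < 1e-4

    def test_expected_probability_is_deterministic_and_equivariant(self):
        rng = np.random.default_rng(4)
        mix = make_mix(rng.normal(size=(3, 2)), log_vars=rng.normal(size=(3, 2)),
                       logits=rng.normal(size=(3, 2)), n_nodes=3)
        p1 = gg.expected_edge_probability(mix)
        p2 = gg.expected_edge_probability(mix)
        assert np.array_equal(p1.p, p2.p)


class TestGumbelSample:
    def test_degenerate_probabilities(self):
        p = gg.EdgeProbability(tensor=gg.edges_to_matrix(Tensor([1.0]), 2))
        lgs = gg.gumbel_sample(p, M=50, temperature=0.5, hard=True, seed=0)
        assert np.all(lgs.graphs.data[:, 0, 1] == 1.0)
        p0 = gg.EdgeProbability(tensor=gg.edges_to_matrix(Tensor([0.0]), 2))
        lgs0 = gg.gumbel_sample(p0, M=50, temperature=0.5, hard=True, seed=0)
        assert np.all(lgs0.graphs.data[:, 0, 1] == 0.0)

    def test_hard_sample_mean_concentrates(self):
        p = gg.EdgeProbability(tensor=gg.edges_to_matrix(Tensor([0.3]), 2))
        lgs = gg.gumbel_sample(p, M=10_000, temperature=0.1, hard=True, seed=1)
        assert lgs.expectation.data[0, 1] == pytest.approx(0.3, abs=0.02)

    def test_low_temperature_relaxed_samples_near_binary(self):
        rng = np.random.default_rng(2)
        pe = Tensor(rng.uniform(0.0, 1.0, size=4950))
        p = gg.EdgeProbability(tensor=gg.edges_to_matrix(pe, 100))
        lgs = gg.gumbel_sample(p, M=400, temperature=0.01, hard=False, seed=3)
        vals = gg.matrix_to_edges(lgs.graphs).data.ravel()
        near = (np.minimum(vals, 1 - vals) <= 0.05).mean()
        assert near >= 0.99

    def test_seeded_reproducibility(self):
        p = gg.EdgeProbability(tensor=gg.edges_to_matrix(Tensor([0.4, 0.6, 0.1]), 3))
        a = gg.gumbel_sample(p, M=5, seed=9).graphs.data
        b = gg.gumbel_sample(p, M=5, seed=9).graphs.data
        assert np.array_equal(a, b)

    def test_invalid_temperature(self):
        p = gg.EdgeProbability(tensor=gg.edges_to_matrix(Tensor([0.5]), 2))
        with pytest.raises(ValueError):
            gg.gumbel_sample(p, M=2, temperature=0.0)


class TestExpectation:
    def test_single_hard_sample_is_its_own_expectation(self):
        p = gg.EdgeProbability(tensor=gg.edges_to_matrix(Tensor([0.7, 0.2, 0.9]), 3))
        lgs = gg.gumbel_sample(p, M=1, hard=True, seed=0)
        exp = gg.expected_connectivity(lgs)
        assert np.array_equal(exp.p, lgs.graphs.data[0])

    def test_hand_listed_graphs_average(self):
        mats = np.stack([
            gg.edges_to_matrix(Tensor(v), 3).data
            for v in ([1, 0, 0], [1, 1, 0], [0, 0, 0], [1, 1, 1.0])])
        lgs = gg.LatentGraphSet(graphs=Tensor(mats),
                                expectation=Tensor(mats.mean(0)), temperature=0.5)
        exp = gg.expected_connectivity(lgs)
        assert np.allclose(gg.matrix_to_edges(exp.tensor).data,
                           [0.75, 0.5, 0.25])

    def test_all_ones(self):
        ones = np.stack([np.ones((3, 3)) - np.eye(3)] * 4)
        lgs = gg.LatentGraphSet(graphs=Tensor(ones),
                                expectation=Tensor(ones.mean(0)), temperature=0.5)
        assert np.allclose(gg.expected_connectivity(lgs).p,
                           np.ones((3, 3)) - np.eye(3))
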