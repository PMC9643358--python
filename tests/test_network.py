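"""Temporal encoder, attentive graph convolution, CNN branch, classifier,
and whole-model invariants."""

import numpy as np
import pytest
from scipy.special import expit

from ggn import _autodiff as ad
from ggn import network as net
from ggn._autodiff import Tensor


class TestTemporalEncoder:
    def test_zero_input_zero_output(self):
        rng = np.random.default_rng(0)
        params = net.init_gru(rng, in_dim=3, hidden=4, layers=2)
        out = net.temporal_encode(np.zeros((2, 5, 3, 6)), params)
        assert np.allclose(out.data, 0.0)

    def test_output_shape_contract(self):
        rng = np.random.default_rng(1)
        params = net.init_gru(rng, in_dim=3, hidden=4, layers=2)
        x = rng.normal(size=(2, 5, 3, 6))
        assert net.temporal_encode(x, params).shape == (2, 5, 4, 6)

    def test_hand_unrolled_recurrence(self):
        """1 node, 1 feature, hand-set weights, T=2: manual unroll oracle."""
        params = {"layers": 1, "hidden": 1}
        vals = {"Wz": 0.5, "Uz": 0.2, "bz": 0.1, "Wr": -0.3, "Ur": 0.4,
                "br": 0.0, "Wn": 0.7, "Un": -0.5, "bn": 0.2}
        for k, v in vals.items():
            shape = (1,) if k.startswith("b") else (1, 1)
            params[k + "0"] = ad.parameter(np.full(shape, v))
        x = np.array([[[0.6, -1.2]]])  # [N=1, C=1, T=2]
        out = net.temporal_encode(x, params).data.ravel()

        h = 0.0
        expected = []
        for t in range(2):
            xt = x[0, 0, t]
            z = expit(vals["Wz"] * xt + vals["Uz"] * h + vals["bz"])
            r = expit(vals["Wr"] * xt + vals["Ur"] * h + vals["br"])
            n = np.tanh(vals["Wn"] * xt + vals["Un"] * (r * h) + vals["bn"])
            h = (1 - z) * n + z * h
            expected.append(h)
        assert np.allclose(out, expected, atol=1e-12)


class TestGraphFamily:
    def test_k1_is_row_normalized_base_with_self_loops(self):
        base = np.array([[0, 2.0], [2.0, 0]])
        fam = net.build_graph_family(base, K=1)
        expected = (base + np.eye(2)) / 3.0
        assert np.allclose(fam.graphs.data[0], expected)

    def test_path_graph_two_hops_reach(self):
        # path a-b-c: Graph_2 connects a to c, Graph_1 does not
        base = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        fam = net.build_graph_family(base, K=2)
        g1, g2 = fam.graphs.data
        assert g1[0, 2] == 0.0
        assert g2[0, 2] > 0.0
        # hand 2-hop power oracle
        p1 = (base + np.eye(3))
        p1 = p1 / p1.sum(axis=1, keepdims=True)
        p2 = p1 @ p1
        p2 = p2 / p2.sum(axis=1, keepdims=True)
        assert np.allclose(g2, p2, atol=1e-12)

    def test_fresh_attention_uniform(self):
        fam = net.build_graph_family(np.zeros((4, 4)), K=3)
        assert np.allclose(fam.attention, 1 / 3)
        assert fam.attention.sum() == pytest.approx(1.0)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            net.build_graph_family(np.zeros((3, 3)), K=0)


class TestAttentiveGraphConv:
    def _params(self, c_in, c_out, rng):
        return {"v": ad.parameter(rng.normal(size=c_in)),
                "W": ad.parameter(rng.normal(size=(c_in, c_out))),
                "b": ad.parameter(np.zeros(c_out))}

    def test_zero_features_zero_output(self):
        rng = np.random.default_rng(0)
        fam = net.build_graph_family(np.abs(rng.normal(size=(4, 4))), K=2)
        out = net.attentive_graph_conv(fam, np.zeros((4, 3)),
                                       self._params(3, 5, rng))
        assert np.allclose(out.h.data, 0.0)

    def test_single_graph_reduces_to_plain_convolution(self):
        rng = np.random.default_rng(1)
        base = np.abs(rng.normal(size=(4, 4)))
        base = 0.5 * (base + base.T)
        np.fill_diagonal(base, 0)
        fam = net.build_graph_family(base, K=1)
        h = rng.normal(size=(4, 3))
        params = self._params(3, 5, rng)
        out = net.attentive_graph_conv(fam, h, params)
        plain = np.maximum(
            fam.graphs.data[0] @ h @ params["W"].data + params["b"].data, 0)
        assert np.allclose(out.h.data, plain, atol=1e-12)

    def test_three_node_hand_computation(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        fam = net.build_graph_family(adj, K=2)
        h = np.array([[1.0, 0], [0, 1], [1, 1]])
        W = np.array([[1.0, -1], [0.5, 2]])
        v = np.array([1.0, -2.0])
        params = {"v": Tensor(v), "W": Tensor(W), "b": Tensor(np.zeros(2))}
        out = net.attentive_graph_conv(fam, h, params)
        g = fam.graphs.data
        scores = np.array([(g[k] @ h).mean(axis=0) @ v for k in range(2)])
        att = np.exp(scores - scores.max())
        att /= att.sum()
        refined = att[0] * g[0] + att[1] * g[1]
        expected = np.maximum(refined @ h @ W, 0)
        assert np.allclose(out.h.data, expected, atol=1e-12)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(2)
        fam = net.build_graph_family(np.abs(rng.normal(size=(5, 5))), K=3)
        out = net.attentive_graph_conv(fam, rng.normal(size=(5, 4)),
                                       self._params(4, 6, rng))
        assert np.all(out.h.data >= 0)


class TestCnnBranch:
    def test_zero_input_zero_vector(self):
        rng = np.random.default_rng(0)
        params = net.init_cnn(rng, c_in=3, filters=2)
        out = net.cnn_branch(np.zeros((2, 4, 3, 6)), params)
        assert np.allclose(out.data, 0.0)

    def test_output_length_independent_of_values(self):
        rng = np.random.default_rng(1)
        params = net.init_cnn(rng, c_in=3, filters=2)
        a = net.cnn_branch(rng.normal(size=(2, 4, 3, 6)), params)
        b = net.cnn_branch(10 * rng.normal(size=(2, 4, 3, 6)), params)
        assert a.shape == b.shape

    def test_degenerate_identity_kernels_reproduce_input(self):
        """1x1 kernels wired as the identity pass features straight through."""
        c = 3
        w_id = np.zeros((c, c, 1, 1))
        for i in range(c):
            w_id[i, i, 0, 0] = 1.0
        params = {"k": 1, "W1": Tensor(w_id), "b1": Tensor(np.zeros(c)),
                  "W2": Tensor(w_id), "b2": Tensor(np.zeros(c))}
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(size=(1, 4, c, 5)))  # nonnegative: ReLU inert
        out = net.cnn_branch(x, params, pool_nodes=False)
        img = np.transpose(x, (0, 2, 1, 3))
        assert np.allclose(out.data, img.reshape(1, -1))


class TestClassifier:
    def _setup(self, rng, n=5, c=4, f=6, k=7):
        params = net.init_classifier(rng, c + f, hidden=8, n_classes=k)
        h = rng.normal(size=(2, n, c))
        vec = rng.normal(size=(2, f))
        return params, h, vec

    def test_probabilities_sum_to_one_positive(self):
        rng = np.random.default_rng(0)
        params, h, vec = self._setup(rng)
        out = net.classify(h, vec, params)
        assert np.allclose(out.probs.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(out.probs > 0)

    def test_node_permutation_invariance(self):
        rng = np.random.default_rng(1)
        params, h, vec = self._setup(rng)
        perm = rng.permutation(h.shape[1])
        a = net.classify(h, vec, params).probs
        b = net.classify(h[:, perm], vec, params).probs
        assert np.allclose(a, b, atol=1e-12)

    def test_equal_logits_give_uniform(self):
        params = {"W1": Tensor(np.zeros((3, 4))), "b1": Tensor(np.zeros(4)),
                  "W2": Tensor(np.zeros((4, 2))), "b2": Tensor(np.full(2, 0.7))}
        out = net.classify(np.ones((1, 2, 2)), np.ones((1, 1)), params)
        assert np.allclose(out.probs, 0.5)


class TestFullModel:
    def test_forward_permutation_equivariance(self, tiny_config, tiny_batch):
        x, a0, _ = tiny_batch
        model = net.GGNModel(tiny_config, seed=0)
        rng = np.random.default_rng(5)
        perm = rng.permutation(tiny_config.n_channels)
        p1 = model.forward(x, a0, rng=None)["probs"].probs
        p2 = model.forward(x[:, perm], a0[np.ix_(perm, perm)], rng=None)["probs"].probs
        assert np.allclose(p1, p2, atol=1e-5)

    def test_outputs_finite_on_random_inputs(self, tiny_config):
        model = net.GGNModel(tiny_config, seed=1)
        rng = np.random.default_rng(2)
        cfg = tiny_config
        for i in range(100):
            x = rng.normal(size=(1, cfg.n_channels, cfg.c_in, cfg.t_steps))
            a0 = np.abs(rng.normal(size=(cfg.n_channels, cfg.n_channels)))
            a0 = 0.5 * (a0 + a0.T)
            np.fill_diagonal(a0, 0)
            out = model.forward(x, a0[None], rng=np.random.default_rng(i))
            assert np.all(np.isfinite(out["probs"].probs))
            assert np.all(np.isfinite(out["p"].p))

    def test_frozen_sampler_deterministic(self, tiny_config, tiny_batch):
        x, a0, _ = tiny_batch
        model = net.GGNModel(tiny_config, seed=3)
        p1 = model.forward(x, a0, rng=np.random.default_rng(9))["probs"].probs
        p2 = model.forward(x, a0, rng=np.random.default_rng(9))["probs"].probs
        assert np.array_equal(p1, p2)

    def test_checkpoint_round_trip(self, tmp_path, tiny_config, tiny_batch):
        x, a0, _ = tiny_batch
        model = net.GGNModel(tiny_config, seed=4)
        before = model.forward(x, a0, rng=None)["probs"].probs
        path = tmp_path / "ckpt.json"
        model.save(path)
        loaded = net.GGNModel.load(path)
        after = loaded.forward(x, a0, rng=None)["probs"].probs
        assert np.allclose(before, after, atol=1e-12)

    def test_checkpoint_version_guard(self, tmp_path, tiny_config):
        path = tmp_path / "ckpt.json"
        net.GGNModel(tiny_config).save(path)
        import json
        doc = json.loads(path.read_text())
        doc["version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            net.GGNModel.load(path)
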