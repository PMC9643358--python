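"""Temporal encoder, attentive-graph-convolution spatial decoder, shallow
CNN branch, pooling, and the fully-connected softmax classifier — plus the
assembled graph-generative model that ties them to the connectivity
generator.

The spatial decoder convolves node features over an attention-weighted
combination of K graphs with increasing neighborhood range (row-normalized
matrix powers of the generated connectivity), so the network learns the
best neighboring range per input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, as_tensor, concat, conv2d, softmax, log_softmax, stack
from . import graph_generator as gg
from .preprocessing import RawTopology

__all__ = [
    "GGNConfig", "NodeRepresentations", "GraphFamily", "ClassProbabilities",
    "init_gru", "temporal_encode",
    "build_graph_family", "attentive_graph_conv",
    "init_cnn", "cnn_branch", "init_classifier", "classify",
    "GGNModel",
]

CHECKPOINT_VERSION = 1


@dataclass
class GGNConfig:
    """Architecture constants. All dimensions are configurable; defaults are
    sized for 20-electrode recordings with 5 band-power features over 10
    sub-frames per 5-s window."""

    n_channels: int = 20
    n_classes: int = 7
    c_in: int = 5            # feature bands
    t_steps: int = 10        # sub-frames per window
    c_enc: int = 16          # temporal-encoder hidden size
    enc_layers: int = 2
    embed_dim: int = 16      # Para-Learner node embedding
    mpnn_rounds: int = 2
    k_mix: int = 2           # mixture components per edge
    n_draws: int = 2         # mixture draws forming p_ij
    m_graphs: int = 3        # latent graphs per forward pass
    temperature: float = 0.5
    hard_samples: bool = True
    k_family: int = 3        # graphs with increasing neighborhood range
    c_out: int = 32          # decoder feature size
    decoder_layers: int = 2
    cnn_filters: int = 8
    cnn_kernel: int = 3      # along the time axis
    cnn_pool_nodes: bool = True
    cnn_on_encoder: bool = True  # CNN sees encoder outputs, not raw bands
    fc_hidden: int = 64

    @classmethod
    def from_yaml(cls, path) -> "GGNConfig":
        import yaml
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


@dataclass
class NodeRepresentations:
    """Per-layer node features h of shape [..., N, C_out]."""

    h: Tensor
    layer_index: int = 0


@dataclass
class GraphFamily:
    """Graphs 1..K with increasing neighborhood range plus attention weights."""

    graphs: Tensor            # [K, ..., N, N], each row-stochastic
    attention: np.ndarray     # [K], sums to 1 (initial weights)

    @property
    def K(self) -> int:
        return self.graphs.shape[0]

    def refined(self, attention=None) -> Tensor:
        att = self.attention if attention is None else attention
        parts = [self.graphs[(k,)] * float(att[k]) for k in range(self.K)]
        out = parts[0]
        for p in parts[1:]:
            out = out + p
        return out


@dataclass
class ClassProbabilities:
    """Softmax class probabilities, shape [..., n_classes]."""

    tensor: Tensor
    log_tensor: Tensor | None = None

    @property
    def probs(self) -> np.ndarray:
        return self.tensor.data


# ---------------------------------------------------------------------------
# temporal encoder (gated recurrent cells)

def init_gru(rng: np.random.Generator, in_dim: int, hidden: int,
             layers: int = 2) -> dict:
    params: dict = {"layers": layers, "hidden": hidden}
    d = in_dim
    for l in range(layers):
        for gate in ("z", "r", "n"):
            params[f"W{gate}{l}"] = ad.glorot(rng, d, hidden)
            params[f"U{gate}{l}"] = ad.glorot(rng, hidden, hidden)
            params[f"b{gate}{l}"] = ad.parameter(np.zeros(hidden))
        d = hidden
    return params


def temporal_encode(x, params: dict) -> Tensor:
    """Per-channel gated recurrent encoding over the time axis.

    x: [..., N, C_in, T] -> output [..., N, hidden, T] (hidden state at each
    step of the last layer). Deterministic given the weights.
    """
    x = as_tensor(x)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("encoder input must be finite")
    T = x.shape[-1]
    hidden = params["hidden"]
    seq = [x[(Ellipsis, t)] for t in range(T)]  # each [..., N, C_in]
    for l in range(params["layers"]):
        h = Tensor(np.zeros(seq[0].shape[:-1] + (hidden,)))
        out = []
        for t in range(T):
            xt = seq[t]
            z = (xt @ params[f"Wz{l}"] + h @ params[f"Uz{l}"] + params[f"bz{l}"]).sigmoid()
            r = (xt @ params[f"Wr{l}"] + h @ params[f"Ur{l}"] + params[f"br{l}"]).sigmoid()
            n = (xt @ params[f"Wn{l}"] + (r * h) @ params[f"Un{l}"] + params[f"bn{l}"]).tanh()
            h = (1.0 - z) * n + z * h
            out.append(h)
        seq = out
    return stack(seq, axis=-1)  # [..., N, hidden, T]


# ---------------------------------------------------------------------------
# attentive graph convolution

def build_graph_family(base, K: int = 3) -> GraphFamily:
    """Graph_k = row-normalized k-th power of (base + I): k-hop reach.

    base: EdgeProbability, LatentGraphSet expectation tensor, or array.
    Attention weights start uniform at 1/K.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    if isinstance(base, gg.EdgeProbability):
        base = base.tensor
    elif isinstance(base, gg.LatentGraphSet):
        base = base.expectation
    base = as_tensor(base)
    n = base.shape[-1]
    eye = Tensor(np.eye(n))
    b = base + eye

    def normalize(m: Tensor) -> Tensor:
        return m * (m.sum(axis=-1, keepdims=True) + 1e-12) ** -1.0

    p1 = normalize(b)
    graphs = [p1]
    for _ in range(1, K):
        graphs.append(normalize(graphs[-1] @ p1))
    return GraphFamily(graphs=stack(graphs, axis=0),
                       attention=np.full(K, 1.0 / K))


def attentive_graph_conv(family: GraphFamily, h, params: dict) -> NodeRepresentations:
    """One attentive graph convolution layer.

    Attention = softmax over K of a learned score per graph (score vector
    dotted with the mean node feature after propagating through that graph);
    output = ReLU(refined @ h @ W + b), nonnegative.
    """
    if isinstance(h, NodeRepresentations):
        layer = h.layer_index
        h = h.h
    else:
        layer = 0
    h = as_tensor(h)
    scores = []
    props = []
    for k in range(family.K):
        gk = family.graphs[(k,)]
        gh = gk @ h                          # [..., N, C]
        props.append(gh)
        m = gh.mean(axis=-2)                 # [..., C]
        scores.append((m * params["v"]).sum(axis=-1))  # [...]
    att = softmax(stack(scores, axis=-1), axis=-1)     # [..., K]
    mixed = None
    for k in range(family.K):
        ak = att[(Ellipsis, k)]
        term = props[k] * ak.reshape(ak.shape + (1, 1))
        mixed = term if mixed is None else mixed + term
    out = (mixed @ params["W"] + params["b"]).relu()
    return NodeRepresentations(h=out, layer_index=layer + 1)


def init_decoder(rng: np.random.Generator, c_in: int, c_out: int,
                 layers: int = 2) -> list[dict]:
    out = []
    d = c_in
    for _ in range(layers):
        out.append({
            "v": ad.glorot(rng, d, 1, d),
            "W": ad.glorot(rng, d, c_out),
            "b": ad.parameter(np.zeros(c_out)),
        })
        d = c_out
    return out


# ---------------------------------------------------------------------------
# shallow CNN branch

def init_cnn(rng: np.random.Generator, c_in: int, filters: int = 8,
             kernel: int = 3) -> dict:
    k = kernel
    fan1 = c_in * k
    fan2 = filters * k
    return {
        "k": k,
        "W1": ad.glorot(rng, fan1, filters, filters, c_in, 1, k),
        "b1": ad.parameter(np.zeros(filters)),
        "W2": ad.glorot(rng, fan2, filters, filters, filters, 1, k),
        "b2": ad.parameter(np.zeros(filters)),
    }


def cnn_branch(x, params: dict, pool_nodes: bool = True) -> Tensor:
    """Two small-kernel convolutions + ReLU + flatten to a 1-D vector.

    The feature dimension of the temporal features is taken as the image
    channel, so x [..., N, C, T] becomes an image batch [B, C, N, T].
    Kernels span the time axis only (1 x k). With ``pool_nodes`` the feature
    map is summed over the electrode axis before flattening, which keeps the
    full classifier invariant to electrode relabeling; without it the op is
    a literal conv + flatten.
    """
    x = as_tensor(x)
    single = x.ndim == 3
    if single:
        x = x.reshape((1,) + x.shape)
    img = x.transpose(0, 2, 1, 3)  # [B, C, N, T]
    pad = (0, params["k"] // 2)
    h1 = conv2d(img, params["W1"], params["b1"], padding=pad).relu()
    h2 = conv2d(h1, params["W2"], params["b2"], padding=pad).relu()
    if pool_nodes:
        h2 = h2.sum(axis=2, keepdims=True)
    B = h2.shape[0]
    flat = h2.reshape(B, int(np.prod(h2.shape[1:])))
    return flat.reshape(flat.shape[1:]) if single else flat


# ---------------------------------------------------------------------------
# classifier

def init_classifier(rng: np.random.Generator, in_dim: int, hidden: int,
                    n_classes: int) -> dict:
    return {
        "W1": ad.glorot(rng, in_dim, hidden),
        "b1": ad.parameter(np.zeros(hidden)),
        "W2": ad.glorot(rng, hidden, n_classes),
        "b2": ad.parameter(np.zeros(n_classes)),
    }


def classify(node_reps, cnn_vec, params: dict) -> ClassProbabilities:
    """Sum-pool node representations, concatenate the CNN vector, and apply
    the two-layer fully-connected softmax head."""
    h = node_reps.h if isinstance(node_reps, NodeRepresentations) else as_tensor(node_reps)
    pooled = h.sum(axis=-2)                     # invariant to node order
    z = concat([pooled, as_tensor(cnn_vec)], axis=-1)
    hid = (z @ params["W1"] + params["b1"]).relu()
    logits = hid @ params["W2"] + params["b2"]
    return ClassProbabilities(tensor=softmax(logits, axis=-1),
                              log_tensor=log_softmax(logits, axis=-1))


# ---------------------------------------------------------------------------
# the assembled model

class GGNModel:
    """The full graph-generative network.

    Parameters are split into theta (temporal encoder, CNN branch, spatial
    decoder, classifier) and omega (the connectivity graph generator), the
    two groups alternated over during training.
    """

    def __init__(self, config: GGNConfig | None = None, seed: int = 0):
        self.config = config or GGNConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        gen_in = cfg.c_enc * cfg.t_steps  # Para-Learner sees encoder output over time
        cnn_c = cfg.c_enc if cfg.cnn_on_encoder else cfg.c_in
        cnn_flat = cfg.cnn_filters * cfg.t_steps * (
            1 if cfg.cnn_pool_nodes else cfg.n_channels)
        self.params = {
            "encoder": init_gru(rng, cfg.c_in, cfg.c_enc, cfg.enc_layers),
            "paralearner": gg.init_para_learner(
                rng, gen_in, cfg.embed_dim, cfg.k_mix, cfg.mpnn_rounds),
            "decoder": init_decoder(rng, cfg.c_enc, cfg.c_out, cfg.decoder_layers),
            "cnn": init_cnn(rng, cnn_c, cfg.cnn_filters, cfg.cnn_kernel),
            "classifier": init_classifier(
                rng, cfg.c_out + cnn_flat, cfg.fc_hidden, cfg.n_classes),
        }

    # -- parameter bookkeeping ----------------------------------------
    @staticmethod
    def _collect(obj, out):
        if isinstance(obj, Tensor):
            out.append(obj)
        elif isinstance(obj, dict):
            for v in obj.values():
                GGNModel._collect(v, out)
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                GGNModel._collect(v, out)

    def theta_params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for group in ("encoder", "decoder", "cnn", "classifier"):
            self._collect(self.params[group], out)
        return out

    def omega_params(self) -> list[Tensor]:
        out: list[Tensor] = []
        self._collect(self.params["paralearner"], out)
        return out

    def param_groups(self) -> dict[str, list[Tensor]]:
        out = {}
        for name, group in self.params.items():
            lst: list[Tensor] = []
            self._collect(group, lst)
            out[name] = lst
        return out

    # -- forward -------------------------------------------------------
    def forward(self, x, a0, rng: np.random.Generator | None = None,
                M: int | None = None) -> dict:
        """Full forward pass on a batch of windows.

        x: [B, N, C_in, T] features; a0: [B, N, N] (or [N, N]) raw topology.
        With ``rng`` None the pass is deterministic: the graph family is
        built from p_ij itself (the infinite-sample expectation) instead of
        Gumbel samples.
        """
        cfg = self.config
        x = as_tensor(x)
        if isinstance(a0, RawTopology):
            a0 = a0.a0
        a0 = as_tensor(a0)
        enc = temporal_encode(x, self.params["encoder"])  # [B, N, C_enc, T]
        mix = gg.para_learn(enc, a0, self.params["paralearner"])
        if rng is None:
            p = gg.expected_edge_probability(mix)
            lgs = None
            base = p
        else:
            p = gg.edge_probability(mix, cfg.n_draws, seed=rng)
            lgs = gg.gumbel_sample(p, M or cfg.m_graphs, cfg.temperature,
                                   hard=cfg.hard_samples, seed=rng)
            base = gg.expected_connectivity(lgs)
        family = build_graph_family(base, cfg.k_family)
        reps = NodeRepresentations(h=enc.mean(axis=-1), layer_index=0)
        for layer_params in self.params["decoder"]:
            reps = attentive_graph_conv(family, reps, layer_params)
        cnn_in = enc if cfg.cnn_on_encoder else x
        vec = cnn_branch(cnn_in, self.params["cnn"], cfg.cnn_pool_nodes)
        cls = classify(reps, vec, self.params["classifier"])
        return {"probs": cls, "p": p, "latent": lgs, "family": family,
                "encoded": enc}

    # -- checkpoints ----------------------------------------------------
    def save(self, path) -> None:
        """Versioned JSON checkpoint: config + every weight as nested lists."""

        def pack(obj):
            if isinstance(obj, Tensor):
                return {"__tensor__": obj.data.tolist()}
            if isinstance(obj, dict):
                return {k: pack(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [pack(v) for v in obj]
            return obj

        doc = {"version": CHECKPOINT_VERSION,
               "config": self.config.__dict__,
               "params": pack(self.params)}
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "GGNModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {doc.get('version')!r}")
        model = cls(GGNConfig(**doc["config"]))

        def unpack(obj):
            if isinstance(obj, dict) and "__tensor__" in obj:
                return ad.parameter(np.asarray(obj["__tensor__"], float))
            if isinstance(obj, dict):
                return {k: unpack(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [unpack(v) for v in obj]
            return obj

        model.params = unpack(doc["params"])
        return model
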