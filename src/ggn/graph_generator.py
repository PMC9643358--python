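"""The connectivity graph generator.

Three independent message-passing networks (the Para-Learner) map the raw
topology A(0) and temporal features to the parameters of a per-edge mixture
Gaussian (means / log-variances / mixing logits). Two reparameterized draws
per node pair are squashed through a logistic to give the edge probability
p_ij, from which M latent graphs A(m) are sampled with the binary-concrete
(Gumbel-softmax) relaxation so the whole path stays differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, as_tensor, concat, softmax, stack

__all__ = [
    "MixtureEdgeParams", "EdgeProbability", "LatentGraphSet",
    "pair_indices", "edges_to_matrix", "matrix_to_edges",
    "init_para_learner", "para_learn",
    "edge_probability", "gumbel_sample", "expected_connectivity",
]

_PARAM_GROUPS = ("means", "log_vars", "logits")


def pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i < j) node-pair indices; E = n(n-1)/2 pairs."""
    return np.triu_indices(n, k=1)


def _scatter_matrix(n: int) -> np.ndarray:
    """Constant [E x n*n] map placing an edge vector into both triangles."""
    iu, ju = pair_indices(n)
    P = np.zeros((len(iu), n * n))
    P[np.arange(len(iu)), iu * n + ju] = 1.0
    P[np.arange(len(iu)), ju * n + iu] = 1.0
    return P


def edges_to_matrix(v: Tensor, n: int) -> Tensor:
    """Edge vector [..., E] -> symmetric zero-diagonal matrix [..., n, n]."""
    v = as_tensor(v)
    lead = v.shape[:-1]
    out = v.reshape(lead + (1, v.shape[-1])) @ Tensor(_scatter_matrix(n))
    return out.reshape(lead + (n, n))


def matrix_to_edges(m: Tensor) -> Tensor:
    """Symmetric matrix [..., n, n] -> upper-triangle edge vector [..., E]."""
    m = as_tensor(m)
    n = m.shape[-1]
    iu, ju = pair_indices(n)
    idx = (Ellipsis, iu, ju)
    return m[idx]


@dataclass
class MixtureEdgeParams:
    """Per-edge mixture-Gaussian parameters, each of shape [..., E, K_mix]."""

    means: Tensor
    log_vars: Tensor
    logits: Tensor
    n_nodes: int

    @property
    def k_mix(self) -> int:
        return self.means.shape[-1]


@dataclass
class EdgeProbability:
    """Edge probabilities p_ij: symmetric [N x N] (or batched), zero diagonal."""

    tensor: Tensor

    @property
    def p(self) -> np.ndarray:
        return self.tensor.data

    @property
    def n_nodes(self) -> int:
        return self.tensor.shape[-1]

    def edges(self) -> Tensor:
        return matrix_to_edges(self.tensor)


@dataclass
class LatentGraphSet:
    """M sampled adjacency matrices plus their expectation.

    graphs has shape [M, ..., N, N] with entries in [0, 1] (relaxed) or
    {0, 1} (hard straight-through); expectation is the entry-wise mean.
    """

    graphs: Tensor
    expectation: Tensor
    temperature: float

    @property
    def M(self) -> int:
        return self.graphs.shape[0]


# ---------------------------------------------------------------------------
# Para-Learner

def _node_input(features) -> Tensor:
    """[..., N, C, T] features -> [..., N, C*T] node vectors.

    The feature-by-time block is flattened rather than time-averaged: the
    sub-frame time courses carry the co-fluctuation signature that lets the
    pair combination h_i * h_j act as a learned similarity kernel between
    coupled channels.
    """
    x = as_tensor(features)
    if x.ndim >= 3:
        lead = x.shape[:-2]
        x = x.reshape(lead + (x.shape[-2] * x.shape[-1],))
    return x


def init_para_learner(rng: np.random.Generator, in_dim: int, embed_dim: int = 16,
                      k_mix: int = 2, rounds: int = 2) -> dict:
    """Initialize three independent message-passing networks.

    Each network: input embedding, `rounds` rounds of sum-aggregation over
    A(0) with shared weights across edges, and a linear edge head over the
    symmetric pair combination [h_i * h_j, h_i + h_j].
    """
    params: dict = {"rounds": rounds, "k_mix": k_mix}
    for group in _PARAM_GROUPS:
        net = {
            "W_in": ad.glorot(rng, in_dim, embed_dim),
            "b_in": ad.parameter(np.zeros(embed_dim)),
            "W_edge": ad.glorot(rng, 2 * embed_dim, k_mix),
            "b_edge": ad.parameter(np.zeros(k_mix)),
        }
        for r in range(rounds):
            net[f"W_self{r}"] = ad.glorot(rng, embed_dim, embed_dim)
            net[f"W_nei{r}"] = ad.glorot(rng, embed_dim, embed_dim)
            net[f"b{r}"] = ad.parameter(np.zeros(embed_dim))
        params[group] = net
    # the log-variance head starts near a moderate spread; the mixing head at 0
    params["log_vars"]["b_edge"].data[:] = -1.0
    return params


def _run_mpnn(net: dict, x: Tensor, a0: Tensor, rounds: int,
              iu: np.ndarray, ju: np.ndarray) -> Tensor:
    h = (x @ net["W_in"] + net["b_in"]).relu()
    for r in range(rounds):
        agg = a0 @ h  # sum-aggregation weighted by the raw topology
        h = (h @ net[f"W_self{r}"] + agg @ net[f"W_nei{r}"] + net[f"b{r}"]).relu()
    hi = h[(Ellipsis, iu, slice(None))]
    hj = h[(Ellipsis, ju, slice(None))]
    pair = concat([hi * hj, hi + hj], axis=-1)
    return pair @ net["W_edge"] + net["b_edge"]


def para_learn(features, a0, params: dict) -> MixtureEdgeParams:
    """Run the three message-passing networks to get per-edge mixture params.

    features: [..., N, C_in, T] (or already [..., N, C]); a0: [..., N, N]
    symmetric raw topology. Deterministic given the weights; permutation
    equivariant in the nodes.
    """
    x = _node_input(features)
    a0_t = as_tensor(a0.a0 if hasattr(a0, "a0") else a0)
    n = a0_t.shape[-1]
    if x.shape[-2] != n:
        raise ValueError(f"feature node count {x.shape[-2]} != topology size {n}")
    if not np.allclose(a0_t.data, np.swapaxes(a0_t.data, -1, -2)):
        raise ValueError("raw topology must be symmetric")
    iu, ju = pair_indices(n)
    out = {g: _run_mpnn(params[g], x, a0_t, params["rounds"], iu, ju)
           for g in _PARAM_GROUPS}
    return MixtureEdgeParams(means=out["means"], log_vars=out["log_vars"],
                             logits=out["logits"], n_nodes=n)


# ---------------------------------------------------------------------------
# edge probability and Gumbel sampling

def _rng_of(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def edge_probability(mix: MixtureEdgeParams, n_draws: int = 2,
                     seed=0, component_temperature: float = 1.0) -> EdgeProbability:
    """Draw samples from each edge's mixture Gaussian and squash their mean.

    Per pair: the mixture component is chosen by a softmax-weighted Gumbel
    relaxation of the mixing logits, the value reparameterized as
    mean + sigma * xi; p_ij = logistic(mean of the draws). Differentiable
    with respect to all mixture parameters.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = _rng_of(seed)
    sigma = (mix.log_vars * 0.5).exp()
    shape = mix.means.shape
    draws = []
    for _ in range(n_draws):
        g = Tensor(rng.gumbel(size=shape))
        w = softmax((mix.logits + g) * (1.0 / component_temperature), axis=-1)
        xi = Tensor(rng.standard_normal(shape))
        value = (w * (mix.means + sigma * xi)).sum(axis=-1)
        draws.append(value)
    s = stack(draws, axis=0).mean(axis=0)
    p_edges = s.sigmoid()
    return EdgeProbability(tensor=edges_to_matrix(p_edges, mix.n_nodes))


def expected_edge_probability(mix: MixtureEdgeParams) -> EdgeProbability:
    """Noise-free edge probabilities: logistic of the mixture mean.

    The deterministic counterpart of :func:`edge_probability` used at
    inference time; exactly permutation equivariant.
    """
    w = softmax(mix.logits, axis=-1)
    s = (w * mix.means).sum(axis=-1)
    return EdgeProbability(tensor=edges_to_matrix(s.sigmoid(), mix.n_nodes))


def gumbel_sample(p: EdgeProbability, M: int = 8, temperature: float = 0.5,
                  hard: bool = False, seed=0) -> LatentGraphSet:
    """Sample M latent graphs with the binary-concrete relaxation.

    Per edge and graph: y = logistic((logit(p_ij) + L) / temperature) with
    logistic noise L; hard=True applies straight-through rounding so values
    are binary while gradients follow the relaxation.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if M < 1:
        raise ValueError("M must be at least 1")
    rng = _rng_of(seed)
    pe = p.edges().clip(1e-12, 1.0 - 1e-12)
    logit = pe.log() - (1.0 - pe).log()
    u = rng.uniform(1e-12, 1.0 - 1e-12, size=(M,) + logit.shape)
    noise = Tensor(np.log(u) - np.log1p(-u))
    y = ((logit + noise) * (1.0 / temperature)).sigmoid()
    if hard:
        y = y + Tensor(np.round(y.data) - y.data)  # straight-through
    graphs = edges_to_matrix(y, p.n_nodes)
    return LatentGraphSet(graphs=graphs, expectation=graphs.mean(axis=0),
                          temperature=temperature)


def expected_connectivity(lgs: LatentGraphSet) -> EdgeProbability:
    """Entry-wise mean of the sampled graphs (the functional connectivity)."""
    if lgs.M < 1:
        raise ValueError("need at least one sampled graph")
    return EdgeProbability(tensor=lgs.graphs.mean(axis=0))
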