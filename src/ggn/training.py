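"""Training: the graph-marginalized likelihood objective, its ELBO
surrogate, weighted cross-entropy, and EM-style alternating optimization of
the model parameters theta and the generator parameters omega.

The variational family Q_omega is the factorized Bernoulli graph
distribution defined by the generated edge probabilities p_ij; maximizing
the ELBO over omega tightens the bound while minimizing weighted
cross-entropy over theta fits the classifier.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Tensor, as_tensor
from . import graph_generator as gg
from . import network as net
from . import preprocessing as pp
from . import synthetic_data as sd

__all__ = [
    "TrainingConfig", "ElboTerms", "Sample",
    "wce_loss", "elbo", "elbo_exact", "enumerated_log_likelihood",
    "em_train", "train_test_split",
    "prepare_samples", "recovery_experiment",
]


@dataclass
class TrainingConfig:
    lr: float = 3e-3
    epochs: int = 10
    batch_size: int = 16
    M: int = 3
    class_weights: np.ndarray | None = None  # omega_k proportions, sum 1
    seed: int = 0
    alternation: tuple[int, int] = (1, 1)    # (steps_theta, steps_omega)
    prior_weight: float = 1.0
    include_a0: bool = False

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1 or self.M < 1:
            raise ValueError("lr, epochs, batch_size and M must be positive")
        if any(s < 0 for s in self.alternation):
            raise ValueError("alternation step counts must be nonnegative")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, float)
            if (w < 0).any():
                raise ValueError("class weights must be nonnegative")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("class weights must sum to 1")
            self.class_weights = w


@dataclass
class ElboTerms:
    """Per-sample, per-graph log P_theta and log Q_omega plus the bound."""

    log_p: np.ndarray   # [M, S]
    log_q: np.ndarray   # [M, S]
    elbo: float
    elbo_tensor: Tensor | None = None


@dataclass
class Sample:
    """One training case: window features, raw topology, class label."""

    x: np.ndarray       # [N, C_in, T]
    a0: np.ndarray      # [N, N]
    label: int
    rec_id: int = -1


# ---------------------------------------------------------------------------
# losses

def wce_loss(probs, labels, class_weights=None) -> Tensor:
    """Weighted cross-entropy: sum_s w_{y_s} * (-log p_s[y_s]) / sum_s w_{y_s}.

    With uniform weights this is the ordinary mean cross-entropy. Zero
    predicted probabilities are clamped at 1e-12 with a warning.
    """
    labels = np.asarray(labels, int)
    if isinstance(probs, net.ClassProbabilities):
        if probs.log_tensor is not None:
            lp = probs.log_tensor
        else:
            lp = probs.tensor.clip(1e-12, 1.0).log()
        k = probs.tensor.shape[-1]
        raw = probs.tensor.data
    else:
        t = as_tensor(probs)
        raw = t.data
        if (raw < 1e-12).any():
            warnings.warn("zero class probabilities clamped at 1e-12")
        lp = t.clip(1e-12, 1.0).log()
        k = t.shape[-1]
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in 0..{k - 1}")
    if class_weights is None:
        w = np.ones(k)
    else:
        w = np.asarray(class_weights, float)
    sw = w[labels]
    if lp.ndim == 1:
        lp = lp.reshape(1, k)
    picked = lp[(np.arange(len(labels)), labels)]
    loss = -(picked * Tensor(sw)).sum() * (1.0 / sw.sum())
    return loss


# ---------------------------------------------------------------------------
# ELBO

def _normalized_prior(a0: np.ndarray) -> np.ndarray:
    """Edge prior probabilities from A(0): scaled into (0, 1)."""
    a0 = np.asarray(a0, float)
    hi = a0.max(axis=(-2, -1), keepdims=True)
    pi = a0 / np.where(hi > 0, hi, 1.0)
    return np.clip(pi, 1e-6, 1.0 - 1e-6)


def _bernoulli_logmass(a_edges: Tensor, p_edges) -> Tensor:
    """sum_e [a log p + (1-a) log(1-p)] along the last axis."""
    p = p_edges if isinstance(p_edges, Tensor) else Tensor(p_edges)
    p = p.clip(1e-12, 1.0 - 1e-12)
    return (a_edges * p.log() + (1.0 - a_edges) * (1.0 - p).log()).sum(axis=-1)


def elbo(model: net.GGNModel, batch: list[Sample], M: int | None = None,
         seed=0, prior_weight: float = 1.0, include_a0: bool = False,
         class_weights=None) -> ElboTerms:
    """Monte-Carlo ELBO of a batch under the current model.

    For each of M hard (straight-through) Gumbel samples A(m):
    log Q = factorized Bernoulli mass of A(m) under p_ij;
    log P = classifier log-likelihood of the label given A(m) plus a
    Bernoulli edge-prior term with probabilities from normalized A(0).
    The bound averages over graphs and sums over samples, and is
    differentiable through the Gumbel relaxation.
    """
    cfg = model.config
    M = M or cfg.m_graphs
    if M < 1:
        raise ValueError("M must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xb = np.stack([s.x for s in batch])
    a0b = np.stack([s.a0 for s in batch])
    labels = np.asarray([s.label for s in batch], int)
    S = len(batch)
    w = (np.ones(cfg.n_classes) if class_weights is None
         else np.asarray(class_weights, float))

    enc = net.temporal_encode(xb, model.params["encoder"])
    mix = gg.para_learn(enc, a0b, model.params["paralearner"])
    p = gg.edge_probability(mix, cfg.n_draws, seed=rng)
    lgs = gg.gumbel_sample(p, M, cfg.temperature, hard=True, seed=rng)
    p_edges = p.edges()                      # [S, E]
    prior_edges = gg.matrix_to_edges(Tensor(_normalized_prior(a0b)))
    cnn_in = enc if cfg.cnn_on_encoder else Tensor(xb)
    vec = net.cnn_branch(cnn_in, model.params["cnn"], cfg.cnn_pool_nodes)

    def class_loglik(adj: Tensor) -> Tensor:
        family = net.build_graph_family(adj, cfg.k_family)
        reps = net.NodeRepresentations(h=enc.mean(axis=-1))
        for lp_ in model.params["decoder"]:
            reps = net.attentive_graph_conv(family, reps, lp_)
        cls = net.classify(reps, vec, model.params["classifier"])
        return cls.log_tensor[(np.arange(S), labels)] * Tensor(w[labels])

    log_p_rows, log_q_rows = [], []
    for m in range(M):
        adj = lgs.graphs[(m,)]
        a_edges = gg.matrix_to_edges(adj)
        lq = _bernoulli_logmass(a_edges, p_edges)
        lprior = _bernoulli_logmass(a_edges, prior_edges)
        lp = class_loglik(adj) + lprior * prior_weight
        log_p_rows.append(lp)
        log_q_rows.append(lq)
    from ._autodiff import stack as ad_stack
    log_p_t = ad_stack(log_p_rows, axis=0)   # [M, S]
    log_q_t = ad_stack(log_q_rows, axis=0)
    bound = (log_p_t - log_q_t).mean(axis=0).sum()
    if include_a0:
        bound = bound + class_loglik(Tensor(_normalized_prior(a0b))).sum()
    return ElboTerms(log_p=log_p_t.data.copy(), log_q=log_q_t.data.copy(),
                     elbo=float(bound.data), elbo_tensor=bound)


def elbo_exact(edge_p: np.ndarray, log_joint) -> float:
    """Exact ELBO of a factorized Bernoulli Q over all 2^E graphs.

    edge_p: per-edge probabilities; log_joint(bits) -> log P(Y, A) for the
    binary edge vector `bits`. Terms with q(A) = 0 contribute zero.
    """
    edge_p = np.asarray(edge_p, float)
    total = 0.0
    for bits in itertools.product((0, 1), repeat=edge_p.size):
        a = np.asarray(bits, float)
        probs = np.where(a > 0, edge_p, 1.0 - edge_p)
        if (probs <= 0).any():
            continue  # q(A) = 0 contributes nothing
        lq = float(np.log(probs).sum())
        total += float(np.exp(lq)) * (log_joint(a) - lq)
    return total


def enumerated_log_likelihood(n_edges: int, log_joint) -> float:
    """log sum over all 2^E graphs of P(Y, A) — the exact marginal."""
    vals = [log_joint(np.asarray(bits, float))
            for bits in itertools.product((0, 1), repeat=n_edges)]
    vals = np.asarray(vals)
    m = vals.max()
    return float(m + np.log(np.exp(vals - m).sum()))


# ---------------------------------------------------------------------------
# EM-style training

def _first_nonfinite_group(model: net.GGNModel) -> str | None:
    for name, tensors in model.param_groups().items():
        for t in tensors:
            if not np.all(np.isfinite(t.data)):
                return name
    return None


def em_train(dataset: list[Sample], cfg: TrainingConfig,
             model: net.GGNModel | None = None,
             config: net.GGNConfig | None = None) -> tuple[net.GGNModel, list[dict]]:
    """Alternating optimization: theta steps minimize WCE with omega frozen,
    omega steps maximize the ELBO with theta frozen. Adam on both groups;
    fully seeded and deterministic for a fixed config.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    if model is None:
        model = net.GGNModel(config or net.GGNConfig(), seed=cfg.seed)
    steps_theta, steps_omega = cfg.alternation
    opt_theta = Adam(model.theta_params(), lr=cfg.lr)
    opt_omega = Adam(model.omega_params(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    all_params = model.theta_params() + model.omega_params()
    history: list[dict] = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        wce_sum = elbo_sum = 0.0
        n_batches = correct = seen = 0
        for start in range(0, len(dataset), cfg.batch_size):
            batch = [dataset[i] for i in order[start:start + cfg.batch_size]]
            xb = np.stack([s.x for s in batch])
            a0b = np.stack([s.a0 for s in batch])
            labels = np.asarray([s.label for s in batch], int)

            for _ in range(steps_theta):
                out = model.forward(xb, a0b, rng=rng, M=cfg.M)
                loss = wce_loss(out["probs"], labels, cfg.class_weights)
                if not np.isfinite(loss.data):
                    bad = _first_nonfinite_group(model) or "loss"
                    raise FloatingPointError(
                        f"non-finite WCE; first affected parameter group: {bad}")
                for t in all_params:
                    t.grad = None
                loss.backward()
                opt_theta.step()
                wce_sum += float(loss.data)
                pred = out["probs"].probs.argmax(axis=-1)
                correct += int((pred == labels).sum())
                seen += len(labels)
            for _ in range(steps_omega):
                terms = elbo(model, batch, M=cfg.M, seed=rng,
                             prior_weight=cfg.prior_weight,
                             include_a0=cfg.include_a0,
                             class_weights=cfg.class_weights)
                if not np.isfinite(terms.elbo):
                    bad = _first_nonfinite_group(model) or "elbo"
                    raise FloatingPointError(
                        f"non-finite ELBO; first affected parameter group: {bad}")
                loss = terms.elbo_tensor * (-1.0 / len(batch))
                for t in all_params:
                    t.grad = None
                loss.backward()
                opt_omega.step()
                elbo_sum += terms.elbo / len(batch)
            n_batches += 1
        history.append({
            "epoch": epoch,
            "wce": wce_sum / max(n_batches * max(steps_theta, 1), 1),
            "elbo": elbo_sum / max(n_batches * max(steps_omega, 1), 1),
            "accuracy": correct / seen if seen else float("nan"),
        })
    return model, history


def train_test_split(cases: list, n_train: int, seed: int = 0) -> tuple[list, list]:
    """Seeded shuffle; first n_train cases train, the rest test."""
    if not (0 < n_train < len(cases)):
        raise ValueError("n_train must satisfy 0 < n_train < len(cases)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    train = [cases[i] for i in order[:n_train]]
    test = [cases[i] for i in order[n_train:]]
    return train, test


# ---------------------------------------------------------------------------
# desk-scale parameter-recovery experiment

def prepare_samples(recordings: list[sd.Recording], label_index: dict[str, int],
                    window_s: float = 5.0, n_bands: int = 5, n_frames: int = 10,
                    topology: str = "correlation", onset_only: bool = True,
                    ) -> list[Sample]:
    """Turn recordings into training samples (one per retained window).

    The raw topology A(0) is computed per recording; with the default
    `correlation` source it is the absolute-Pearson adjacency over the full
    recording.
    """
    coords = None
    samples = []
    for rid, rec in enumerate(recordings):
        if topology == "correlation":
            a0 = pp.correlation_topology(rec).a0
        elif topology == "distance":
            if coords is None or coords.shape[0] != rec.n_channels:
                coords = sd.default_electrode_coords(rec.n_channels)
            a0 = pp.distance_topology(coords).a0
        elif topology == "blend":
            if coords is None or coords.shape[0] != rec.n_channels:
                coords = sd.default_electrode_coords(rec.n_channels)
            a0 = pp.blend_topology(rec, coords).a0
        else:
            raise ValueError(f"unknown topology source {topology!r}")
        feats = pp.windowed_features(rec, window_s, n_bands, n_frames,
                                     onset_only=onset_only)
        for f in feats:
            samples.append(Sample(x=f.x, a0=a0, label=label_index[rec.label],
                                  rec_id=rid))
    return samples


def _recording_prediction(model: net.GGNModel, samples: list[Sample]) -> tuple[int, np.ndarray]:
    """Mean class probabilities and mean p_ij over one recording's windows."""
    xb = np.stack([s.x for s in samples])
    a0b = np.stack([s.a0 for s in samples])
    out = model.forward(xb, a0b, rng=None)
    probs = out["probs"].probs.mean(axis=0)
    p_mean = out["p"].p.mean(axis=0)
    return int(np.argmax(probs)), p_mean


def recovery_experiment(seed: int = 0, n_recordings: int = 150,
                        templates: tuple[str, ...] = ("resting", "FN", "GN"),
                        duration_s: float = 30.0, fs: float = 250.0,
                        n_channels: int = 20, window_s: float = 5.0,
                        n_train: int | None = None,
                        train_cfg: TrainingConfig | None = None) -> dict:
    """Train the full model on synthetic recordings with planted coupling and
    measure held-out classification accuracy and edge-recovery AUROC of the
    inferred p_ij against the planted onset coupling graph.
    """
    from .evaluation import binary_auc

    per = n_recordings // len(templates)
    counts = [per + (1 if i < n_recordings % len(templates) else 0)
              for i in range(len(templates))]
    recs = []
    k = 0
    for tmpl, c in zip(templates, counts):
        for _ in range(c):
            rec, _truth = sd.generate_recording(
                tmpl, duration_s, fs, seed=seed * 100003 + k, n_channels=n_channels)
            recs.append(rec)
            k += 1
    label_index = {t: i for i, t in enumerate(templates)}

    train_recs, test_recs = train_test_split(
        recs, n_train or (2 * n_recordings) // 3, seed=seed)
    samples = prepare_samples(train_recs, label_index, window_s=window_s)

    cfg = net.GGNConfig(n_channels=n_channels, n_classes=len(templates))
    tcfg = train_cfg or TrainingConfig(seed=seed)
    model, history = em_train(samples, tcfg, config=cfg)

    correct = 0
    aucs = []
    iu, ju = gg.pair_indices(n_channels)
    for rec in test_recs:
        rec_samples = prepare_samples([rec], label_index, window_s=window_s)
        pred, p_mean = _recording_prediction(model, rec_samples)
        correct += int(pred == label_index[rec.label])
        if rec.label != "resting":
            truth = sd.template_mask(rec.label, n_channels)[iu, ju]
            if 0 < truth.sum() < truth.size:
                aucs.append(binary_auc(p_mean[iu, ju], truth.astype(int)))
    return {
        "model": model,
        "history": history,
        "accuracy": correct / len(test_recs),
        "edge_auroc": float(np.mean(aucs)) if aucs else float("nan"),
        "n_test": len(test_recs),
    }
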