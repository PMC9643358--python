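"""Connection-strength transform, edge filtering and connectivity-graph
serialization.

The display transform maps an edge probability p_ij in [0, 1] onto
strength(i, j) = exp((exp(eps * p_ij) - 1) / sigma), a doubly-exponential
curve chosen to reflect the exponential chaoticity of epileptic signals: it
runs from the minimal value 1 at p = 0 to exp((exp(eps) - 1) / sigma) at
p = 1 and is strictly increasing in between. Exported graphs keep only the
top-k strongest undirected edges (k = 25 by default, the printed display
rule) and flag as colored those above the threshold beta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph_generator import EdgeProbability

__all__ = [
    "ConnectivityGraph", "Edge",
    "connection_strength", "strength_range", "top_k_edges",
    "color_by_threshold", "export_graph", "read_edge_list_tsv",
]


@dataclass
class Edge:
    i: int
    j: int
    strength: float
    colored: bool = False


@dataclass
class ConnectivityGraph:
    """Filtered, strength-transformed edges of one time window."""

    strengths: np.ndarray
    edges: list[Edge]
    window_interval: tuple[float, float] = (0.0, 0.0)
    eps: float = 2.0
    sigma: float = 1.0
    beta: float = 0.0
    k: int = 25


def connection_strength(p, eps: float = 2.0, sigma: float = 1.0) -> np.ndarray:
    """exp((exp(eps * p_ij) - 1) / sigma), entry-wise; diagonal at the
    minimum value 1."""
    if eps <= 0 or sigma <= 0:
        raise ValueError("eps and sigma must be positive")
    if isinstance(p, EdgeProbability):
        p = p.p
    p = np.asarray(p, float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    s = np.exp((np.exp(eps * p) - 1.0) / sigma)
    if s.ndim == 2 and s.shape[0] == s.shape[1]:
        np.fill_diagonal(s, 1.0)
    return s


def strength_range(eps: float, sigma: float) -> tuple[float, float]:
    """The attainable [min, max] strength for given hyperparameters."""
    return 1.0, float(np.exp((np.exp(eps) - 1.0) / sigma))


def top_k_edges(strengths: np.ndarray, k: int = 25) -> list[Edge]:
    """The k highest-strength undirected edges (upper triangle), sorted
    descending; ties broken by (i, j) lexicographic order."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    strengths = np.asarray(strengths, float)
    n = strengths.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = sorted(range(len(iu)),
                   key=lambda e: (-strengths[iu[e], ju[e]], iu[e], ju[e]))
    return [Edge(int(iu[e]), int(ju[e]), float(strengths[iu[e], ju[e]]))
            for e in order[:k]]


def color_by_threshold(edges: list[Edge], beta: float) -> list[Edge]:
    """Flag edges with strength strictly greater than beta as colored;
    the rest stay gray."""
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    return [Edge(e.i, e.j, e.strength, colored=e.strength > beta)
            for e in edges]


def build_graph(p, window_interval=(0.0, 0.0), eps: float = 2.0,
                sigma: float = 1.0, beta: float | None = None,
                k: int = 25) -> ConnectivityGraph:
    """Full export pipeline: strengths, top-k filter, threshold coloring.

    Default beta is the midpoint of the attainable strength range.
    """
    strengths = connection_strength(p, eps, sigma)
    if beta is None:
        lo, hi = strength_range(eps, sigma)
        beta = 0.5 * (lo + hi)
    edges = color_by_threshold(top_k_edges(strengths, k), beta)
    return ConnectivityGraph(strengths=strengths, edges=edges,
                             window_interval=tuple(window_interval),
                             eps=eps, sigma=sigma, beta=beta, k=k)


def export_graph(cg: ConnectivityGraph, path, format: str = "tsv") -> None:
    """Serialize edges + hyperparameters + window interval.

    Formats: 'tsv' edge list, 'graphml' (strength and colored as edge
    attributes), or 'json'.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as f:
            f.write(f"# window: {cg.window_interval[0]} {cg.window_interval[1]}\n")
            f.write(f"# eps: {cg.eps}\n# sigma: {cg.sigma}\n"
                    f"# beta: {cg.beta}\n# k: {cg.k}\n")
            f.write("src\tdst\tstrength\tcolored\n")
            for e in cg.edges:
                f.write(f"{e.i}\t{e.j}\t{e.strength:.12g}\t{int(e.colored)}\n")
    elif format == "graphml":
        import networkx as nx
        g = nx.Graph()
        g.graph.update(eps=cg.eps, sigma=cg.sigma, beta=cg.beta, k=cg.k,
                       window_start=cg.window_interval[0],
                       window_end=cg.window_interval[1])
        n = cg.strengths.shape[0] if cg.strengths.ndim == 2 else 0
        g.add_nodes_from(range(n))
        for e in cg.edges:
            g.add_edge(e.i, e.j, strength=e.strength, colored=bool(e.colored))
        nx.write_graphml(g, path)
    elif format == "json":
        doc = {
            "window_interval": list(cg.window_interval),
            "hyperparams": {"eps": cg.eps, "sigma": cg.sigma,
                            "beta": cg.beta, "k": cg.k},
            "edges": [{"src": e.i, "dst": e.j, "strength": e.strength,
                       "colored": bool(e.colored)} for e in cg.edges],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_edge_list_tsv(path) -> list[Edge]:
    edges = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or line.startswith("src"):
            continue
        i, j, s, c = line.split("\t")
        edges.append(Edge(int(i), int(j), float(s), bool(int(c))))
    return edges
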