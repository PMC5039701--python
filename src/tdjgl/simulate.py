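"""Synthetic cross-platform scenarios with known networks and differential edges.

A scenario is built in five steps, mirroring the usual joint-graphical-lasso
benchmark designs:

1. draw a gene network on p nodes (Erdos-Renyi with edge probability 0.02,
   Barabasi-Albert scale-free growth with ``mlinks`` edges per new node, or a
   two-community layout where edges outside the top/bottom 60% blocks are
   removed), and pick a fraction ``tau`` of its edges, uniformly at random, as
   differential edges;
2. for each of the K platforms, independently:
3. fill a symmetric weight matrix A^{k1} with Unif([-1,-0.5] U [0.5,1]) on the
   edges; copy it to A^{k2} and, for every differential edge, either zero the
   entry or flip its sign (a fair coin per edge);
4. shift both to positive definiteness: with d = min of the two smallest
   eigenvalues, ``Theta^{kc} = A^{kc} + (0.1 + |d|) I`` (minimum eigenvalue at
   least 0.1 by construction);
5. draw n independent observations per group from ``N(0, (Theta^{kc})^{-1})``.

The network, the differential edge set and hence the supports are shared by
all K platforms; edge values vary by platform.  Everything is driven by the
single ``seed`` in the config.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.linalg import solve_triangular

from .model_core import MultiPlatformData

__all__ = [
    "ScenarioConfig",
    "SimulationTruth",
    "generate_network",
    "assign_differential_edges",
    "build_precision_pair",
    "sample_scenario",
]

NETWORK_TYPES = ("erdos_renyi", "scale_free", "community")


@dataclass
class ScenarioConfig:
    network_type: str = "erdos_renyi"
    p: int = 100
    n: int = 100  # samples per group
    K: int = 3
    tau: float = 0.10
    edge_prob: float = 0.02
    mlinks: int = 2
    # community layout: two blocks covering the top/bottom community_frac of
    # genes; with p=100 and frac 0.6 the blocks are 60x60 sharing genes 41-60
    community_frac: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.network_type not in NETWORK_TYPES:
            raise ValueError(f"network_type must be one of {NETWORK_TYPES}")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must be in [0, 1]")


@dataclass
class SimulationTruth:
    adjacency: np.ndarray  # shared 0/1 symmetric, zero diagonal
    diff_edges: set  # unordered pairs (i, j), i < j
    Theta_true: list  # K x 2 PD matrices
    A_matrices: list  # K x 2 pre-shift weight matrices

    @property
    def K(self) -> int:
        return len(self.Theta_true)

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    def support(self, k: int, c: int) -> np.ndarray:
        """True off-diagonal support of dataset (k, c)."""
        sup = self.Theta_true[k][c] != 0.0
        np.fill_diagonal(sup, False)
        return sup


def generate_network(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Symmetric 0/1 adjacency with zero diagonal for the configured topology."""
    p = cfg.p
    if cfg.network_type == "scale_free":
        # Barabasi-Albert preferential attachment stands in for Matlab's SFNG
        g = nx.barabasi_albert_graph(p, cfg.mlinks, seed=int(rng.integers(2**31)))
        adj = nx.to_numpy_array(g, nodelist=range(p)) > 0
        adj = adj.astype(float)
    else:
        iu = np.triu_indices(p, 1)
        upper = rng.random(len(iu[0])) < cfg.edge_prob
        adj = np.zeros((p, p))
        adj[iu] = upper
        adj += adj.T
        if cfg.network_type == "community":
            hi = int(np.ceil(cfg.community_frac * p))  # block end / block start
            lo = p - hi
            adj[:lo, hi:] = 0.0
            adj[hi:, :lo] = 0.0
    return adj


def assign_differential_edges(
    adjacency: np.ndarray, tau: float, rng: np.random.Generator
) -> set:
    """Uniformly sample round(tau * |edges|) edges (half-up rounding)."""
    iu = np.triu_indices(adjacency.shape[0], 1)
    edges = [(int(i), int(j)) for i, j in zip(*iu) if adjacency[i, j] != 0]
    if not edges:
        raise ValueError("graph has no edges")
    m = int(np.floor(tau * len(edges) + 0.5))
    chosen = rng.choice(len(edges), size=m, replace=False)
    return {edges[i] for i in chosen}


def build_precision_pair(
    adjacency: np.ndarray,
    diff_edges: set,
    rng: np.random.Generator,
    diff_actions: dict | None = None,
) -> tuple:
    """One platform's (Theta1, Theta2, A1, A2).

    Group 1 is the reference: differential edges perturb A2 only, each zeroed
    or sign-flipped with probability 1/2.  ``diff_actions`` maps an edge to
    'zero' or 'flip'; sharing one map across platforms keeps the group-2
    support identical on every platform (drawn fresh when omitted)."""
    p = adjacency.shape[0]
    iu = np.triu_indices(p, 1)
    A1 = np.zeros((p, p))
    for i, j in zip(*iu):
        if adjacency[i, j] != 0:
            val = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            A1[i, j] = A1[j, i] = val
    A2 = A1.copy()
    if diff_actions is None:
        diff_actions = draw_differential_actions(diff_edges, rng)
    for i, j in sorted(diff_edges):
        factor = 0.0 if diff_actions[(i, j)] == "zero" else -1.0
        A2[i, j] = A2[j, i] = factor * A1[i, j]
    d = min(
        float(np.linalg.eigvalsh(A1)[0]), float(np.linalg.eigvalsh(A2)[0])
    )
    shift = (0.1 + abs(d)) * np.eye(p)
    return A1 + shift, A2 + shift, A1, A2


def draw_differential_actions(
    diff_edges: set, rng: np.random.Generator
) -> dict:
    """Fair coin per differential edge: remove it ('zero') or flip its sign."""
    return {
        e: ("zero" if rng.random() < 0.5 else "flip") for e in sorted(diff_edges)
    }


def _sample_gaussian(
    Theta: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n draws from N(0, Theta^{-1}) via the Cholesky factor of Theta."""
    L = np.linalg.cholesky(Theta)
    z = rng.standard_normal((n, Theta.shape[0]))
    # x = L^{-T} z  so that Cov(x) = (L L^T)^{-1} = Theta^{-1}
    return solve_triangular(L.T, z.T, lower=False).T


def sample_scenario(cfg: ScenarioConfig) -> tuple:
    """Generate a full scenario: (MultiPlatformData, SimulationTruth)."""
    rng = np.random.default_rng(cfg.seed)
    adjacency = generate_network(cfg, rng)
    diff_edges = assign_differential_edges(adjacency, cfg.tau, rng)
    # one zero-vs-flip decision per edge, shared by all platforms, so the
    # supports (and differential structure) are preserved across platforms
    actions = draw_differential_actions(diff_edges, rng)
    Theta_true, A_matrices, X = [], [], []
    for _ in range(cfg.K):
        T1, T2, A1, A2 = build_precision_pair(
            adjacency, diff_edges, rng, diff_actions=actions
        )
        Theta_true.append([T1, T2])
        A_matrices.append([A1, A2])
        X.append([_sample_gaussian(T1, cfg.n, rng), _sample_gaussian(T2, cfg.n, rng)])
    genes = [f"g{i + 1}" for i in range(cfg.p)]
    data = MultiPlatformData(X=X, genes=genes)
    truth = SimulationTruth(
        adjacency=adjacency,
        diff_edges=diff_edges,
        Theta_true=Theta_true,
        A_matrices=A_matrices,
    )
    return data, truth
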