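"""Differential networks, hub genes and enrichment from fitted precision matrices.

For platform k and group c, the partial correlation between genes i and j is
``rho_ij = -theta_ij / sqrt(theta_ii * theta_jj)``.  The platform-k
differential score is ``d^k_ij = rho^{k1}_ij - rho^{k2}_ij``; an edge belongs
to the k-th differential network iff d^k_ij != 0, with strength |d| and sign
sign(d) (positive: the dependency is stronger in group 1).  Edges present in
all K differential networks are the cross-platform consensus.

Sparsity is taken from the ADMM consensus copies Z: off-diagonal entries whose
Z is exactly zero are treated as theta = 0 before computing partial
correlations, so "edge iff theta-hat != 0" is exact.

Hub genes are genes whose differential degree exceeds a threshold on every
platform; enrichment of the hub set in an annotated gene set is assessed with
a Fisher exact test (one-sided hypergeometric upper tail by default, since
the question is enrichment; a two-sided variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import TDJGLFit
from .model_core import PrecisionSet

__all__ = [
    "DifferentialNetwork",
    "EnrichmentResult",
    "partial_correlations",
    "differential_scores",
    "consensus_and_hubs",
    "hub_degree_table",
    "hub_enrichment",
]

SCORE_TOL = 1e-10


@dataclass
class DifferentialNetwork:
    """Per-platform differential scores and the edge sets derived from them.

    Edges are unordered pairs (i, j) with i < j of gene indices."""

    scores: list  # K score matrices, symmetric, zero diagonal
    group_networks: list  # K x 2 sets of edges
    diff_edges: list  # K dicts {(i, j): (strength, sign)}
    consensus_edges: set
    degrees: np.ndarray  # (K, p) differential degrees
    genes: list
    platform_labels: list

    @property
    def K(self) -> int:
        return len(self.scores)

    @property
    def p(self) -> int:
        return self.scores[0].shape[0]


@dataclass
class EnrichmentResult:
    universe_size: int
    annotated_in_universe: int
    hub_count: int
    annotated_hubs: int
    p_value: float
    alternative: str = "greater"


def partial_correlations(Theta: np.ndarray) -> np.ndarray:
    """``rho_ij = -theta_ij / sqrt(theta_ii theta_jj)``, zero diagonal."""
    Theta = np.asarray(Theta, dtype=float)
    d = np.diag(Theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix has a nonpositive diagonal entry")
    scale = np.sqrt(np.outer(d, d))
    rho = -Theta / scale
    np.fill_diagonal(rho, 0.0)
    return rho


def _masked_theta(precisions: PrecisionSet, k: int, c: int) -> np.ndarray:
    """Theta with off-diagonal entries zeroed wherever the sparse copy Z is zero."""
    T = precisions.Theta[k][c].copy()
    if precisions.Z is not None:
        mask = precisions.Z[k][c] == 0.0
        np.fill_diagonal(mask, False)
        T[mask] = 0.0
    return T


def differential_scores(
    fit: TDJGLFit | PrecisionSet,
    genes: list | None = None,
    platform_labels: list | None = None,
    tol: float = SCORE_TOL,
) -> DifferentialNetwork:
    """Build the K differential networks from a fit (or a bare PrecisionSet)."""
    precisions = fit.precisions if isinstance(fit, TDJGLFit) else fit
    K, p = precisions.K, precisions.p
    if genes is None:
        genes = [f"g{i + 1}" for i in range(p)]
    if platform_labels is None:
        platform_labels = [f"platform{k + 1}" for k in range(K)]

    scores = []
    group_networks = []
    diff_edges = []
    degrees = np.zeros((K, p), dtype=int)
    iu = np.triu_indices(p, 1)
    for k in range(K):
        rho = [partial_correlations(_masked_theta(precisions, k, c)) for c in range(2)]
        d = rho[0] - rho[1]
        np.fill_diagonal(d, 0.0)
        scores.append(d)
        nets = []
        for c in range(2):
            sup = np.abs(rho[c]) > tol
            nets.append({(i, j) for i, j in zip(*iu) if sup[i, j]})
        group_networks.append(nets)
        edges = {}
        for i, j in zip(*iu):
            if abs(d[i, j]) > tol:
                edges[(int(i), int(j))] = (abs(float(d[i, j])), int(np.sign(d[i, j])))
        diff_edges.append(edges)
        for i, j in edges:
            degrees[k, i] += 1
            degrees[k, j] += 1
    consensus = set(diff_edges[0]) if K else set()
    for k in range(1, K):
        consensus &= set(diff_edges[k])
    return DifferentialNetwork(
        scores=scores,
        group_networks=group_networks,
        diff_edges=diff_edges,
        consensus_edges=consensus,
        degrees=degrees,
        genes=list(genes),
        platform_labels=list(platform_labels),
    )


def consensus_and_hubs(
    net: DifferentialNetwork,
    min_degree: int = 2,
    require_all_platforms: bool = True,
) -> list:
    """Genes with differential degree strictly greater than ``min_degree``.

    With ``require_all_platforms`` the threshold must hold on every platform
    (the hub definition used for the cross-platform analysis); otherwise on at
    least one."""
    if min_degree < 0:
        raise ValueError("min_degree must be nonnegative")
    over = net.degrees > min_degree
    keep = over.all(axis=0) if require_all_platforms else over.any(axis=0)
    return [net.genes[i] for i in np.flatnonzero(keep)]


def hub_degree_table(net: DifferentialNetwork, hubs: list | None = None) -> pd.DataFrame:
    """Per-platform differential degrees, with an ``a|b|c``-style summary column."""
    if hubs is None:
        hubs = net.genes
    idx = [net.genes.index(g) for g in hubs]
    df = pd.DataFrame(
        net.degrees[:, idx].T, index=hubs, columns=net.platform_labels
    )
    df["degrees"] = ["|".join(str(v) for v in row) for row in df.to_numpy()]
    return df.sort_values(list(net.platform_labels), ascending=False)


def hub_enrichment(
    hubs, annotated, universe, alternative: str = "greater"
) -> EnrichmentResult:
    """Fisher exact test of hub genes against an annotated set.

    One-sided ('greater'): hypergeometric upper tail P(X >= overlap) drawing
    n = |hubs| from a universe of N genes of which K are annotated."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    hubs = set(hubs)
    if not hubs <= universe:
        raise ValueError("hub genes must be a subset of the universe")
    annotated = set(annotated) & universe
    N = len(universe)
    K = len(annotated)
    n = len(hubs)
    x = len(hubs & annotated)
    if alternative == "greater":
        p_value = float(stats.hypergeom.sf(x - 1, N, K, n))
    elif alternative == "two-sided":
        table = [[x, n - x], [K - x, N - K - (n - x)]]
        p_value = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return EnrichmentResult(
        universe_size=N,
        annotated_in_universe=K,
        hub_count=n,
        annotated_hubs=x,
        p_value=p_value,
        alternative=alternative,
    )
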