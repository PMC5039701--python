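"""Data model and objective for the two-dimensional joint graphical lasso (TDJGL).

TDJGL estimates 2K sparse Gaussian precision matrices at once: expression of the
same ``p`` genes is measured for two patient groups (``c = 1, 2``) on ``K``
platforms, giving 2K data sets ``X^{kc}`` (``n_c`` samples by ``p`` genes).
Each data set is modelled as i.i.d. draws from ``N(0, (Theta^{kc})^{-1})``, and
measurements of the same patients on different platforms are treated as
independent in the likelihood.

The fitted objective is a penalized negative log-likelihood::

    sum_{k,c} w_c ( -log det Theta^{kc} + tr(S^{kc} Theta^{kc}) )  +  P({Theta})

with a two-part group bridge penalty ``P``::

    P = lambda1 * sum_{i != j} sqrt( sum_{k,c} |theta_ij^{kc}| )
      + lambda2 * sum_{i != j} sqrt( sum_k  |theta_ij^{k1} - theta_ij^{k2}| )

The first term couples each (i, j) entry across all 2K matrices, encouraging a
shared sparsity pattern of the gene networks; the second couples the
between-group differences across platforms, encouraging a shared pattern of
differential edges.  Sums run over ordered off-diagonal pairs (each unordered
edge counted twice, the usual ``||Theta||_1`` convention).  The diagonal is
excluded from the lasso-type first term unless explicitly requested (shrinking
variances is never desired) but kept in the fusion-type second term, the
fused-graphical-lasso convention: under strong fusion the two group estimates
then coincide entirely and the differential network is exactly empty.

Likelihood weights ``w_c`` are the group sample sizes ``n_c`` by default;
``equal_group_weights`` sets them to 1 so that a small group is not penalized
into a much sparser network than a large one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiPlatformData",
    "SampleCovarianceSet",
    "PrecisionSet",
    "ObjectiveConfig",
    "compute_sample_covariances",
    "negative_log_likelihood",
    "penalty",
    "objective",
]


@dataclass
class MultiPlatformData:
    """2K expression matrices: ``X[k][c]`` is group ``c`` measured on platform ``k``.

    All matrices share the same genes in the same column order; within a group
    the K platform matrices have identical row counts (same patients).
    """

    X: list  # K x 2 nested list of (n_c, p) float arrays
    genes: list
    group_labels: tuple = ("group1", "group2")
    platform_labels: list | None = None

    def __post_init__(self):
        self.X = [[np.asarray(Xkc, dtype=float) for Xkc in row] for row in self.X]
        if self.platform_labels is None:
            self.platform_labels = [f"platform{k + 1}" for k in range(self.K)]
        self.validate()

    @property
    def K(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.X[0][0].shape[1]

    @property
    def n(self) -> tuple:
        return tuple(self.X[0][c].shape[0] for c in range(2))

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("need at least one platform")
        p = self.p
        if len(self.genes) != p:
            raise ValueError(
                f"gene list length {len(self.genes)} does not match p={p}"
            )
        for k in range(self.K):
            if len(self.X[k]) != 2:
                raise ValueError("each platform needs exactly 2 group matrices")
            for c in range(2):
                if self.X[k][c].shape[1] != p:
                    raise ValueError(
                        f"platform {k} group {c}: gene count "
                        f"{self.X[k][c].shape[1]} != {p} (mismatched gene sets)"
                    )
                if self.X[k][c].shape[0] != self.X[0][c].shape[0]:
                    raise ValueError(
                        f"platform {k} group {c}: sample count differs from "
                        "platform 0 (platforms must share patients per group)"
                    )
                if not np.all(np.isfinite(self.X[k][c])):
                    raise ValueError(
                        f"platform {k} group {c}: non-finite values in data"
                    )


@dataclass
class SampleCovarianceSet:
    """Per-dataset sample covariances ``S[k][c] = (1/n_c) X^T X`` and weights."""

    S: list  # K x 2 nested list of (p, p) arrays
    n: tuple
    weights: tuple

    @property
    def K(self) -> int:
        return len(self.S)

    @property
    def p(self) -> int:
        return self.S[0][0].shape[0]


@dataclass
class PrecisionSet:
    """The 2K precision estimates.

    ``Theta[k][c]`` are the positive-definite estimates from the log-det step;
    ``Z[k][c]`` are the exactly-sparse ADMM consensus copies from which edge
    supports are read (the log-det step never produces exact zeros).
    """

    Theta: list
    Z: list | None = None

    def __post_init__(self):
        self.Theta = [[np.asarray(T, dtype=float) for T in row] for row in self.Theta]
        if self.Z is not None:
            self.Z = [[np.asarray(Zm, dtype=float) for Zm in row] for row in self.Z]
        tol = 1e-8
        for row in self.Theta:
            for T in row:
                if not np.allclose(T, T.T, atol=tol):
                    raise ValueError("precision matrices must be symmetric")

    @property
    def K(self) -> int:
        return len(self.Theta)

    @property
    def p(self) -> int:
        return self.Theta[0][0].shape[0]

    def support(self, k: int, c: int, tol: float = 0.0):
        """Boolean off-diagonal support, read from Z (falls back to Theta)."""
        M = self.Theta[k][c] if self.Z is None else self.Z[k][c]
        sup = np.abs(M) > tol
        np.fill_diagonal(sup, False)
        return sup


@dataclass
class ObjectiveConfig:
    """Tuning parameters of the penalized likelihood."""

    lambda1: float = 0.0
    lambda2: float = 0.0
    equal_group_weights: bool = False
    penalize_diagonal: bool = False

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be nonnegative")


def compute_sample_covariances(
    data: MultiPlatformData,
    standardize: bool = False,
    equal_group_weights: bool = False,
) -> SampleCovarianceSet:
    """Center (and optionally standardize) each data set, form S = (1/n) X'X.

    Raises if a column has zero variance while ``standardize`` is on, naming
    the offending gene.
    """
    n = data.n
    if min(n) < 2:
        raise ValueError("need at least 2 samples per group")
    S = []
    for k in range(data.K):
        row = []
        for c in range(2):
            X = data.X[k][c] - data.X[k][c].mean(axis=0)
            if standardize:
                sd = X.std(axis=0)
                bad = np.flatnonzero(sd == 0)
                if bad.size:
                    raise ValueError(
                        f"zero-variance gene '{data.genes[bad[0]]}' in "
                        f"platform {data.platform_labels[k]}, "
                        f"group {data.group_labels[c]}"
                    )
                X = X / sd
            row.append(X.T @ X / n[c])
        S.append(row)
    weights = (1.0, 1.0) if equal_group_weights else (float(n[0]), float(n[1]))
    return SampleCovarianceSet(S=S, n=n, weights=weights)


def _logdet_pd(T: np.ndarray) -> float:
    """log det of a symmetric positive-definite matrix via Cholesky."""
    try:
        L = np.linalg.cholesky(T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is not positive definite") from exc
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def negative_log_likelihood(theta: PrecisionSet, cov: SampleCovarianceSet) -> float:
    """``sum_{k,c} w_c ( -log det Theta^{kc} + tr(S^{kc} Theta^{kc}) )``."""
    total = 0.0
    for k in range(cov.K):
        for c in range(2):
            T = theta.Theta[k][c]
            total += cov.weights[c] * (
                -_logdet_pd(T) + float(np.sum(cov.S[k][c] * T))
            )
    return total


def penalty(theta: PrecisionSet, cfg: ObjectiveConfig) -> float:
    """Group bridge penalty of the TDJGL objective, evaluated at Theta.

    Both terms sum over ordered off-diagonal pairs (i, j), i != j; the
    first (lasso-type) term includes the diagonal only when
    ``cfg.penalize_diagonal`` is set, the second (fusion-type) term always
    includes it.
    """
    K, p = theta.K, theta.p
    stack = np.stack([theta.Theta[k][c] for k in range(K) for c in range(2)])
    abs_sum = np.abs(stack).sum(axis=0)
    diff_sum = np.zeros((p, p))
    for k in range(K):
        diff_sum += np.abs(theta.Theta[k][0] - theta.Theta[k][1])
    mask1 = np.ones((p, p), dtype=bool)
    if not cfg.penalize_diagonal:
        np.fill_diagonal(mask1, False)
    # the fusion term always keeps the diagonal: equalizing the two groups'
    # variances is the fused-graphical-lasso convention and makes the
    # strong-fusion limit (identical group estimates, hence an exactly empty
    # differential network) hold exactly
    return float(
        cfg.lambda1 * np.sqrt(abs_sum[mask1]).sum()
        + cfg.lambda2 * np.sqrt(diff_sum).sum()
    )


def objective(
    theta: PrecisionSet, cov: SampleCovarianceSet, cfg: ObjectiveConfig
) -> float:
    """Full penalized negative log-likelihood."""
    return negative_log_likelihood(theta, cov) + penalty(theta, cfg)
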