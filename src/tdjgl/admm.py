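"""ADMM engine for the weighted fused graphical lasso subproblem.

Each outer iteration of the TDJGL algorithm reduces, per platform, to

    min_{Theta1, Theta2 PD}  sum_c w_c ( -log det Theta_c + tr(S_c Theta_c) )
        + lambda1 * sum_{i != j} omega_ij (|theta1_ij| + |theta2_ij|)
        + lambda2 * sum_{i != j} psi_ij |theta1_ij - theta2_ij|

a two-matrix graphical lasso with elementwise weighted lasso and weighted
fusion penalties.  It is solved here by consensus ADMM with a split
``Theta_c = Z_c``:

* Theta-update: exact minimizer of the log-det quadratic, via one
  eigendecomposition per group;
* Z-update: the closed-form proximal operator of the weighted fused pair
  penalty, applied elementwise;
* scaled dual update, with standard combined absolute/relative stopping
  criteria and optional adaptive rho rescaling.

Edge supports must be read from Z: the Theta-update output is dense by
construction, while the proximal step produces exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WFGLProblem",
    "ADMMSettings",
    "ADMMResult",
    "theta_update",
    "prox_weighted_fused_pair",
    "solve_wfgl",
]


@dataclass
class WFGLProblem:
    """One platform's pair of covariances plus penalty weights.

    Omega and Psi are symmetric nonnegative weight matrices carrying the
    local-linear-approximation weights (constants 1/2 or 1 reproduce the plain
    fused graphical lasso / graphical lasso).  Omega has a zero diagonal
    (variances are not lasso-penalized); Psi may carry diagonal fusion
    weights."""

    S1: np.ndarray
    S2: np.ndarray
    w1: float
    w2: float
    Omega: np.ndarray
    Psi: np.ndarray
    lambda1: float
    lambda2: float

    def __post_init__(self):
        for name in ("S1", "S2", "Omega", "Psi"):
            M = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(M)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, M)
        for name in ("Omega", "Psi"):
            M = getattr(self, name)
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if M.min() < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def p(self) -> int:
        return self.S1.shape[0]


@dataclass
class ADMMSettings:
    # tolerances are tight by default: the outer loop's descent guarantee
    # only holds insofar as each subproblem is solved accurately
    rho: float = 2.0
    max_iter: int = 2000
    tol_abs: float = 1e-9
    tol_rel: float = 1e-7
    adaptive_rho: bool = True
    rho_factor: float = 2.0
    residual_ratio: float = 10.0

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.tol_abs <= 0 or self.tol_rel <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ADMMResult:
    Theta1: np.ndarray
    Theta2: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray
    iterations: int
    primal_residual: float
    dual_residual: float
    converged: bool
    # carried so outer LLA iterations can warm-start the solver
    U1: np.ndarray | None = None
    U2: np.ndarray | None = None
    rho: float | None = None


def _check_symmetric(M: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=tol):
        raise ValueError(f"{name} is not symmetric (tolerance {tol})")
    return 0.5 * (M + M.T)


def theta_update(A: np.ndarray, S: np.ndarray, w: float, rho: float) -> np.ndarray:
    """Exact minimizer of ``w(-logdet T + tr(S T)) + (rho/2)||T - A||_F^2``.

    Eigendecompose ``rho*A - w*S = V diag(d) V'`` and map each eigenvalue
    through ``(d + sqrt(d^2 + 4*rho*w)) / (2*rho)``, which is strictly
    positive, so the result is always positive definite.
    """
    A = _check_symmetric(A, "A")
    S = _check_symmetric(S, "S")
    d, V = np.linalg.eigh(rho * A - w * S)
    d_new = (d + np.sqrt(d * d + 4.0 * rho * w)) / (2.0 * rho)
    return (V * d_new) @ V.T


def prox_weighted_fused_pair(a1, a2, l1, l2):
    """Prox of ``l1(|z1|+|z2|) + l2|z1 - z2|`` at (a1, a2); elementwise on arrays.

    Fuse first: if ``|a1 - a2| <= 2*l2`` both coordinates collapse to the
    midpoint, otherwise each moves ``l2`` toward the other; then
    soft-threshold both by ``l1``.  Exact for the two-group case.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    gap = a1 - a2
    fuse = np.abs(gap) <= 2.0 * np.asarray(l2)
    mid = 0.5 * (a1 + a2)
    sgn = np.sign(gap)
    y1 = np.where(fuse, mid, a1 - l2 * sgn)
    y2 = np.where(fuse, mid, a2 + l2 * sgn)
    z1 = np.sign(y1) * np.maximum(np.abs(y1) - l1, 0.0)
    z2 = np.sign(y2) * np.maximum(np.abs(y2) - l1, 0.0)
    if z1.ndim == 0:
        return float(z1), float(z2)
    return z1, z2


def wfgl_objective(problem: WFGLProblem, T1: np.ndarray, T2: np.ndarray) -> float:
    """Subproblem objective; used for oracle checks and descent assertions."""
    val = 0.0
    for S, w, T in ((problem.S1, problem.w1, T1), (problem.S2, problem.w2, T2)):
        sign, logdet = np.linalg.slogdet(T)
        if sign <= 0:
            return np.inf
        val += w * (-logdet + float(np.sum(S * T)))
    # the weight matrices encode the diagonal convention (Omega zero there)
    val += problem.lambda1 * float((problem.Omega * (np.abs(T1) + np.abs(T2))).sum())
    val += problem.lambda2 * float((problem.Psi * np.abs(T1 - T2)).sum())
    return val


def solve_wfgl(
    problem: WFGLProblem,
    settings: ADMMSettings | None = None,
    init: ADMMResult | tuple | None = None,
) -> ADMMResult:
    """Run consensus ADMM on the two-matrix weighted fused problem.

    ``init`` may be a previous ADMMResult (full warm start, including scaled
    duals) or a pair of symmetric matrices used to seed Theta and Z.
    """
    if settings is None:
        settings = ADMMSettings()
    p = problem.p
    if p < 2:
        raise ValueError("p must be at least 2")
    rho = settings.rho

    if init is None:
        Z1 = np.eye(p)
        Z2 = np.eye(p)
        U1 = np.zeros((p, p))
        U2 = np.zeros((p, p))
    elif isinstance(init, ADMMResult):
        Z1, Z2 = init.Z1.copy(), init.Z2.copy()
        U1 = init.U1.copy() if init.U1 is not None else np.zeros((p, p))
        U2 = init.U2.copy() if init.U2 is not None else np.zeros((p, p))
        if init.rho is not None:
            rho = init.rho
    else:
        T1, T2 = init
        Z1 = _check_symmetric(T1, "init[0]").copy()
        Z2 = _check_symmetric(T2, "init[1]").copy()
        U1 = np.zeros((p, p))
        U2 = np.zeros((p, p))

    sqrt_dim = np.sqrt(2.0 * p * p)
    converged = False
    r_norm = s_norm = np.nan
    Theta1 = Z1
    Theta2 = Z2
    it = 0
    for it in range(1, settings.max_iter + 1):
        Theta1 = theta_update(Z1 - U1, problem.S1, problem.w1, rho)
        Theta2 = theta_update(Z2 - U2, problem.S2, problem.w2, rho)

        A1 = Theta1 + U1
        A2 = Theta2 + U2
        A1 = 0.5 * (A1 + A1.T)
        A2 = 0.5 * (A2 + A2.T)
        Z1_old, Z2_old = Z1, Z2
        L1 = problem.lambda1 * problem.Omega / rho
        L2 = problem.lambda2 * problem.Psi / rho
        # Omega has zero diagonal, so variances see l1=0 there; Psi may carry
        # diagonal fusion weights (prox with l1=l2=0 reduces to a copy)
        Z1, Z2 = prox_weighted_fused_pair(A1, A2, L1, L2)

        U1 = U1 + Theta1 - Z1
        U2 = U2 + Theta2 - Z2

        r_norm = np.sqrt(
            np.linalg.norm(Theta1 - Z1) ** 2 + np.linalg.norm(Theta2 - Z2) ** 2
        )
        s_norm = rho * np.sqrt(
            np.linalg.norm(Z1 - Z1_old) ** 2 + np.linalg.norm(Z2 - Z2_old) ** 2
        )
        if not (np.isfinite(r_norm) and np.isfinite(s_norm)):
            raise FloatingPointError(
                "ADMM diverged (non-finite residuals); try a smaller rho"
            )
        theta_norm = np.sqrt(
            np.linalg.norm(Theta1) ** 2 + np.linalg.norm(Theta2) ** 2
        )
        z_norm = np.sqrt(np.linalg.norm(Z1) ** 2 + np.linalg.norm(Z2) ** 2)
        u_norm = np.sqrt(np.linalg.norm(U1) ** 2 + np.linalg.norm(U2) ** 2)
        eps_pri = sqrt_dim * settings.tol_abs + settings.tol_rel * max(
            theta_norm, z_norm
        )
        eps_dual = sqrt_dim * settings.tol_abs + settings.tol_rel * rho * u_norm
        if r_norm <= eps_pri and s_norm <= eps_dual:
            converged = True
            break

        if settings.adaptive_rho:
            if r_norm > settings.residual_ratio * s_norm:
                rho *= settings.rho_factor
                U1 = U1 / settings.rho_factor
                U2 = U2 / settings.rho_factor
            elif s_norm > settings.residual_ratio * r_norm:
                rho /= settings.rho_factor
                U1 = U1 * settings.rho_factor
                U2 = U2 * settings.rho_factor

    return ADMMResult(
        Theta1=Theta1,
        Theta2=Theta2,
        Z1=Z1,
        Z2=Z2,
        iterations=it,
        primal_residual=float(r_norm),
        dual_residual=float(s_norm),
        converged=converged,
        U1=U1,
        U2=U2,
        rho=rho,
    )
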