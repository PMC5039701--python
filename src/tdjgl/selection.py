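"""Stability-based selection of the penalty pair (lambda1, lambda2).

The StARS idea: refit the model on B row-subsamples of the data and measure,
for every possible edge, the fraction f of subsamples in which it is selected.
The instability of a grid point is the average of 2 f (1 - f) over all
off-diagonal pairs, platforms and groups — 0 when every subsample agrees,
maximal (0.5) when selection is a coin flip.  Sparse settings are stable by
default, so raw instability is monotonized from the sparse corner of the grid
(running maximum over all pairs with both penalties at least as large), and
the selected pair is the least-regularized one whose monotonized instability
stays below the threshold ``beta``: the densest model that is still stable.

Subsampling respects the shared-patient design: within a group, the same rows
are kept across all K platforms.  Subsample size follows the usual
``floor(10 sqrt(n))`` rule, capped at 0.8 n for small n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admm import ADMMSettings
from .estimator import LLASettings, fit_tdjgl
from .model_core import MultiPlatformData, ObjectiveConfig

logger = logging.getLogger("tdjgl")

__all__ = ["StabilityGrid", "StabilityReport", "default_grid", "stars_select"]


@dataclass
class StabilityGrid:
    lambda1_values: np.ndarray = field(default=None)
    lambda2_values: np.ndarray = field(default=None)
    n_subsamples: int = 20
    subsample_fraction: float | None = None  # None: floor(10*sqrt(n))/n capped at 0.8
    beta: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.lambda1_values is None:
            self.lambda1_values = _log_grid()
        if self.lambda2_values is None:
            self.lambda2_values = _log_grid()
        for name in ("lambda1_values", "lambda2_values"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v <= 0):
                raise ValueError(f"{name} must be positive")
            setattr(self, name, -np.sort(-v))  # descending: sparse first
        if self.subsample_fraction is not None and not (
            0 < self.subsample_fraction < 1
        ):
            raise ValueError("subsample_fraction must be in (0, 1)")


@dataclass
class StabilityReport:
    instability: pd.DataFrame  # index lambda1 (desc), columns lambda2 (desc)
    monotonized: pd.DataFrame
    selected: tuple
    edge_selection_frequencies: list  # K x 2 matrices at the selected pair


def _log_grid(top: float = 0.25, bottom: float = 0.025, size: int = 20) -> np.ndarray:
    return np.geomspace(top, bottom, size)


def default_grid(**kwargs) -> StabilityGrid:
    """20 penalty values equally spaced in log scale from 0.25 down to 0.025."""
    return StabilityGrid(
        lambda1_values=_log_grid(), lambda2_values=_log_grid(), **kwargs
    )


def subsample_size(n: int, fraction: float | None = None) -> int:
    if fraction is not None:
        return int(np.floor(fraction * n))
    return min(int(np.floor(10.0 * np.sqrt(n))), int(np.floor(0.8 * n)))


def stars_select(
    data: MultiPlatformData,
    grid: StabilityGrid | None = None,
    cfg_base: ObjectiveConfig | None = None,
    lla: LLASettings | None = None,
    admm: ADMMSettings | None = None,
    standardize: bool = False,
) -> StabilityReport:
    """Subsampled-instability selection over the (lambda1, lambda2) grid."""
    if grid is None:
        grid = default_grid()
    if cfg_base is None:
        cfg_base = ObjectiveConfig(equal_group_weights=True)
    n = data.n
    sizes = [subsample_size(nc, grid.subsample_fraction) for nc in n]
    if min(sizes) < 2:
        raise ValueError("subsample size below 2; more samples needed")
    rng = np.random.default_rng(grid.seed)
    subsamples = [
        [rng.choice(nc, size=b, replace=False) for nc, b in zip(n, sizes)]
        for _ in range(grid.n_subsamples)
    ]

    l1s, l2s = grid.lambda1_values, grid.lambda2_values
    p = data.p
    iu = np.triu_indices(p, 1)
    inst = np.zeros((len(l1s), len(l2s)))
    freqs = {}
    for b, rows in enumerate(subsamples):
        sub = MultiPlatformData(
            X=[
                [data.X[k][c][rows[c]] for c in range(2)]
                for k in range(data.K)
            ],
            genes=data.genes,
            group_labels=data.group_labels,
            platform_labels=data.platform_labels,
        )
        from .model_core import compute_sample_covariances

        cov = compute_sample_covariances(
            sub, standardize=standardize,
            equal_group_weights=cfg_base.equal_group_weights,
        )
        for i, l1 in enumerate(l1s):
            for j, l2 in enumerate(l2s):
                cfg = ObjectiveConfig(
                    lambda1=float(l1),
                    lambda2=float(l2),
                    equal_group_weights=cfg_base.equal_group_weights,
                    penalize_diagonal=cfg_base.penalize_diagonal,
                )
                fit = fit_tdjgl(cov=cov, cfg=cfg, lla=lla, admm=admm)
                key = (i, j)
                if key not in freqs:
                    freqs[key] = np.zeros((data.K, 2, len(iu[0])))
                for k in range(data.K):
                    for c in range(2):
                        freqs[key][k, c] += fit.precisions.support(k, c)[iu]
        logger.info("stars: subsample %d/%d done", b + 1, grid.n_subsamples)

    B = grid.n_subsamples
    for (i, j), counts in freqs.items():
        f = counts / B
        inst[i, j] = float((2.0 * f * (1.0 - f)).mean())

    inst_df = pd.DataFrame(inst, index=l1s, columns=l2s)
    # running max from the sparse corner: D_bar(l1, l2) accounts for every
    # grid point at least as sparse in both penalties
    mono = np.maximum.accumulate(np.maximum.accumulate(inst, axis=0), axis=1)
    mono_df = pd.DataFrame(mono, index=l1s, columns=l2s)

    admissible = np.argwhere(mono <= grid.beta)
    if admissible.size == 0:
        sel_i, sel_j = 0, 0  # nothing stable: fall back to the sparsest corner
        logger.warning("no grid point met the instability threshold; "
                       "selecting the sparsest corner")
    else:
        # least regularization that is still stable: smallest lambda1,
        # tie-broken by smallest lambda2 (grids are descending)
        order = np.lexsort((-admissible[:, 1], -admissible[:, 0]))
        sel_i, sel_j = admissible[order[0]]
    selected = (float(l1s[sel_i]), float(l2s[sel_j]))
    sel_freqs = freqs[(sel_i, sel_j)] / B
    freq_mats = []
    for k in range(data.K):
        row = []
        for c in range(2):
            M = np.zeros((p, p))
            M[iu] = sel_freqs[k, c]
            row.append(M + M.T)
        freq_mats.append(row)
    return StabilityReport(
        instability=inst_df,
        monotonized=mono_df,
        selected=selected,
        edge_selection_frequencies=freq_mats,
    )
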