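"""Support-recovery and estimation metrics, plus the method-comparison sweep.

Metrics are counted over unordered off-diagonal pairs:

* edge metrics, summed over all 2K data sets — positives (estimated nonzero,
  read from the exactly-sparse Z copies), true positives (also nonzero in the
  true precision matrix) and false positives;
* differential metrics, summed over the K platforms — a pair is an estimated
  differential edge when Z^{k1} and Z^{k2} differ, a true one when it belongs
  to the simulated differential edge set;
* squared estimation error ``sum_{k,c} ||Theta_hat - Theta_true||_F^2`` over
  all matrix entries.

``run_benchmark`` sweeps methods (tdjgl / fgl / gl) over penalty grids on
freshly simulated replicates and returns a tidy table; curve helpers compare
methods at a matched operating point (e.g. true positives at equal false
positives) by linear interpolation along each method's penalty path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admm import ADMMSettings
from .estimator import LLASettings, fit_baseline, fit_tdjgl
from .model_core import ObjectiveConfig, PrecisionSet
from .simulate import ScenarioConfig, SimulationTruth, sample_scenario

__all__ = [
    "MetricsReport",
    "edge_metrics",
    "differential_metrics",
    "estimation_error",
    "compute_metrics",
    "run_benchmark",
    "value_at_matched",
    "compare_at_matched",
    "mean_curves",
]

DIFF_TOL = 1e-10


@dataclass
class MetricsReport:
    positives: int
    tp_edges: int
    fp_edges: int
    tp_diff: int
    fp_diff: int
    sq_error: float


def _est_support(est: PrecisionSet, k: int, c: int) -> np.ndarray:
    Z = est.Z[k][c] if est.Z is not None else est.Theta[k][c]
    return Z != 0.0


def edge_metrics(est: PrecisionSet, truth: SimulationTruth) -> tuple:
    """(positives, tp, fp) over unordered pairs, summed over all 2K data sets."""
    if est.p != truth.p:
        raise ValueError("estimate and truth have different dimensions")
    iu = np.triu_indices(est.p, 1)
    positives = tp = fp = 0
    for k in range(truth.K):
        for c in range(2):
            e = _est_support(est, k, c)[iu]
            t = truth.support(k, c)[iu]
            positives += int(e.sum())
            tp += int((e & t).sum())
            fp += int((e & ~t).sum())
    return positives, tp, fp


def differential_metrics(est: PrecisionSet, truth: SimulationTruth) -> tuple:
    """(tp_diff, fp_diff) over unordered pairs, summed over the K platforms."""
    iu = np.triu_indices(est.p, 1)
    true_diff = np.zeros((est.p, est.p), dtype=bool)
    for i, j in truth.diff_edges:
        true_diff[i, j] = True
    true_diff = true_diff[iu]
    tp = fp = 0
    for k in range(truth.K):
        Z1 = est.Z[k][0] if est.Z is not None else est.Theta[k][0]
        Z2 = est.Z[k][1] if est.Z is not None else est.Theta[k][1]
        est_diff = (np.abs(Z1 - Z2) > DIFF_TOL)[iu]
        tp += int((est_diff & true_diff).sum())
        fp += int((est_diff & ~true_diff).sum())
    return tp, fp


def estimation_error(est: PrecisionSet, truth: SimulationTruth) -> float:
    """``sum_{k,c} ||Theta_hat^{kc} - Theta_true^{kc}||_F^2`` (all entries)."""
    err = 0.0
    for k in range(truth.K):
        for c in range(2):
            err += float(
                np.linalg.norm(est.Theta[k][c] - truth.Theta_true[k][c]) ** 2
            )
    return err


def compute_metrics(est: PrecisionSet, truth: SimulationTruth) -> MetricsReport:
    positives, tp, fp = edge_metrics(est, truth)
    tp_d, fp_d = differential_metrics(est, truth)
    return MetricsReport(
        positives=positives,
        tp_edges=tp,
        fp_edges=fp,
        tp_diff=tp_d,
        fp_diff=fp_d,
        sq_error=estimation_error(est, truth),
    )


def _fit_for(method, cov, lambda1, lambda2, lla, admm):
    cfg = ObjectiveConfig(
        lambda1=lambda1, lambda2=lambda2, equal_group_weights=True
    )
    if method == "tdjgl":
        return fit_tdjgl(cov=cov, cfg=cfg, lla=lla, admm=admm)
    return fit_baseline(method=method, cov=cov, cfg=cfg, admm=admm)


def run_benchmark(
    cfgs,
    methods: dict,
    replicates: int = 20,
    seed: int = 0,
    lla: LLASettings | None = None,
    admm: ADMMSettings | None = None,
) -> pd.DataFrame:
    """Sweep methods over penalty grids on simulated replicates.

    ``cfgs`` is a ScenarioConfig or list of them; ``methods`` maps a method
    name ('tdjgl', 'fgl', 'gl') to a list of (lambda1, lambda2) pairs.  Each
    replicate r of a scenario is generated with seed ``cfg.seed + r``.  Group
    weights are equal (w_c = 1) so that penalty grids are comparable across
    sample sizes.  Returns one tidy row per (scenario, replicate, method,
    lambda1, lambda2); failed cells are recorded as NaN rows with a warning.
    """
    if isinstance(cfgs, ScenarioConfig):
        cfgs = [cfgs]
    from .model_core import compute_sample_covariances

    rows = []
    for cfg in cfgs:
        for r in range(replicates):
            scen = ScenarioConfig(**{**cfg.__dict__, "seed": cfg.seed + seed + r})
            data, truth = sample_scenario(scen)
            cov = compute_sample_covariances(data, equal_group_weights=True)
            for method, grid in methods.items():
                for lambda1, lambda2 in grid:
                    base = dict(
                        network=cfg.network_type,
                        p=cfg.p,
                        n=cfg.n,
                        tau=cfg.tau,
                        replicate=r,
                        method=method,
                        lambda1=lambda1,
                        lambda2=lambda2,
                    )
                    try:
                        fit = _fit_for(method, cov, lambda1, lambda2, lla, admm)
                        m = compute_metrics(fit.precisions, truth)
                        rows.append({**base, **m.__dict__})
                    except Exception as exc:  # solver failure is not fatal
                        warnings.warn(
                            f"benchmark cell failed ({method}, l1={lambda1}, "
                            f"l2={lambda2}): {exc}",
                            RuntimeWarning,
                            stacklevel=2,
                        )
                        rows.append(
                            {
                                **base,
                                **{
                                    f: np.nan
                                    for f in MetricsReport.__annotations__
                                },
                            }
                        )
    return pd.DataFrame(rows)


def mean_curves(df: pd.DataFrame) -> pd.DataFrame:
    """Average metrics over replicates per (method, lambda1, lambda2)."""
    keys = ["method", "lambda1", "lambda2"]
    return df.groupby(keys, as_index=False)[
        ["positives", "tp_edges", "fp_edges", "tp_diff", "fp_diff", "sq_error"]
    ].mean()


def value_at_matched(
    curve: pd.DataFrame, x_col: str, y_col: str, x_target: float
) -> float:
    """Linearly interpolate a method's mean curve at a matched x value.

    The curve rows are one per penalty setting; they are sorted by ``x_col``
    (e.g. false positives) and ``y_col`` is interpolated at ``x_target``.
    Raises if the target is outside the curve's range (no extrapolation)."""
    pts = curve[[x_col, y_col]].dropna().sort_values(x_col)
    x = pts[x_col].to_numpy()
    y = pts[y_col].to_numpy()
    if len(x) < 2:
        raise ValueError("need at least two curve points to interpolate")
    if not (x[0] <= x_target <= x[-1]):
        raise ValueError(
            f"matched value {x_target} outside curve range [{x[0]}, {x[-1]}]"
        )
    return float(np.interp(x_target, x, y))


def compare_at_matched(
    curve_a: pd.DataFrame,
    curve_b: pd.DataFrame,
    x_col: str,
    y_col: str,
    x_target: float | None = None,
) -> tuple:
    """Interpolate two methods' mean curves at a common x value.

    When ``x_target`` is None the midpoint of the overlap of the two curves'
    x ranges is used.  Returns (y_a, y_b, x_target)."""
    lo = max(curve_a[x_col].min(), curve_b[x_col].min())
    hi = min(curve_a[x_col].max(), curve_b[x_col].max())
    if lo >= hi:
        raise ValueError(f"curves do not overlap in {x_col}: [{lo}, {hi}]")
    if x_target is None:
        x_target = 0.5 * (lo + hi)
    return (
        value_at_matched(curve_a, x_col, y_col, x_target),
        value_at_matched(curve_b, x_col, y_col, x_target),
        float(x_target),
    )


def plot_tp_fp_curves(df: pd.DataFrame, out_path: str) -> None:
    """Optional true-positive vs false-positive curves, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = mean_curves(df)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for method, sub in curves.groupby("method"):
        for lam2, path in sub.groupby("lambda2"):
            path = path.sort_values("fp_edges")
            axes[0].plot(
                path["fp_edges"], path["tp_edges"], marker="o",
                label=f"{method} (l2={lam2:g})",
            )
            path = path.sort_values("fp_diff")
            axes[1].plot(
                path["fp_diff"], path["tp_diff"], marker="o",
                label=f"{method} (l2={lam2:g})",
            )
    axes[0].set_xlabel("FP edges")
    axes[0].set_ylabel("TP edges")
    axes[1].set_xlabel("FP differential edges")
    axes[1].set_ylabel("TP differential edges")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
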