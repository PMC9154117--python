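"""Quantitative readouts: distance to target, per-run SSE, ensemble variance.

Conventions: the squared distance to the target (R^2) and the sum of
squared errors (SSE) are computed over committed *fractions* only — the
uncommitted pool is excluded, and counts are divided by S so values are
comparable across population sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import TargetDistribution
from .stochastic import Ensemble

__all__ = [
    "MetricValue",
    "r2_error",
    "sse",
    "ensemble_variance",
    "delay_log10",
    "tukey_summary",
]


@dataclass(frozen=True)
class MetricValue:
    """One named metric with its evaluation context."""

    name: str  # r2 | sse | variance | convergence_time | delay_log10
    value: float
    context: dict

    def __post_init__(self) -> None:
        if self.name in ("r2", "sse", "variance") and self.value < 0.0:
            raise ValueError(f"{self.name} must be >= 0")


def _target_values(target: "TargetDistribution | np.ndarray") -> np.ndarray:
    if isinstance(target, TargetDistribution):
        return target.values
    return np.asarray(target, dtype=float)


def r2_error(
    committed_fractions: np.ndarray, target: "TargetDistribution | np.ndarray"
) -> float:
    """Sum over patches of squared distance to the target fractions."""
    x = np.asarray(committed_fractions, dtype=float)
    ref = _target_values(target)
    if x.shape != ref.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {ref.shape}")
    d = x - ref
    return float(d @ d)


def allocation_r2(
    committed_fractions: np.ndarray, target: "TargetDistribution | np.ndarray"
) -> float:
    """Squared distance of the normalised committed allocation from the target.

    Divides out the small uncommitted residual: ``x/sum(x)`` is the share
    of the *committed* foragers on each patch, so a fixed point that is
    exactly quality-proportional scores exactly 0 here even though its
    committed total is slightly below one.
    """
    x = np.asarray(committed_fractions, dtype=float)
    total = x.sum()
    if total <= 0.0:
        raise ValueError("no committed foragers: allocation undefined")
    return r2_error(x / total, target)


def sse(
    ensemble: Ensemble,
    target: "TargetDistribution | np.ndarray",
    t_eval: float,
) -> np.ndarray:
    """Per-run squared error at ``t_eval`` (the full distribution).

    Definitionally the per-run :func:`r2_error` at a fixed late time;
    returned per run so the ensemble spread can be summarised or
    boxplotted.
    """
    if len(ensemble.runs) == 0:
        raise ValueError("empty ensemble")
    if t_eval > ensemble.t_end:
        raise ValueError("t_eval beyond the ensemble horizon")
    ref = _target_values(target)
    fr = ensemble.committed_fractions_at(t_eval)
    return np.asarray([r2_error(row, ref) for row in fr])


def ensemble_variance(ensemble: Ensemble, t_eval: float) -> np.ndarray:
    """Per-patch unbiased sample variance of committed fractions."""
    if len(ensemble.runs) < 2:
        raise ValueError("ensemble variance needs at least 2 runs")
    fr = ensemble.committed_fractions_at(t_eval)
    return fr.var(axis=0, ddof=1)


def delay_log10(t_slow: float, t_fast: float) -> float:
    """Convergence delay in orders of magnitude: log10(t_slow / t_fast)."""
    if t_slow <= 0.0 or t_fast <= 0.0:
        raise ValueError("both times must be > 0")
    return math.log10(t_slow / t_fast)


def tukey_summary(values: np.ndarray) -> dict:
    """Conventional Tukey boxplot statistics (1.5 IQR whiskers)."""
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside[0]) if inside.size else float(q1),
        "whisker_high": float(inside[-1]) if inside.size else float(q3),
        "outliers": v[(v < lo_fence) | (v > hi_fence)].tolist(),
        "n": int(v.size),
    }


def metric_frame(records: "list[MetricValue]") -> pd.DataFrame:
    """Tidy metric table: (metric, value, context columns)."""
    rows = [{"metric": m.name, "value": m.value, **m.context} for m in records]
    return pd.DataFrame(rows)
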