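"""Post-projection analytics: stage-by-time dynamics, heat summation,
agreement statistics between alternative stagings, and trait trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoothing import loess_smooth_gene
from .types import ExpressionTensor

__all__ = [
    "StageSeries",
    "stage_rate",
    "growing_degree_days",
    "lin_concordance",
    "concordance_class",
    "shift_statistics",
    "trait_stage_trend",
    "replicate_consistency_profile",
]


@dataclass
class StageSeries:
    """Ordered (time, stage) pairs for one cultivar x vintage series.

    Times may be day-of-year, days after flowering, or cumulative growing
    degree days; they must be strictly increasing.
    """

    times: np.ndarray
    stages: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.stages = np.asarray(self.stages, dtype=float)
        if self.times.shape != self.stages.shape:
            raise ValueError("times and stages must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def stage_rate(series: StageSeries) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference rate of stage progression, at interval midpoints.

    Approximates the derivative of the stage-over-time curve:
    rate = (stage[t+1] - stage[t]) / (time[t+1] - time[t]).
    """
    if series.times.size < 2:
        raise ValueError("need at least two points")
    dt = np.diff(series.times)
    rate = np.diff(series.stages) / dt
    mid = series.times[:-1] + dt / 2.0
    return mid, rate


def growing_degree_days(daily_mean_temps: np.ndarray, base: float = 10.0) -> np.ndarray:
    """Cumulative heat summation above a base temperature (default 10 C)."""
    temps = np.asarray(daily_mean_temps, dtype=float)
    if not np.all(np.isfinite(temps)):
        raise ValueError("temperatures must be finite")
    return np.cumsum(np.maximum(temps - base, 0.0))


def lin_concordance(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments).

    rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2);
    1 means perfect agreement, -1 perfect reversal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise ValueError("both inputs are constant")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def concordance_class(rho_c: float) -> str:
    """McBride's interpretation bins for Lin's coefficient."""
    if not -1.0 <= rho_c <= 1.0:
        raise ValueError("rho_c must be in [-1, 1]")
    if rho_c < 0.90:
        return "poor"
    if rho_c < 0.95:
        return "moderate"
    if rho_c <= 0.99:
        return "substantial"
    return "almost perfect"


def shift_statistics(stages_a: np.ndarray, stages_b: np.ndarray) -> dict:
    """Paired shift summary between two stagings of the same samples.

    shift_s = stage_a[s] - stage_b[s]; reports the mean absolute shift and
    the median/IQR of the signed shifts (linear-interpolation quantiles).
    """
    a = np.asarray(stages_a, dtype=float)
    b = np.asarray(stages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("stage sequences must have equal length")
    shifts = a - b
    q1, med, q3 = np.quantile(shifts, [0.25, 0.5, 0.75])
    return {
        "mean_abs_shift": float(np.mean(np.abs(shifts))),
        "median_shift": float(med),
        "iqr": float(q3 - q1),
        "shifts": shifts,
    }


def trait_stage_trend(
    stages: np.ndarray, trait: np.ndarray, degree: int = 2, span: float = 0.75
) -> tuple[np.ndarray, np.ndarray]:
    """LOESS trend of a trait (e.g. % reducing sugars) over assigned stages."""
    stages = np.asarray(stages, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if stages.size < 5:
        raise ValueError("need at least 5 (stage, trait) pairs")
    return loess_smooth_gene(stages, trait, degree=degree, span=span)


def replicate_consistency_profile(
    tensor: ExpressionTensor, core_genes: list[str], stages: np.ndarray
) -> pd.DataFrame:
    """Per-condition mean replicate CV over the core genes, joined to stages.

    Conditions where a gene's replicate mean is zero are excluded from that
    gene's average.
    """
    gidx = tensor.gene_index(core_genes)
    vals = tensor.values[:, :, gidx]
    m = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    cvs = np.where(m > 0, sd / np.where(m > 0, m, 1.0), np.nan)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean_cv = np.nanmean(cvs, axis=1)
    return pd.DataFrame(
        {
            "condition_id": tensor.condition_ids(),
            "stage": np.asarray(stages, dtype=int),
            "mean_cv": mean_cv,
        }
    )
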