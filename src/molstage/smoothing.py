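"""LOESS smoothing of expression time series and replicate summaries.

Each cultivar x vintage series is smoothed independently, gene by gene:
a local polynomial of degree 2 is fitted by tricube-weighted least squares
over the ceil(span * n) points nearest to each target timepoint (replicates
count as separate points sharing a predictor value), and evaluated at the
target.  Because LOESS is linear in the response, the smoother is built
once per series as a hat matrix and applied to all genes at once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionTensor

__all__ = [
    "replicate_mean",
    "series_mean",
    "replicate_cv",
    "loess_hat_matrix",
    "loess_smooth_gene",
    "smooth_dataset",
]


def replicate_mean(tensor: ExpressionTensor, gene: int, condition: int) -> float:
    """Average expression m_ji over replicates of one gene in one condition."""
    return float(tensor.values[condition, :, gene].mean())


def series_mean(tensor: ExpressionTensor, gene: int, series_key: tuple[str, str]) -> float:
    """Average expression m_hi over replicates and timepoints of one series."""
    idx = tensor.series().get(tuple(series_key))
    if idx is None or len(idx) == 0:
        raise ValueError(f"empty series {series_key}")
    return float(tensor.values[idx, :, gene].mean())


def replicate_cv(tensor: ExpressionTensor, gene: int, condition: int) -> float:
    """Replicate coefficient of variation (sample sd / mean); NaN if mean is 0."""
    reps = tensor.values[condition, :, gene]
    m = reps.mean()
    if m <= 0:
        return float("nan")
    return float(reps.std(ddof=1) / m)


def _hat_row(times: np.ndarray, t0: float, degree: int, span: float) -> np.ndarray:
    """Equivalent-kernel weights for the LOESS fit evaluated at t0."""
    n = times.size
    d = np.abs(times - t0)
    q = int(np.ceil(span * n))
    q = min(max(q, degree + 1), n)
    dq = np.partition(d, q - 1)[q - 1]
    window = d <= dq  # ties at the window edge are all included
    dw = d[window]
    dmax = dw.max()
    if dmax > 0:
        w = (1.0 - (dw / dmax) ** 3) ** 3
        w[dw >= dmax] = 0.0
    else:
        w = np.ones_like(dw)
    # keep enough support for the local polynomial
    if np.count_nonzero(w) < degree + 1 or np.unique(times[window][w > 0]).size < degree + 1:
        w = np.ones_like(dw)
    tw = times[window] - t0
    basis = np.vander(tw, degree + 1, increasing=True)
    wb = basis * w[:, None]
    coef_map = np.linalg.solve(basis.T @ wb, wb.T)  # (degree+1) x n_window
    row = np.zeros(n)
    row[window] = coef_map[0]
    return row


def loess_hat_matrix(
    times: np.ndarray, targets: np.ndarray, degree: int = 2, span: float = 0.75
) -> np.ndarray:
    """Linear-smoother matrix H so that H @ y gives fitted values at ``targets``."""
    times = np.asarray(times, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if np.unique(times).size < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} distinct predictor values, "
            f"got {np.unique(times).size}"
        )
    return np.vstack([_hat_row(times, t0, degree, span) for t0 in targets])


def loess_smooth_gene(
    times: np.ndarray, values: np.ndarray, degree: int = 2, span: float = 0.75
) -> tuple[np.ndarray, np.ndarray]:
    """LOESS-smooth one gene's series; returns (distinct timepoints, fitted values).

    Replicates enter as separate points sharing a predictor value; the fit
    is evaluated at each distinct timepoint.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have the same length")
    targets = np.unique(times)
    hat = loess_hat_matrix(times, targets, degree=degree, span=span)
    return targets, hat @ values


def smooth_dataset(
    tensor: ExpressionTensor,
    core_genes: list[str],
    degree: int = 2,
    span: float = 0.75,
    predictor: str = "timepoint",
) -> pd.DataFrame:
    """Smoothed, replicate-averaged expression for every condition and core gene.

    Returns a conditions x |F| DataFrame (rows in tensor condition order,
    columns in core-gene order).  Smoothing is local to each cultivar x
    vintage series.
    """
    gidx = tensor.gene_index(core_genes)
    out = np.empty((tensor.n_conditions, len(core_genes)))
    for key, cond_idx in tensor.series().items():
        if predictor == "timepoint":
            tvals = np.asarray([tensor.meta[j].timepoint for j in cond_idx], dtype=float)
        elif predictor == "doy":
            tvals = np.asarray([tensor.meta[j].doy for j in cond_idx], dtype=float)
            if np.any(~np.isfinite(tvals)):
                raise ValueError(f"missing doy in series {key}")
        else:
            raise ValueError(f"unknown predictor {predictor!r}")
        # replicate-level design: each condition contributes n_replicates points
        rep_times = np.repeat(tvals, tensor.n_replicates)
        hat = loess_hat_matrix(rep_times, tvals, degree=degree, span=span)
        # (n_cond * n_rep) x n_genes response, one column per gene
        y = tensor.values[cond_idx][:, :, gidx].reshape(-1, len(core_genes))
        out[cond_idx] = hat @ y
    return pd.DataFrame(out, index=tensor.condition_ids(), columns=list(core_genes))
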