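"""Whole-core-set screening: keep genes with consistent, development-
associated expression across every cultivar x vintage series.

Four configurable filter families, evaluated in a fixed order so that
each rejected gene carries the tag of the first filter it fails:

a. expression presence — replicate-mean expression reaches
   ``min_mean_expr`` in at least one condition of every series;
b. replicate noise — median replicate CV across conditions at most
   ``max_replicate_cv``;
c. cross-series consistency — minimum pairwise Pearson correlation of
   the LOESS-smoothed per-series profiles, interpolated to a common
   ordinal grid, at least ``min_cross_series_corr``;
d. reference congruence (optional) — mean Pearson correlation between
   the gene's reference-panel stage profile (one profile per reference
   cultivar) and its training mean profile resampled to the reference's
   stage count, at least ``min_reference_corr``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoothing import loess_hat_matrix
from .types import ExpressionTensor

__all__ = ["ScreeningConfig", "screen_genes"]

RETAINED = "retained"
TAG_NO_EXPRESSION = "no_expression"
TAG_NOISY = "noisy_replicates"
TAG_INCONSISTENT = "inconsistent_series"
TAG_REFERENCE = "reference_incongruent"


@dataclass
class ScreeningConfig:
    min_mean_expr: float = 1.0
    max_replicate_cv: float = 0.8
    min_cross_series_corr: float = 0.6
    min_reference_corr: float = 0.5
    require_reference_panel: bool = False
    smooth_degree: int = 2
    smooth_span: float = 0.75
    grid_points: int = 10

    def validate(self) -> None:
        for name in ("min_mean_expr", "max_replicate_cv"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.max_replicate_cv <= 0:
            raise ValueError("max_replicate_cv must be > 0")
        for name in ("min_cross_series_corr", "min_reference_corr"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1], got {v}")


def _series_smoothed_profiles(
    tensor: ExpressionTensor, cfg: ScreeningConfig
) -> dict[tuple[str, str], np.ndarray]:
    """Per series: smoothed profiles (timepoints x genes) on replicate data."""
    out = {}
    for key, idx in tensor.series().items():
        tps = np.asarray([tensor.meta[j].timepoint for j in idx], dtype=float)
        rep_t = np.repeat(tps, tensor.n_replicates)
        hat = loess_hat_matrix(rep_t, tps, degree=cfg.smooth_degree, span=cfg.smooth_span)
        y = tensor.values[idx].reshape(-1, tensor.n_genes)
        out[key] = hat @ y
    return out


def _interp_to_grid(profiles: np.ndarray, n_grid: int) -> np.ndarray:
    """Resample a (timepoints x genes) profile block onto [0, 1] ordinally."""
    n_t = profiles.shape[0]
    x = np.linspace(0.0, 1.0, n_t)
    grid = np.linspace(0.0, 1.0, n_grid)
    return np.column_stack([
        np.interp(grid, x, profiles[:, i]) for i in range(profiles.shape[1])
    ])


def _pairwise_min_corr(stack: np.ndarray) -> np.ndarray:
    """Minimum pairwise Pearson correlation across series, per gene.

    ``stack`` is (series, grid, genes).  Constant profiles yield NaN and
    force the minimum to NaN (treated as failing).
    """
    s, g, n = stack.shape
    centered = stack - stack.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    # profiles that are constant up to round-off have no direction
    scale = np.abs(stack).max(axis=1)
    flat = norms <= 1e-9 * (scale + 1.0)
    norms = np.where(flat, np.nan, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = centered / norms[:, None, :]
    min_corr = np.full(n, np.inf)
    for a in range(s):
        for b in range(a + 1, s):
            corr = np.einsum("gi,gi->i", unit[a], unit[b])
            min_corr = np.minimum(min_corr, corr)
    return min_corr


def screen_genes(
    tensor: ExpressionTensor,
    reference: ExpressionTensor | None = None,
    cfg: ScreeningConfig | None = None,
) -> tuple[list[str], pd.Series]:
    """Apply the screening filters; returns (core gene list F, per-gene tag).

    The tag series is indexed by gene id; retained genes carry
    ``"retained"``, rejected genes the first failing filter's tag.
    """
    cfg = cfg or ScreeningConfig()
    cfg.validate()
    if cfg.require_reference_panel and reference is None:
        raise ValueError("reference panel required by config but not provided")
    if reference is not None:
        shared = set(tensor.gene_ids) & set(reference.gene_ids)
        if not shared:
            raise ValueError("reference panel gene ids disjoint from tensor's")
        for key, idx in reference.series().items():
            if len(idx) < 3:
                raise ValueError(
                    f"reference series {key} has {len(idx)} stages; "
                    "congruence screening needs at least 3"
                )

    n = tensor.n_genes
    tags = np.array([RETAINED] * n, dtype=object)
    m = tensor.replicate_means()  # conditions x genes
    series = tensor.series()

    # (a) expression presence in every series
    present = np.ones(n, dtype=bool)
    for _, idx in series.items():
        present &= (m[idx] >= cfg.min_mean_expr).any(axis=0)
    tags[~present] = TAG_NO_EXPRESSION

    # (b) replicate noise: median CV over conditions
    sd = tensor.values.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(m > 0, sd / np.where(m > 0, m, 1.0), np.nan)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med_cv = np.nanmedian(cv, axis=0)
    ok_b = np.isfinite(med_cv) & (med_cv <= cfg.max_replicate_cv)
    tags[(tags == RETAINED) & ~ok_b] = TAG_NOISY

    # (c) cross-series consistency of smoothed profiles
    profiles = _series_smoothed_profiles(tensor, cfg)
    stack = np.stack([
        _interp_to_grid(p, cfg.grid_points) for p in profiles.values()
    ])
    min_corr = _pairwise_min_corr(stack)
    ok_c = np.isfinite(min_corr) & (min_corr >= cfg.min_cross_series_corr)
    tags[(tags == RETAINED) & ~ok_c] = TAG_INCONSISTENT

    # (d) reference-panel congruence
    if reference is not None:
        ref_m = reference.replicate_means()
        ref_series = reference.series()
        n_stages = len(next(iter(ref_series.values())))
        # training mean profile resampled to the reference stage count:
        # average of per-series replicate-mean profiles on a common grid
        train = np.stack([
            _interp_to_grid(m[idx], n_stages) for idx in series.values()
        ]).mean(axis=0)  # n_stages x genes
        ref_pos = {g: i for i, g in enumerate(reference.gene_ids)}
        centered_t = train - train.mean(axis=0)
        norm_t = np.linalg.norm(centered_t, axis=0)
        corrs = np.full(n, np.nan)
        for i, g in enumerate(tensor.gene_ids):
            if g not in ref_pos or norm_t[i] == 0:
                continue
            vals = []
            for idx in ref_series.values():
                prof = ref_m[idx, ref_pos[g]]
                c = prof - prof.mean()
                nc = np.linalg.norm(c)
                if nc == 0:
                    continue
                vals.append(float(c @ centered_t[:, i]) / (nc * norm_t[i]))
            if vals:
                corrs[i] = np.mean(vals)
        ok_d = np.isnan(corrs) | (corrs >= cfg.min_reference_corr)
        # genes absent from the reference cannot be evaluated and pass through
        evaluable = np.isin(tensor.gene_ids, list(ref_pos))
        ok_d = np.where(evaluable, ok_d & np.isfinite(corrs), True)
        tags[(tags == RETAINED) & ~ok_d] = TAG_REFERENCE

    tag_series = pd.Series(tags, index=tensor.gene_ids, name="screen_tag")
    core = [g for g, t in zip(tensor.gene_ids, tags) if t == RETAINED]
    return core, tag_series
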