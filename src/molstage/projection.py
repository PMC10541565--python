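"""Project expression matrices onto a frozen phenology scale.

Two cases:

* the full core set F is observed — standardize the columns, multiply by
  the eigenvector matrix A to estimate the three PC coordinates, and
  assign each sample to the nearest of the scale's marks;
* only a reduced panel of genes is observed — for each selected component
  the unobserved genes are imputed with the per-sample average of the
  observed genes sharing the sign of the gene's eigenvector coefficient,
  then projected as above.

Column standardization uses the projected dataset's own means and
population sds ("dataset" mode); "training" mode reuses the scale's
training statistics, which is the only well-defined choice for a single
sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .types import GenePanel, ProjectionResult, ScaleArtifact

__all__ = ["project_full", "project_reduced", "assign_stages", "panel_from_scale"]


def assign_stages(coords: np.ndarray, marks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-mark assignment (Euclidean); ties go to the lower stage index."""
    d = cdist(np.asarray(coords, dtype=float), np.asarray(marks, dtype=float))
    idx = np.argmin(d, axis=1)
    return idx + 1, d[np.arange(len(idx)), idx]


def panel_from_scale(scale: ScaleArtifact, gene_ids: list[str],
                     provenance: str = "") -> GenePanel:
    """Build a panel for a subset of core genes, signs from the eigenvectors."""
    pos = {g: i for i, g in enumerate(scale.core_gene_ids)}
    missing = [g for g in gene_ids if g not in pos]
    if missing:
        raise ValueError(f"panel genes not in core set: {missing[:5]}")
    rows = np.asarray([pos[g] for g in gene_ids])
    signs = np.where(scale.eigenvectors[rows] >= 0, 1, -1)
    return GenePanel(gene_ids=list(gene_ids), signs=signs, provenance=provenance)


def _standardize(Z: pd.DataFrame, scale: ScaleArtifact, mode: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-standardize; returns (standardized frame, mask of zero-variance columns)."""
    X = Z.to_numpy(dtype=float)
    if mode == "dataset":
        if X.shape[0] < 2:
            raise ValueError(
                "dataset-local standardization is undefined for a single sample; "
                "use standardize='training'"
            )
        means = X.mean(axis=0)
        sds = X.std(axis=0)
    elif mode == "training":
        pos = {g: i for i, g in enumerate(scale.core_gene_ids)}
        idx = np.asarray([pos[g] for g in Z.columns])
        means = scale.column_means[idx]
        sds = scale.column_sds[idx]
    else:
        raise ValueError(f"unknown standardize mode {mode!r}")
    dead = sds <= 0
    safe = np.where(dead, 1.0, sds)
    return pd.DataFrame((X - means) / safe, index=Z.index, columns=Z.columns), dead


def project_full(
    Z_obs: pd.DataFrame, scale: ScaleArtifact, standardize: str = "dataset"
) -> ProjectionResult:
    """Project a samples x genes matrix observing the whole core set F."""
    missing = [g for g in scale.core_gene_ids if g not in Z_obs.columns]
    if missing:
        raise ValueError(
            f"{len(missing)} core genes absent from the observed matrix "
            f"(e.g. {missing[:3]}); use project_reduced with a gene panel"
        )
    Z = Z_obs[scale.core_gene_ids]
    Zs, dead = _standardize(Z, scale, standardize)
    if dead.any():
        kept = [g for g, d in zip(scale.core_gene_ids, dead) if not d]
        warnings.warn(
            f"{int(dead.sum())} zero-variance columns dropped and treated as "
            "unobserved (reduced-panel imputation)"
        )
        panel = panel_from_scale(scale, kept, provenance="zero-variance fallback")
        return project_reduced(Z_obs[kept], panel, scale, standardize=standardize)
    X = Zs.to_numpy()
    coords = np.column_stack([X @ scale.eigenvectors[:, q] for q in range(3)])
    stage, dist = assign_stages(coords, scale.marks)
    return ProjectionResult(list(Z.index.astype(str)), stage, coords, dist, "full")


def project_reduced(
    Z_obs: pd.DataFrame, panel: GenePanel, scale: ScaleArtifact,
    standardize: str = "dataset",
) -> ProjectionResult:
    """Project a samples x panel-genes matrix with sign-based imputation."""
    core = scale.core_gene_ids
    pos = {g: i for i, g in enumerate(core)}
    bad = [g for g in panel.gene_ids if g not in pos]
    if bad:
        raise ValueError(f"panel genes outside the core set: {bad[:5]}")
    absent = [g for g in panel.gene_ids if g not in Z_obs.columns]
    if absent:
        raise ValueError(f"panel genes missing from observations: {absent[:5]}")
    # work in core-set order so the no-missing-gene case reproduces
    # project_full operation for operation
    panel_genes = sorted(panel.gene_ids, key=lambda g: pos[g])
    Z = Z_obs[panel_genes]
    Zs, dead = _standardize(Z, scale, standardize)
    if dead.any():
        keep = [g for g, d in zip(panel_genes, dead) if not d]
        warnings.warn(
            f"{int(dead.sum())} zero-variance panel columns dropped"
        )
        reordered = panel.subset(sorted(panel.gene_ids, key=lambda g: pos[g]))
        return project_reduced(
            Z_obs[keep], reordered.subset(keep), scale, standardize=standardize,
        )
    A = scale.eigenvectors
    obs_rows = np.asarray([pos[g] for g in panel_genes])
    obs_mask = np.zeros(len(core), dtype=bool)
    obs_mask[obs_rows] = True
    X = Zs.to_numpy()  # samples x |panel|, in panel order
    if panel.pools is not None:
        order = {g: i for i, g in enumerate(panel.gene_ids)}
        pools = panel.pools[[order[g] for g in panel_genes]]

    coords = np.empty((X.shape[0], 3))
    for q in range(3):
        a = A[:, q]
        if panel.pools is not None:
            # structured panel: impute from this component's own sign pools
            sign_obs = None
            in_pos = (pools[:, 0] == q) & (pools[:, 1] == 1)
            in_neg = (pools[:, 0] == q) & (pools[:, 1] == -1)
            if not in_pos.any() or not in_neg.any():
                raise ValueError(
                    f"panel not sign-balanced for PC {scale.pc_indices[q]}"
                )
            pos_mean = X[:, in_pos].mean(axis=1)
            neg_mean = X[:, in_neg].mean(axis=1)
        else:
            sign_obs = a[obs_rows] >= 0
            if sign_obs.all() or (~sign_obs).all():
                raise ValueError(
                    f"panel not sign-balanced for PC {scale.pc_indices[q]}"
                )
            pos_mean = X[:, sign_obs].mean(axis=1)
            neg_mean = X[:, ~sign_obs].mean(axis=1)
        # observed part of the dot product
        y = X @ a[obs_rows]
        # imputed part: unobserved coefficients grouped by sign
        a_unobs = a[~obs_mask]
        pos_coef = a_unobs[a_unobs >= 0].sum()
        neg_coef = a_unobs[a_unobs < 0].sum()
        coords[:, q] = y + pos_mean * pos_coef + neg_mean * neg_coef
    stage, dist = assign_stages(coords, scale.marks)
    return ProjectionResult(list(Z.index.astype(str)), stage, coords, dist, "reduced")
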