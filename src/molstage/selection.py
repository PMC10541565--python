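"""Stage-associated transcript selection and reduced marker panels.

Two selection problems:

* which transcripts track the late (stage >= 20) scale progression —
  answered with gradient-boosting variable importances (relative
  influence of cultivar, vintage and stage on each gene's expression),
  a quantile criterion across genes, and a Spearman confirmation;
* which small panels of transcripts suffice to rebuild the scale —
  pools of top positive/negative loading genes per selected component,
  thinned with hierarchical clustering (1 - Pearson r distance, average
  linkage) so small panels sample distinct co-expression clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.ensemble import GradientBoostingRegressor

from .types import ExpressionTensor, GenePanel, ScaleArtifact

__all__ = [
    "GbmConfig",
    "gbm_vims",
    "compute_vim_table",
    "select_stage_genes",
    "stage_spearman",
    "select_reduced_core_sets",
]


@dataclass
class GbmConfig:
    n_estimators: int = 500
    max_depth: int = 3
    learning_rate: float = 0.05
    subsample: float = 1.0


def gbm_vims(
    features: pd.DataFrame, y: np.ndarray, cfg: GbmConfig | None = None, seed: int = 0
) -> tuple[float, float, float]:
    """Relative influence (percent, summing to 100) of cultivar, vintage
    and stage on one gene's replicate-level expression.

    ``features`` must have columns cultivar, vintage, stage.  Constant
    expression returns (0, 0, 0) by convention.
    """
    cfg = cfg or GbmConfig()
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    if np.allclose(y, y[0]):
        return (0.0, 0.0, 0.0)
    X = np.column_stack([
        pd.factorize(features["cultivar"])[0],
        pd.factorize(features["vintage"])[0],
        np.asarray(features["stage"], dtype=float),
    ])
    gbm = GradientBoostingRegressor(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        learning_rate=cfg.learning_rate,
        subsample=cfg.subsample,
        random_state=seed,
    )
    gbm.fit(X, y)
    imp = gbm.feature_importances_
    tot = imp.sum()
    if tot <= 0:
        return (0.0, 0.0, 0.0)
    vim = 100.0 * imp / tot
    return (float(vim[0]), float(vim[1]), float(vim[2]))


def compute_vim_table(
    tensor: ExpressionTensor,
    stages: np.ndarray,
    s_min: int = 20,
    cfg: GbmConfig | None = None,
    seed: int = 0,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """VIMc/VIMy/VIMs per gene on conditions with stage >= ``s_min``,
    plus the Spearman correlation of expression with stage on that subset.
    """
    stages = np.asarray(stages)
    keep = np.flatnonzero(stages >= s_min)
    if keep.size == 0:
        raise ValueError(f"no conditions with stage >= {s_min}")
    gene_ids = genes if genes is not None else tensor.gene_ids
    gidx = tensor.gene_index(gene_ids)
    feats = pd.DataFrame(
        {
            "cultivar": np.repeat([tensor.meta[j].cultivar for j in keep],
                                  tensor.n_replicates),
            "vintage": np.repeat([tensor.meta[j].vintage for j in keep],
                                 tensor.n_replicates),
            "stage": np.repeat(stages[keep], tensor.n_replicates),
        }
    )
    rows = []
    for g in gidx:
        y = tensor.values[keep, :, g].reshape(-1)
        vimc, vimy, vims = gbm_vims(feats, y, cfg=cfg, seed=seed)
        if np.allclose(y, y[0]):
            rho = 0.0
        else:
            rho = spearmanr(feats["stage"], y).statistic
            rho = float(rho) if np.isfinite(rho) else 0.0
        rows.append((vimc, vimy, vims, rho))
    return pd.DataFrame(
        rows, index=gene_ids, columns=["VIMc", "VIMy", "VIMs", "spearman_rho"]
    )


def select_stage_genes(
    vims: pd.DataFrame, q_c: float = 0.10, q_y: float = 0.20, q_s: float = 0.20
) -> list[str]:
    """Genes whose expression tracks stage and is little affected by
    cultivar or vintage: VIMc <= its q_c quantile, VIMy <= its q_y
    quantile, VIMs >= its q_s quantile (quantiles across genes,
    boundaries inclusive).
    """
    tc = vims["VIMc"].quantile(q_c)
    ty = vims["VIMy"].quantile(q_y)
    ts = vims["VIMs"].quantile(q_s)
    mask = (vims["VIMc"] <= tc) & (vims["VIMy"] <= ty) & (vims["VIMs"] >= ts)
    selected = list(vims.index[mask])
    if not selected:
        import warnings

        warnings.warn("no genes pass the VIM quantile criterion")
    return selected


def stage_spearman(
    expression: np.ndarray, stages: np.ndarray, interval: tuple[float, float] = (20, 30)
) -> float:
    """Spearman correlation of expression with stage within a stage interval."""
    expression = np.asarray(expression, dtype=float)
    stages = np.asarray(stages, dtype=float)
    lo, hi = interval
    keep = (stages >= lo) & (stages <= hi)
    if keep.sum() < 3:
        raise ValueError("need at least 3 conditions in the stage interval")
    sub = expression[keep]
    if np.allclose(sub, sub[0]):
        raise ValueError("constant expression in the interval")
    return float(spearmanr(sub, stages[keep]).statistic)


def _pool_candidates(
    pcorr: np.ndarray, q: int, sign: int, used: set[int]
) -> np.ndarray:
    vals = pcorr[:, q]
    cand = np.flatnonzero((np.sign(vals) == sign) & ~np.isin(
        np.arange(len(vals)), list(used)
    ))
    return cand


def select_reduced_core_sets(
    scale: ScaleArtifact,
    standardized: pd.DataFrame,
    scores: np.ndarray,
    sizes: tuple[int, ...] = (120, 60, 30, 12),
    n_clusters: int = 20,
    n_top: int = 100,
) -> dict[int, GenePanel]:
    """Build one reduced panel per requested size from PCA loadings.

    For each selected component and sign, genes are ranked by p-corr (the
    Pearson correlation between the gene's standardized smoothed profile
    and the component's score vector).  The pooled ``n_top`` genes by
    |p-corr| are hierarchically clustered; large panels prefer genes from
    the most populated clusters, small panels take representatives of
    distinct clusters.  The third component's pools are ranked purely by
    |p-corr|.
    """
    genes = list(standardized.columns)
    if genes != list(scale.core_gene_ids):
        raise ValueError("standardized matrix columns must match the core set")
    Z = standardized.to_numpy(dtype=float)
    n_cond, n_genes = Z.shape
    S = np.asarray(scores, dtype=float)
    if S.shape != (n_cond, 3):
        raise ValueError("scores must be conditions x 3")
    # p-corr: Z columns are standardized (population), so correlation is a
    # normalized dot product with the centered score vectors
    Sc = (S - S.mean(axis=0)) / S.std(axis=0)
    pcorr = Z.T @ Sc / n_cond  # genes x 3
    order_top = np.argsort(-np.max(np.abs(pcorr), axis=1), kind="stable")[:n_top]
    prof = Z[:, order_top]
    corr = np.corrcoef(prof.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    lab = fcluster(linkage(squareform(dist, checks=False), method="average"),
                   t=n_clusters, criterion="maxclust")
    cluster_of = {int(g): int(c) for g, c in zip(order_top, lab)}
    csize = {c: int(np.sum(lab == c)) for c in np.unique(lab)}

    panels: dict[int, GenePanel] = {}
    for size in sizes:
        if size % 6 != 0:
            raise ValueError(f"panel size {size} not divisible into 3 PC x 2 sign pools")
        pool_n = size // 6
        diverse = pool_n <= 5  # small panels sample distinct clusters
        used: set[int] = set()
        chosen: list[int] = []
        pool_rows: list[tuple[int, int]] = []
        for q in range(3):
            for sign in (1, -1):
                cand = _pool_candidates(pcorr, q, sign, used)
                strength = np.abs(pcorr[cand, q])
                if q == 2 or not diverse:
                    if q == 2:
                        # third component: p-corr only
                        key = sorted(
                            range(len(cand)),
                            key=lambda i: (-strength[i], genes[cand[i]]),
                        )
                    else:
                        # highest |p-corr| first; populated clusters break ties
                        key = sorted(
                            range(len(cand)),
                            key=lambda i: (
                                -strength[i],
                                -csize.get(cluster_of.get(int(cand[i]), -1), 0),
                                genes[cand[i]],
                            ),
                        )
                    pick = [int(cand[i]) for i in key[:pool_n]]
                else:
                    # distinct-cluster representatives, by descending |p-corr|
                    key = sorted(
                        range(len(cand)),
                        key=lambda i: (-strength[i], genes[cand[i]]),
                    )
                    pick, seen_clusters = [], set()
                    for i in key:
                        g = int(cand[i])
                        c = cluster_of.get(g)  # genes outside the top set
                        if c is not None and c in seen_clusters:
                            continue
                        if c is not None:
                            seen_clusters.add(c)
                        pick.append(g)
                        if len(pick) == pool_n:
                            break
                if len(pick) < pool_n:
                    raise ValueError(
                        f"pool (component {q + 1}, sign {sign:+d}) has only "
                        f"{len(pick)} candidates, {pool_n} requested"
                    )
                chosen.extend(pick)
                pool_rows.extend([(q, sign)] * len(pick))
                used.update(pick)
        ids = [genes[g] for g in chosen]
        signs = np.where(scale.eigenvectors[chosen] >= 0, 1, -1)
        panels[size] = GenePanel(
            gene_ids=ids, signs=signs,
            provenance=f"reduced core set, {size} genes from PCA loadings",
            pools=np.asarray(pool_rows),
        )
    return panels
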