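"""Build the molecular phenology scale: PCA on smoothed expression, a
Bezier curve through the 3-D score scatter, and equal-arc-length marks.

Pipeline (given a screened core gene set F):

1. column-standardize the conditions x |F| smoothed matrix;
2. PCA by SVD; orient each component so its scores increase with timepoint;
3. triage components into stage / cultivar / vintage / mixed by effect
   size, keep the three stage-associated ones (or take explicit indices);
4. least-squares Bezier fit (k control points, Bernstein basis) to the
   conditions x 3 score scatter, with foot-point parameter refinement;
5. place ``n_marks`` marks at equal arc-length fractions along the curve
   and assign each training condition to its nearest mark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .smoothing import smooth_dataset
from .types import ExpressionTensor, SampleMeta, ScaleArtifact, bezier_point

__all__ = [
    "PCModel",
    "BezierCurve",
    "ScaleConfig",
    "standardize_columns",
    "fit_pca",
    "triage_components",
    "fit_bezier",
    "place_marks",
    "build_scale",
]


@dataclass
class ScaleConfig:
    n_pcs: int = 6
    pc_indices: list[int] | None = None  # 1-based; None = automatic triage
    k: int = 5
    n_marks: int = 30
    refine_iters: int = 2
    dense_samples: int = 10001
    degree: int = 2
    span: float = 0.75
    predictor: str = "timepoint"


@dataclass
class PCModel:
    """Principal components of the standardized smoothed matrix."""

    column_means: np.ndarray
    column_sds: np.ndarray
    eigenvectors: np.ndarray  # genes x n_pcs
    explained_variance_pct: np.ndarray
    scores: np.ndarray  # conditions x n_pcs
    factor_assoc: list[str] = field(default_factory=list)
    factor_effects: np.ndarray | None = None  # n_pcs x 3 (cultivar, vintage, stage)


@dataclass
class BezierCurve:
    control_points: np.ndarray
    params: np.ndarray  # fitted parameter per data point
    residual: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return bezier_point(self.control_points, t)


def standardize_columns(
    matrix: np.ndarray, gene_ids: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale each column to mean 0, population sd 1."""
    M = np.asarray(matrix, dtype=float)
    means = M.mean(axis=0)
    sds = M.std(axis=0)  # population sd (denominator n)
    bad = np.flatnonzero(sds <= 0)
    if bad.size:
        name = gene_ids[bad[0]] if gene_ids is not None else f"column {bad[0]}"
        raise ValueError(f"zero-variance column: {name}")
    return (M - means) / sds, means, sds


def _bernstein(t: np.ndarray, k: int) -> np.ndarray:
    from scipy.special import comb

    n = k - 1
    i = np.arange(k)
    t = np.asarray(t, dtype=float)
    return comb(n, i)[None, :] * t[:, None] ** i * (1.0 - t[:, None]) ** (n - i)


def fit_pca(Z: np.ndarray, n_pcs: int = 6, meta: list[SampleMeta] | None = None,
            column_means: np.ndarray | None = None,
            column_sds: np.ndarray | None = None) -> PCModel:
    """PCA by SVD of the standardized matrix.

    Explained variance percentages come from the squared singular values.
    When ``meta`` is given, each component is sign-oriented so that its
    score sequence correlates non-negatively with timepoint order.
    """
    Z = np.asarray(Z, dtype=float)
    if n_pcs > min(Z.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(matrix shape)={min(Z.shape)}")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    explained = 100.0 * s**2 / np.sum(s**2)
    scores = U * s
    vecs = Vt.T
    if meta is not None:
        tps = np.asarray([m.timepoint for m in meta], dtype=float)
        for q in range(min(n_pcs, scores.shape[1])):
            rho = spearmanr(scores[:, q], tps).statistic
            if np.isfinite(rho) and rho < 0:
                scores[:, q] *= -1
                vecs[:, q] *= -1
    nz = Z.shape[1] if column_means is None else None
    return PCModel(
        column_means=column_means if column_means is not None else np.zeros(nz),
        column_sds=column_sds if column_sds is not None else np.ones(nz),
        eigenvectors=vecs[:, :n_pcs],
        explained_variance_pct=explained[:n_pcs],
        scores=scores[:, :n_pcs],
    )


def _eta_squared(scores: np.ndarray, groups: np.ndarray) -> float:
    grand = scores.mean()
    ss_tot = np.sum((scores - grand) ** 2)
    if ss_tot == 0:
        return 0.0
    ss_between = 0.0
    for g in np.unique(groups):
        sel = scores[groups == g]
        ss_between += sel.size * (sel.mean() - grand) ** 2
    return float(ss_between / ss_tot)


def triage_components(
    model: PCModel, meta: list[SampleMeta], margin: float = 0.1
) -> tuple[list[str], list[int]]:
    """Label each PC by its dominant factor and pick the stage components.

    Effect sizes: eta-squared of scores against cultivar, vintage and
    timepoint order (the timepoint grouping captures stage dependence that
    is strong but non-monotone, as for the second and later stage
    components).  A PC is labelled by the largest effect if it beats the
    runner-up by at least ``margin``, else "mixed".  Returns (labels,
    1-based indices of the three stage PCs ranked by explained variance).
    """
    cult = np.asarray([m.cultivar for m in meta])
    vint = np.asarray([m.vintage for m in meta])
    tps = np.asarray([m.timepoint for m in meta], dtype=float)
    labels: list[str] = []
    effects = np.zeros((model.scores.shape[1], 3))
    for q in range(model.scores.shape[1]):
        sc = model.scores[:, q]
        e_c = _eta_squared(sc, cult)
        e_v = _eta_squared(sc, vint)
        e_s = _eta_squared(sc, tps)
        effects[q] = (e_c, e_v, e_s)
        order = np.sort(effects[q])[::-1]
        if order[0] - order[1] < margin:
            labels.append("mixed")
        else:
            labels.append(("cultivar", "vintage", "stage")[int(np.argmax(effects[q]))])
    model.factor_assoc = labels
    model.factor_effects = effects
    stage_pcs = [q for q, lab in enumerate(labels) if lab == "stage"]
    if len(stage_pcs) < 3:
        raise ValueError(
            "fewer than three stage-associated components found; "
            "set pc_indices explicitly in the scale config"
        )
    stage_pcs.sort(key=lambda q: -model.explained_variance_pct[q])
    return labels, [q + 1 for q in stage_pcs[:3]]


def fit_bezier(
    points: np.ndarray,
    k: int = 5,
    refine_iters: int = 2,
    t_init: np.ndarray | None = None,
    dense_samples: int = 4001,
) -> BezierCurve:
    """Least-squares Bezier fit with foot-point parameter refinement.

    Control points solve a linear least-squares problem on the
    degree-(k-1) Bernstein basis at the current parameters; parameters are
    then refreshed by projecting each point onto the densely sampled curve.
    The iterate with the smallest summed squared residual wins.
    """
    pts = np.asarray(points, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if pts.shape[0] < k:
        raise ValueError(f"need at least k={k} points, got {pts.shape[0]}")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate input: all points identical")
    if t_init is None:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        t = cum / cum[-1]
    else:
        t = np.asarray(t_init, dtype=float)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(refine_iters + 1):
        B = _bernstein(t, k)
        cp, *_ = np.linalg.lstsq(B, pts, rcond=None)
        resid = float(np.sum((B @ cp - pts) ** 2))
        if best is None or resid < best[0]:
            best = (resid, cp, t.copy())
        # foot-point correction: nearest parameter on a dense curve sample
        tgrid = np.linspace(0.0, 1.0, dense_samples)
        curve = _bernstein(tgrid, k) @ cp
        d2 = ((pts[:, None, :] - curve[None, :, :]) ** 2).sum(axis=2)
        t = tgrid[np.argmin(d2, axis=1)]
    resid, cp, t = best
    return BezierCurve(control_points=cp, params=t, residual=resid)


def place_marks(
    curve: BezierCurve | np.ndarray, n_marks: int = 30, dense_samples: int = 10001
) -> tuple[np.ndarray, np.ndarray]:
    """Marks at equal arc-length fractions along the curve.

    Arc length is computed on a dense polyline; returns (marks, the curve
    parameters of the marks).
    """
    cp = curve.control_points if isinstance(curve, BezierCurve) else np.asarray(curve)
    if n_marks < 2:
        raise ValueError("n_marks must be >= 2")
    tgrid = np.linspace(0.0, 1.0, dense_samples)
    pts = bezier_point(cp, tgrid)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n_marks)
    t_marks = np.interp(targets, cum, tgrid)
    return bezier_point(cp, t_marks), t_marks


def _assign_nearest(coords: np.ndarray, marks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial.distance import cdist

    d = cdist(coords, marks)
    idx = np.argmin(d, axis=1)  # ties resolve to the lower stage index
    return idx + 1, d[np.arange(len(idx)), idx]


def build_scale(
    tensor: ExpressionTensor,
    core_genes: list[str],
    cfg: ScaleConfig | None = None,
) -> tuple[ScaleArtifact, PCModel]:
    """Run the full scale-construction pipeline on a training tensor."""
    cfg = cfg or ScaleConfig()
    smoothed = smooth_dataset(
        tensor, core_genes, degree=cfg.degree, span=cfg.span, predictor=cfg.predictor
    )
    Z, means, sds = standardize_columns(smoothed.to_numpy(), core_genes)
    model = fit_pca(Z, n_pcs=cfg.n_pcs, meta=tensor.meta,
                    column_means=means, column_sds=sds)
    if cfg.pc_indices is not None:
        if len(cfg.pc_indices) != 3:
            raise ValueError("pc_indices must list exactly three components")
        pcs = list(cfg.pc_indices)
        triage_components(model, tensor.meta)  # labels for reporting only
    else:
        _, pcs = triage_components(model, tensor.meta)
    sel = [p - 1 for p in pcs]
    A = model.eigenvectors[:, sel]
    scores3 = model.scores[:, sel]

    # initial Bezier parameter: normalized within-series timepoint
    t_init = np.empty(tensor.n_conditions)
    for _, idx in tensor.series().items():
        tps = np.asarray([tensor.meta[j].timepoint for j in idx], dtype=float)
        t_init[idx] = (tps - 1.0) / max(tps.max() - 1.0, 1.0)
    curve = fit_bezier(scores3, k=cfg.k, refine_iters=cfg.refine_iters,
                       t_init=t_init, dense_samples=max(cfg.dense_samples // 2, 2001))
    marks, mark_params = place_marks(curve, cfg.n_marks, cfg.dense_samples)
    stages, _ = _assign_nearest(scores3, marks)

    # orient the scale: stage 1 is the earliest-development end
    tps = tensor.timepoints()
    rho = spearmanr(stages, tps).statistic
    flip = (np.isfinite(rho) and rho < 0)
    if not flip and (not np.isfinite(rho) or rho == 0):
        first_series = next(iter(tensor.series().values()))
        flip = stages[first_series[0]] > stages[first_series[-1]]
    if flip:
        marks = marks[::-1].copy()
        mark_params = mark_params[::-1].copy()
    stages, _ = _assign_nearest(scores3, marks)

    artifact = ScaleArtifact(
        core_gene_ids=core_genes,
        column_means=means,
        column_sds=sds,
        eigenvectors=A,
        pc_indices=pcs,
        control_points=curve.control_points,
        marks=marks,
        mark_params=mark_params,
        n_marks=cfg.n_marks,
        explained_variance_pct=model.explained_variance_pct[sel],
        training_condition_ids=tensor.condition_ids(),
        training_stages=stages,
    )
    return artifact, model
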