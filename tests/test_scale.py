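"""Scale construction: standardization, PCA, triage, Bezier fit, marks."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import spearmanr

from molstage import SampleMeta
from molstage.scale import (
    BezierCurve,
    ScaleConfig,
    build_scale,
    fit_bezier,
    fit_pca,
    place_marks,
    standardize_columns,
    triage_components,
)
from molstage.types import bezier_point

from conftest import make_tensor


class TestStandardize:
    def test_simple_column(self):
        Z, mu, sd = standardize_columns(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(Z[:, 0], [-1.22474487, 0.0, 1.22474487])
        assert mu[0] == 2.0 and sd[0] == pytest.approx(np.sqrt(2 / 3))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        Z, *_ = standardize_columns(rng.normal(size=(20, 5)))
        Z2, *_ = standardize_columns(Z)
        assert np.allclose(Z, Z2, atol=1e-10)

    def test_constant_column_names_gene(self):
        M = np.column_stack([np.arange(3.0), np.ones(3)])
        with pytest.raises(ValueError, match="geneB"):
            standardize_columns(M, ["geneA", "geneB"])


class TestFitPca:
    def test_rank_one_explains_everything(self):
        u = np.arange(5.0) - 2.0
        Z = np.outer(u, np.ones(4))
        model = fit_pca(Z, n_pcs=2)
        assert model.explained_variance_pct[0] == pytest.approx(100.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(4)
        Z, *_ = standardize_columns(rng.normal(size=(10, 50)))
        model = fit_pca(Z, n_pcs=10)
        assert np.allclose(model.scores @ model.eigenvectors.T, Z, atol=1e-8)
        gram = model.eigenvectors.T @ model.eigenvectors
        assert np.allclose(gram, np.eye(10), atol=1e-8)

    def test_planted_variance_shares(self):
        """PCA recovers the variance split of an exactly low-rank matrix."""
        rng = np.random.default_rng(9)
        n, g = 40, 200
        U = np.linalg.qr(rng.normal(size=(n, 3)))[0]
        V = np.linalg.qr(rng.normal(size=(g, 3)))[0]
        sig = np.array([30.0, 15.0, 5.0])
        Z = (U * sig) @ V.T
        planted = 100 * sig**2 / np.sum(sig**2)
        model = fit_pca(Z, n_pcs=3)
        assert np.allclose(model.explained_variance_pct, planted, atol=2.0)

    def test_too_many_components(self):
        with pytest.raises(ValueError, match="n_pcs"):
            fit_pca(np.zeros((4, 6)), n_pcs=5)


def _factor_meta():
    meta = []
    for cult in ("A", "B"):
        for vint in ("Y1", "Y2", "Y3"):
            for t in range(1, 13):
                meta.append(SampleMeta(f"{cult}_{vint}_{t}", cult, vint, t))
    return meta


class TestTriage:
    def test_planted_factor_labels(self):
        """Six planted score patterns recover their factor labels."""
        meta = _factor_meta()
        tp = np.array([m.timepoint for m in meta], float)
        cult = np.array([1.0 if m.cultivar == "A" else -1.0 for m in meta])
        vint = np.array([{"Y1": 1.0, "Y2": 0.0, "Y3": -1.0}[m.vintage] for m in meta])
        rng = np.random.default_rng(2)
        scores = np.column_stack([
            tp - tp.mean(),                       # stage (monotone)
            (tp - tp.mean()) ** 2 - 11.0,         # stage (non-monotone)
            cult * 3.0,                           # cultivar
            vint * 3.0,                           # vintage
            np.sin(tp / 2.0),                     # stage (oscillating with time)
            cult * 2.0,                           # cultivar
        ])
        scores += rng.normal(0, 0.05, scores.shape)
        from molstage.scale import PCModel

        model = PCModel(
            column_means=np.zeros(6), column_sds=np.ones(6),
            eigenvectors=np.eye(6),
            explained_variance_pct=np.array([40, 25, 15, 10, 6, 4.0]),
            scores=scores,
        )
        labels, pcs = triage_components(model, meta)
        planted = ["stage", "stage", "cultivar", "vintage", "stage", "cultivar"]
        assert sum(a == b for a, b in zip(labels, planted)) >= 5
        assert pcs == [1, 2, 5]

    def test_timepoint_scores_labelled_stage(self):
        meta = _factor_meta()
        tp = np.array([m.timepoint for m in meta], float)
        from molstage.scale import PCModel

        model = PCModel(
            column_means=np.zeros(3), column_sds=np.ones(3),
            eigenvectors=np.eye(3), explained_variance_pct=np.array([50, 30, 20.0]),
            scores=np.column_stack([tp, tp**2, -tp]),
        )
        labels, _ = triage_components(model, meta)
        assert labels == ["stage", "stage", "stage"]

    def test_cultivar_scores_labelled_cultivar(self):
        meta = _factor_meta()
        cult = np.array([1.0 if m.cultivar == "A" else -1.0 for m in meta])
        from molstage.scale import PCModel

        model = PCModel(
            column_means=np.zeros(1), column_sds=np.ones(1),
            eigenvectors=np.eye(1), explained_variance_pct=np.array([100.0]),
            scores=cult[:, None],
        )
        with pytest.raises(ValueError, match="pc_indices"):
            triage_components(model, meta)
        assert model.factor_assoc == ["cultivar"]


class TestFitBezier:
    def test_line_is_reproduced(self):
        t = np.linspace(0, 1, 20)
        pts = np.outer(t, [3.0, -1.0, 2.0])
        curve = fit_bezier(pts, k=5)
        assert curve.residual < 1e-10

    def test_recovers_known_quartic_control_points(self):
        rng = np.random.default_rng(6)
        cp = rng.normal(size=(5, 3)) * 5
        t = np.linspace(0, 1, 25)
        pts = bezier_point(cp, t)
        curve = fit_bezier(pts, k=5, t_init=t, refine_iters=0)
        assert np.allclose(curve.control_points, cp, atol=1e-6)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_bezier(np.ones((10, 3)), k=5)

    def test_order_must_be_at_least_two(self):
        with pytest.raises(ValueError, match="k"):
            fit_bezier(np.random.default_rng(0).normal(size=(10, 3)), k=1)


class TestPlaceMarks:
    def test_line_marks_uniform(self):
        cp = np.column_stack([np.linspace(0, 29, 5), np.zeros(5), np.zeros(5)])
        marks, _ = place_marks(cp, 30)
        assert np.allclose(marks[:, 0], np.arange(30.0), atol=1e-6)
        assert np.allclose(marks[:, 1:], 0.0)

    def test_two_marks_are_endpoints(self):
        rng = np.random.default_rng(8)
        cp = rng.normal(size=(5, 3))
        marks, _ = place_marks(cp, 2)
        assert np.allclose(marks[0], cp[0], atol=1e-12)
        assert np.allclose(marks[-1], cp[-1], atol=1e-12)

    def test_arc_spacing_matches_quadrature_oracle(self):
        """Inter-mark arc lengths agree with adaptive quadrature to 1e-3."""
        cp = np.array([
            [0.0, 0.0, 0.0], [2.0, 4.0, 1.0], [5.0, 4.5, -1.0],
            [8.0, 3.0, 0.5], [10.0, 0.0, 0.0],
        ])
        marks, params = place_marks(cp, 12)

        def speed(t):
            eps = 1e-7
            p0 = bezier_point(cp, max(t - eps, 0.0))[0]
            p1 = bezier_point(cp, min(t + eps, 1.0))[0]
            return np.linalg.norm(p1 - p0) / (min(t + eps, 1.0) - max(t - eps, 0.0))

        arcs = [
            quad(speed, params[i], params[i + 1], limit=200)[0]
            for i in range(len(params) - 1)
        ]
        arcs = np.asarray(arcs)
        assert np.all(np.abs(arcs - arcs.mean()) / arcs.mean() < 1e-3)

    def test_minimum_marks(self):
        with pytest.raises(ValueError, match="n_marks"):
            place_marks(np.zeros((5, 3)), 1)


class TestBuildScale:
    def test_stage_order_mostly_monotone(self, default_dataset, built_scale):
        tensor, _ = default_dataset
        artifact, _, _ = built_scale
        ok = tot = 0
        for _, idx in tensor.series().items():
            d = np.diff(artifact.training_stages[idx])
            ok += int((d >= 0).sum())
            tot += d.size
        assert ok / tot >= 0.9

    def test_defaults_match_method(self, built_scale):
        artifact, _, _ = built_scale
        cfg = ScaleConfig()
        assert artifact.n_marks == 30
        assert artifact.control_points.shape[0] == cfg.k == 5
        assert cfg.span == 0.75

    def test_gene_permutation_invariance(self, default_dataset):
        tensor, _ = default_dataset
        rng = np.random.default_rng(0)
        core = list(rng.permutation(tensor.gene_ids)[:300])
        a1, _ = build_scale(tensor, core)
        perm = list(rng.permutation(core))
        a2, _ = build_scale(tensor, perm)
        assert np.allclose(a1.marks, a2.marks, atol=1e-8)
        assert np.array_equal(a1.training_stages, a2.training_stages)

    def test_orientation_stage_one_is_early(self, default_dataset, built_scale):
        tensor, _ = default_dataset
        artifact, _, _ = built_scale
        tps = tensor.timepoints()
        early = tps[artifact.training_stages <= 5].mean()
        late = tps[artifact.training_stages >= 25].mean()
        assert early < late

    def test_end_to_end_latent_recovery(self, default_dataset, built_scale):
        tensor, truth = default_dataset
        artifact, _, _ = built_scale
        rho = spearmanr(artifact.training_stages, truth.latent).statistic
        assert rho >= 0.95
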