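"""Domain-type validation and file round trips."""

import json

import numpy as np
import pytest

from molstage import (
    ExpressionTensor,
    GenePanel,
    SampleMeta,
    ScaleArtifact,
    read_expression,
    read_scale,
    write_expression,
    write_scale,
)
from molstage.io import read_panel, write_panel
from molstage.scale import place_marks
from molstage.types import bezier_point

from conftest import make_tensor


def _write_toy_files(tmp_path, values, samples, genes, meta_rows):
    expr = tmp_path / "expr.tsv"
    lines = ["gene_id\t" + "\t".join(samples)]
    for g, row in zip(genes, values):
        lines.append(g + "\t" + "\t".join(str(v) for v in row))
    expr.write_text("\n".join(lines) + "\n")
    meta = tmp_path / "meta.tsv"
    header = "sample\tcultivar\tvintage\ttimepoint\treplicate"
    meta.write_text("\n".join([header] + meta_rows) + "\n")
    return expr, meta


def _toy_meta_rows(samples):
    rows = []
    for s in samples:
        cult, rep = s.split("_")
        rows.append(f"{s}\t{cult}\tY1\t1\t{rep[1:]}")
    return rows


class TestReadExpression:
    def test_two_conditions_three_replicates(self, tmp_path):
        samples = ["A_r1", "A_r2", "A_r3", "B_r1", "B_r2", "B_r3"]
        vals = np.arange(24).reshape(4, 6).astype(float)
        expr, meta = _write_toy_files(
            tmp_path, vals, samples, list("wxyz"), _toy_meta_rows(samples)
        )
        t = read_expression(expr, meta)
        assert t.n_conditions == 2 and t.n_replicates == 3 and t.n_genes == 4
        # normalization is a pure permutation: the value multiset survives
        assert sorted(t.values.ravel()) == sorted(vals.ravel())

    def test_negative_value_rejected(self, tmp_path):
        samples = ["A_r1", "A_r2", "A_r3"]
        vals = [[1.0, 2.0, -1.0]]
        expr, meta = _write_toy_files(tmp_path, vals, samples, ["g"], _toy_meta_rows(samples))
        with pytest.raises(ValueError, match="negative expression"):
            read_expression(expr, meta)

    def test_non_contiguous_timepoints_rejected(self, tmp_path):
        samples = ["A_r1", "A_r2"]
        expr, _ = _write_toy_files(tmp_path, [[1.0, 2.0]], samples, ["g"], [])
        meta = tmp_path / "meta.tsv"
        meta.write_text(
            "sample\tcultivar\tvintage\ttimepoint\treplicate\n"
            "A_r1\tA\tY1\t1\t1\nA_r2\tA\tY1\t3\t1\n"
        )
        with pytest.raises(ValueError, match="non-contiguous timepoints"):
            read_expression(expr, meta)

    def test_sample_missing_from_metadata(self, tmp_path):
        samples = ["A_r1", "A_r2", "A_r3"]
        expr, meta = _write_toy_files(
            tmp_path, [[1.0, 2.0, 3.0]], samples, ["g"], _toy_meta_rows(samples[:2])
        )
        with pytest.raises(ValueError, match="absent from metadata"):
            read_expression(expr, meta)

    def test_unequal_replicate_counts(self, tmp_path):
        samples = ["A_r1", "A_r2", "A_r3", "B_r1"]
        rows = _toy_meta_rows(samples)
        expr, meta = _write_toy_files(tmp_path, [[1.0, 2, 3, 4]], samples, ["g"], rows)
        with pytest.raises(ValueError, match="replicate counts"):
            read_expression(expr, meta)

    def test_duplicate_gene_ids(self, tmp_path):
        samples = ["A_r1", "A_r2", "A_r3"]
        expr, meta = _write_toy_files(
            tmp_path, [[1.0, 2, 3], [4.0, 5, 6]], samples, ["g", "g"],
            _toy_meta_rows(samples),
        )
        with pytest.raises(ValueError, match="duplicate gene ids"):
            read_expression(expr, meta)

    def test_round_trip_preserves_values(self, tmp_path):
        prof = {("A", "Y1"): np.random.default_rng(3).uniform(0, 50, (4, 5))}
        t = make_tensor(prof, noise=0.2, seed=4)
        write_expression(t, tmp_path / "e.tsv", tmp_path / "m.tsv")
        t2 = read_expression(tmp_path / "e.tsv", tmp_path / "m.tsv")
        assert np.array_equal(t.values, t2.values)
        assert t.gene_ids == t2.gene_ids


class TestTensorInvariants:
    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite|non-numeric"):
            ExpressionTensor(
                np.full((1, 3, 1), np.nan), ["g"],
                [SampleMeta("c", "A", "Y1", 1)], 3,
            )

    def test_timepoint_must_be_positive(self):
        with pytest.raises(ValueError):
            SampleMeta("c", "A", "Y1", 0)


def _toy_artifact(n_genes=6, n_marks=30):
    rng = np.random.default_rng(0)
    A = np.linalg.qr(rng.normal(size=(n_genes, 3)))[0]
    cp = np.column_stack([np.linspace(0, 29, 5), np.zeros(5), np.zeros(5)])
    marks, params = place_marks(cp, n_marks)
    return ScaleArtifact(
        core_gene_ids=[f"g{i}" for i in range(n_genes)],
        column_means=rng.normal(size=n_genes),
        column_sds=rng.uniform(0.5, 2, n_genes),
        eigenvectors=A,
        pc_indices=[1, 2, 5],
        control_points=cp,
        marks=marks,
        mark_params=params,
        n_marks=n_marks,
        explained_variance_pct=np.array([53.6, 15.8, 4.2]),
        training_condition_ids=["c1", "c2"],
        training_stages=np.array([1, 30]),
    )


class TestScaleArtifact:
    def test_round_trip_bit_exact(self, tmp_path):
        a = _toy_artifact()
        write_scale(a, tmp_path / "s.json")
        b = read_scale(tmp_path / "s.json")
        assert a == b

    def test_default_mark_count_serialized(self, tmp_path):
        a = _toy_artifact()
        write_scale(a, tmp_path / "s.json")
        doc = json.loads((tmp_path / "s.json").read_text())
        assert doc["n_marks"] == 30

    def test_truncated_file_rejected(self, tmp_path):
        a = _toy_artifact()
        write_scale(a, tmp_path / "s.json")
        text = (tmp_path / "s.json").read_text()
        (tmp_path / "s.json").write_text(text[: len(text) // 2])
        with pytest.raises(ValueError, match="corrupt scale artifact"):
            read_scale(tmp_path / "s.json")

    def test_checksum_tamper_rejected(self, tmp_path):
        a = _toy_artifact()
        write_scale(a, tmp_path / "s.json")
        doc = json.loads((tmp_path / "s.json").read_text())
        doc["core_gene_ids"][0] = "tampered"
        (tmp_path / "s.json").write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="checksum"):
            read_scale(tmp_path / "s.json")

    def test_version_mismatch_rejected(self, tmp_path):
        a = _toy_artifact()
        write_scale(a, tmp_path / "s.json")
        doc = json.loads((tmp_path / "s.json").read_text())
        doc["version"] = 99
        (tmp_path / "s.json").write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version mismatch"):
            read_scale(tmp_path / "s.json")

    def test_orthonormality_enforced(self):
        a = _toy_artifact()
        with pytest.raises(ValueError, match="orthonormal"):
            ScaleArtifact(
                a.core_gene_ids, a.column_means, a.column_sds,
                a.eigenvectors * 2.0, a.pc_indices, a.control_points,
                a.marks, a.mark_params, a.n_marks,
            )

    def test_marks_must_lie_on_curve(self):
        a = _toy_artifact()
        marks = a.marks.copy()
        marks[3, 1] += 1e-3
        with pytest.raises(ValueError, match="marks"):
            ScaleArtifact(
                a.core_gene_ids, a.column_means, a.column_sds,
                a.eigenvectors, a.pc_indices, a.control_points,
                marks, a.mark_params, a.n_marks,
            )

    def test_mark_params_evaluate_onto_marks(self):
        a = _toy_artifact()
        pts = bezier_point(a.control_points, a.mark_params)
        assert np.allclose(pts, a.marks, atol=1e-9)


class TestGenePanel:
    def test_round_trip(self, tmp_path):
        p = GenePanel(["a", "b"], np.array([[1, -1, 1], [-1, 1, 1]]), "test")
        write_panel(p, tmp_path / "p.json")
        q = read_panel(tmp_path / "p.json")
        assert p.gene_ids == q.gene_ids and np.array_equal(p.signs, q.signs)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenePanel(["a", "a"], np.array([[1, 1, 1], [1, 1, 1]]))
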