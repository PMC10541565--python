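"""Core domain types for molecular phenology staging.

The central container is :class:`ExpressionTensor`: replicate-level gene
expression ``x[j, r, i]`` indexed by experimental condition *j* (one
cultivar x vintage x timepoint combination), replicate *r* and gene *i*,
in RPKM-like non-negative units.  A frozen scale is carried around as a
:class:`ScaleArtifact`; reduced marker panels as :class:`GenePanel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SampleMeta",
    "ExpressionTensor",
    "GenePanel",
    "ScaleArtifact",
    "ProjectionResult",
    "bezier_point",
]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one experimental condition (cultivar x vintage x timepoint)."""

    condition_id: str
    cultivar: str
    vintage: str
    timepoint: int
    doy: int | None = None
    daf: int | None = None

    def __post_init__(self) -> None:
        if self.timepoint < 1:
            raise ValueError(f"timepoint must be >= 1, got {self.timepoint}")


@dataclass
class ExpressionTensor:
    """Replicate-level expression values with per-condition metadata.

    Parameters
    ----------
    values
        Array of shape ``(n_conditions, n_replicates, n_genes)``,
        non-negative and finite.
    gene_ids
        Ordered unique gene identifiers (length ``n_genes``).
    meta
        One :class:`SampleMeta` per condition, in row order of ``values``.
    """

    values: np.ndarray
    gene_ids: list[str]
    meta: list[SampleMeta]
    n_replicates: int = 3

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 3:
            raise ValueError("values must be (conditions, replicates, genes)")
        if self.values.shape != (len(self.meta), self.n_replicates, len(self.gene_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"({len(self.meta)}, {self.n_replicates}, {len(self.gene_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-numeric or non-finite expression value")
        if np.any(self.values < 0):
            raise ValueError("negative expression value")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        self._validate_series()

    def _validate_series(self) -> None:
        for key, idx in self.series().items():
            tps = [self.meta[j].timepoint for j in idx]
            if sorted(tps) != list(range(1, len(tps) + 1)):
                raise ValueError(
                    f"non-contiguous timepoints {sorted(tps)} in series {key}"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[2]

    def series(self) -> dict[tuple[str, str], np.ndarray]:
        """Condition indices per cultivar x vintage series, ordered by timepoint."""
        out: dict[tuple[str, str], list[int]] = {}
        for j, m in enumerate(self.meta):
            out.setdefault((m.cultivar, m.vintage), []).append(j)
        return {
            key: np.asarray(sorted(idx, key=lambda j: self.meta[j].timepoint))
            for key, idx in out.items()
        }

    def timepoints(self) -> np.ndarray:
        return np.asarray([m.timepoint for m in self.meta], dtype=float)

    def condition_ids(self) -> list[str]:
        return [m.condition_id for m in self.meta]

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes absent from tensor: {missing[:5]}")
        return np.asarray([pos[g] for g in gene_ids])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionTensor":
        idx = self.gene_index(gene_ids)
        return ExpressionTensor(
            self.values[:, :, idx], list(gene_ids), list(self.meta), self.n_replicates
        )

    def replicate_means(self) -> np.ndarray:
        """Matrix m[j, i] of replicate-averaged expression (conditions x genes)."""
        return self.values.mean(axis=1)


@dataclass
class GenePanel:
    """Ordered marker-gene subset of a scale's core set, with loading signs.

    ``signs`` has one row per gene and one column per selected principal
    component, entries in {-1, +1}: the sign of the gene's eigenvector
    coefficient, used by the reduced-panel imputation rule.

    ``pools`` (optional) records which component x sign pool each gene was
    selected for, as an (n_genes, 2) array of (component index 0..2,
    sign +-1).  Structured panels impute each component's missing genes
    from that component's own pools; unstructured panels fall back to
    splitting all observed genes by eigenvector-coefficient sign.
    """

    gene_ids: list[str]
    signs: np.ndarray
    provenance: str = ""
    pools: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.signs = np.asarray(self.signs, dtype=int)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in panel")
        if self.signs.shape[0] != len(self.gene_ids):
            raise ValueError("signs row count must match gene count")
        if not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("panel signs must be -1 or +1")
        if self.pools is not None:
            self.pools = np.asarray(self.pools, dtype=int)
            if self.pools.shape != (len(self.gene_ids), 2):
                raise ValueError("pools must be (n_genes, 2)")
            if not np.all(np.isin(self.pools[:, 0], (0, 1, 2))):
                raise ValueError("pool component index must be 0..2")
            if not np.all(np.isin(self.pools[:, 1], (-1, 1))):
                raise ValueError("pool sign must be -1 or +1")

    def subset(self, gene_ids: Sequence[str]) -> "GenePanel":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.asarray([pos[g] for g in gene_ids])
        return GenePanel(
            list(gene_ids), self.signs[idx], self.provenance,
            None if self.pools is None else self.pools[idx],
        )


def bezier_point(control_points: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate a Bezier curve with k control points at parameters t in [0, 1]."""
    from scipy.special import comb

    cp = np.asarray(control_points, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k = cp.shape[0]
    n = k - 1
    i = np.arange(k)
    basis = comb(n, i)[None, :] * t[:, None] ** i * (1.0 - t[:, None]) ** (n - i)
    return basis @ cp


@dataclass
class ScaleArtifact:
    """A frozen molecular phenology scale.

    Holds everything needed to project new samples: the core gene list F,
    the training column means/sds, the eigenvector matrix A (|F| x 3) of the
    three stage-associated principal components, the Bezier control points
    and the ``n_marks`` equal-arc-length stage marks along the curve.
    """

    core_gene_ids: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray
    eigenvectors: np.ndarray
    pc_indices: list[int]
    control_points: np.ndarray
    marks: np.ndarray
    mark_params: np.ndarray
    n_marks: int = 30
    explained_variance_pct: np.ndarray | None = None
    training_condition_ids: list[str] = field(default_factory=list)
    training_stages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.core_gene_ids = list(self.core_gene_ids)
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.column_sds = np.asarray(self.column_sds, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.marks = np.asarray(self.marks, dtype=float)
        self.mark_params = np.asarray(self.mark_params, dtype=float)
        if self.explained_variance_pct is not None:
            self.explained_variance_pct = np.asarray(
                self.explained_variance_pct, dtype=float
            )
        if self.training_stages is not None:
            self.training_stages = np.asarray(self.training_stages, dtype=int)
        self.validate()

    def validate(self) -> None:
        nf = len(self.core_gene_ids)
        if self.eigenvectors.shape != (nf, 3):
            raise ValueError("eigenvector matrix must be |F| x 3")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(3), atol=1e-8):
            raise ValueError("eigenvector columns not orthonormal")
        if self.column_means.shape != (nf,) or self.column_sds.shape != (nf,):
            raise ValueError("column means/sds must have one entry per core gene")
        if np.any(self.column_sds <= 0):
            raise ValueError("column sds must be strictly positive")
        if self.n_marks < 2:
            raise ValueError("n_marks must be >= 2")
        if self.marks.shape != (self.n_marks, 3):
            raise ValueError("marks must be n_marks x 3")
        on_curve = bezier_point(self.control_points, self.mark_params)
        if np.max(np.linalg.norm(on_curve - self.marks, axis=1)) > 1e-6:
            raise ValueError("marks do not lie on the Bezier curve")

    def numeric_fields(self) -> dict[str, np.ndarray]:
        out = {
            "column_means": self.column_means,
            "column_sds": self.column_sds,
            "eigenvectors": self.eigenvectors,
            "control_points": self.control_points,
            "marks": self.marks,
            "mark_params": self.mark_params,
        }
        if self.explained_variance_pct is not None:
            out["explained_variance_pct"] = self.explained_variance_pct
        if self.training_stages is not None:
            out["training_stages"] = self.training_stages
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScaleArtifact):
            return NotImplemented
        if (
            self.core_gene_ids != other.core_gene_ids
            or self.pc_indices != other.pc_indices
            or self.n_marks != other.n_marks
            or self.training_condition_ids != other.training_condition_ids
        ):
            return False
        a, b = self.numeric_fields(), other.numeric_fields()
        if a.keys() != b.keys():
            return False
        return all(np.array_equal(a[k], b[k]) for k in a)


@dataclass
class ProjectionResult:
    """Per-sample stage assignments from projecting expression onto a scale."""

    condition_ids: list[str]
    stage: np.ndarray
    coords: np.ndarray
    mark_distance: np.ndarray
    panel_mode: str = "full"

    def __post_init__(self) -> None:
        self.stage = np.asarray(self.stage, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.mark_distance = np.asarray(self.mark_distance, dtype=float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "condition_id": self.condition_ids,
                "stage": self.stage,
                "pc_a": self.coords[:, 0],
                "pc_b": self.coords[:, 1],
                "pc_c": self.coords[:, 2],
                "distance": self.mark_distance,
            }
        )
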