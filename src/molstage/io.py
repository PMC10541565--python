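"""Readers and writers: TSV expression matrices with sample metadata,
JSON scale artifacts (full decimal precision, checksummed gene list) and
panel files.

Expression files are tab-separated, UTF-8, '.' decimal, genes in rows
with the gene id in the first column and one sample per remaining
column.  The metadata file maps each sample column to (cultivar, vintage,
timepoint, replicate) plus optional day-of-year / days-after-flowering.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ExpressionTensor, GenePanel, SampleMeta, ScaleArtifact

__all__ = [
    "read_expression",
    "write_expression",
    "read_scale",
    "write_scale",
    "read_panel",
    "write_panel",
]

SCALE_FORMAT_VERSION = 1


def _gene_checksum(gene_ids: list[str]) -> str:
    return hashlib.sha256("\n".join(gene_ids).encode()).hexdigest()[:16]


def read_expression(path: str | Path, meta_path: str | Path) -> ExpressionTensor:
    """Read a genes x samples TSV plus its sample metadata into a tensor.

    Samples are normalized to (cultivar, vintage, timepoint, replicate)
    order; every condition must have the same replicate count.
    """
    expr = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()][0]
        raise ValueError(f"duplicate gene ids (e.g. {dup!r})")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"cultivar": str, "vintage": str})
    required = {"sample", "cultivar", "vintage", "timepoint", "replicate"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    meta = meta.set_index("sample")
    unknown = [s for s in expr.columns if s not in meta.index]
    if unknown:
        raise ValueError(f"samples absent from metadata: {unknown[:5]}")
    try:
        values = expr.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite expression value")
    if np.any(values < 0):
        raise ValueError("negative expression value")

    meta = meta.loc[list(expr.columns)]
    groups: dict[tuple, list[str]] = {}
    for sample, row in meta.iterrows():
        key = (str(row["cultivar"]), str(row["vintage"]), int(row["timepoint"]))
        groups.setdefault(key, []).append((int(row["replicate"]), sample))
    counts = {len(v) for v in groups.values()}
    if len(counts) != 1:
        raise ValueError(f"unequal replicate counts across conditions: {sorted(counts)}")
    n_rep = counts.pop()

    sample_pos = {s: i for i, s in enumerate(expr.columns)}
    metas: list[SampleMeta] = []
    blocks = []
    for key in sorted(groups):
        cultivar, vintage, tp = key
        reps = sorted(groups[key])
        cols = [sample_pos[s] for _, s in reps]
        blocks.append(values[:, cols].T)  # replicates x genes
        row0 = meta.loc[reps[0][1]]
        metas.append(SampleMeta(
            condition_id=f"{cultivar}_{vintage}_T{tp:02d}",
            cultivar=cultivar, vintage=vintage, timepoint=tp,
            doy=int(row0["doy"]) if "doy" in meta.columns and pd.notna(row0.get("doy")) else None,
            daf=int(row0["daf"]) if "daf" in meta.columns and pd.notna(row0.get("daf")) else None,
        ))
    tensor_values = np.stack(blocks)
    return ExpressionTensor(tensor_values, list(expr.index.astype(str)), metas, n_rep)


def write_expression(tensor: ExpressionTensor, path: str | Path,
                     meta_path: str | Path) -> None:
    """Write a tensor back to the TSV expression + metadata pair."""
    cols, meta_rows = [], []
    data = []
    for j, m in enumerate(tensor.meta):
        for r in range(tensor.n_replicates):
            name = f"{m.condition_id}_R{r + 1}"
            cols.append(name)
            data.append(tensor.values[j, r])
            meta_rows.append({
                "sample": name, "cultivar": m.cultivar, "vintage": m.vintage,
                "timepoint": m.timepoint, "replicate": r + 1,
                "doy": m.doy if m.doy is not None else "",
                "daf": m.daf if m.daf is not None else "",
            })
    frame = pd.DataFrame(np.asarray(data).T, index=tensor.gene_ids, columns=cols)
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)


def write_scale(artifact: ScaleArtifact, path: str | Path) -> None:
    """Serialize a scale artifact to JSON with full decimal precision."""
    doc = {
        "format": "molstage-scale",
        "version": SCALE_FORMAT_VERSION,
        "gene_checksum": _gene_checksum(artifact.core_gene_ids),
        "core_gene_ids": artifact.core_gene_ids,
        "pc_indices": list(artifact.pc_indices),
        "n_marks": artifact.n_marks,
        "training_condition_ids": artifact.training_condition_ids,
    }
    for name, arr in artifact.numeric_fields().items():
        doc[name] = np.asarray(arr).tolist()
    Path(path).write_text(json.dumps(doc, indent=1))


def read_scale(path: str | Path) -> ScaleArtifact:
    """Load and validate a scale artifact written by :func:`write_scale`."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupt scale artifact: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "molstage-scale":
        raise ValueError("corrupt scale artifact: not a scale file")
    if doc.get("version") != SCALE_FORMAT_VERSION:
        raise ValueError(
            f"scale artifact version mismatch: {doc.get('version')} "
            f"(supported: {SCALE_FORMAT_VERSION})"
        )
    try:
        genes = list(doc["core_gene_ids"])
        if doc["gene_checksum"] != _gene_checksum(genes):
            raise ValueError("scale artifact gene list checksum failure")
        return ScaleArtifact(
            core_gene_ids=genes,
            column_means=np.asarray(doc["column_means"]),
            column_sds=np.asarray(doc["column_sds"]),
            eigenvectors=np.asarray(doc["eigenvectors"]),
            pc_indices=list(doc["pc_indices"]),
            control_points=np.asarray(doc["control_points"]),
            marks=np.asarray(doc["marks"]),
            mark_params=np.asarray(doc["mark_params"]),
            n_marks=int(doc["n_marks"]),
            explained_variance_pct=(
                np.asarray(doc["explained_variance_pct"])
                if "explained_variance_pct" in doc else None
            ),
            training_condition_ids=list(doc.get("training_condition_ids", [])),
            training_stages=(
                np.asarray(doc["training_stages"])
                if "training_stages" in doc else None
            ),
        )
    except KeyError as exc:
        raise ValueError(f"corrupt scale artifact: missing field {exc}") from exc


def write_panel(panel: GenePanel, path: str | Path) -> None:
    doc = {
        "format": "molstage-panel",
        "gene_ids": panel.gene_ids,
        "signs": panel.signs.tolist(),
        "provenance": panel.provenance,
    }
    if panel.pools is not None:
        doc["pools"] = panel.pools.tolist()
    Path(path).write_text(json.dumps(doc, indent=1))


def read_panel(path: str | Path) -> GenePanel:
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupt panel file: {exc}") from exc
    if doc.get("format") != "molstage-panel":
        raise ValueError("corrupt panel file")
    return GenePanel(
        gene_ids=list(doc["gene_ids"]),
        signs=np.asarray(doc["signs"]),
        provenance=doc.get("provenance", ""),
        pools=np.asarray(doc["pools"]) if "pools" in doc else None,
    )
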