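"""Readers and writers for the package's on-disk formats.

Expression matrices travel as TSV (first column = gene id, header = sample
ids) or as MatrixMarket triplet files with ``genes.tsv`` / ``barcodes.tsv``
companions; signatures as GMT; assignments and clinical tables as TSV.
Write-then-read is the identity for every type, including unit tags and
class order.
"""

from __future__ import annotations

import json
import os
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    ClinicalTable,
    ExpressionMatrix,
    MultiLabelAssignment,
    SignatureSet,
    ValidationError,
    assignments_to_frame,
)


class ParseError(ValueError):
    """Raised when a file cannot be parsed; names the offending line."""


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(
    path: str,
    format: str = "tsv",
    unit: str = "raw_counts",
    genes_path: Optional[str] = None,
    samples_path: Optional[str] = None,
) -> ExpressionMatrix:
    """Read a gene-by-sample matrix from TSV or MatrixMarket triplet format.

    For ``mtx-triplet`` the gene and sample (barcode) identifier files default
    to ``genes.tsv`` and ``barcodes.tsv`` next to the matrix file.
    """
    if format == "tsv":
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pandas reports the offending line itself
            raise ParseError(f"cannot parse expression TSV {path}: {exc}") from exc
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        if frame.isna().any().any():
            bad = frame.index[frame.isna().any(axis=1)][0]
            raise ValidationError(f"missing value in gene row {bad!r}; imputation is not supported")
        return ExpressionMatrix(frame, unit)
    if format == "mtx-triplet":
        folder = os.path.dirname(os.path.abspath(path))
        genes_path = genes_path or os.path.join(folder, "genes.tsv")
        samples_path = samples_path or os.path.join(folder, "barcodes.tsv")
        for p in (genes_path, samples_path):
            if not os.path.exists(p):
                raise FileNotFoundError(f"companion identifier file missing: {p}")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        samples = pd.read_csv(samples_path, sep="\t", header=None)[0].astype(str).tolist()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"matrix shape {dense.shape} does not match {len(genes)} genes x {len(samples)} samples"
            )
        return ExpressionMatrix(pd.DataFrame(dense, index=genes, columns=samples), unit)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx-triplet'")


def write_expression(matrix: ExpressionMatrix, path: str, format: str = "tsv") -> None:
    if format == "tsv":
        matrix.data.to_csv(path, sep="\t")
    elif format == "mtx-triplet":
        folder = os.path.dirname(os.path.abspath(path))
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.values))
        pd.Series(matrix.gene_ids).to_csv(
            os.path.join(folder, "genes.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(matrix.sample_ids).to_csv(
            os.path.join(folder, "barcodes.tsv"), sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# signatures (GMT)


def read_signature(path: str) -> SignatureSet:
    """Read a GMT file: one line per class, ``name<TAB>description<TAB>gene...``."""
    class_names: List[str] = []
    markers = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected class, description and >=1 gene, got {len(fields)} fields"
                )
            name = fields[0]
            if name in markers:
                raise ValidationError(f"{path}:{lineno}: duplicate class name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: class {name!r} has an empty gene list")
            class_names.append(name)
            markers[name] = tuple(genes)
    if not class_names:
        raise ParseError(f"{path}: empty GMT file")
    return SignatureSet(tuple(class_names), markers)


def write_signature(signature: SignatureSet, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name in signature.class_names:
            fh.write("\t".join([name, "na", *signature.markers[name]]) + "\n")


# ---------------------------------------------------------------------------
# assignments


def write_assignments(
    assignments: Sequence[MultiLabelAssignment],
    class_names: Sequence[str],
    path: str,
) -> None:
    """Write one row per sample: id, primary (or NC), secondary set, per-class score/FDR."""
    frame = assignments_to_frame(assignments, class_names)
    frame.to_csv(path, sep="\t")


def read_assignments(path: str) -> List[MultiLabelAssignment]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    score_cols = [c for c in frame.columns if c.startswith("score_")]
    class_names = [c[len("score_"):] for c in score_cols]
    out = []
    for sid, row in frame.iterrows():
        secondary = frozenset(str(row["secondary"]).split(";")) if pd.notna(row["secondary"]) and str(row["secondary"]) else frozenset()
        scores = {k: float(row[f"score_{k}"]) for k in class_names} if class_names else None
        fdr = (
            {k: float(row[f"fdr_{k}"]) for k in class_names}
            if class_names and all(f"fdr_{k}" in row for k in class_names)
            else None
        )
        if scores and any(np.isnan(v) for v in scores.values()):
            scores, fdr = None, None
        out.append(
            MultiLabelAssignment(
                sample_id=str(sid),
                primary=str(row["primary"]),
                secondary=secondary,
                scores=scores,
                fdr=fdr,
            )
        )
    return out


# ---------------------------------------------------------------------------
# clinical tables and metadata


def read_clinical(path: str) -> ClinicalTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    if "event" in frame.columns:
        frame["event"] = frame["event"].astype(bool)
    return ClinicalTable(frame)


def write_clinical(table: ClinicalTable, path: str) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_meta(path: str) -> pd.DataFrame:
    """Sample metadata TSV with columns sample_id, patient[, replica_group]."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in frame.columns or "patient" not in frame.columns:
        raise ParseError(f"{path}: expected columns sample_id and patient")
    return frame


def write_json(obj, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
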