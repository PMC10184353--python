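"""Bulk and single-cell preprocessing: sequencing-quality filters,
patient-level deduplication, CPM normalization, cell QC, pseudo-bulk
aggregation, and restriction to the signature feature space.

All filters only drop rows or columns; surviving values are never modified,
so every filter is idempotent.
"""

from __future__ import annotations

import logging
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, SignatureSet, ValidationError

logger = logging.getLogger(__name__)


def _require_unit(matrix: ExpressionMatrix, unit: str, op: str) -> None:
    if matrix.unit != unit:
        raise ValidationError(f"{op} requires a {unit} matrix, got {matrix.unit}")


def filter_top5_dominance(matrix: ExpressionMatrix, fraction: float = 0.2) -> ExpressionMatrix:
    """Drop samples whose 5 highest gene counts account for >= ``fraction`` of
    the sample's total raw counts — a mark of shallow, poorly complex
    libraries at the sequencing depth used.
    """
    _require_unit(matrix, "raw_counts", "top-5 dominance filter")
    if matrix.n_genes < 5:
        raise ValidationError("top-5 dominance is undefined with fewer than 5 genes")
    values = matrix.values
    totals = values.sum(axis=0)
    # top-5 sum per sample; only the sum matters, so ties at rank 5 are moot
    top5 = np.sort(values, axis=0)[-5:, :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(totals > 0, top5 / np.where(totals > 0, totals, 1.0), 1.0)
    keep = share < fraction
    dropped = [s for s, k in zip(matrix.sample_ids, keep) if not k]
    if dropped:
        logger.info("top-5 dominance filter dropped %d samples: %s", len(dropped), dropped[:10])
    return ExpressionMatrix(matrix.data.loc[:, keep], matrix.unit)


def dedupe_by_patient(matrix: ExpressionMatrix, meta: pd.DataFrame) -> ExpressionMatrix:
    """Keep one sample per patient (the one with the most raw counts),
    first collapsing technical replicas by the same rule.

    ``meta`` needs columns ``sample_id`` and ``patient`` and may carry
    ``replica_group``. Ties break to the lexicographically smaller sample id.
    """
    _require_unit(matrix, "raw_counts", "patient deduplication")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing[:5]}")
    totals = pd.Series(matrix.values.sum(axis=0), index=matrix.sample_ids)

    def best(sample_ids) -> str:
        sub = totals.loc[list(sample_ids)]
        top = sub[sub == sub.max()].index
        return sorted(top)[0]

    survivors = list(matrix.sample_ids)
    if "replica_group" in meta.columns and meta["replica_group"].notna().any():
        kept = []
        groups = meta.loc[survivors].groupby("replica_group", dropna=False, sort=False)
        for key, sub in groups:
            if pd.isna(key):
                kept.extend(sub.index)
            else:
                kept.append(best(sub.index))
        survivors = [s for s in matrix.sample_ids if s in set(kept)]
    kept = set()
    for _, sub in meta.loc[survivors].groupby("patient", sort=False):
        kept.add(best(sub.index))
    survivors = [s for s in survivors if s in kept]
    return matrix.select_samples(survivors)


def cpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: scale each sample to a library size of 10^6."""
    _require_unit(matrix, "raw_counts", "CPM normalization")
    totals = matrix.values.sum(axis=0)
    zero = [s for s, t in zip(matrix.sample_ids, totals) if t == 0]
    if zero:
        raise ValidationError(f"cannot CPM-normalize zero-total samples: {zero[:5]}")
    cpm = matrix.data / totals * 1e6
    return ExpressionMatrix(cpm, "cpm")


def filter_cells_qc(
    matrix: ExpressionMatrix, min_genes: int = 1000, min_reads: int = 4
) -> ExpressionMatrix:
    """Remove low-quality cells with fewer than ``min_genes`` genes supported
    by at least ``min_reads`` reads (strict: a cell needs >= min_genes such
    genes to survive).
    """
    _require_unit(matrix, "raw_counts", "cell QC")
    supported = (matrix.values >= min_reads).sum(axis=0)
    keep = supported >= min_genes
    if not keep.any():
        logger.warning("cell QC removed every cell (min_genes=%d, min_reads=%d)", min_genes, min_reads)
    return ExpressionMatrix(matrix.data.loc[:, keep], matrix.unit)


def make_pseudobulk(matrix: ExpressionMatrix, grouping: Mapping[str, str]) -> ExpressionMatrix:
    """Sum the counts of all cells belonging to the same group (patient),
    yielding one pseudo-bulk column per group. Total counts are conserved
    within each group.
    """
    _require_unit(matrix, "raw_counts", "pseudo-bulk aggregation")
    missing = [c for c in matrix.sample_ids if c not in grouping]
    if missing:
        raise ValidationError(f"cells missing from grouping: {missing[:5]}")
    groups = pd.Series({c: grouping[c] for c in matrix.sample_ids})
    # preserve first-appearance group order
    order = list(dict.fromkeys(groups[matrix.sample_ids]))
    summed = matrix.data.T.groupby(groups, sort=False).sum().T
    summed = summed.loc[:, order]
    return ExpressionMatrix(summed, "raw_counts")


def restrict_to_signature(
    matrix: ExpressionMatrix, signature: SignatureSet
) -> ExpressionMatrix:
    """Keep only the signature's feature-space genes present in the matrix,
    in signature order. The retained fraction is logged; see
    :func:`signature_coverage` for the number itself.
    """
    space = signature.feature_space
    present = [g for g in space if g in matrix.data.index]
    if not present:
        raise ValidationError("matrix shares no genes with the signature feature space")
    frac = len(present) / len(space)
    logger.info("signature restriction retained %d/%d genes (%.1f%%)", len(present), len(space), 100 * frac)
    return matrix.select_genes(present)


def signature_coverage(matrix: ExpressionMatrix, signature: SignatureSet) -> float:
    """Fraction of signature feature-space genes present in the matrix."""
    space = signature.feature_space
    present = sum(1 for g in space if g in matrix.data.index)
    return present / len(space)


def restrict_to_genes(matrix: ExpressionMatrix, genes) -> ExpressionMatrix:
    """Generic intersection restriction (e.g., harmonizing cohorts to a
    common gene set), preserving the order of ``genes``."""
    present = [g for g in genes if g in matrix.data.index]
    if not present:
        raise ValidationError("no overlap with the requested gene set")
    return matrix.select_genes(present)
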