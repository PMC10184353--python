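"""Nearest-template prediction (NTP) and its multi-label extension.

A sample's Z-scored profile over the signature feature space is compared to
one binary template per class (marker genes = 1, all other signature genes =
0) by cosine distance. Significance comes from a permutation null: templates
with the same marker count drawn uniformly at random within the feature
space. Per-sample p-values are Benjamini-Hochberg adjusted across the K
classes; the minimal-distance class becomes the primary call when its FDR
clears the threshold (default 0.2), and further significant classes whose
score s = 1 - d clears a class-specific 5th-percentile threshold become
secondary calls.

Numerical determinism
---------------------
For a binary template with m markers the cosine reduces to
``d = 1 - S/(||x|| * sqrt(m))`` where S is the sum of x over the marker
positions. All template sums are computed by sequential addition over
positions sorted in increasing index order, and the permutation tie count is
taken in sum space (``S_null >= S_obs``), so results are bit-reproducible and
independent of vectorization strategy. Each sample draws its permutations
from an RNG keyed on (seed, CRC32 of its id): permuting sample order permutes
the output identically.
"""

from __future__ import annotations

import logging
import math
import zlib
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import restrict_to_signature
from .types import (
    ExpressionMatrix,
    MultiLabelAssignment,
    NOT_CLASSIFIED,
    NTPResult,
    SignatureSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.2
DEFAULT_SECONDARY_PERCENTILE = 5.0
DEFAULT_N_PERM = 1000


# ---------------------------------------------------------------------------
# normalization


def zscore_by_gene(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Dataset-wide per-gene Z-score: each gene row is centred on its mean and
    scaled by its sample (n-1) standard deviation across all samples of the
    dataset. Constant genes map to all-zeros.

    Z-scoring is a cohort operation: it is undefined for a single sample
    (use the single-sample ML classifier for that case).
    """
    if matrix.unit == "zscore":
        raise ValidationError("matrix is already Z-scored")
    if matrix.n_samples < 2:
        raise ValidationError(
            "Z-score needs >= 2 samples; single samples require the single-sample (ML2CRIS) classifier"
        )
    values = matrix.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    centred = values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centred / np.where(sd > 0, sd, 1.0), 0.0)
    frame = pd.DataFrame(z, index=matrix.gene_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(frame, "zscore")


# ---------------------------------------------------------------------------
# distances


def template_matrix(signature: SignatureSet, genes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Binary membership templates (genes x classes) over the feature space
    (or over ``genes``, a subset of it, e.g. after single-cell dropout)."""
    genes = list(genes) if genes is not None else signature.feature_space
    frame = pd.DataFrame(0.0, index=genes, columns=list(signature.class_names))
    for name in signature.class_names:
        present = [g for g in signature.markers[name] if g in frame.index]
        if not present:
            raise ValidationError(f"class {name!r} has no marker genes in the matrix")
        frame.loc[present, name] = 1.0
    return frame


def cosine_distance(x: np.ndarray, t: np.ndarray) -> float:
    """General cosine distance ``1 - x.t/(||x|| ||t||)`` in [0, 2];
    an all-zero profile is at distance 1 from every template by convention."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.shape != t.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {t.shape}")
    nt = float(np.sqrt(np.dot(t, t)))
    if nt == 0.0:
        raise ValidationError("template vector must be nonzero")
    nx = float(np.sqrt(np.dot(x, x)))
    if nx == 0.0:
        return 1.0
    return 1.0 - float(np.dot(x, t)) / (nx * nt)


def _seq_sum(values: np.ndarray) -> float:
    """Strict left-to-right sequential float addition (np.cumsum is exact
    sequential accumulation; verified against a Python loop)."""
    if values.size == 0:
        return 0.0
    return float(np.cumsum(values)[-1])


def _template_sum(x: np.ndarray, positions: np.ndarray) -> float:
    """Canonical marker sum: sequential addition over ascending positions."""
    return _seq_sum(x[np.sort(positions)])


def _profile_sq_norm(x: np.ndarray) -> float:
    return _seq_sum(x * x)


def _binary_distance(s: float, sq_norm: float, m: int) -> float:
    # single sqrt of the product keeps d exactly 0 for a template profile
    if sq_norm == 0.0:
        return 1.0
    return 1.0 - s / math.sqrt(sq_norm * m)


def sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample RNG keyed on the sample id, making results invariant to
    sample order."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(sample_id.encode())]))


def permutation_pvalue(
    x: np.ndarray,
    marker_positions: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple:
    """Permutation p-value for one sample/class pair.

    Null templates keep the marker count but draw their positions uniformly
    at random (without replacement) within the feature space. The p-value is
    the ties-inclusive estimator ``(1 + #{d_null <= d_obs}) / (1 + n_perm)``,
    evaluated in marker-sum space.

    Returns ``(p, d_obs)``.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    n_genes = x.size
    m = int(marker_positions.size)
    if m >= n_genes:
        raise ValidationError("marker count must be smaller than the feature-space size")
    sq_norm = _profile_sq_norm(x)
    s_obs = _template_sum(x, marker_positions)
    d_obs = _binary_distance(s_obs, sq_norm, m)
    count = 0
    for _ in range(n_perm):
        pos = rng.choice(n_genes, size=m, replace=False)
        if _template_sum(x, pos) >= s_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return p, d_obs


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Canonical op sequence (stable sort; ``(p*n)/rank``; backward running
    minimum; clip at 1) so adjusted values are bit-reproducible.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = (ranked * n) / np.arange(1, n + 1, dtype=float)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# classification


def ntp_classify(
    matrix: ExpressionMatrix,
    signature: SignatureSet,
    n_perm: int = DEFAULT_N_PERM,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    seed: int = 0,
    fdr_scope: str = "sample",
) -> NTPResult:
    """Classify every sample of a Z-scored matrix against the signature.

    ``matrix`` must be Z-scored and restricted to (a subset of) the signature
    feature space. ``fdr_scope`` selects whether BH runs within each sample's
    K class p-values (default) or across the whole cohort x class matrix.
    """
    if matrix.unit != "zscore":
        raise ValidationError("ntp_classify expects a Z-scored matrix (run zscore_by_gene first)")
    if fdr_scope not in ("sample", "cohort"):
        raise ValidationError(f"unknown fdr_scope {fdr_scope!r}")
    genes = matrix.gene_ids
    extra = set(genes) - set(signature.feature_space)
    if extra:
        raise ValidationError(
            f"matrix contains genes outside the signature feature space: {sorted(extra)[:5]}"
        )
    templates = template_matrix(signature, genes)
    classes = list(signature.class_names)
    positions = {
        k: np.flatnonzero(templates[k].to_numpy() > 0) for k in classes
    }
    values = matrix.values
    samples = matrix.sample_ids
    dist = np.empty((len(samples), len(classes)))
    pval = np.empty_like(dist)
    for j, sid in enumerate(samples):
        x = values[:, j]
        rng = sample_rng(seed, sid)
        for i, k in enumerate(classes):
            p, d = permutation_pvalue(x, positions[k], n_perm, rng)
            pval[j, i] = p
            dist[j, i] = d
    if fdr_scope == "sample":
        fdr = np.vstack([bh_adjust(pval[j]) for j in range(len(samples))])
    else:
        fdr = bh_adjust(pval.ravel()).reshape(pval.shape)
    primary = []
    for j in range(len(samples)):
        best = int(np.argmin(dist[j]))
        primary.append(classes[best] if fdr[j, best] < fdr_threshold else NOT_CLASSIFIED)
    index = pd.Index(samples, name="sample_id")
    return NTPResult(
        distance=pd.DataFrame(dist, index=index, columns=classes),
        score=pd.DataFrame(1.0 - dist, index=index, columns=classes),
        pvalue=pd.DataFrame(pval, index=index, columns=classes),
        fdr=pd.DataFrame(fdr, index=index, columns=classes),
        primary=pd.Series(primary, index=index, name="primary"),
        fdr_threshold=fdr_threshold,
    )


def compute_secondary_thresholds(
    result: NTPResult, percentile: float = DEFAULT_SECONDARY_PERCENTILE
) -> Dict[str, float]:
    """Class-specific score thresholds: the 5th percentile (linear
    interpolation between order statistics) of each class's scores over the
    samples carrying it as primary. Classes with no primary samples get
    +inf, ruling out secondary calls for them."""
    if len(result.sample_ids) == 0:
        raise ValidationError("cannot compute thresholds from an empty result set")
    thresholds: Dict[str, float] = {}
    for k in result.class_names:
        mask = result.primary == k
        if not mask.any():
            logger.info("class %s has no primary samples; secondary calls disabled for it", k)
            thresholds[k] = math.inf
        else:
            thresholds[k] = float(np.percentile(result.score.loc[mask, k].to_numpy(), percentile))
    return thresholds


def multicris_assign(
    result: NTPResult,
    thresholds: Dict[str, float],
    fdr_threshold: Optional[float] = None,
) -> List[MultiLabelAssignment]:
    """Primary + secondary label sets: a secondary class must be significant
    (FDR below threshold) AND score at least the class threshold. NC samples
    get an empty label set."""
    thr = result.fdr_threshold if fdr_threshold is None else fdr_threshold
    out = []
    for sid in result.sample_ids:
        primary = result.primary.loc[sid]
        scores = result.score.loc[sid]
        fdr = result.fdr.loc[sid]
        if primary == NOT_CLASSIFIED:
            secondary: frozenset = frozenset()
        else:
            secondary = frozenset(
                k
                for k in result.class_names
                if k != primary and fdr[k] < thr and scores[k] >= thresholds.get(k, math.inf)
            )
        out.append(
            MultiLabelAssignment(
                sample_id=sid,
                primary=primary,
                secondary=secondary,
                scores=scores.to_dict(),
                fdr=fdr.to_dict(),
            )
        )
    return out


def classify_cohort(
    matrix: ExpressionMatrix,
    signature: SignatureSet,
    n_perm: int = DEFAULT_N_PERM,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    percentile: float = DEFAULT_SECONDARY_PERCENTILE,
    seed: int = 0,
    fdr_scope: str = "sample",
):
    """End-to-end multi-label cohort classification.

    Restricts the matrix to the signature space, Z-scores it (unless already
    Z-scored), runs NTP, derives cohort-specific secondary thresholds, and
    returns ``(result, thresholds, assignments)``.
    """
    restricted = restrict_to_signature(matrix, signature)
    if restricted.unit != "zscore":
        restricted = zscore_by_gene(restricted)
    result = ntp_classify(
        restricted, signature, n_perm=n_perm, fdr_threshold=fdr_threshold, seed=seed, fdr_scope=fdr_scope
    )
    thresholds = compute_secondary_thresholds(result, percentile=percentile)
    assignments = multicris_assign(result, thresholds)
    return result, thresholds, assignments
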