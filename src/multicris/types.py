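"""Core domain types shared by every stage of the classification stack.

An :class:`ExpressionMatrix` is a gene-by-sample numeric table tagged with the
unit it carries (raw counts, CPM, or per-gene Z-scores); a
:class:`SignatureSet` holds the ordered subtype classes and their marker gene
lists, whose union defines the classifier feature space; an
:class:`NTPResult` collects the per-sample nearest-template statistics; a
:class:`MultiLabelAssignment` is the final primary + secondary call for one
sample; a :class:`ClinicalTable` carries survival and binary annotations used
by the association procedures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Units an expression matrix may carry.
UNITS = ("raw_counts", "cpm", "zscore")

#: Label used for samples with no significant class call.
NOT_CLASSIFIED = "NC"


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample expression values with an explicit unit tag.

    Parameters
    ----------
    data
        DataFrame with gene identifiers on the index and sample identifiers
        on the columns.
    unit
        One of ``raw_counts``, ``cpm`` or ``zscore``. Count-like units must
        be finite and non-negative; Z-scores must be finite.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("expression values must be finite (no NaN/Inf)")
        if self.unit in ("raw_counts", "cpm") and (values < 0).any():
            raise ValidationError(f"{self.unit} values must be >= 0")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.unit)

    def select_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids), :], self.unit)

    def with_unit(self, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data, unit)


@dataclass(frozen=True)
class SignatureSet:
    """Ordered subtype classes with their marker gene lists.

    The feature space of every classifier in the package is the ordered union
    of the marker lists (class order, then list order, first occurrence wins).
    """

    class_names: tuple
    markers: Mapping[str, tuple]

    def __post_init__(self) -> None:
        names = tuple(self.class_names)
        object.__setattr__(self, "class_names", names)
        if len(names) < 2:
            raise ValidationError("a signature needs at least 2 classes")
        _check_unique(names, "class names")
        markers = {}
        for name in names:
            if name not in self.markers:
                raise ValidationError(f"class {name!r} has no marker list")
            genes = tuple(self.markers[name])
            if not genes:
                raise ValidationError(f"class {name!r} has an empty marker list")
            _check_unique(genes, f"marker genes of class {name!r}")
            markers[name] = genes
        object.__setattr__(self, "markers", markers)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def feature_space(self) -> List[str]:
        """Ordered union of all marker lists."""
        seen = dict()
        for name in self.class_names:
            for g in self.markers[name]:
                seen.setdefault(g, None)
        return list(seen)


@dataclass(frozen=True)
class MultiLabelAssignment:
    """Primary + secondary class call for a single sample.

    ``primary`` is a class name or :data:`NOT_CLASSIFIED`; ``secondary`` is a
    (possibly empty) set of additional significant classes. A not-classified
    sample has an empty label set.
    """

    sample_id: str
    primary: str
    secondary: FrozenSet[str] = frozenset()
    scores: Optional[Mapping[str, float]] = None
    fdr: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "secondary", frozenset(self.secondary))
        if self.primary in self.secondary:
            raise ValidationError(
                f"sample {self.sample_id}: primary class repeated in secondary set"
            )
        if self.primary == NOT_CLASSIFIED and self.secondary:
            raise ValidationError(
                f"sample {self.sample_id}: not-classified sample cannot carry secondary classes"
            )

    @property
    def labels(self) -> FrozenSet[str]:
        """The full label set ({} for a not-classified sample)."""
        if self.primary == NOT_CLASSIFIED:
            return frozenset()
        return frozenset({self.primary}) | self.secondary


@dataclass(frozen=True)
class NTPResult:
    """Per-sample nearest-template statistics for all classes.

    All four frames are samples x classes; ``primary`` maps each sample to its
    minimal-distance class when that class is significant, else ``NC``.
    """

    distance: pd.DataFrame
    score: pd.DataFrame
    pvalue: pd.DataFrame
    fdr: pd.DataFrame
    primary: pd.Series
    fdr_threshold: float

    @property
    def sample_ids(self) -> List[str]:
        return list(self.distance.index)

    @property
    def class_names(self) -> List[str]:
        return list(self.distance.columns)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample survival and binary annotations.

    ``data`` is indexed by sample id. Recognised columns: ``time`` (months,
    >= 0), ``event`` (bool), ``response`` (one of resistant/stable/sensitive,
    optional), and any number of boolean annotation flags.
    """

    data: pd.DataFrame

    RESPONSE_CLASSES = ("resistant", "stable", "sensitive")

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        has_time = "time" in self.data.columns
        has_event = "event" in self.data.columns
        if has_time != has_event:
            raise ValidationError("survival time and event flag must be present together")
        if has_time:
            t = self.data["time"].astype(float)
            if (t < 0).any() or not np.isfinite(t).all():
                raise ValidationError("survival times must be finite and >= 0")
            ev = self.data["event"]
            if not set(pd.unique(ev.dropna())) <= {True, False, 0, 1}:
                raise ValidationError("event flags must be boolean")
        if "response" in self.data.columns:
            resp = set(self.data["response"].dropna().unique())
            bad = resp - set(self.RESPONSE_CLASSES)
            if bad:
                raise ValidationError(f"unknown response classes: {sorted(bad)}")
        for col in self.annotation_columns:
            vals = set(pd.unique(self.data[col].dropna()))
            if not vals <= {True, False, 0, 1}:
                raise ValidationError(f"annotation {col!r} must be boolean or missing")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def annotation_columns(self) -> List[str]:
        reserved = {"time", "event", "response"}
        return [c for c in self.data.columns if c not in reserved]


def assignments_to_frame(
    assignments: Sequence[MultiLabelAssignment], class_names: Sequence[str]
) -> pd.DataFrame:
    """Tabulate assignments (one row per sample) with per-class score/FDR columns."""
    rows = []
    for a in assignments:
        row: Dict[str, object] = {
            "sample_id": a.sample_id,
            "primary": a.primary,
            "secondary": ";".join(sorted(a.secondary)),
        }
        for k in class_names:
            row[f"score_{k}"] = a.scores[k] if a.scores is not None else np.nan
            row[f"fdr_{k}"] = a.fdr[k] if a.fdr is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
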