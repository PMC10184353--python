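"""Synthetic tumor-heterogeneity generator.

Emulates the data structures the classification stack is built for:
centroid-structured expression profiles organised into K marker-gene
classes, bulk cohorts containing pure samples and two-class cell mixtures,
single-cell populations with sparse capture and occasional hybrid cells
(one cell carrying two class programmes at half strength), and class-linked
survival / drug-response outcomes. Every simulated object comes with full
ground truth, so downstream recovery can be measured.

Count model: each gene has a log-normal baseline mean; a cell of class k has
its class's marker-gene means elevated by ``marker_effect`` on the natural
log scale (hybrid cells: two blocks at half effect each); per-cell per-gene
log-normal noise of ``noise_sd`` multiplies the mean; observed counts are
Poisson draws thinned binomially by ``capture_rate``. Bulk samples are the
exact pseudo-bulk (column sums) of their own generated cell population.
"""

from __future__ import annotations

import dataclasses
import math
import string
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .types import ClinicalTable, ExpressionMatrix, SignatureSet, ValidationError


def _default_class_names(k: int) -> List[str]:
    if k <= 26:
        return list(string.ascii_uppercase[:k])
    return [f"K{i+1}" for i in range(k)]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort generator (defaults define the study
    conditions used throughout the test suite).

    ``marker_effect`` is the natural-log elevation of a class's marker-gene
    means in its cells; ``noise_sd`` is the per-cell per-gene log-normal
    noise, fixed at half the marker effect. ``mixture_fraction`` is the
    proportion of bulks built as two-class cell mixtures (default 0.5,
    mirroring the roughly half of real tumors that receive multiple class
    assignments); ``capture_rate`` is the per-transcript sampling probability
    modelling single-cell dropout.
    """

    n_classes: int = 5
    markers_per_class: int = 40
    n_background_genes: int = 400
    marker_effect: float = 2.0
    noise_sd: float = 1.0
    n_samples: int = 200
    mixture_fraction: float = 0.5
    mixture_minority: Optional[float] = None  # None -> Uniform(0.2, 0.5)
    hybrid_cell_fraction: float = 0.1
    cells_per_sample: int = 100
    capture_rate: float = 0.2
    purity_range: tuple = (0.5, 0.95)  # bulk tumor-cell fraction; rest is baseline background
    membership_leak_max: float = 0.2  # per-sample cap on low-level activity of non-planted classes
    diffuse_fraction: float = 0.2  # ambiguous tumors with Dirichlet composition, no dominant class
    diffuse_alpha: float = 3.0
    base_log_mean: float = math.log(5.0)
    base_log_sd: float = 1.0
    hazard_ratio_by_class: Optional[Dict[str, float]] = None
    response_prob_by_class: Optional[Dict[str, float]] = None
    response_baseline: float = 0.3
    baseline_hazard: float = 1.0 / 60.0  # events per month
    censor_horizon: float = 60.0  # months of administrative follow-up
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.marker_effect <= 0:
            raise ValidationError("marker_effect must be > 0")
        for name in ("mixture_fraction", "hybrid_cell_fraction", "capture_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.mixture_minority is not None and not 0.0 < self.mixture_minority <= 0.5:
            raise ValidationError("mixture_minority must lie in (0, 0.5]")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("purity_range must satisfy 0 < low <= high <= 1")
        if not 0.0 <= self.membership_leak_max < 1.0:
            raise ValidationError("membership_leak_max must lie in [0, 1)")
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise ValidationError("diffuse_fraction must lie in [0, 1]")
        names = _default_class_names(self.n_classes)
        # default clinical links: one poor-prognosis class, one drug-sensitive class
        if self.hazard_ratio_by_class is None:
            self.hazard_ratio_by_class = {names[1]: 3.0}
        if self.response_prob_by_class is None:
            self.response_prob_by_class = {names[min(2, self.n_classes - 1)]: 0.6}

    @property
    def class_names(self) -> List[str]:
        return _default_class_names(self.n_classes)

    @property
    def n_genes(self) -> int:
        return self.n_classes * self.markers_per_class + self.n_background_genes

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a simulated cohort: per-sample class composition
    (proportions summing to 1), per-cell labels (class name, or the hybrid
    pair joined by '+'), and the clinical generating parameters."""

    composition: Mapping[str, Mapping[str, float]]
    cells: Optional[pd.DataFrame] = None  # columns: cell_id, sample_id, label, is_hybrid
    purity: Optional[Mapping[str, float]] = None  # bulk tumor-cell fraction per sample
    planted: Optional[Mapping[str, tuple]] = None  # the 1 or 2 deliberately planted classes
    clinical_params: Optional[pd.DataFrame] = None  # columns: hazard, p_sensitive

    def classes_of(self, sample_id: str, min_proportion: float = 0.15) -> List[str]:
        """Classes with substantial membership (at least ``min_proportion``
        of the tumor component); low-level leak does not count."""
        return [k for k, v in self.composition[sample_id].items() if v >= min_proportion]

    def primary_of(self, sample_id: str) -> str:
        comp = self.composition[sample_id]
        return max(sorted(comp), key=lambda k: comp[k])


@dataclass(frozen=True)
class SimulatedCohort:
    """A bulk cohort with its generating cell population and ground truth."""

    bulk: ExpressionMatrix
    cells: ExpressionMatrix
    cell_grouping: Dict[str, str]
    truth: TruthTable
    signature: SignatureSet
    config: GeneratorConfig


def make_signature(config: GeneratorConfig) -> SignatureSet:
    """K disjoint marker blocks plus background genes; deterministic names."""
    if config.markers_per_class < 1:
        raise ValidationError("markers_per_class must be >= 1")
    markers = {}
    for name in config.class_names:
        markers[name] = tuple(
            f"g{name}_{i:03d}" for i in range(1, config.markers_per_class + 1)
        )
    return SignatureSet(tuple(config.class_names), markers)


def background_genes(config: GeneratorConfig) -> List[str]:
    return [f"bg_{i:04d}" for i in range(1, config.n_background_genes + 1)]


def all_genes(config: GeneratorConfig) -> List[str]:
    sig = make_signature(config)
    return sig.feature_space + background_genes(config)


def _baseline_log_means(config: GeneratorConfig) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    return rng.normal(config.base_log_mean, config.base_log_sd, size=config.n_genes)


def _marker_slices(config: GeneratorConfig) -> Dict[str, slice]:
    out = {}
    for i, name in enumerate(config.class_names):
        start = i * config.markers_per_class
        out[name] = slice(start, start + config.markers_per_class)
    return out


def _draw_cell_counts(
    config: GeneratorConfig,
    labels: List[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Counts matrix (genes x cells) for cells with the given truth labels
    ('A' for pure, 'A+B' for hybrid)."""
    base = _baseline_log_means(config)
    slices = _marker_slices(config)
    n_cells = len(labels)
    log_mean = np.tile(base[:, None], (1, n_cells))
    for j, label in enumerate(labels):
        if label == "bg":  # non-tumor background cell: baseline expression only
            continue
        parts = label.split("+")
        effect = config.marker_effect / len(parts)
        for part in parts:
            log_mean[slices[part], j] += effect
    log_mean += rng.normal(0.0, config.noise_sd, size=log_mean.shape)
    counts = rng.poisson(np.exp(log_mean))
    if config.capture_rate < 1.0:
        counts = rng.binomial(counts, config.capture_rate)
    return counts.astype(float)


def simulate_cells(
    config: GeneratorConfig,
    n_cells: int = 500,
    seed: Optional[int] = None,
) -> tuple:
    """Simulate a single-cell population: each cell is a pure class draw
    (uniform over classes) or, with probability ``hybrid_cell_fraction``, a
    hybrid of two distinct classes at half effect each.

    Returns ``(ExpressionMatrix of raw counts, TruthTable)``.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    names = config.class_names
    labels = []
    for _ in range(n_cells):
        if rng.random() < config.hybrid_cell_fraction:
            a, b = rng.choice(config.n_classes, size=2, replace=False)
            labels.append(f"{names[a]}+{names[b]}")
        else:
            labels.append(names[rng.integers(config.n_classes)])
    counts = _draw_cell_counts(config, labels, rng)
    if config.capture_rate == 0.0:
        import logging

        logging.getLogger(__name__).warning("capture_rate=0: all-zero matrix")
    cell_ids = [f"cell{i+1:05d}" for i in range(n_cells)]
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=all_genes(config), columns=cell_ids), "raw_counts"
    )
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": "pool",
            "label": labels,
            "is_hybrid": ["+" in lbl for lbl in labels],
        }
    )
    composition = {"pool": _label_composition(labels)}
    return matrix, TruthTable(composition=composition, cells=cells)


def _allocate_cells(n: int, fractions: np.ndarray) -> np.ndarray:
    """Deterministic largest-remainder allocation of n cells to class
    fractions, so planted compositions are realized exactly up to rounding."""
    base = np.floor(n * fractions).astype(int)
    remainder = n * fractions - base
    short = n - int(base.sum())
    if short > 0:
        order = np.argsort(-remainder, kind="stable")
        base[order[:short]] += 1
    return base


def _label_composition(labels: List[str]) -> Dict[str, float]:
    counts: Dict[str, float] = {}
    for lbl in labels:
        if lbl == "bg":
            continue
        parts = lbl.split("+")
        for part in parts:
            counts[part] = counts.get(part, 0.0) + 1.0 / len(parts)
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}


def simulate_composition(
    config: GeneratorConfig,
    seed: Optional[int] = None,
):
    """Draw the cohort's per-sample cell-label lists and ground truth
    without generating expression.

    Each sample is pure (one class), a two-class mixture (probability
    ``mixture_fraction``, minority proportion ``mixture_minority`` or
    Uniform(0.2, 0.5)), or a diffuse ambiguous tumor (probability
    ``diffuse_fraction``, Dirichlet composition). On top of the tumor
    composition every bulk carries a tumor purity drawn from
    ``purity_range`` (remaining cells are non-tumor background, label
    ``bg``) and, for planted samples, a Dirichlet membership leak over the
    non-planted classes modelling the continuous class-membership spectrum.
    Major classes are balanced across the cohort (shuffled round-robin).

    Returns ``(sample_ids, labels_by_sample, TruthTable)``.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    names = config.class_names
    n_cells = config.cells_per_sample
    sample_ids = [f"s{i+1:04d}" for i in range(config.n_samples)]
    labels_by_sample: Dict[str, List[str]] = {}
    composition: Dict[str, Dict[str, float]] = {}
    purity: Dict[str, float] = {}
    planted: Dict[str, tuple] = {}
    lo, hi = config.purity_range
    majors = [names[i % config.n_classes] for i in range(config.n_samples)]
    rng.shuffle(majors)
    for sid, major in zip(sample_ids, majors):
        pur = float(rng.uniform(lo, hi))
        n_tumor = max(1, int(round(pur * n_cells)))
        purity[sid] = n_tumor / n_cells
        main = np.zeros(config.n_classes)
        if rng.random() < config.diffuse_fraction:
            # ambiguous tumor: membership spread over all classes; these
            # populate the weak tail of every class's primary-score range
            fractions = rng.dirichlet(np.full(config.n_classes, config.diffuse_alpha))
            planted[sid] = ()
        else:
            if rng.random() < config.mixture_fraction:
                minor = names[
                    (names.index(major) + 1 + rng.integers(config.n_classes - 1))
                    % config.n_classes
                ]
                f = (
                    config.mixture_minority
                    if config.mixture_minority is not None
                    else float(rng.uniform(0.2, 0.5))
                )
                main[names.index(major)] = 1.0 - f
                main[names.index(minor)] = f
                planted[sid] = (major, minor)
            else:
                main[names.index(major)] = 1.0
                planted[sid] = (major,)
            # continuous class membership: every tumor carries low-level
            # activity of other class programmes, modelled as a Dirichlet
            # leak spread over the non-planted classes; the planted classes
            # keep their exact ratio
            leak = float(rng.uniform(0.0, config.membership_leak_max))
            others = [i for i in range(config.n_classes) if main[i] == 0.0]
            fractions = (1.0 - leak) * main
            if others:
                fractions[others] += leak * rng.dirichlet(np.ones(len(others)))
        cells_by_class = _allocate_cells(n_tumor, fractions)
        labels = [
            name for name, cnt in zip(names, cells_by_class) for _ in range(int(cnt))
        ] + ["bg"] * (n_cells - n_tumor)
        labels_by_sample[sid] = labels
        composition[sid] = _label_composition(labels)
    cell_rows = [
        (f"{sid}_c{j+1:04d}", sid, lbl, False)
        for sid in sample_ids
        for j, lbl in enumerate(labels_by_sample[sid])
    ]
    truth = TruthTable(
        composition=composition,
        cells=pd.DataFrame(cell_rows, columns=["cell_id", "sample_id", "label", "is_hybrid"]),
        purity=purity,
        planted=planted,
    )
    return sample_ids, labels_by_sample, truth


def simulate_bulk(
    config: GeneratorConfig,
    seed: Optional[int] = None,
) -> SimulatedCohort:
    """Simulate a bulk cohort: each sample is the exact pseudo-bulk of its
    own generated cell population (see :func:`simulate_composition` for the
    composition model). Bulk member cells are pure; hybrid cells concern the
    single-cell simulator.
    """
    seed = config.seed if seed is None else seed
    sample_ids, labels_by_sample, truth = simulate_composition(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    n_cells = config.cells_per_sample
    all_labels: List[str] = []
    grouping: Dict[str, str] = {}
    for sid in sample_ids:
        for j, lbl in enumerate(labels_by_sample[sid]):
            grouping[f"{sid}_c{j+1:04d}"] = sid
        all_labels.extend(labels_by_sample[sid])
    counts = _draw_cell_counts(config, all_labels, rng)
    cell_ids = list(truth.cells["cell_id"])
    cells = ExpressionMatrix(
        pd.DataFrame(counts, index=all_genes(config), columns=cell_ids), "raw_counts"
    )
    # bulk = exact pseudo-bulk of the sample's cells
    bulk_values = np.stack(
        [
            counts[:, i * n_cells : (i + 1) * n_cells].sum(axis=1)
            for i in range(config.n_samples)
        ],
        axis=1,
    )
    bulk = ExpressionMatrix(
        pd.DataFrame(bulk_values, index=all_genes(config), columns=sample_ids), "raw_counts"
    )
    return SimulatedCohort(
        bulk=bulk,
        cells=cells,
        cell_grouping=grouping,
        truth=truth,
        signature=make_signature(config),
        config=config,
    )


def simulate_clinical(
    truth: TruthTable,
    config: GeneratorConfig,
    seed: Optional[int] = None,
) -> ClinicalTable:
    """Class-linked outcomes: survival times are exponential with hazard
    ``baseline x max(hazard ratio over the sample's substantial composition
    classes)`` (the max rule lets secondary membership carry risk, while
    low-level leak membership below 15% does not), administratively
    censored past ``censor_horizon`` months. Drug response is drawn with
    sensitivity probability ``max(response_prob over classes, baseline)``;
    the remainder splits evenly between stable and resistant.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    hr = config.hazard_ratio_by_class or {}
    rp = config.response_prob_by_class or {}
    rows = []
    for sid in truth.composition:
        classes = truth.classes_of(sid) or truth.classes_of(sid, min_proportion=0.0)
        hazard = config.baseline_hazard * max([hr.get(k, 1.0) for k in classes])
        time = float(rng.exponential(1.0 / hazard))
        event = True
        if time > config.censor_horizon:
            time, event = config.censor_horizon, False
        p_sens = max([rp.get(k, config.response_baseline) for k in classes])
        u = rng.random()
        if u < p_sens:
            response = "sensitive"
        elif u < p_sens + (1.0 - p_sens) / 2.0:
            response = "stable"
        else:
            response = "resistant"
        rows.append((sid, time, event, response, hazard, p_sens))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "time", "event", "response", "hazard", "p_sensitive"]
    ).set_index("sample_id")
    if truth.clinical_params is None:
        object.__setattr__(truth, "clinical_params", frame[["hazard", "p_sensitive"]])
    return ClinicalTable(frame[["time", "event", "response"]])
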