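"""End-to-end recovery experiments on synthetic cohorts.

These are the package's reproducibility harness: each function builds a
seeded synthetic cohort, runs the relevant part of the classification stack,
and measures how well planted truth is recovered. They back both the test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import clinical, metrics, mla, ntp, preprocess, synthetic
from .types import ExpressionMatrix, MultiLabelAssignment, NOT_CLASSIFIED


def _child_seed(seed: int, tag: int) -> int:
    """Derived seeds kept below 2^31."""
    return int((seed * 1000003 + tag) % (2**31 - 1))


def classify_default_cohort(
    seed: int,
    n_samples: int = 200,
    n_perm: int = 500,
    mixture_minority: Optional[float] = None,
    config_kwargs: Optional[dict] = None,
):
    """Simulate a bulk cohort at the default study conditions and run the
    full multi-label nearest-template pipeline on it."""
    kwargs = dict(config_kwargs or {})
    cfg = synthetic.GeneratorConfig(
        n_samples=n_samples, seed=seed, mixture_minority=mixture_minority, **kwargs
    )
    cohort = synthetic.simulate_bulk(cfg)
    cpm = preprocess.cpm_normalize(cohort.bulk)
    result, thresholds, assignments = ntp.classify_cohort(
        cpm, cohort.signature, n_perm=n_perm, seed=seed
    )
    return cohort, cpm, result, thresholds, assignments


def noise_free_recovery(seed: int = 0, n_perm: int = 1000) -> Dict[str, float]:
    """Samples equal to the class templates must come back with their
    generating class at exactly distance zero."""
    cfg = synthetic.GeneratorConfig()
    sig = synthetic.make_signature(cfg)
    genes = sig.feature_space
    data = np.zeros((len(genes), sig.n_classes))
    for j, k in enumerate(sig.class_names):
        for g in sig.markers[k]:
            data[genes.index(g), j] = 1.0
    mat = ExpressionMatrix(
        pd.DataFrame(data, index=genes, columns=[f"t_{k}" for k in sig.class_names]),
        "zscore",
    )
    res = ntp.ntp_classify(mat, sig, n_perm=n_perm, seed=seed)
    recovered = np.mean(
        [res.primary[f"t_{k}"] == k for k in sig.class_names]
    )
    max_distance = max(
        res.distance.loc[f"t_{k}", k] for k in sig.class_names
    )
    return {"recovery": float(recovered), "max_distance": float(max_distance)}


def noisy_recovery(seed: int = 1, n_samples: int = 200, n_perm: int = 500) -> Dict[str, float]:
    """Primary recovery of the planted major class on a default high-signal
    cohort (diffuse samples carry no planted class and are excluded)."""
    cohort, _, result, _, assignments = classify_default_cohort(seed, n_samples, n_perm)
    planted = {s: p for s, p in cohort.truth.planted.items() if p}
    recovery = float(np.mean([result.primary[s] == p[0] for s, p in planted.items()]))
    classified = float((result.primary != NOT_CLASSIFIED).mean())
    multi = float(np.mean([bool(a.secondary) for a in assignments]))
    return {"recovery": recovery, "classified_fraction": classified, "multilabel_fraction": multi}


def mixture_recovery(
    seed: int = 1,
    proportions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    n_samples: int = 400,
    n_perm: int = 300,
) -> Dict[float, float]:
    """Fraction of planted two-class mixtures whose full label set contains
    both generating classes, per minority proportion."""
    rates: Dict[float, float] = {}
    for f in proportions:
        cohort, _, _, _, assignments = classify_default_cohort(
            _child_seed(seed, int(100 * f)), n_samples, n_perm, mixture_minority=f
        )
        by_id = {a.sample_id: a for a in assignments}
        mixtures = [s for s, p in cohort.truth.planted.items() if len(p) == 2]
        rates[f] = float(
            np.mean([set(cohort.truth.planted[s]) <= by_id[s].labels for s in mixtures])
        )
    return rates


def null_cohort(
    seeds: Sequence[int],
    n_samples: int = 200,
    n_perm: int = 1000,
) -> Dict[str, object]:
    """Structureless Gaussian cohorts: per-seed significantly-assigned
    fraction and per-class KS uniformity of the permutation p-values pooled
    across seeds."""
    cfg = synthetic.GeneratorConfig()
    sig = synthetic.make_signature(cfg)
    genes = sig.feature_space
    fractions: List[float] = []
    pooled: Dict[str, List[float]] = {k: [] for k in sig.class_names}
    for seed in seeds:
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.normal(size=(len(genes), n_samples)),
            index=genes,
            columns=[f"n{seed}_{i}" for i in range(n_samples)],
        )
        res = ntp.ntp_classify(ExpressionMatrix(data, "zscore"), sig, n_perm=n_perm, seed=seed)
        fractions.append(float((res.primary != NOT_CLASSIFIED).mean()))
        for k in sig.class_names:
            pooled[k].extend(res.pvalue[k].tolist())
    ks = {k: float(scipy.stats.kstest(v, "uniform").pvalue) for k, v in pooled.items()}
    return {"assigned_fractions": fractions, "ks_pvalues": ks}


def lsvm_concordance(
    seed: int = 1,
    n_samples: int = 200,
    n_perm: int = 500,
    kind: str = "linear_svm",
):
    """Train a single-sample classifier on the cohort's nearest-template
    primaries (70/30 stratified split, 10-fold CV) and measure held-out
    concordance with the nearest-template reference.

    Returns ``(summary dict, model, held-out matrix, held-out references)``.
    """
    cohort, cpm, result, thresholds, assignments = classify_default_cohort(
        seed, n_samples, n_perm
    )
    confident = [a for a in assignments if a.primary != NOT_CLASSIFIED]
    matrix = preprocess.restrict_to_signature(cpm, cohort.signature)
    matrix = matrix.select_samples([a.sample_id for a in confident])
    labels = {a.sample_id: a.primary for a in confident}
    plan = mla.stratified_split(
        [labels[s] for s in matrix.sample_ids], fraction=0.7, seed=seed
    )
    model = mla.train_single_label(
        matrix,
        labels,
        mla.ModelSpec(kind, seed=seed),
        plan=plan,
        cv_folds=10,
        class_names=cohort.signature.class_names,
    )
    train = matrix.select_samples([matrix.sample_ids[i] for i in plan.train_indices])
    test = matrix.select_samples([matrix.sample_ids[i] for i in plan.test_indices])
    train_refs = [a for a in confident if a.sample_id in set(train.sample_ids)]
    test_refs = [a for a in confident if a.sample_id in set(test.sample_ids)]
    mla.calibrate_mla_thresholds(model, train, train_refs)
    predictions = mla.predict_multilabel(model, test)
    primary = mla.predict_primary(model, test)
    ref = {a.sample_id: a.primary for a in test_refs}
    agreement = float(np.mean([primary[s] == ref[s] for s in test.sample_ids]))
    summary = metrics.multilabel_metrics(predictions, test_refs, cohort.signature.class_names)
    summary["primary_agreement"] = agreement
    return summary, model, test, test_refs


def clinical_recovery(
    seeds: Sequence[int],
    n_samples: int = 200,
) -> Dict[str, object]:
    """Detection of planted clinical effects from truth-derived label sets:
    per-seed log-rank p for the high-hazard class and Fisher p/odds ratio for
    the drug-sensitive class, across the stated number of cohorts."""
    logrank_ps: List[float] = []
    fisher_ps: List[float] = []
    odds: List[float] = []
    for seed in seeds:
        cfg = synthetic.GeneratorConfig(n_samples=n_samples, seed=seed)
        _, _, truth = synthetic.simulate_composition(cfg)
        table = synthetic.simulate_clinical(truth, cfg)
        assignments = []
        for sid in truth.composition:
            classes = truth.classes_of(sid)
            if not classes:
                classes = truth.classes_of(sid, min_proportion=0.0)
            comp = truth.composition[sid]
            top = max(classes, key=lambda k: comp[k])
            secondary = frozenset(k for k in classes if k != top)
            assignments.append(MultiLabelAssignment(sid, top, secondary))
        hr_class = next(iter(cfg.hazard_ratio_by_class))
        rp_class = next(iter(cfg.response_prob_by_class))
        surv = clinical.survival_association(assignments, table, hr_class)
        logrank_ps.append(float(surv.loc["primary_plus_secondary", "p_value"]))
        cohorts = clinical.build_cohorts(assignments, rp_class)
        flag = clinical.dichotomize_response(table)
        fisher = clinical.fisher_association(cohorts["primary_plus_secondary"], flag)
        fisher_ps.append(fisher.p_value)
        odds.append(fisher.odds_ratio)
    return {
        "logrank_detection": float(np.mean(np.array(logrank_ps) < 0.05)),
        "fisher_detection": float(np.mean(np.array(fisher_ps) < 0.05)),
        "median_odds_ratio": float(np.median(odds)),
    }
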