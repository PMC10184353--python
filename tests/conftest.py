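import numpy as np
import pandas as pd
import pytest

from multicris import mla, ntp, preprocess, synthetic
from multicris.types import ExpressionMatrix, NOT_CLASSIFIED, SignatureSet


@pytest.fixture(scope="session")
def small_signature():
    return SignatureSet(
        ("A", "B"),
        {"A": ("gA1", "gA2", "gA3"), "B": ("gB1", "gB2", "gB3")},
    )


@pytest.fixture(scope="session")
def fast_config():
    """A small cohort configuration used where full scale is unnecessary."""
    return synthetic.GeneratorConfig(
        n_samples=60, cells_per_sample=50, markers_per_class=15,
        n_background_genes=100, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(fast_config):
    return synthetic.simulate_bulk(fast_config)


@pytest.fixture(scope="session")
def classified_cohort(small_cohort):
    cpm = preprocess.cpm_normalize(small_cohort.bulk)
    result, thresholds, assignments = ntp.classify_cohort(
        cpm, small_cohort.signature, n_perm=200, seed=7
    )
    return cpm, result, thresholds, assignments


@pytest.fixture(scope="session")
def trained_lsvm(small_cohort, classified_cohort):
    """A linear-SVM classifier trained on the small cohort's NTP primaries,
    with calibrated multi-label thresholds, plus its train/test split."""
    cpm, result, thresholds, assignments = classified_cohort
    confident = [a for a in assignments if a.primary != NOT_CLASSIFIED]
    matrix = preprocess.restrict_to_signature(cpm, small_cohort.signature)
    matrix = matrix.select_samples([a.sample_id for a in confident])
    labels = {a.sample_id: a.primary for a in confident}
    plan = mla.stratified_split([labels[s] for s in matrix.sample_ids], fraction=0.7, seed=7)
    model = mla.train_single_label(
        matrix,
        labels,
        mla.ModelSpec("linear_svm", seed=7),
        plan=plan,
        cv_folds=5,
        class_names=small_cohort.signature.class_names,
    )
    train = matrix.select_samples([matrix.sample_ids[i] for i in plan.train_indices])
    test = matrix.select_samples([matrix.sample_ids[i] for i in plan.test_indices])
    train_refs = [a for a in confident if a.sample_id in set(train.sample_ids)]
    test_refs = [a for a in confident if a.sample_id in set(test.sample_ids)]
    mla.calibrate_mla_thresholds(model, train, train_refs)
    return model, train, test, train_refs, test_refs
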