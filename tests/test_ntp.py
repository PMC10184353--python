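"""Nearest-template classifier: Z-scoring, distances, permutation
significance, BH adjustment, and primary/secondary assignment."""

import math

import numpy as np
import pandas as pd
import pytest

from bruteforce import bf_bh
from multicris import ntp
from multicris.types import ExpressionMatrix, NTPResult, SignatureSet, ValidationError


def zmat(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "zscore")


SIG = SignatureSet(
    ("A", "B", "C"),
    {"A": ("a1", "a2"), "B": ("b1", "b2"), "C": ("c1", "c2")},
)
GENES = SIG.feature_space


class TestZscore:
    def test_centres_and_scales_with_sample_sd(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["s1", "s2", "s3"]), "cpm"
        )
        out = ntp.zscore_by_gene(m)
        assert out.values[0] == pytest.approx([-1.0, 0.0, 1.0])
        assert out.unit == "zscore"

    def test_constant_gene_maps_to_zeros(self):
        m = ExpressionMatrix(
            pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("xyz")), "cpm"
        )
        assert (ntp.zscore_by_gene(m).values == 0).all()

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.uniform(1, 100, size=(30, 12)),
                index=[f"g{i}" for i in range(30)],
                columns=[f"s{j}" for j in range(12)],
            ),
            "cpm",
        )
        z = ntp.zscore_by_gene(m).values
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_single_sample_is_an_error(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0]], index=["g"], columns=["s"]), "cpm")
        with pytest.raises(ValidationError, match="single-sample"):
            ntp.zscore_by_gene(m)


class TestCosineDistance:
    def test_identity_is_zero(self):
        t = np.array([1.0, 0.0, 1.0])
        assert ntp.cosine_distance(t, t) == pytest.approx(0.0, abs=1e-15)

    def test_orthogonality_is_one(self):
        assert ntp.cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_known_angle(self):
        assert ntp.cosine_distance([1, 0], [1, 1]) == pytest.approx(1 - 1 / math.sqrt(2))

    def test_zero_profile_convention(self):
        assert ntp.cosine_distance([0, 0], [1, 1]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            ntp.cosine_distance([1, 2], [1, 2, 3])


class TestBH:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.005, 0.1), (0.01, 0.1)),
            ((0.5,), (0.5,)),
        ],
    )
    def test_step_up_examples(self, pvals, expected):
        assert ntp.bh_adjust(np.array(pvals)) == pytest.approx(expected)

    def test_adjusted_never_below_raw_and_matches_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.uniform(1e-4, 1.0, size=rng.integers(1, 8))
            q = ntp.bh_adjust(p)
            assert (q >= p - 1e-15).all()
            assert q == pytest.approx(bf_bh(list(p)))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            ntp.bh_adjust(np.array([0.0, 0.5]))


class TestPermutationPvalue:
    def test_template_profile_reaches_the_floor(self):
        rng = np.random.default_rng(0)
        n_genes, m, n_perm = 100, 5, 150
        x = np.zeros(n_genes)
        pos = np.arange(m)
        x[pos] = 1.0
        p, d = ntp.permutation_pvalue(x, pos, n_perm, np.random.default_rng(1))
        assert d == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1 / (1 + n_perm))

    def test_p_has_the_plus_one_floor(self):
        # any profile: p can never be smaller than 1/(1+n_perm)
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        p, _ = ntp.permutation_pvalue(x, np.array([0, 1, 2]), 100, rng)
        assert p >= 1 / 101

    def test_uniform_under_gaussian_null(self):
        # p-values across many Gaussian profiles are uniform (KS at alpha=0.01)
        import scipy.stats

        rng = np.random.default_rng(3)
        pos = np.arange(4)
        ps = []
        for i in range(500):
            x = rng.normal(size=40)
            p, _ = ntp.permutation_pvalue(x, pos, 100, np.random.default_rng(1000 + i))
            ps.append(p)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValidationError):
            ntp.permutation_pvalue(np.ones(10), np.array([0]), 99, np.random.default_rng(0))

    def test_marker_count_must_be_below_feature_count(self):
        with pytest.raises(ValidationError):
            ntp.permutation_pvalue(np.ones(3), np.array([0, 1, 2]), 100, np.random.default_rng(0))


BIG_SIG = SignatureSet(
    ("A", "B", "C"),
    {k: tuple(f"{k.lower()}{i}" for i in range(8)) for k in ("A", "B", "C")},
)


class TestClassify:
    def template_matrix(self):
        # three samples, each exactly a class template (8 markers per class)
        data = np.zeros((24, 3))
        for j in range(3):
            data[8 * j : 8 * (j + 1), j] = 1.0
        return zmat(data, BIG_SIG.feature_space, ["sA", "sB", "sC"])

    def test_noise_free_templates_recovered_at_distance_zero(self):
        res = ntp.ntp_classify(self.template_matrix(), BIG_SIG, n_perm=200, seed=0)
        assert list(res.primary) == ["A", "B", "C"]
        for sid, k in zip(["sA", "sB", "sC"], "ABC"):
            assert res.distance.loc[sid, k] == pytest.approx(0.0, abs=1e-15)
            assert res.fdr.loc[sid, k] < 0.2

    def test_swapping_class_names_permutes_calls(self):
        m = self.template_matrix()
        swapped = SignatureSet(
            ("B", "A", "C"),
            {
                "B": BIG_SIG.markers["A"],
                "A": BIG_SIG.markers["B"],
                "C": BIG_SIG.markers["C"],
            },
        )
        res = ntp.ntp_classify(m, swapped, n_perm=200, seed=0)
        assert list(res.primary) == ["B", "A", "C"]

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        m = zmat(rng.normal(size=(6, 5)), GENES, [f"s{i}" for i in range(5)])
        res = ntp.ntp_classify(m, SIG, n_perm=150, seed=9)
        perm = [3, 0, 4, 1, 2]
        m2 = m.select_samples([m.sample_ids[i] for i in perm])
        res2 = ntp.ntp_classify(m2, SIG, n_perm=150, seed=9)
        for sid in m2.sample_ids:
            assert (res2.distance.loc[sid] == res.distance.loc[sid]).all()
            assert (res2.pvalue.loc[sid] == res.pvalue.loc[sid]).all()
            assert res2.primary.loc[sid] == res.primary.loc[sid]

    def test_fixed_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(5)
        m = zmat(rng.normal(size=(6, 4)), GENES, list("wxyz"))
        r1 = ntp.ntp_classify(m, SIG, n_perm=150, seed=2)
        r2 = ntp.ntp_classify(m, SIG, n_perm=150, seed=2)
        assert (r1.pvalue.values == r2.pvalue.values).all()

    def test_requires_zscore_unit(self):
        m = ExpressionMatrix(
            pd.DataFrame(np.ones((6, 3)), index=GENES, columns=list("abc")), "cpm"
        )
        with pytest.raises(ValidationError):
            ntp.ntp_classify(m, SIG, n_perm=100)

    def test_score_is_one_minus_distance(self):
        rng = np.random.default_rng(6)
        m = zmat(rng.normal(size=(6, 3)), GENES, list("abc"))
        res = ntp.ntp_classify(m, SIG, n_perm=100, seed=0)
        assert np.allclose(res.score.values, 1 - res.distance.values)
        assert (res.fdr.values >= res.pvalue.values - 1e-15).all()


def make_result(scores, fdr, primary, classes=("A", "B", "C")):
    idx = pd.Index([f"s{i}" for i in range(len(primary))], name="sample_id")
    score = pd.DataFrame(scores, index=idx, columns=list(classes))
    q = pd.DataFrame(fdr, index=idx, columns=list(classes))
    return NTPResult(
        distance=1 - score,
        score=score,
        pvalue=q.clip(upper=1.0) / 2 + 1e-6,
        fdr=q,
        primary=pd.Series(primary, index=idx),
        fdr_threshold=0.2,
    )


class TestSecondaryThresholds:
    def test_linear_interpolation_on_uniform_grid(self):
        scores = np.linspace(0.01, 1.0, 100)[:, None] * [1, 0, 0]
        res = make_result(scores, np.full((100, 3), 0.01), ["A"] * 100)
        thr = ntp.compute_secondary_thresholds(res, percentile=5)
        assert thr["A"] == pytest.approx(0.0595)

    def test_single_sample_degenerate_percentile(self):
        res = make_result([[0.7, 0.1, 0.1]], [[0.01, 1, 1]], ["A"])
        thr = ntp.compute_secondary_thresholds(res)
        assert thr["A"] == pytest.approx(0.7)
        assert thr["B"] == math.inf  # no primary samples

    def test_all_equal_scores(self):
        res = make_result([[0.4, 0, 0]] * 5, np.full((5, 3), 0.01), ["A"] * 5)
        assert ntp.compute_secondary_thresholds(res)["A"] == pytest.approx(0.4)


class TestMulticrisAssign:
    def test_primary_only_when_others_not_significant(self):
        res = make_result([[0.8, 0.5, 0.4]], [[0.05, 0.5, 0.5]], ["A"])
        a = ntp.multicris_assign(res, {"A": 0.0, "B": 0.0, "C": 0.0})[0]
        assert a.primary == "A" and a.secondary == frozenset()

    def test_significant_and_above_threshold_becomes_secondary(self):
        res = make_result([[0.6, 0.2, 0.5]], [[0.01, 0.9, 0.10]], ["A"])
        a = ntp.multicris_assign(res, {"A": 0.0, "B": 0.45, "C": 0.45})[0]
        assert a.secondary == frozenset({"C"})

    def test_threshold_veto(self):
        res = make_result([[0.6, 0.2, 0.40]], [[0.01, 0.9, 0.10]], ["A"])
        a = ntp.multicris_assign(res, {"A": 0.0, "B": 0.45, "C": 0.45})[0]
        assert a.secondary == frozenset()

    def test_nc_sample_gets_empty_label_set(self):
        res = make_result([[0.6, 0.2, 0.5]], [[0.5, 0.9, 0.5]], ["NC"])
        a = ntp.multicris_assign(res, {"A": 0.0, "B": 0.0, "C": 0.0})[0]
        assert a.labels == frozenset()

    def test_removing_thresholds_only_adds_labels(self):
        rng = np.random.default_rng(7)
        n = 40
        scores = rng.uniform(0, 1, size=(n, 3))
        fdr = rng.uniform(0, 1, size=(n, 3))
        primary = ["A" if i % 2 else "B" for i in range(n)]
        res = make_result(scores, fdr, primary)
        thr = {"A": 0.5, "B": 0.5, "C": 0.5}
        no_thr = {"A": -math.inf, "B": -math.inf, "C": -math.inf}
        with_t = ntp.multicris_assign(res, thr)
        without_t = ntp.multicris_assign(res, no_thr)
        for a, b in zip(with_t, without_t):
            assert a.secondary <= b.secondary
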