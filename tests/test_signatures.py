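"""Signature engine: Gaussian Wasserstein, MCC thresholds, oriented signatures."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from markersig import (
    Arrow,
    GroupStats,
    SampleSelection,
    ValidationError,
    best_threshold_mcc,
    compute_signature,
    gaussian_wasserstein,
    mcc,
    oriented_signature,
    pearson_r,
    project_onto_arrow,
    rank_by_wasserstein,
)

from conftest import make_dataset


def numerical_w2(mu1, s1, mu2, s2, grid=20001):
    """Oracle: 2-Wasserstein via quantile-function integration."""
    q = np.linspace(1e-7, 1 - 1e-7, grid)
    d = scipy.stats.norm.ppf(q, mu1, max(s1, 1e-300)) - \
        scipy.stats.norm.ppf(q, mu2, max(s2, 1e-300))
    return float(np.sqrt(np.trapezoid(d * d, q)))


def brute_force_threshold(values, in_a):
    """Oracle: exhaustive scan of every midpoint in both polarities."""
    v = np.asarray(values, float)
    a = np.asarray(in_a, bool)
    u = np.unique(v)
    if u.size == 1:
        return float(u[0]), "up_in_A", 0.0
    best = (None, None, -np.inf)
    for theta in (u[:-1] + u[1:]) / 2:
        for direction in ("up_in_A", "down_in_A"):
            pred = v > theta if direction == "up_in_A" else v < theta
            m = mcc((pred & a).sum(), (~pred & ~a).sum(),
                    (pred & ~a).sum(), (~pred & a).sum())
            if m > best[2]:  # scan order = ascending theta, up first
                best = (float(theta), direction, m)
    return best


class TestGaussianWasserstein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((0, 1), (0, 1), 0.0), ((3, 1), (0, 1), 3.0),
         ((0, 2), (0, 0.5), 1.5), ((1, 1), (0, 0), np.sqrt(2))],
    )
    def test_closed_form_examples(self, a, b, expected):
        stats = GroupStats([a[0]], [a[1]], [b[0]], [b[1]])
        assert gaussian_wasserstein(stats)[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_numerical_quantile_integral(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            mu1, mu2 = rng.uniform(-5, 5, 2)
            s1, s2 = rng.uniform(0.1, 3, 2)
            w = gaussian_wasserstein(GroupStats([mu1], [s1], [mu2], [s2]))[0]
            assert w == pytest.approx(numerical_w2(mu1, s1, mu2, s2), abs=1e-3)

    def test_symmetry_and_zero_iff_identical(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(-2, 2, 20)
        s = rng.uniform(0, 2, 20)
        fwd = gaussian_wasserstein(GroupStats(mu, s, mu[::-1], s[::-1]))
        bwd = gaussian_wasserstein(GroupStats(mu[::-1], s[::-1], mu, s))
        np.testing.assert_allclose(fwd, bwd)
        same = gaussian_wasserstein(GroupStats(mu, s, mu, s))
        np.testing.assert_array_equal(same, np.zeros(20))


class TestWassersteinRanking:
    def test_planted_mean_shift_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 20))
        X[:10, 7] += 10.0
        ds = make_dataset(X)
        a = SampleSelection(np.arange(40) < 10)
        order = rank_by_wasserstein(ds, a, a.complement(), 20)
        assert order[0] == 7

    def test_variance_only_marker_beats_exact_nulls(self):
        rng = np.random.default_rng(1)
        X = np.ones((40, 10))  # constant nulls: W exactly 0
        X[:, 4] = rng.normal(size=40)
        X[:10, 4] *= 3.0
        ds = make_dataset(X)
        a = SampleSelection(np.arange(40) < 10)
        order = rank_by_wasserstein(ds, a, a.complement(), 10)
        assert order[0] == 4

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 20))
        ds = make_dataset(X)
        mask = np.arange(30) < 12
        a, b = SampleSelection(mask), SampleSelection(~mask)
        got = rank_by_wasserstein(ds, a, b, 20)
        w = np.array([
            np.sqrt((X[mask, j].mean() - X[~mask, j].mean()) ** 2
                    + (X[mask, j].std() - X[~mask, j].std()) ** 2)
            for j in range(20)
        ])
        expected = sorted(range(20), key=lambda j: (-w[j], j))
        np.testing.assert_array_equal(got, expected)

    def test_n_prefilter_clamped_with_warning(self, small_dataset, selection_pair):
        a, b = selection_pair
        with pytest.warns(UserWarning, match="clamped"):
            order = rank_by_wasserstein(small_dataset, a, b, 999)
        assert order.size == small_dataset.n_features
        with pytest.raises(ValueError):
            rank_by_wasserstein(small_dataset, a, b, 0)


class TestMCC:
    @pytest.mark.parametrize(
        "tp,tn,fp,fn,expected",
        [(10, 10, 0, 0, 1.0), (5, 5, 5, 5, 0.0), (0, 0, 10, 10, -1.0),
         (10, 0, 10, 0, 0.0)],
    )
    def test_examples(self, tp, tn, fp, fn, expected):
        assert mcc(tp, tn, fp, fn) == pytest.approx(expected)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            mcc(-1, 0, 0, 0)
        with pytest.raises(ValueError):
            mcc(0, 0, 0, 0)


class TestBestThreshold:
    def test_perfectly_separable(self):
        theta, direction, m = best_threshold_mcc(
            [1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]
        )
        assert (theta, direction, m) == (6.5, "up_in_A", pytest.approx(1.0))

    def test_constant_values_convention(self):
        theta, direction, m = best_threshold_mcc([5.0] * 6, [1, 0, 1, 0, 1, 0])
        assert (theta, direction, m) == (5.0, "up_in_A", 0.0)

    def test_small_example_matches_brute_force(self):
        got = best_threshold_mcc([1, 2, 3, 4], [0, 1, 0, 1])
        assert got == brute_force_threshold([1, 2, 3, 4], [0, 1, 0, 1])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_on_random_instances(self, data):
        n = data.draw(st.integers(2, 50))
        v = np.array(data.draw(st.lists(
            st.integers(-5, 5), min_size=n, max_size=n)), float)
        a = np.zeros(n, bool)
        a[: data.draw(st.integers(1, n - 1))] = True
        got = best_threshold_mcc(v, a)  # max_grid=100 > all midpoints at n<=50
        exp = brute_force_threshold(v, a)
        assert got[0] == pytest.approx(exp[0])
        assert got[1] == exp[1]
        assert got[2] == pytest.approx(exp[2])

    def test_monotone_transform_invariance_and_negation_flip(self):
        rng = np.random.default_rng(17)
        v = rng.normal(size=30)
        a = rng.random(30) < 0.4
        a[0] = True
        a[1] = False
        _, d0, m0 = best_threshold_mcc(v, a)
        _, d1, m1 = best_threshold_mcc(np.exp(v) + v**3, a)
        assert m1 == pytest.approx(m0, abs=1e-12)
        _, d2, m2 = best_threshold_mcc(-v, a)
        assert m2 == pytest.approx(m0, abs=1e-12)
        assert d2 != d0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            best_threshold_mcc([1, 2, 3], [1, 1, 1])


class TestComputeSignature:
    def test_perfect_marker_ranks_first_with_unit_mcc(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 500), scale=1.0)
        in_a = np.arange(60) < 15
        X[:, 123] = in_a.astype(float)  # 0 outside A, 1 inside A
        ds = make_dataset(X)
        res = compute_signature(ds, SampleSelection(in_a))
        assert res.entries[0].feature == "f123"
        assert res.entries[0].mcc == pytest.approx(1.0)
        assert res.entries[0].direction == "up_in_A"

    def test_default_returns_exactly_100_entries(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng.normal(size=(50, 500)))
        res = compute_signature(ds, SampleSelection(np.arange(50) < 20))
        assert len(res) == 100

    def test_a_vs_b_ignores_unrelated_samples(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 15))
        ds = make_dataset(X)
        mask_a = np.zeros(30, bool)
        mask_a[:8] = True
        mask_b = np.zeros(30, bool)
        mask_b[8:16] = True
        res_full = compute_signature(ds, SampleSelection(mask_a),
                                     SampleSelection(mask_b),
                                     n_prefilter=15, n_top=15)
        ds_trim = ds.subset(np.arange(16))  # drop samples in neither group
        res_trim = compute_signature(ds_trim, SampleSelection(mask_a[:16]),
                                     SampleSelection(mask_b[:16]),
                                     n_prefilter=15, n_top=15)
        assert [(e.feature, e.mcc) for e in res_full.entries] == \
            [(e.feature, e.mcc) for e in res_trim.entries]

    def test_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 20))
        in_a = rng.random(40) < 0.5
        in_a[:2] = [True, False]
        ds = make_dataset(X)
        perm = rng.permutation(40)
        ds_p = ds.subset(perm)
        res = compute_signature(ds, SampleSelection(in_a), n_prefilter=20, n_top=20)
        res_p = compute_signature(ds_p, SampleSelection(in_a[perm]),
                                  n_prefilter=20, n_top=20)
        assert [(e.feature, e.mcc, e.threshold) for e in res.entries] == \
            [(e.feature, e.mcc, e.threshold) for e in res_p.entries]

    def test_invariant_to_feature_permutation(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 20))
        in_a = np.arange(40) < 15
        ds = make_dataset(X)
        perm = rng.permutation(20)
        names = [f"f{j}" for j in range(20)]
        ds_p = make_dataset(X[:, perm])
        # rename so the permuted dataset carries the original feature names
        ds_p.feature_names = np.array([names[j] for j in perm], dtype=object)
        res = compute_signature(ds, SampleSelection(in_a), n_prefilter=20, n_top=20)
        res_p = compute_signature(ds_p, SampleSelection(in_a), n_prefilter=20, n_top=20)
        assert {(e.feature, round(e.mcc, 12)) for e in res.entries} == \
            {(e.feature, round(e.mcc, 12)) for e in res_p.entries}

    def test_marker_recovery_across_seeds(self):
        """Mean-shift marker (3 sigma) lands in the top 10 of the signature."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(200, 500))
            in_a = np.zeros(200, bool)
            in_a[:50] = True
            X[in_a, 250] += 3.0
            ds = make_dataset(X)
            res = compute_signature(ds, SampleSelection(in_a))
            hits += "f250" in [e.feature for e in res.entries[:10]]
        assert hits == 5

    def test_bad_sizes_rejected(self, small_dataset, selection_pair):
        a, b = selection_pair
        with pytest.raises(ValueError):
            compute_signature(small_dataset, a, b, n_top=0)
        with pytest.raises(ValueError):
            compute_signature(small_dataset, a, b, n_prefilter=5, n_top=6)


class TestArrowProjection:
    @pytest.mark.parametrize(
        "start,end,point,expected",
        [((0, 0), (1, 0), (0.5, 7), 0.5), ((0, 0), (1, 0), (0, 0), 0.0),
         ((0, 0), (1, 0), (1, 0), 1.0), ((0, 0), (2, 0), (3, 1), 1.5)],
    )
    def test_projection_values(self, start, end, point, expected):
        arrow = Arrow(start=start, end=end)
        assert project_onto_arrow(np.array([point]), arrow)[0] == pytest.approx(expected)

    def test_zero_length_arrow_rejected(self):
        with pytest.raises(ValidationError, match="zero-length"):
            Arrow(start=(1, 1), end=(1, 1))


class TestPearson:
    def test_examples(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        assert pearson_r(x, [1, 3, 2]) == pytest.approx(0.5)
        assert pearson_r(x, [7.0, 7.0, 7.0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2, 3])


class TestOrientedSignature:
    def _dataset_with_t_feature(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        emb = rng.normal(size=(n, 2))
        arrow = Arrow(start=(0.0, 0.0), end=(1.0, 0.0), embedding_name="emb")
        t = project_onto_arrow(emb, arrow)
        X = rng.normal(size=(n, 10))
        X[:, 3] = t
        X[:, 7] = -t
        return make_dataset(X, embedding=emb), arrow

    def test_feature_equal_to_projection_ranks_first(self):
        ds, arrow = self._dataset_with_t_feature()
        res = oriented_signature(ds, SampleSelection(np.ones(50, bool)), arrow)
        assert res.entries[0][0] == "f3"
        assert res.entries[0][1] == pytest.approx(1.0)

    def test_negated_feature_ranks_last_under_signed_ordering(self):
        ds, arrow = self._dataset_with_t_feature()
        res = oriented_signature(ds, SampleSelection(np.ones(50, bool)), arrow)
        assert res.entries[-1][0] == "f7"
        assert res.entries[-1][1] == pytest.approx(-1.0)

    def test_absolute_ranking_puts_negated_feature_on_top(self):
        ds, arrow = self._dataset_with_t_feature()
        res = oriented_signature(ds, SampleSelection(np.ones(50, bool)), arrow,
                                 absolute=True)
        assert {res.entries[0][0], res.entries[1][0]} == {"f3", "f7"}

    def test_noisy_planted_feature_recovered(self):
        rng = np.random.default_rng(123)
        n = 200
        emb = np.column_stack([rng.uniform(0, 1, n), rng.normal(size=n)])
        arrow = Arrow(start=(0.0, 0.0), end=(1.0, 0.0), embedding_name="emb")
        t = project_onto_arrow(emb, arrow)
        X = rng.normal(size=(n, 50))
        X[:, 20] = t + 0.01 * t.std() * rng.standard_normal(n)
        ds = make_dataset(X, embedding=emb)
        res = oriented_signature(ds, SampleSelection(np.ones(n, bool)), arrow)
        assert res.entries[0][0] == "f20"

    def test_selection_too_small_rejected(self):
        ds, arrow = self._dataset_with_t_feature()
        tiny = SampleSelection(np.arange(50) < 2)
        with pytest.raises(ValidationError, match="at least 3"):
            oriented_signature(ds, tiny, arrow)
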