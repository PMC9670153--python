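"""Tests of cross-profile statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from aufaces.au import EXPRESSIONS
from aufaces.probe import ProfileSet
from aufaces.profile_stats import (
    build_feature_matrix,
    correlate_with_confusion,
    cross_correlation_matrix,
    per_expression_correlations,
    profile_correlation,
    reduce_profile,
    run_pca,
    spearman_rs,
)


def brute_force_spearman(x, y):
    """Independent oracle: midranks by pairwise counting, explicit Pearson."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = sum(1 for vj in v if vj < vi)
            equal = sum(1 for vj in v if vj == vi)
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = midranks(x), midranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx * dx).sum() * (dy * dy).sum()))


class TestSpearman:
    def test_strictly_increasing_pair_is_one(self):
        rs, _ = spearman_rs([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rs == pytest.approx(1.0)

    def test_reversed_pair_is_minus_one(self):
        rs, _ = spearman_rs([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert rs == pytest.approx(-1.0)

    def test_worked_small_example(self):
        # oracle: d^2 sum = 4 -> rs = 1 - 6*4 / (5 * 24) = 0.8
        x, y = [1, 2, 3, 4, 5], [1, 3, 2, 5, 4]
        assert brute_force_spearman(x, y) == pytest.approx(0.8)
        rs, _ = spearman_rs(x, y)
        assert rs == pytest.approx(0.8)

    def test_matches_brute_force_oracle_on_random_vectors(self):
        """1,000 random vectors (with ties): agreement to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 8, n).astype(float)   # heavy ties
            y = rng.normal(size=n)
            if np.all(x == x[0]):
                continue
            rs, _ = spearman_rs(x, y)
            assert abs(rs - brute_force_spearman(x, y)) < 1e-12

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_rs([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])


class TestProfileCorrelation:
    def test_identical_profiles_correlate_perfectly(self, rng):
        p = rng.normal(size=(20, 11))
        rs, _ = profile_correlation(p, p)
        assert rs == pytest.approx(1.0)

    def test_null_exclusion_leaves_200_pairs(self, rng):
        p = rng.normal(size=(20, 11))
        p[:, 0] = 0.0
        a, b = p[:, 1:].ravel(), (2 * p)[:, 1:].ravel()
        assert a.size == 200 == b.size
        rs, _ = profile_correlation(p, 2 * p)
        assert rs == pytest.approx(1.0)   # rank invariance under doubling

    def test_without_exclusion_ties_at_null_shift_rs(self, rng):
        p = rng.normal(size=(20, 11))
        p[:, 0] = 0.0
        q = rng.normal(size=(20, 11))
        q[:, 0] = 0.0
        with_null = profile_correlation(p, q, exclude_null=False)
        without = profile_correlation(p, q, exclude_null=True)
        assert with_null[0] != pytest.approx(without[0])


def _profile_sets(rng):
    a = ProfileSet(rng.normal(size=(7, 20, 11)))
    b = ProfileSet(a.responses + rng.normal(scale=0.5, size=(7, 20, 11)))
    return a, b


class TestPerExpressionCorrelations:
    def test_self_comparison_all_ones(self, rng):
        a, _ = _profile_sets(rng)
        df = per_expression_correlations(a, a)
        assert np.allclose(df["rs"], 1.0)
        assert list(df["expression"]) == list(EXPRESSIONS)

    def test_bonferroni_threshold_at_m7(self):
        # p = 0.0090 exceeds 0.05/7 ~ 0.00714 -> not significant
        assert not (0.0090 < 0.05 / 7)
        assert 0.0050 < 0.05 / 7


class TestCrossCorrelationMatrix:
    def test_49_cells_and_diagonal_self_correlation(self, rng):
        a, _ = _profile_sets(rng)
        m = cross_correlation_matrix(a, a, names=("A", "A"))
        assert m.rs.shape == (7, 7)
        assert np.allclose(np.diag(m.rs), 1.0)
        assert m.n_pairs == 200

    def test_orientation_swap_transposes_without_changing_values(self, rng):
        a, b = _profile_sets(rng)
        m1 = cross_correlation_matrix(a, b, orientation="a-rows", names=("A", "B"))
        m2 = cross_correlation_matrix(a, b, orientation="b-rows", names=("A", "B"))
        assert np.array_equal(m1.rs.T, m2.rs)
        assert m2.row_group == "B"


class TestCorrelateWithConfusion:
    def test_monotone_transform_gives_perfect_rank_correlation(self, rng):
        a, b = _profile_sets(rng)
        m = cross_correlation_matrix(a, b, names=("A", "B"))
        confusion = 1.0 / (1.0 + np.exp(-3 * m.rs))   # softmax-like monotone map
        rs, _ = correlate_with_confusion(m, confusion)
        assert rs == pytest.approx(1.0)

    def test_axis_convention_mismatch_rejected(self, rng):
        a, b = _profile_sets(rng)
        m = cross_correlation_matrix(a, b, names=("A", "B"))
        with pytest.raises(ValueError, match="axis"):
            correlate_with_confusion(m, np.eye(7), confusion_true_group="B")


class TestReduceProfile:
    def test_all_zero_profile_reduces_to_zeros(self):
        assert not reduce_profile(np.zeros((20, 11))).values.any()

    def test_monotone_row_keeps_endpoint(self, rng):
        p = np.zeros((20, 11))
        p[0] = np.linspace(0, 1, 11)
        assert reduce_profile(p).values[0] == 1.0

    def test_trough_kept_with_sign(self):
        p = np.zeros((20, 11))
        p[3, 1] = -0.5
        p[3, 2] = 0.3
        assert reduce_profile(p).values[3] == -0.5

    def test_magnitude_tie_resolves_to_higher_intensity(self):
        p = np.zeros((20, 11))
        p[5, 2] = 0.7
        p[5, 9] = -0.7
        assert reduce_profile(p).values[5] == -0.7


class TestFeatureMatrixAndPCA:
    @pytest.fixture
    def reduced(self, rng):
        return [
            reduce_profile(rng.normal(size=(20, 11)), unit=label, database=db)
            for db in ("A", "B") for label in EXPRESSIONS
        ]

    def test_shape_and_column_lookup(self, reduced):
        fm = build_feature_matrix(reduced)
        assert fm.shape == (20, 14)
        col = fm[("A", "happy")]
        src = next(r for r in reduced if r.database == "A" and r.unit == "happy")
        assert np.array_equal(col.to_numpy(), src.values)

    def test_input_order_irrelevant(self, reduced):
        fm1 = build_feature_matrix(reduced)
        fm2 = build_feature_matrix(list(reversed(reduced)))
        pd.testing.assert_frame_equal(fm1, fm2)

    def test_missing_profile_rejected(self, reduced):
        with pytest.raises(ValueError, match="14"):
            build_feature_matrix(reduced[:-1])

    def test_explained_variance_sums_to_one(self, reduced):
        res = run_pca(build_feature_matrix(reduced), n_components=3)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.scores.shape == (14, 3)

    def test_rank_one_matrix_explained_by_first_component(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=14)
        fm = pd.DataFrame(
            np.outer(u, v),
            index=[f"AU#{i}" for i in range(20)],
            columns=pd.MultiIndex.from_product([("A", "B"), EXPRESSIONS]),
        )
        res = run_pca(fm, n_components=2)
        assert res.explained_variance_ratio[0] > 0.999

    def test_too_many_components_rejected(self, reduced):
        with pytest.raises(ValueError, match="components"):
            run_pca(build_feature_matrix(reduced), n_components=14)

    def test_score_geometry_sign_invariant(self, reduced):
        """Pairwise score distances are reproducible across refits."""
        fm = build_feature_matrix(reduced)
        s1 = run_pca(fm, 3).scores
        s2 = run_pca(fm.iloc[:, :], 3).scores
        d1 = np.linalg.norm(s1[:, None] - s1[None], axis=-1)
        d2 = np.linalg.norm(s2[:, None] - s2[None], axis=-1)
        assert np.allclose(d1, d2)
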