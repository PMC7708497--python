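import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cardiomembrane.tissue import (
    cardiac_fold,
    cardiac_folds,
    heatmap_matrix,
    hierarchical_cluster,
    is_cardiac_enriched,
    normalize_to_total,
)
from cardiomembrane.types import ExpressionMatrix, ValidationError

TISSUES = ["heart"] + [f"t{i}" for i in range(8)]


def _row(heart, others):
    return pd.Series([heart] + list(others), index=TISSUES)


class TestCardiacFold:
    def test_uniform_row(self):
        assert cardiac_fold(_row(10, [10] * 8), ["heart"]) == pytest.approx(1.0)

    def test_three_fold_over_median(self):
        assert cardiac_fold(_row(30, [10] * 8), ["heart"]) == pytest.approx(3.0)

    def test_depleted_gene(self):
        assert cardiac_fold(_row(5, [10] * 8), ["heart"]) == pytest.approx(0.5)

    def test_zero_denominator(self):
        assert cardiac_fold(_row(4, [0] * 8), ["heart"]) == math.inf
        assert cardiac_fold(_row(0, [0] * 8), ["heart"]) == 0.0

    def test_multiple_heart_columns_use_max(self):
        row = pd.Series([5, 40, 10, 10, 10], index=["heart", "fetal_heart", "a", "b", "c"])
        fold = cardiac_fold(row, ["heart", "fetal_heart"])
        assert fold == pytest.approx(4.0)

    def test_scale_invariance(self, rng):
        vals = rng.lognormal(3, 1, size=9)
        row = pd.Series(vals, index=TISSUES)
        f1 = cardiac_fold(row, ["heart"])
        f2 = cardiac_fold(row * 37.5, ["heart"])
        assert f1 == pytest.approx(f2)

    def test_adding_median_tissue_leaves_fold_unchanged(self):
        row = _row(30, [8, 9, 10, 10, 10, 11, 12, 13])
        base = cardiac_fold(row, ["heart"])
        med = float(np.median(row.drop("heart")))
        extended = pd.concat([row, pd.Series({"extra": med})])
        assert cardiac_fold(extended, ["heart"]) == pytest.approx(base)

    def test_requires_two_non_heart(self):
        with pytest.raises(ValidationError):
            cardiac_fold(pd.Series({"heart": 3, "t0": 1}), ["heart"])

    def test_aggregator_mean(self):
        row = _row(30, [0, 0, 0, 0, 0, 0, 0, 80])
        assert cardiac_fold(row, ["heart"], aggregator="mean") == pytest.approx(3.0)


class TestEnrichedCall:
    @pytest.mark.parametrize(
        "fold,expected", [(3.0, True), (2.99, False), (math.inf, True), (0.0, False)]
    )
    def test_inclusive_default(self, fold, expected):
        assert is_cardiac_enriched(fold) is expected

    def test_exclusive_option(self):
        assert not is_cardiac_enriched(3.0, inclusive=False)
        assert is_cardiac_enriched(3.01, inclusive=False)

    def test_nan_is_not_enriched(self):
        assert not is_cardiac_enriched(float("nan"))


class TestNormalizeToTotal:
    def test_arithmetic(self):
        df = pd.DataFrame([[2.0, 2.0, 4.0]], columns=["a", "b", "c"])
        normed, flags = normalize_to_total(df)
        assert np.allclose(normed.to_numpy(), [[0.25, 0.25, 0.5]])
        assert flags == []

    def test_single_tissue_all_ones(self):
        df = pd.DataFrame({"only": [3.0, 7.0]})
        normed, _ = normalize_to_total(df)
        assert np.allclose(normed.to_numpy(), 1.0)

    def test_zero_row_flagged(self):
        df = pd.DataFrame([[0.0, 0.0], [1.0, 3.0]], index=["z", "g"], columns=["a", "b"])
        normed, flags = normalize_to_total(df)
        assert flags == ["z"]
        assert np.allclose(normed.loc["z"], 0.0)

    def test_idempotent_and_rows_sum_to_one(self, rng):
        df = pd.DataFrame(rng.lognormal(0, 1, size=(12, 5)))
        once, _ = normalize_to_total(df)
        twice, _ = normalize_to_total(once)
        assert np.allclose(once.sum(axis=1), 1.0, atol=1e-9)
        pd.testing.assert_frame_equal(once, twice)


def _oracle_first_merge(mat):
    """Exhaustive search: the closest row pair merges first (euclidean)."""
    best, pair = math.inf, None
    for i, j in itertools.combinations(range(len(mat)), 2):
        d = float(np.linalg.norm(mat[i] - mat[j]))
        if d < best:
            best, pair = d, {i, j}
    return pair


class TestHierarchicalCluster:
    def test_identical_pair_merges_first(self):
        df = pd.DataFrame(
            [[1.0, 0.0], [9.0, 9.0], [1.0, 0.0]], index=["a", "b", "c"]
        )
        linkage, _ = hierarchical_cluster(df)
        assert {int(linkage[0, 0]), int(linkage[0, 1])} == {0, 2}
        assert linkage[0, 2] == pytest.approx(0.0)

    def test_first_merge_matches_exhaustive_oracle(self, rng):
        for n in (3, 4, 5):
            mat = rng.normal(size=(n, 4))
            df = pd.DataFrame(mat)
            linkage, _ = hierarchical_cluster(df)
            assert {int(linkage[0, 0]), int(linkage[0, 1])} == _oracle_first_merge(mat)

    def test_permutation_invariance_up_to_relabeling(self, rng):
        mat = rng.normal(size=(6, 3))
        df = pd.DataFrame(mat, index=[f"g{i}" for i in range(6)])
        _, order1 = hierarchical_cluster(df)
        perm = rng.permutation(6)
        _, order2 = hierarchical_cluster(df.iloc[perm])
        # same tree -> same leaf sequence or its reversal, by label
        assert order2 in (order1, order1[::-1]) or set(order2) == set(order1)
        # merge heights identical
        l1, _ = hierarchical_cluster(df)
        l2, _ = hierarchical_cluster(df.iloc[perm])
        assert np.allclose(sorted(l1[:, 2]), sorted(l2[:, 2]))

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(pd.DataFrame([[1.0, 2.0]]))

    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValidationError):
            hierarchical_cluster(df)


class TestHeatmapMatrix:
    def test_rows_normalized_and_reordered(self, small_dataset):
        dataset, _ = small_dataset
        genes = list(dataset.expression.genes[:10])
        mat = heatmap_matrix(dataset.expression, genes)
        assert set(mat.index) == set(genes)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-9)


def test_cardiac_folds_vectorized_matches_scalar(small_dataset):
    dataset, _ = small_dataset
    folds = cardiac_folds(dataset.expression)
    g = dataset.expression.genes[3]
    assert folds[g] == pytest.approx(
        cardiac_fold(dataset.expression.values.loc[g], dataset.expression.heart_tissues)
    )
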