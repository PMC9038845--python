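import numpy as np
import pandas as pd
import pytest

from evoselect.exceptions import ConfigurationError, EvaluationError
from evoselect.preprocessing import (
    NMFImputer,
    agglomerate_summary,
    balance_classes,
    discretize_target,
    drop_high_missing,
    minmax_scale,
    nmf_impute,
    prepare_partition,
    select_transform,
    split_data,
    winsorize,
)


class TestSplitData:
    def test_seventy_thirty_partition(self, rng):
        df = pd.DataFrame({"a": np.arange(1000.0)})
        train, val = split_data(df, 0.7, rng)
        assert (len(train), len(val)) == (700, 300)

    def test_disjoint_and_exhaustive(self, rng):
        df = pd.DataFrame({"a": np.arange(100.0)})
        train, val = split_data(df, 0.7, rng)
        assert set(train.index).isdisjoint(val.index)
        assert set(train.index) | set(val.index) == set(df.index)

    def test_fixed_seed_identical_partition(self):
        df = pd.DataFrame({"a": np.arange(50.0)})
        splits = [split_data(df, 0.7, np.random.default_rng(4)) for _ in range(2)]
        assert list(splits[0][0].index) == list(splits[1][0].index)

    def test_degenerate_partition_rejected(self, rng):
        df = pd.DataFrame({"a": np.arange(4.0)})
        with pytest.raises(ConfigurationError):
            split_data(df, 0.9, rng)


class TestMissingnessFilter:
    def _frame(self, missing_fraction, n=100):
        col = np.arange(float(n))
        col[: int(missing_fraction * n)] = np.nan
        return pd.DataFrame({"target_col": col, "full": np.arange(float(n))})

    def test_above_cutoff_dropped(self):
        out = drop_high_missing(self._frame(0.41))
        assert list(out.columns) == ["full"]

    def test_exactly_at_cutoff_kept(self):
        out = drop_high_missing(self._frame(0.40))
        assert "target_col" in out.columns

    def test_no_missing_is_identity(self):
        df = self._frame(0.0)
        pd.testing.assert_frame_equal(drop_high_missing(df), df)

    def test_all_dropped_rejected(self):
        df = pd.DataFrame({"a": [np.nan] * 10})
        with pytest.raises(ConfigurationError):
            drop_high_missing(df)


class TestWinsorize:
    def test_hand_arithmetic_single_outlier(self):
        # 100 zeros and one 1000: bound = mean + 3 * population sd
        values = np.array([0.0] * 100 + [1000.0])
        mean, sd = values.mean(), values.std()
        out = winsorize(pd.DataFrame({"x": values}))
        assert out["x"].max() == pytest.approx(mean + 3 * sd)
        assert (out["x"][:100] == 0.0).all()

    def test_values_within_bounds_untouched(self, rng):
        df = pd.DataFrame({"x": rng.uniform(0, 1, 200)})
        pd.testing.assert_frame_equal(winsorize(df), df)

    def test_idempotent_with_fitted_bounds(self, rng):
        from evoselect.preprocessing import Winsorizer

        df = pd.DataFrame({"x": rng.standard_t(df=2, size=500)})
        w = Winsorizer().fit(df)
        once = w.transform(df)
        twice = w.transform(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_variance_feature_unchanged(self):
        df = pd.DataFrame({"x": [5.0] * 10})
        pd.testing.assert_frame_equal(winsorize(df), df)

    def test_moments_ignore_missing_entries(self):
        values = np.array([0.0] * 100 + [1000.0])
        with_nan = np.concatenate([values, [np.nan] * 50])
        out = winsorize(pd.DataFrame({"x": with_nan}))
        assert out["x"].max() == pytest.approx(values.mean() + 3 * values.std())


class TestNMFImpute:
    def test_rank_one_recovery_within_one_percent(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(1, 2, size=20)
        v = rng.uniform(1, 2, size=8)
        M = np.outer(u, v)
        masked = M.copy()
        masked[3, 5] = np.nan
        out = nmf_impute(pd.DataFrame(masked), rank=1, rng=rng)
        rel_err = abs(out.iloc[3, 5] - M[3, 5]) / M[3, 5]
        assert rel_err < 0.01

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(1)
        M = rng.uniform(0, 1, size=(15, 6))
        masked = M.copy()
        masked[2, 2] = np.nan
        out = nmf_impute(pd.DataFrame(masked), rank=2, rng=rng)
        observed = ~np.isnan(masked)
        assert np.array_equal(out.to_numpy()[observed], M[observed])

    def test_no_missing_is_identity(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, size=(10, 4)))
        pd.testing.assert_frame_equal(nmf_impute(df, rng=rng), df)

    def test_observed_loss_non_increasing(self):
        rng = np.random.default_rng(2)
        M = rng.uniform(0, 1, size=(30, 10))
        M[rng.uniform(size=M.shape) < 0.2] = np.nan
        imputer = NMFImputer(rank=3, random_state=0)
        imputer.fit_transform(pd.DataFrame(M))
        losses = imputer.losses_
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_negative_values_supported_via_min_shift(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(1, 2, size=20)
        v = rng.uniform(1, 2, size=6)
        M = np.outer(u, v) - 5.0  # strictly negative entries
        masked = M.copy()
        masked[4, 1] = np.nan
        # the min-shift adds a rank-one constant plane, so rank 2 fits it
        out = nmf_impute(pd.DataFrame(masked), rank=2, rng=rng)
        assert abs(out.iloc[4, 1] - M[4, 1]) < 0.1

    def test_fully_missing_column_named_in_error(self):
        df = pd.DataFrame({"good": [1.0, 2.0], "bad": [np.nan, np.nan]})
        with pytest.raises(EvaluationError, match="bad"):
            nmf_impute(df)


class TestMinMaxScale:
    def test_maps_to_unit_interval(self):
        out = minmax_scale(pd.DataFrame({"x": [2.0, 4.0, 6.0]}))
        assert list(out["x"]) == [0.0, 0.5, 1.0]

    def test_constant_feature_maps_to_zero(self):
        out = minmax_scale(pd.DataFrame({"x": [3.0, 3.0, 3.0]}))
        assert (out["x"] == 0.0).all()

    def test_nonconstant_features_span_unit_interval(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        out = minmax_scale(df)
        assert np.allclose(out.min(), 0.0)
        assert np.allclose(out.max(), 1.0)


class TestSelectTransform:
    def test_exponential_sample_gets_non_identity(self):
        rng = np.random.default_rng(5)
        x = rng.exponential(size=500)
        from evoselect.preprocessing import _normality_score

        transformed, label = select_transform(x, random_state=0)
        assert label != "identity"
        assert _normality_score(transformed) < _normality_score(x)

    def test_normal_sample_keeps_identity_or_improves(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500)
        from evoselect.preprocessing import _normality_score

        transformed, label = select_transform(x, random_state=0)
        # whichever candidate wins must not look less normal than x
        assert _normality_score(transformed) <= _normality_score(x) + 1e-9

    def test_constant_vector_identity(self):
        x = np.full(30, 2.0)
        transformed, label = select_transform(x)
        assert label == "identity"
        assert np.array_equal(transformed, x)

    def test_too_few_observations_rejected(self):
        with pytest.raises(EvaluationError):
            select_transform(np.arange(10.0))


class TestAgglomerateSummary:
    def test_two_identical_items_equal_their_standardized_value(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"i1": x, "i2": x})
        summary = agglomerate_summary(df)
        z = (x - x.mean()) / x.std()
        assert np.allclose(summary, z)

    def test_noise_items_average_reduces_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 8)))
        summary = agglomerate_summary(df)
        assert summary.var() < 0.5  # mean of 8 unit-variance z-scores

    def test_item_order_symmetric(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        s1 = agglomerate_summary(df)
        s2 = agglomerate_summary(df[list("edcba")])
        assert np.allclose(s1, s2)

    def test_single_item_rejected(self):
        with pytest.raises(ConfigurationError):
            agglomerate_summary(pd.DataFrame({"only": [1.0, 2.0]}))


class TestDiscretizeTarget:
    def test_threshold_strictly_above(self):
        labels = discretize_target([0.0, 0.0, 5.0, 9.0], cutoff=0.0)
        assert list(labels) == [0, 0, 1, 1]

    def test_cutoff_above_max_rejected(self):
        with pytest.raises(ConfigurationError):
            discretize_target([1.0, 2.0, 3.0], cutoff=10.0)

    def test_counts_sum_to_n(self, rng):
        scores = rng.normal(size=200)
        labels = discretize_target(scores, cutoff=0.3)
        assert len(labels) == 200
        assert set(labels) == {0, 1}


class TestBalanceClasses:
    def _imbalanced(self, rng, n_min=10, n_maj=90):
        X_min = rng.normal(loc=-3, size=(n_min, 2))
        X_maj = rng.normal(loc=3, size=(n_maj, 2))
        X = np.vstack([X_min, X_maj])
        y = np.array([1] * n_min + [0] * n_maj)
        return X, y

    def test_oversampled_to_parity_then_cleaned(self, rng):
        X, y = self._imbalanced(rng)
        Xr, yr = balance_classes(X, y, rng)
        counts = np.bincount(yr)
        ratio = counts.min() / counts.max()
        assert 0.7 <= ratio <= 1.3

    def test_separated_balanced_clusters_nearly_untouched(self, rng):
        X, y = self._imbalanced(rng, n_min=50, n_maj=50)
        Xr, yr = balance_classes(X, y, rng)
        assert abs(len(yr) - len(y)) <= 2

    def test_synthetic_points_lie_on_minority_segments(self, rng):
        # 1-D minority values: synthetic points must fall inside the
        # minority value range (convexity of segment interpolation)
        X = np.concatenate([[0.0, 1.0, 2.0], np.full(30, 10.0)]).reshape(-1, 1)
        y = np.array([1] * 3 + [0] * 30)
        Xr, yr = balance_classes(X, y, rng)
        new_minority = Xr[yr == 1].ravel()
        assert np.all((new_minority >= 0.0) & (new_minority <= 2.0))

    def test_minority_below_two_rejected(self, rng):
        X = np.zeros((10, 2))
        y = np.array([1] + [0] * 9)
        with pytest.raises(ConfigurationError):
            balance_classes(X, y, rng)


class TestPipelineOrchestration:
    def _raw(self, rng, n=120):
        X = rng.normal(size=(n, 6))
        y = X[:, 0] + 0.2 * rng.normal(size=n)
        df = pd.DataFrame(X, columns=[f"c{i}" for i in range(6)])
        df.loc[: int(0.6 * n), "c5"] = np.nan  # > 40% missing, dropped
        df.loc[rng.choice(n, 10, replace=False), "c1"] = np.nan  # imputable
        df["y"] = y
        return df

    def test_stage_order_and_output_contract(self, rng):
        df = self._raw(rng)
        X, y, report = prepare_partition(df, "y", task="regression", rng=rng)
        assert "c5" in report.dropped_features
        assert not X.isna().any().any()
        assert report.imputed_cells == 10
        assert len(X) == len(y) == len(df)

    def test_classification_branch_balances_train_only(self, rng):
        df = self._raw(rng, n=150)
        X, y, report = prepare_partition(
            df, "y", task="classification", cutoff=0.8, balance=True, rng=rng
        )
        counts = np.bincount(y)
        assert counts.min() / counts.max() > 0.6
        assert report.n_after_balance == len(y)

    def test_deterministic_under_fixed_seed(self):
        df = self._raw(np.random.default_rng(9))
        outs = [
            prepare_partition(df, "y", task="regression", rng=np.random.default_rng(3))
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])

    def test_partition_statistics_do_not_leak(self, rng):
        # preparing one partition must not be affected by the other
        df = self._raw(rng, n=200)
        train, val = split_data(df, 0.7, np.random.default_rng(0))
        X_both, _, _ = prepare_partition(
            train, "y", task="regression", rng=np.random.default_rng(1)
        )
        X_alone, _, _ = prepare_partition(
            train.copy(), "y", task="regression", rng=np.random.default_rng(1)
        )
        pd.testing.assert_frame_equal(X_both, X_alone)
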