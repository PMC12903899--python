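"""Cross-validation, correlation metrics, and the diagnostic analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import guidescreen as gs
from guidescreen.evaluation import (
    _safe_pearson,
    _safe_spearman,
    cross_validate,
    dinuc_profile,
    error_by_count,
)
from guidescreen.model import build_linear


def random_onehot(n, length, seed=0):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 4, length))
    codes = rng.integers(0, 4, size=(n, length))
    for i in range(n):
        X[i, codes[i], np.arange(length)] = 1.0
    return X


class TestCorrelationMetrics:
    def test_agree_with_independent_reference(self):
        """scipy metrics vs hand-rolled rank/moment formulas to 1e-12."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            a, b = rng.normal(size=200), rng.normal(size=200)
            ref_pearson = np.corrcoef(a, b)[0, 1]
            ra, rb = stats.rankdata(a), stats.rankdata(b)
            ref_spearman = np.corrcoef(ra, rb)[0, 1]
            assert abs(_safe_pearson(a, b) - ref_pearson) < 1e-12
            assert abs(_safe_spearman(a, b) - ref_spearman) < 1e-12

    def test_constant_vector_reports_missing(self):
        assert np.isnan(_safe_spearman(np.ones(10), np.arange(10.0)))


class TestCrossValidate:
    def test_perfect_predictor_scores_one(self, label_lookup_cls):
        X = random_onehot(60, 10, seed=2)
        y = np.random.default_rng(3).normal(size=60)
        res = cross_validate((X, y), lambda s=None: label_lookup_cls(X, y), k=5, seed=4)
        assert res.spearman_mean == pytest.approx(1.0)
        assert res.pearson_mean == pytest.approx(1.0)

    def test_permuted_labels_give_null_correlation(self):
        """Labels with no sequence dependence: CV Spearman centred at 0 over 10 seeds."""
        X = random_onehot(1000, 12, seed=20)
        means = []
        for seed in range(10):
            y = np.random.default_rng(seed + 100).normal(size=1000)
            res = cross_validate((X, y), lambda s=None: build_linear(), k=5, seed=seed)
            means.append(res.spearman_mean)
        assert abs(np.mean(means)) <= 0.1

    def test_each_sample_validated_exactly_once(self):
        from sklearn.model_selection import KFold

        kf = KFold(n_splits=5, shuffle=True, random_state=11)
        seen = np.zeros(83, dtype=int)
        for _, va in kf.split(np.zeros((83, 1))):
            seen[va] += 1
        assert (seen == 1).all()

    def test_constant_predictions_flagged_missing(self, constant_factory):
        X = random_onehot(40, 8, seed=5)
        y = np.random.default_rng(6).normal(size=40)
        res = cross_validate((X, y), constant_factory, k=4, seed=7)
        assert res.n_missing_folds == 4

    def test_more_folds_than_samples_rejected(self):
        X = random_onehot(3, 8)
        with pytest.raises(ValueError):
            cross_validate((X, np.zeros(3)), lambda s=None: build_linear(), k=5)


class TestDinucProfile:
    def _windows(self, n, width, seed):
        rng = np.random.default_rng(seed)
        return ["".join(rng.choice(list("ACGT"), size=width)) for _ in range(n)]

    def test_constant_labels_give_constant_cells(self):
        windows = self._windows(300, 30, seed=8)
        prof = dinuc_profile(windows, np.full(300, 2.5), range(-5, 4), spacer_offset=5)
        occupied = prof.means.to_numpy()[prof.counts.to_numpy() > 0]
        assert np.allclose(occupied, 2.5)

    def test_planted_tt_bonus_is_row_maximum(self):
        windows = self._windows(2000, 30, seed=9)
        # spacer positions 19-20 are PAM-relative (-2, -1) with offset 5
        labels = np.array([3.0 if w[5 + 18 : 5 + 20] == "TT" else 0.0 for w in windows])
        prof = dinuc_profile(windows, labels, [-4, -2, 2], spacer_offset=5)
        assert prof.means[-2].idxmax() == "TT"

    def test_per_position_counts_sum_to_n(self):
        windows = self._windows(500, 30, seed=10)
        prof = dinuc_profile(windows, np.zeros(500), range(-10, 4), spacer_offset=5)
        assert (prof.counts.sum(axis=0) == 500).all()

    def test_position_outside_window_rejected(self):
        windows = self._windows(10, 25, seed=11)
        with pytest.raises(ValueError, match="outside"):
            dinuc_profile(windows, np.zeros(10), [10], spacer_offset=0)


class TestErrorByCount:
    def _scores(self, counts):
        return pd.DataFrame(
            {"score": np.zeros(len(counts)), "mean_control_count": counts},
            index=pd.Index([f"g{i}" for i in range(len(counts))], name="guide_id"),
        )

    def test_zero_error_when_predictions_equal_scores(self):
        scores = self._scores([2.0, 7.0, 30.0, 60.0])
        pred = pd.Series(scores["score"].to_numpy(), index=scores.index)
        res = error_by_count(pred, scores, bins=[1, 10, 100])
        assert (res["mae"] == 0).all()

    def test_bin_counts_partition_the_guides(self):
        rng = np.random.default_rng(12)
        counts = rng.uniform(1, 99, size=200)
        scores = self._scores(counts)
        pred = pd.Series(rng.normal(size=200), index=scores.index)
        res = error_by_count(pred, scores)
        assert res["n"].sum() == 200
        assert (res["n_positive"] + res["n_negative"]).equals(res["n"])

    def test_unmatched_guide_ids_rejected(self):
        scores = self._scores([5.0, 10.0])
        pred = pd.Series([0.1], index=["unknown"])
        with pytest.raises(ValueError, match="unmatched"):
            error_by_count(pred, scores)

    def test_sign_stratification(self):
        scores = self._scores([2.0, 2.0])
        pred = pd.Series([1.0, -2.0], index=scores.index)
        res = error_by_count(pred, scores, bins=[1, 10])
        row = res.iloc[0]
        assert row["mae_positive"] == pytest.approx(1.0)
        assert row["mae_negative"] == pytest.approx(2.0)


class TestSweepLengths:
    def test_upstream_zero_entry_is_the_baseline(self, small_study):
        res = gs.sweep_lengths(
            small_study.genome, small_study.sites, small_study.scores,
            "upstream", 2, lambda s=None: build_linear(), k=3, seed=3,
        )
        assert res.entries.loc[0, "delta_vs_baseline"] == 0.0

    def test_unknown_mode_rejected(self, small_study):
        with pytest.raises(ValueError, match="mode"):
            gs.sweep_lengths(
                small_study.genome, small_study.sites, small_study.scores,
                "sideways", 2, lambda s=None: build_linear(),
            )
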