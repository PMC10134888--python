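import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mginfeval import (
    AbundanceTable,
    PermutationPlan,
    TableError,
    feature_concordance,
    permutation_robustness,
    permute_pair,
    restrict_to_shared_features,
    spearman,
    summarize_concordance,
)
from mginfeval.concordance import columnwise_spearman

import _oracles


def _table(values, ids, cols, scale="counts"):
    return AbundanceTable(
        pd.DataFrame(np.asarray(values, dtype=float), index=ids, columns=cols), scale
    )


class TestRestrictToSharedFeatures:
    def _three_tables(self):
        ids = ["s1", "s2"]
        observed = _table([[1, 2, 3, 0], [1, 1, 1, 0]], ids, ["K1", "K2", "K3", "K5"])
        pred_a = _table([[1, 2, 0, 4], [2, 2, 0, 4]], ids, ["K1", "K2", "K3", "K4"])
        pred_b = _table([[2, 1, 5], [1, 1, 5]], ids, ["K1", "K2", "K5"])
        return observed, {"a": pred_a, "b": pred_b}

    def test_toy_intersection_is_exactly_two_kos(self):
        observed, predicted = self._three_tables()
        obs, preds, shared = restrict_to_shared_features(observed, predicted)
        assert shared.feature_ids == ("K1", "K2")
        assert shared.n_shared == 2
        assert obs.feature_ids == ["K1", "K2"]
        for t in preds.values():
            assert t.feature_ids == ["K1", "K2"]

    def test_values_not_renormalized_by_default(self):
        observed, predicted = self._three_tables()
        obs, _, _ = restrict_to_shared_features(observed, predicted)
        np.testing.assert_array_equal(obs.values, [[1, 2], [1, 1]])

    def test_renormalize_flag(self):
        observed, predicted = self._three_tables()
        obs, _, _ = restrict_to_shared_features(observed, predicted, renormalize=True)
        np.testing.assert_allclose(obs.values.sum(axis=1), 1.0)

    def test_identical_feature_sets_pass_through(self):
        ids, cols = ["s1", "s2", "s3"], ["K1", "K2"]
        observed = _table([[1, 2], [2, 1], [3, 3]], ids, cols)
        predicted = {"m": _table([[2, 2], [1, 1], [3, 1]], ids, cols)}
        obs, _, shared = restrict_to_shared_features(observed, predicted)
        assert shared.n_shared == 2
        np.testing.assert_array_equal(obs.values, observed.values)

    def test_disjoint_feature_sets_error(self):
        ids = ["s1", "s2"]
        observed = _table([[1, 2], [2, 1]], ids, ["K1", "K2"])
        predicted = {"m": _table([[1, 2], [2, 1]], ids, ["K3", "K4"])}
        with pytest.raises(TableError, match="no features shared"):
            restrict_to_shared_features(observed, predicted)

    def test_source_counts_track_positive_features(self):
        observed, predicted = self._three_tables()
        _, _, shared = restrict_to_shared_features(observed, predicted)
        assert shared.source_counts == {"observed": 3, "a": 3, "b": 3}


class TestSpearman:
    def test_monotone_vectors(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_example_matches_frozen_oracle_value(self):
        # mid-ranks of x=(1,2,2,4) vs y=(3,1,1,2), Pearson by hand: -1/3
        assert spearman([1, 2, 2, 4], [3, 1, 1, 2]) == pytest.approx(-1 / 3, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        assert spearman([1, 1, 1], [1, 2, 3]) is None

    @given(
        st.lists(st.integers(min_value=0, max_value=5), min_size=3, max_size=8),
        st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_midrank_pearson_oracle_with_ties(self, x, seed):
        y = list(np.random.default_rng(seed).integers(0, 5, size=len(x)))
        expected = _oracles.spearman_oracle(x, y)
        got = spearman(x, y)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_columnwise_matches_scalar(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 4, size=(10, 6)).astype(float)
        y = rng.integers(0, 4, size=(10, 6)).astype(float)
        vec = columnwise_spearman(x, y)
        for j in range(6):
            scalar = spearman(x[:, j], y[:, j])
            if scalar is None:
                assert np.isnan(vec[j])
            else:
                assert vec[j] == pytest.approx(scalar, abs=1e-12)


class TestFeatureConcordance:
    def test_perfect_prediction_gives_rho_one_everywhere(self, small_dataset):
        obs, preds, _ = restrict_to_shared_features(
            small_dataset.observed_ko, {"self": small_dataset.observed_ko}
        )
        records = feature_concordance(obs, preds, small_dataset.frame)
        defined = records["rho"].dropna()
        np.testing.assert_allclose(defined, 1.0, atol=1e-12)

    def test_shuffled_samples_destroy_concordance(self, default_dataset):
        obs = default_dataset.observed_ko
        rng = np.random.default_rng(1)
        perm = rng.permutation(obs.n_samples)
        shuffled = AbundanceTable(
            pd.DataFrame(
                obs.values[perm], index=obs.sample_ids, columns=obs.feature_ids
            ),
            "relative",
        )
        obs_cut, preds, _ = restrict_to_shared_features(obs, {"shuffled": shuffled})
        records = feature_concordance(obs_cut, preds, default_dataset.frame, ("overall",))
        assert abs(records["rho"].median()) < 0.1

    def test_small_stratum_flagged_not_dropped(self, toy_table, toy_frame):
        records = feature_concordance(
            toy_table, {"m": toy_table}, toy_frame, ("overall", "cluster")
        )
        assert (records["reason"] == "fewer than 3 samples").all()
        assert records["rho"].isna().all()

    def test_category_records_relabel_overall(self, small_dataset):
        obs, preds, _ = restrict_to_shared_features(
            small_dataset.observed_ko, small_dataset.predicted_ko
        )
        records = feature_concordance(
            obs, preds, small_dataset.frame, ("overall",),
            annotation=small_dataset.annotation,
        )
        overall = records[records["stratum_type"] == "overall"]
        cats = records[records["stratum_type"] == "category"]
        assert len(cats) == len(overall)
        merged = overall.merge(cats, on=["feature_id", "method"], suffixes=("_o", "_c"))
        np.testing.assert_array_equal(merged["rho_o"], merged["rho_c"])


class TestSummarize:
    def test_median_and_range(self):
        records = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "stratum": "overall",
                "stratum_type": "overall",
                "method": "m",
                "rho": [0.1, 0.2, 0.3],
                "n_samples": 5,
                "reason": "",
            }
        )
        row = summarize_concordance(records).iloc[0]
        assert row["median_rho"] == pytest.approx(0.2)
        assert (row["min_rho"], row["max_rho"]) == (pytest.approx(0.1), pytest.approx(0.3))

    def test_undefined_counted_separately(self):
        records = pd.DataFrame(
            {
                "feature_id": ["a", "b"],
                "stratum": "overall",
                "stratum_type": "overall",
                "method": "m",
                "rho": [0.4, np.nan],
                "n_samples": 5,
                "reason": ["", "constant vector"],
            }
        )
        row = summarize_concordance(records).iloc[0]
        assert row["n_defined"] == 1
        assert row["n_undefined"] == 1
        assert row["median_rho"] == pytest.approx(0.4)


class TestPermutation:
    def test_column_multisets_preserved_exactly(self, small_dataset):
        obs, preds, _ = restrict_to_shared_features(
            small_dataset.observed_ko, small_dataset.predicted_ko
        )
        plan = PermutationPlan(n_permutations=3, seed=9)
        obs_p, preds_p = permute_pair(obs, preds, plan, 0)
        for orig, perm in [(obs, obs_p)] + [
            (preds[k], preds_p[k]) for k in preds
        ]:
            for col in orig.feature_ids:
                assert sorted(orig.data[col]) == sorted(perm.data[col])

    def test_same_replicate_is_deterministic(self, small_dataset):
        obs, preds, _ = restrict_to_shared_features(
            small_dataset.observed_ko, small_dataset.predicted_ko
        )
        plan = PermutationPlan(n_permutations=2, seed=10)
        a, _ = permute_pair(obs, preds, plan, 1)
        b, _ = permute_pair(obs, preds, plan, 1)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_observed_and_predicted_permutations_differ(self, default_dataset):
        obs, preds, _ = restrict_to_shared_features(
            default_dataset.observed_ko, default_dataset.predicted_ko
        )
        plan = PermutationPlan(n_permutations=1, seed=11)
        obs_p, preds_p = permute_pair(obs, preds, plan, 0)
        # at n = 72 the chance of any shared column permutation is negligible
        pred_p = next(iter(preds_p.values()))
        obs_rank = obs_p.data.rank()
        pred_rank = pred_p.data.rank()
        same = (obs_rank.to_numpy() == pred_rank.to_numpy()).all(axis=0).sum()
        assert same == 0

    def test_out_of_range_replicate_rejected(self, small_dataset):
        obs, preds, _ = restrict_to_shared_features(
            small_dataset.observed_ko, small_dataset.predicted_ko
        )
        with pytest.raises(ValueError, match="replicate"):
            permute_pair(obs, preds, PermutationPlan(2, 0), 2)


class TestPermutationRobustness:
    def test_single_replicate_summary_shape(self, small_dataset):
        from mginfeval import summarize_concordance

        obs, preds, _ = restrict_to_shared_features(
            small_dataset.observed_ko, small_dataset.predicted_ko
        )
        reps, grand = permutation_robustness(
            obs, preds, PermutationPlan(1, 3),
            evaluator=lambda o, p: feature_concordance(
                o, p, small_dataset.frame, ("overall",)
            ),
            summarizer=summarize_concordance,
        )
        assert reps["replicate"].unique().tolist() == [0]
        assert set(grand.columns) >= {"stratum", "method", "grand_median"}
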