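import numpy as np
import pandas as pd
import pytest
from scipy import stats

import morphonorm as mn
from morphonorm.data_prep import (
    extreme_mask,
    make_age_bins,
    mean_centre,
    remove_extremes,
    stratified_split,
)


def _table(ages, sites=None, seed=0):
    n = len(ages)
    rng = np.random.default_rng(seed)
    return mn.MorphometryTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "sex": np.where(np.arange(n) % 2 == 0, "F", "M"),
                "age": ages,
                "site": sites if sites is not None else ["one"] * n,
                "vendor": "Siemens",
                "fs_version": "7.1",
                "euler": -40,
                "icv": rng.uniform(1.2e6, 1.6e6, n),
                "mean_ct": rng.uniform(2.2, 2.9, n),
                "total_sa": rng.uniform(1.5e5, 1.9e5, n),
            }
        )
    )


class TestStratifiedSplit:
    def test_single_stratum_gives_exact_80_20(self):
        table = _table(np.random.default_rng(0).uniform(21, 29, 1000))
        res = stratified_split(table, seed=3)
        assert len(res.train.df) == 800
        assert len(res.test.df) == 200

    def test_five_subject_stratum_splits_4_1(self):
        table = _table([25.0] * 5)
        res = stratified_split(table, seed=0)
        assert (len(res.train.df), len(res.test.df)) == (4, 1)

    def test_per_stratum_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(3, 90, 700)
        sites = rng.choice(["a", "b", "c"], 700)
        table = _table(ages, sites)
        res = stratified_split(table, seed=5)
        # brute-force tally: recount strata on the output subsets
        for _, row in res.strata_report.iterrows():
            tr = res.train.df
            in_stratum = (tr["site"] == row["site"]) & (
                np.asarray(make_age_bins(tr["age"]).astype(str)) == row["age_bin"]
            )
            assert in_stratum.sum() == row["n_train"]
            assert abs(row["n_train"] - 0.8 * row["n"]) <= 1

    def test_no_overlap_and_exhaustive(self):
        rng = np.random.default_rng(2)
        table = _table(rng.uniform(3, 90, 300), rng.choice(["a", "b"], 300))
        res = stratified_split(table, seed=7)
        train_ids = set(res.train.df["subject_id"])
        test_ids = set(res.test.df["subject_id"])
        assert not train_ids & test_ids
        assert train_ids | test_ids == set(table.df["subject_id"])

    def test_row_order_does_not_change_assignment(self):
        rng = np.random.default_rng(3)
        table = _table(rng.uniform(3, 90, 200), rng.choice(["a", "b"], 200))
        res1 = stratified_split(table, seed=11)
        shuffled = mn.MorphometryTable(
            table.df.sample(frac=1, random_state=4).reset_index(drop=True)
        )
        res2 = stratified_split(shuffled, seed=11)
        assert set(res1.train.df["subject_id"]) == set(res2.train.df["subject_id"])

    def test_singleton_stratum_warns_into_train(self):
        table = _table([5.0, 5.0, 5.0, 5.0, 85.0])
        with pytest.warns(UserWarning, match="single subject"):
            res = stratified_split(table, seed=0)
        assert "s4" in set(res.train.df["subject_id"])


class TestRemoveExtremes:
    def test_hand_computed_tukey_fences(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 1000], dtype=float)
        kept, removed = remove_extremes(vals)
        # type-7 quantiles: Q1=3.25, Q3=7.75, fences [-3.5, 14.5]
        assert removed == 1
        assert kept.tolist() == list(range(1, 10))

    def test_constant_vector_removes_nothing(self):
        kept, removed = remove_extremes(np.full(10, 3.3))
        assert removed == 0 and len(kept) == 10

    def test_idempotent_when_fences_do_not_narrow(self):
        # idempotence is conditional: a second pass removes nothing whenever
        # the fences recomputed on the kept values widen or stay put
        def fences(v):
            q1, q3 = np.quantile(v, [0.25, 0.75])
            iqr = q3 - q1
            return q1 - 1.5 * iqr, q3 + 1.5 * iqr

        rng = np.random.default_rng(0)
        checked = 0
        for i in range(50):
            if i % 2:  # light tails: fences exceed the data range
                vals = rng.uniform(-1, 1, 200)
            else:  # heavy tails: fences typically narrow after trimming
                vals = rng.standard_t(df=3, size=200)
            kept, _ = remove_extremes(vals)
            lo1, hi1 = fences(vals)
            lo2, hi2 = fences(kept)
            _, removed2 = remove_extremes(kept)
            if lo2 <= lo1 and hi2 >= hi1:
                assert removed2 == 0
                checked += 1
            else:  # narrowed fences may trim, but only values they exclude
                assert removed2 == int(((kept < lo2) | (kept > hi2)).sum())
        assert checked >= 1  # the unconditional branch was exercised

    def test_normal_removal_rate_matches_theory(self):
        # P(|Z| beyond Tukey fences) for a normal is ~0.7%
        rng = np.random.default_rng(42)
        _, removed = remove_extremes(rng.normal(size=100_000))
        q = stats.norm.ppf([0.25, 0.75])
        iqr = q[1] - q[0]
        expect = 2 * stats.norm.sf(q[1] + 1.5 * iqr)
        assert removed / 100_000 == pytest.approx(expect, abs=0.002)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            remove_extremes([1.0, 2.0, 3.0])


class TestMeanCentre:
    def test_train_mean_zero_and_constants_stored(self):
        rng = np.random.default_rng(5)
        table = _table(rng.uniform(3, 90, 400), rng.choice(["a", "b"], 400))
        split = stratified_split(table, seed=1)
        pre_mean = float(split.train.df["age"].mean())
        centred = mean_centre(split, ["age", "icv"])
        assert centred.train.df["age"].mean() == pytest.approx(0.0, abs=1e-10)
        assert centred.centring_constants["age"] == pytest.approx(pre_mean)

    def test_stored_constants_reproduce_test_subset(self):
        rng = np.random.default_rng(6)
        table = _table(rng.uniform(3, 90, 300))
        split = stratified_split(table, seed=2)
        centred = mean_centre(split, ["age"])
        manual = split.test.df["age"] - centred.centring_constants["age"]
        np.testing.assert_allclose(centred.test.df["age"], manual)

    def test_zero_variance_column_flagged(self):
        table = _table([25.0] * 50)
        split = stratified_split(table, seed=0)
        with pytest.warns(UserWarning, match="zero variance"):
            mean_centre(split, ["age"])


class TestAgeBins:
    def test_nine_bins_cover_full_range(self):
        ages = np.linspace(3, 90, 500)
        bins = make_age_bins(ages)
        labels = set(bins.astype(str)) - {"out_of_range"}
        assert len(labels) == 9

    def test_boundary_membership(self):
        bins = make_age_bins([3.0, 10.0, 10.01, 90.0])
        assert list(bins.astype(str)) == ["bin1", "bin1", "bin2", "bin9"]

    def test_out_of_range_label(self):
        bins = make_age_bins([2.0, 95.0, 50.0])
        assert list(bins.astype(str)) == ["out_of_range", "out_of_range", "bin5"]


def test_extreme_mask_consistent_with_remove_extremes():
    rng = np.random.default_rng(9)
    vals = rng.normal(size=500)
    vals[::50] += 20
    mask = extreme_mask(vals)
    kept, removed = remove_extremes(vals)
    assert mask.sum() == len(kept)
    np.testing.assert_allclose(np.sort(vals[mask]), np.sort(kept))
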