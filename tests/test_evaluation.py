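import numpy as np
import pandas as pd
import pytest

import morphonorm as mn
from morphonorm.evaluation import (
    COVARIATE_COMBINATIONS,
    compare_algorithms,
    covariate_search,
    crossval,
    metrics,
    paired_signed_rank_p,
)


def bh_step_up_oracle(pvals, q):
    """Literal Benjamini-Hochberg step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order]
    below = np.nonzero(ranked <= (np.arange(1, m + 1) / m) * q)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.mae, m.rmse, m.ev) == (0.0, 0.0, 1.0)

    def test_hand_computed_example(self):
        m = metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m.mae == pytest.approx(2 / 3)
        assert m.rmse == pytest.approx(np.sqrt(2 / 3))

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            y = rng.normal(size=20)
            p = rng.normal(size=20)
            m = metrics(y, p)
            assert m.mae <= m.rmse + 1e-12

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            m = metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(m.ev)


class TestCrossval:
    def test_fold_sizes_partition_103(self, small_cohort):
        table, _ = small_cohort
        df = table.by_sex("F").df.iloc[:103]
        cv = crossval("olsr", df, "Left-Thalamus", ("age",), seed=0)
        sizes = sorted(len(f.__dict__) and 0 for f in cv.per_fold)
        # fold sizes recovered from the partition directly
        from sklearn.model_selection import KFold

        counts = sorted(
            len(te) for _, te in KFold(5, shuffle=True,
                                       random_state=0).split(np.arange(103))
        )
        assert counts == [20, 20, 21, 21, 21]

    def test_truth_model_zero_noise_gives_zero_mae(self):
        rng = np.random.default_rng(1)
        n = 200
        df = pd.DataFrame(
            {
                "age": rng.uniform(3, 90, n),
                "euler": -40.0,
                "vendor": "Siemens",
                "fs_version": "7.1",
            }
        )
        df["icv"] = 1.4e6
        df["mean_ct"] = 2.5
        df["total_sa"] = 1.7e5
        df["Left-Thalamus"] = 3000 + 10 * df["age"]
        cv = crossval("olsr", df, "Left-Thalamus", ("age",), seed=2)
        assert cv.mean.mae == pytest.approx(0.0, abs=1e-8)

    def test_same_seed_reproduces_metrics(self, small_cohort):
        table, _ = small_cohort
        df = table.by_sex("M").df
        a = crossval("mfpr", df, "Left-Thalamus", ("age", "global_linear"),
                     seed=9)
        b = crossval("mfpr", df, "Left-Thalamus", ("age", "global_linear"),
                     seed=9)
        assert a.mean.mae == b.mean.mae
        assert a.mean.rmse == b.mean.rmse

    def test_cv_mae_converges_to_noise_level(self):
        # the truth model's CV MAE approaches sigma*sqrt(2/pi)
        rng = np.random.default_rng(3)
        n = 10_000
        sigma = 2.0
        df = pd.DataFrame(
            {
                "age": rng.uniform(3, 90, n),
                "euler": -40.0,
                "vendor": "Siemens",
                "fs_version": "7.1",
                "icv": 1.4e6,
                "mean_ct": 2.5,
                "total_sa": 1.7e5,
            }
        )
        df["Left-Thalamus"] = 3000 + 10 * df["age"] + rng.normal(0, sigma, n)
        cv = crossval("olsr", df, "Left-Thalamus", ("age",), seed=4)
        assert cv.mean.mae == pytest.approx(sigma * np.sqrt(2 / np.pi),
                                            rel=0.03)

    def test_lms_rejects_extra_covariates(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError, match="only age"):
            crossval("lms", table.by_sex("F").df, "Left-Thalamus",
                     ("age", "global_linear"))


class TestCovariateSearch:
    def test_nine_default_combinations(self):
        assert len(COVARIATE_COMBINATIONS) == 9
        assert COVARIATE_COMBINATIONS[0] == ("age",)

    def test_nonzero_coupling_selects_global_linear(self):
        cfg = mn.SyntheticConfig(
            n_per_sex=900,
            measures=["lh_bankssts_thickness", "rh_precentral_thickness",
                      "lh_cuneus_thickness"],
            site_count=1,
            site_offset_sd=0.0,
            site_scale_sd=0.0,
            global_coupling=2.0,
            outlier_rate=0.0,
            noise_sd_range=(0.02, 0.04),
            seed=21,
        )
        table, _ = mn.generate_cohort(cfg)
        res = covariate_search(
            table,
            measures=cfg.measures,
            sex="F",
            combinations=[("age",), ("age", "global_linear"),
                          ("age", "euler")],
            seed=0,
        )
        assert res.best_set == ("age", "global_linear")
        assert res.significant[("age", "global_linear")]
        assert res.mean_mae[("age", "global_linear")] < res.mean_mae[("age",)]

    def test_zero_coupling_retains_age_only(self):
        cfg = mn.SyntheticConfig(
            n_per_sex=700,
            measures=["lh_bankssts_thickness", "rh_precentral_thickness"],
            site_count=1,
            site_offset_sd=0.0,
            site_scale_sd=0.0,
            global_coupling=0.0,
            outlier_rate=0.0,
            seed=22,
        )
        table, _ = mn.generate_cohort(cfg)
        res = covariate_search(
            table,
            measures=cfg.measures,
            sex="M",
            combinations=[("age",), ("age", "global_linear"),
                          ("age", "euler")],
            seed=1,
        )
        assert res.best_set == ("age",)


class TestCompareAlgorithms:
    def test_identical_vectors_not_flagged(self):
        v = np.linspace(1, 2, 150)
        rep = compare_algorithms(
            {"a": {"mae": v}, "b": {"mae": v.copy()}}
        )
        assert not rep.table["significant"].any()

    def test_constant_shift_flagged(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 2, 150)
        rep = compare_algorithms(
            {"a": {"mae": v}, "b": {"mae": v + 0.05}}
        )
        assert rep.table["significant"].all()

    def test_bh_hand_example(self):
        # p = (0.01, 0.02, 0.04, 0.5) at q=0.05: exactly the first two reject
        reject = bh_step_up_oracle([0.01, 0.02, 0.04, 0.5], 0.05)
        assert reject.tolist() == [True, True, False, False]
        from statsmodels.stats.multitest import multipletests

        rej, *_ = multipletests([0.01, 0.02, 0.04, 0.5], alpha=0.05,
                                method="fdr_bh")
        assert rej.tolist() == reject.tolist()

    def test_bh_matches_step_up_oracle_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.uniform(size=m)
            rej, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert rej.tolist() == bh_step_up_oracle(p, 0.05).tolist()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compare_algorithms(
                {"a": {"mae": np.ones(5)}, "b": {"mae": np.ones(6)}}
            )


def test_signed_rank_all_ties_returns_one():
    assert paired_signed_rank_p(np.ones(10), np.ones(10)) == 1.0
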