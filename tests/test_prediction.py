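"""Family-grouped splits, nested-CV evaluation, permutation significance."""

import numpy as np
import pandas as pd
import pytest

import neurogsp as ng
from neurogsp.prediction import (
    FamilyShuffleSplit,
    default_model_spec,
    fit_evaluate,
    make_family_splits,
    permutation_null,
    run_prediction,
    significance,
    summarize,
    ModelSpec,
    PredictionResult,
    SplitScheme,
)


def _singleton_table(n):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "family_id": [f"f{i}" for i in range(n)],
        }
    )


def _family_table(rng, n_families, max_size=4):
    sizes = rng.integers(1, max_size + 1, size=n_families)
    fam = np.repeat(np.arange(n_families), sizes)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(fam.size)],
            "family_id": [f"f{f}" for f in fam],
        }
    )


class TestFamilySplits:
    def test_singleton_families_hit_exact_fraction(self):
        splits = make_family_splits(_singleton_table(1000), n_splits=5,
                                    test_frac=0.15, seed=1)
        assert all(s.test_ids.size == 150 for s in splits)

    def test_no_family_straddles_the_split(self, rng):
        table = _family_table(rng, 120)
        fam = table["family_id"].to_numpy()
        for s in make_family_splits(table, n_splits=10, seed=2):
            assert not set(fam[s.train_ids]) & set(fam[s.test_ids])

    def test_partition_covers_cohort(self, rng):
        table = _family_table(rng, 80)
        for s in make_family_splits(table, n_splits=4, seed=0):
            joint = np.sort(np.concatenate([s.train_ids, s.test_ids]))
            assert np.array_equal(joint, np.arange(len(table)))

    def test_test_sizes_near_target_with_mixed_families(self, rng):
        # empirical band over 100 seeded draws on a 979-subject cohort
        spec = ng.CohortSpec(n_subjects=979, n_regions=20, seed=13)
        table = ng.synthetic.generate_cohort(spec)
        sizes = []
        for seed in range(10):
            for s in make_family_splits(table, n_splits=10, seed=seed):
                sizes.append(s.test_ids.size)
        frac = np.array(sizes) / 979
        assert np.all(np.abs(frac - 0.15) <= 0.03)

    def test_oversized_family_rejected(self):
        table = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(10)],
             "family_id": ["f0"] * 9 + ["f1"]}
        )
        with pytest.raises(ValueError, match="family"):
            make_family_splits(table, n_splits=2, test_frac=0.15, seed=0)

    def test_sklearn_splitter_interface(self):
        sp = FamilyShuffleSplit(n_splits=3, test_frac=0.2, random_state=0)
        groups = np.repeat(np.arange(20), 2)
        assert sp.get_n_splits() == 3
        folds = list(sp.split(np.zeros(40), groups=groups))
        assert len(folds) == 3

    def test_groups_required(self):
        with pytest.raises(ValueError, match="groups"):
            list(FamilyShuffleSplit().split(np.zeros(10)))


class TestFitEvaluate:
    def _split(self, n, rng, frac=0.25):
        idx = rng.permutation(n)
        k = int(n * frac)
        return SplitScheme(split_id=1, train_ids=idx[k:], test_ids=idx[:k])

    def test_exact_linear_function_recovered(self, rng):
        x = rng.normal(size=(200, 5))
        y = x @ np.array([1.0, -2.0, 0.5, 3.0, 0.0])
        fam = np.arange(200)
        spec = default_model_spec("elastic_net", small_grid=False)
        r2 = fit_evaluate(x, y, self._split(200, rng), spec, fam)
        assert r2 > 0.99

    def test_null_target_r2_centered_at_or_below_zero(self, rng):
        spec = default_model_spec("elastic_net", small_grid=True)
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(size=(80, 10))
            y = r.normal(size=80)
            vals.append(fit_evaluate(x, y, self._split(80, r), spec, np.arange(80)))
        assert np.mean(vals) <= 0.0

    def test_separable_binary_target_perfect_svm(self, rng):
        x = rng.normal(size=(100, 3))
        y = (x[:, 0] > 0).astype(int)
        x[:, 0] += np.where(y == 1, 5.0, -5.0)  # wide margin
        spec = default_model_spec("svm")
        acc = fit_evaluate(x, y, self._split(100, rng), spec, np.arange(100))
        assert acc == 1.0

    def test_nonfinite_features_rejected_with_subject_names(self, rng):
        x = rng.normal(size=(50, 4))
        x[7, 2] = np.nan
        ids = np.array([f"sub-{i:03d}" for i in range(50)])
        with pytest.raises(ValueError, match="sub-007"):
            fit_evaluate(
                x, rng.normal(size=50), self._split(50, rng),
                default_model_spec("elastic_net", small_grid=True),
                np.arange(50), subject_ids=ids,
            )

    def test_krr_runs(self, rng):
        x = rng.normal(size=(90, 6))
        y = x[:, 0] + 0.1 * rng.normal(size=90)
        r2 = fit_evaluate(x, y, self._split(90, rng),
                          default_model_spec("krr"), np.arange(90))
        assert r2 > 0.8

    def test_model_task_compatibility_enforced(self):
        with pytest.raises(ValueError, match="regression"):
            ModelSpec(name="elastic_net", task="classification",
                      hyper_grid={"model__alpha": [1.0]})
        with pytest.raises(ValueError, match="non-empty"):
            ModelSpec(name="krr", task="regression", hyper_grid={})


class TestPermutationNull:
    def test_null_count_is_splits_times_perms(self, rng):
        x = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        table = _singleton_table(60)
        splits = make_family_splits(table, n_splits=3, seed=0)
        null = permutation_null(
            x, y, splits, default_model_spec("elastic_net", small_grid=True),
            table["family_id"].to_numpy(), n_perms=4, seed=1,
        )
        assert null.shape == (3, 4)

    def test_zero_perms_gives_empty_null(self, rng):
        x = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        table = _singleton_table(40)
        splits = make_family_splits(table, n_splits=2, seed=0)
        null = permutation_null(
            x, y, splits, default_model_spec("elastic_net", small_grid=True),
            table["family_id"].to_numpy(), n_perms=0, seed=1,
        )
        assert null.shape == (2, 0)
        with pytest.raises(ValueError, match="non-empty"):
            significance(np.array([0.1]), null)

    def test_identity_permutation_reproduces_real_metric(self, rng):
        # a permutation that happens to be the identity must give exactly the
        # unpermuted metric: the null pipeline is the real pipeline
        x = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        table = _singleton_table(50)
        split = make_family_splits(table, n_splits=1, seed=3)[0]
        spec = default_model_spec("elastic_net", small_grid=True)
        fam = table["family_id"].to_numpy()
        real = fit_evaluate(x, y, split, spec, fam)
        again = fit_evaluate(x, y[np.arange(50)], split, spec, fam)
        assert real == again


class TestSignificance:
    def test_real_mean_above_all_nulls(self):
        p, sig = significance(np.full(10, 0.5), np.zeros(1000))
        assert sig and p == pytest.approx(1 / 1001)

    def test_real_mean_at_null_maximum(self):
        # mean equals the null maximum: still above the 95th percentile, and
        # the p-value counts the one null value >= the mean
        null = np.linspace(0, 1, 100)
        p, sig = significance(np.array([1.0]), null)
        assert sig
        assert p == pytest.approx(2 / 101)

    def test_equal_to_percentile_not_significant(self):
        null = np.zeros(100)
        p, sig = significance(np.zeros(5), null)
        assert not sig and p == 1.0

    def test_type_i_error_rate_near_nominal(self, rng):
        # real metrics drawn from the null itself: the mean-vs-95th-percentile
        # rule rejects at most ~5% of the time (it is conservative because the
        # mean of 10 draws concentrates)
        hits = 0
        for _ in range(200):
            null = rng.normal(size=500)
            real = rng.normal(size=10)
            hits += significance(real, null)[1]
        assert hits / 200 <= 0.08  # 5% nominal + binomial slack


class TestSummarize:
    def test_identical_metrics_collapse(self):
        r = PredictionResult(
            feature="fc", target="y", model="krr",
            per_split_metric=np.full(10, 0.3),
            null_metrics=np.zeros((10, 2)), p_value=0.01, significant=True,
        )
        row = summarize([r]).iloc[0]
        for col in ("mean", "median", "q1", "q3"):
            assert row[col] == pytest.approx(0.3)
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_quantiles_linear_interpolation(self):
        m = np.arange(1, 11) / 10
        r = PredictionResult(
            feature="fc", target="y", model="krr", per_split_metric=m,
            null_metrics=np.zeros((10, 1)), p_value=0.5, significant=False,
        )
        row = summarize([r]).iloc[0]
        assert row["median"] == pytest.approx(0.55)
        assert row["q1"] == pytest.approx(np.percentile(m, 25))
        assert row["q3"] == pytest.approx(np.percentile(m, 75))

    def test_empty_results_give_headers_only(self):
        df = summarize([])
        assert len(df) == 0 and "p_value" in df.columns


class TestRunPrediction:
    def test_full_run_deterministic(self, tiny_cohort):
        kw = dict(
            model=default_model_spec("elastic_net", small_grid=True),
            n_splits=3, n_perms=2, seed=5,
        )
        a = run_prediction(tiny_cohort, "sd", "score", **kw)
        b = run_prediction(tiny_cohort, "sd", "score", **kw)
        assert np.array_equal(a.per_split_metric, b.per_split_metric)
        assert np.array_equal(a.null_metrics, b.null_metrics)
        assert a.p_value == b.p_value

    def test_gsp_feature_consensus_fit_on_train_only(self, tiny_cohort):
        # recomputation check: the training consensus must not change when
        # test subjects' connectomes are permuted among themselves
        from neurogsp import gsp
        from neurogsp.features import make_extractor

        splits = make_family_splits(tiny_cohort, n_splits=1, seed=2)
        split = splits[0]
        ext = make_extractor("psd")
        ext.fit(tiny_cohort.subset(split.train_ids))
        ref = ext.consensus_.weights

        shuffled = tiny_cohort.subset(np.arange(tiny_cohort.n_subjects))
        te = split.test_ids
        for i, j in zip(te, np.roll(te, 1)):
            shuffled.connectomes[i] = tiny_cohort.connectomes[j]
        ext2 = make_extractor("psd")
        ext2.fit(shuffled.subset(split.train_ids))
        assert np.array_equal(ext2.consensus_.weights, ref)

    def test_scaler_leakage_free(self, tiny_cohort):
        # permuting test-subject feature rows never changes the fitted scaler
        from sklearn.preprocessing import StandardScaler

        ext = ng.make_extractor("sd")
        feats = ext.fit(tiny_cohort).transform(tiny_cohort)
        split = make_family_splits(tiny_cohort, n_splits=1, seed=4)[0]
        ref = StandardScaler().fit(feats[split.train_ids])
        feats2 = feats.copy()
        feats2[split.test_ids] = feats[np.roll(split.test_ids, 1)]
        again = StandardScaler().fit(feats2[split.train_ids])
        assert np.array_equal(ref.mean_, again.mean_)
        assert np.array_equal(ref.scale_, again.scale_)

    def test_missing_target_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="target"):
            run_prediction(tiny_cohort, "sd", "nope", n_splits=2, n_perms=0)
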