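import numpy as np
import pandas as pd
import pytest

from opsinpred.encode import ColumnProfile
from opsinpred.experiments import (
    HoldoutResult,
    aic_least_squares,
    entropy_importance_regression,
    fit_curves,
    iterative_holdout,
    learning_curve,
    record_tag,
    residual_breakdown,
)
from opsinpred.seqdata import Dataset
from opsinpred.synthdata import StudyConfig, generate_study

from conftest import make_record


def tiny_dataset(n=12, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        seq = "".join(rng.choice(list("AVDE"), size=10))
        lam = 500.0 + 15.0 * (seq[0] == "V") + rng.normal(0, 1)
        records.append(make_record(f"r{i}", seq, lam))
    return Dataset(records=records)


class TestIterativeHoldout:
    def test_every_record_predicted_exactly_once(self):
        ds = tiny_dataset(10)
        hr = iterative_holdout(ds, group_size=3, estimator="ridge", seed=0)
        assert sorted(hr.table["accession"]) == sorted(ds.accessions)
        assert hr.table["accession"].is_unique

    @pytest.mark.parametrize("n,gs", [(10, 3), (9, 3), (7, 4), (8, 1), (11, 5)])
    def test_partition_grid(self, n, gs):
        ds = tiny_dataset(n, seed=n)
        hr = iterative_holdout(ds, group_size=gs, estimator="ridge", seed=1)
        assert len(hr.table) == n
        assert hr.table["accession"].is_unique

    def test_same_seed_same_groups(self):
        ds = tiny_dataset(10)
        a = iterative_holdout(ds, group_size=3, estimator="ridge", seed=5)
        b = iterative_holdout(ds, group_size=3, estimator="ridge", seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_group_size_covering_targets_is_single_split(self, epistasis_toy):
        # all mutant targets held out at once, trained on the wild type alone
        hr = iterative_holdout(
            epistasis_toy, group_size=3, estimator="ridge", seed=2,
            target_filter="mutants_only",
        )
        assert len(hr.table) == 3

    def test_unknown_estimator(self):
        with pytest.raises(ValueError, match="unknown estimator"):
            iterative_holdout(tiny_dataset(8), group_size=2, estimator="nope", seed=0)

    def test_target_filter_restricts_targets(self, epistasis_toy):
        hr = iterative_holdout(
            epistasis_toy, group_size=1, estimator="ridge", seed=0,
            target_filter="mutants_only",
        )
        assert sorted(hr.table["accession"]) == ["m_c4s", "m_d2n", "m_dbl"]


class TestRecordTag:
    def test_tags(self, epistasis_toy):
        tags = {r.accession: record_tag(r) for r in epistasis_toy}
        assert tags == {
            "wt1": "wt",
            "m_d2n": "single-mutant",
            "m_c4s": "single-mutant",
            "m_dbl": "multi-mutant",
        }


class TestResidualBreakdown:
    def make_hr(self, residuals):
        table = pd.DataFrame(
            {
                "accession": [f"r{i}" for i in range(len(residuals))],
                "known": [500.0] * len(residuals),
                "predicted": [500.0 + r for r in residuals],
                "residual": residuals,
                "tag": ["wt"] * len(residuals),
                "outlier": [abs(r) > 10 for r in residuals],
            }
        )
        return HoldoutResult(table=table, group_size=1, estimator="ridge", seed=0)

    def test_twelve_nm_is_outlier(self):
        out = residual_breakdown(self.make_hr([12.0, 0.0]))
        assert out.iloc[0]["outliers"] == 1

    def test_exactly_ten_nm_is_not_outlier(self):
        out = residual_breakdown(self.make_hr([10.0, -10.0]))
        assert out.iloc[0]["outliers"] == 0

    def test_all_zero_residuals(self):
        out = residual_breakdown(self.make_hr([0.0, 0.0, 0.0]))
        assert out.iloc[0]["median_residual"] == 0.0
        assert out.iloc[0]["mae"] == 0.0
        assert out.iloc[0]["outliers"] == 0


class TestLearningCurve:
    def test_sizes_and_reps(self):
        ds = tiny_dataset(40, seed=4)
        pts = learning_curve(ds, step=10, reps=3, estimator="ridge", seed=0, k=4)
        assert sorted(set(pts["n_train"])) == [10, 20, 30, 40]
        assert all((pts["n_train"] == s).sum() == 3 for s in [10, 20, 30, 40])

    def test_non_divisible_includes_full_size(self):
        ds = tiny_dataset(25, seed=5)
        pts = learning_curve(ds, step=10, reps=1, estimator="ridge", seed=0, k=4)
        assert sorted(set(pts["n_train"])) == [10, 20, 25]

    def test_dataset_smaller_than_step(self):
        with pytest.raises(ValueError, match="smaller"):
            learning_curve(tiny_dataset(5), step=10, estimator="ridge", seed=0)

    def test_more_data_helps_on_clean_signal(self):
        cfg = StudyConfig(
            n_tips=50, L=80, sigma_e=0.0, sigma_phylo2=0.0, n_interactions=0,
            min_minor_count=5, n_mutant_parents=0, epistatic_trio_parents=0,
            pair_double_parents=0,
        )
        study = generate_study(cfg, seed=3)
        pts = learning_curve(study.dataset, step=15, reps=2, estimator="ridge", seed=0, k=4)
        by_size = pts.groupby("n_train")["r2"].mean()
        assert by_size.iloc[-1] >= by_size.iloc[0]


class TestFitCurves:
    def test_aic_arithmetic_fixture(self):
        assert aic_least_squares(rss=10.0, n=10, k=2) == pytest.approx(4.0)

    def test_reciprocal_recovered_from_exact_data(self):
        x = np.arange(20, 420, 20, dtype=float)
        y = 0.95 - 44.0 / x
        fits = fit_curves(list(zip(x, y)))
        assert fits[0].name == "reciprocal"
        assert fits[0].params["a"] == pytest.approx(0.95, abs=1e-6)
        assert fits[0].params["b"] == pytest.approx(-44.0, abs=1e-6)

    def test_constant_y_prefers_fewest_parameters(self):
        x = np.arange(1.0, 11.0)
        y = np.full_like(x, 0.9)
        fits = fit_curves(list(zip(x, y)))
        assert fits[0].n_params == 2
        # every 2-parameter model that fits exactly outranks the exact
        # 3-parameter ones (AIC ties broken by parameter count)
        quad = next(f for f in fits if f.name == "quadratic")
        recip = next(f for f in fits if f.name == "reciprocal")
        assert fits.index(recip) < fits.index(quad)

    def test_all_six_candidates_fitted(self):
        x = np.arange(10.0, 210.0, 10.0)
        y = 0.9 - 30.0 / x + np.random.default_rng(0).normal(0, 0.01, size=len(x))
        fits = fit_curves(list(zip(x, y)))
        assert {f.name for f in fits} == {
            "reciprocal", "exponential_rise", "logarithmic", "power",
            "saturating", "quadratic",
        }
        aics = [f.aic for f in fits if f.ok]
        assert aics == sorted(aics)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="few points"):
            fit_curves([(1.0, 1.0)])


class TestEntropyImportanceRegression:
    def make_profiles(self, values):
        return [
            ColumnProfile(
                column=i, frequencies={}, gap_fraction=0.0,
                entropy_bits=v, relative_entropy=v,
            )
            for i, v in enumerate(values)
        ]

    def test_identical_importance_gives_r2_one(self):
        vals = np.linspace(0.1, 1.0, 20)
        profiles = self.make_profiles(vals)
        imp = pd.DataFrame({"column": np.arange(1, 21), "mean_relative_importance": vals})
        assert entropy_importance_regression(profiles, imp) == pytest.approx(1.0)

    def test_shuffled_importance_uncorrelated(self):
        rng = np.random.default_rng(42)
        vals = rng.uniform(0, 1, size=1000)
        shuffled = rng.permutation(vals)
        profiles = self.make_profiles(vals)
        imp = pd.DataFrame(
            {"column": np.arange(1, 1001), "mean_relative_importance": shuffled}
        )
        assert entropy_importance_regression(profiles, imp) < 0.05

    def test_two_columns_rejected(self):
        profiles = self.make_profiles([0.2, 0.8])
        imp = pd.DataFrame({"column": [1, 2], "mean_relative_importance": [0.1, 0.9]})
        with pytest.raises(ValueError, match=">=3"):
            entropy_importance_regression(profiles, imp)
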