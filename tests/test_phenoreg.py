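import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from conftest import two_arm_config
from repeatrisk.phenoreg import (
    PhenotypeModel,
    a2_split_profile,
    fit_phenotype_model,
    item_subset_score,
    normative_deviation,
    orthogonalize_a1,
)
from repeatrisk.simulate import PlantedPhenotype, generate_cohort


def pheno_cohort(planted, n_case=300, n_con=300, seed=0, **kwargs):
    cfg = two_arm_config(
        n_case=n_case, n_con=n_con, planted_phenotypes=tuple(planted), **kwargs
    )
    cohort = generate_cohort(cfg, seed=seed)
    cohort["status"] = (cohort["group"] != "CON").astype(int)
    return cohort


class TestOrthogonalize:
    def test_identical_alleles_give_zero(self):
        a = np.array([15.0, 18.0, 21.0, 24.0])
        np.testing.assert_allclose(orthogonalize_a1(a, a), 0.0, atol=1e-12)

    def test_orthogonal_fixture_returns_centered_a1(self):
        a1 = np.array([15.0, 15.0, 17.0, 17.0])
        a2 = np.array([18.0, 22.0, 18.0, 22.0])  # exactly uncorrelated with a1
        np.testing.assert_allclose(orthogonalize_a1(a1, a2), a1 - a1.mean(), atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        a2 = rng.normal(21, 3, 50)
        a1 = 5 + 0.4 * a2 + rng.normal(0, 1, 50)
        slope = np.cov(a1, a2, ddof=1)[0, 1] / np.var(a2, ddof=1)
        expected = (a1 - a1.mean()) - slope * (a2 - a2.mean())
        np.testing.assert_allclose(orthogonalize_a1(a1, a2), expected, atol=1e-10)

    def test_exactly_uncorrelated_with_a2(self, null_cohort):
        res = orthogonalize_a1(
            null_cohort.a1.to_numpy(float), null_cohort.a2.to_numpy(float)
        )
        a2c = null_cohort.a2.to_numpy(float) - null_cohort.a2.mean()
        assert abs(res @ a2c) / len(res) < 1e-12

    def test_span_invariance(self, null_cohort):
        """OLS predictions identical with (A1, A2) or (A1_orth, A2)."""
        a1 = null_cohort.a1.to_numpy(float)
        a2 = null_cohort.a2.to_numpy(float)
        rng = np.random.default_rng(8)
        y = 0.3 * a1 - 0.2 * a2 + rng.normal(0, 1, len(a1))
        X1 = sm.add_constant(np.column_stack([a1, a2]))
        X2 = sm.add_constant(np.column_stack([orthogonalize_a1(a1, a2), a2]))
        f1, f2 = sm.OLS(y, X1).fit(), sm.OLS(y, X2).fit()
        np.testing.assert_allclose(f1.fittedvalues, f2.fittedvalues, atol=1e-8)

    def test_constant_a2_raises(self):
        with pytest.raises(ValueError):
            orthogonalize_a1(np.array([15.0, 16, 17]), np.array([20.0, 20, 20]))


class TestNormativeDeviation:
    @staticmethod
    def volumes_frame(n=500, seed=4, noise=30.0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "age": rng.uniform(20, 80, n),
                "sex": rng.choice(["female", "male"], n),
                "eICV": rng.normal(1450, 120, n),
                "coil": rng.choice(["12ch", "32ch"], n),
            }
        )
        df["vol"] = (
            900
            - 2.0 * df.age
            + 0.25 * df.eICV
            + 15 * (df.sex == "male")
            + rng.normal(0, noise, n)
        )
        return df

    def test_subject_on_regression_plane_is_zero(self):
        df = self.volumes_frame(noise=0.0)
        dev = normative_deviation(df, "vol", np.ones(len(df), bool))
        np.testing.assert_allclose(dev, 0.0, atol=1e-8)

    def test_ten_percent_above_prediction(self):
        df = self.volumes_frame(noise=0.0)
        mask = np.ones(len(df), bool)
        mask[:100] = False  # fit on the remainder only
        df2 = df.copy()
        df2.loc[: 99, "vol"] = df2.loc[: 99, "vol"] * 1.1
        dev = normative_deviation(df2, "vol", mask)
        np.testing.assert_allclose(dev[:100], 10.0, atol=1e-8)

    def test_reference_mean_deviation_near_zero(self):
        df = self.volumes_frame(n=500)
        dev = normative_deviation(df, "vol", np.ones(len(df), bool))
        assert abs(dev.mean()) < 0.5

    def test_small_reference_raises(self):
        df = self.volumes_frame(n=40)
        with pytest.raises(ValueError):
            normative_deviation(df, "vol", np.ones(40, bool))


class TestPhenotypeModel:
    def test_planted_standardized_betas_recovered(self):
        planted = PlantedPhenotype(
            name="vol", betas=(("A2", -0.3), ("A1orth_x_age", -0.41))
        )
        betas_a2, betas_int = [], []
        for seed in range(25):
            cohort = pheno_cohort([planted], seed=seed)
            fit = PhenotypeModel(
                cohort, "vol", extra_covariates=("status", "eICV", "coil")
            ).fit()
            betas_a2.append(fit.params["A2"])
            betas_int.append(fit.params["A1orth_x_age"])
        assert np.mean(betas_a2) == pytest.approx(-0.3, abs=0.05)
        assert np.mean(betas_int) == pytest.approx(-0.41, abs=0.05)

    def test_all_noise_outcome_p_uniform(self):
        pvals = []
        planted = PlantedPhenotype(name="noise")
        for seed in range(150):
            cohort = pheno_cohort([planted], n_case=100, n_con=100, seed=seed)
            fit = PhenotypeModel(cohort, "noise", extra_covariates=("status",)).fit()
            pvals.append(fit.pvalues["A1orth"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_duplicating_records_keeps_betas_shrinks_p(self):
        planted = PlantedPhenotype(name="vol", betas=(("A2", -0.15),))
        cohort = pheno_cohort([planted], seed=1)
        doubled = pd.concat([cohort, cohort], ignore_index=True)
        f1 = PhenotypeModel(cohort, "vol", extra_covariates=("status",)).fit()
        f2 = PhenotypeModel(doubled, "vol", extra_covariates=("status",)).fit()
        assert f2.params["A2"] == pytest.approx(f1.params["A2"], abs=1e-10)
        assert f2.pvalues["A2"] < f1.pvalues["A2"]

    def test_standardized_beta_equals_scaled_raw_beta(self):
        planted = PlantedPhenotype(name="vol", betas=(("A2", -0.3),), scale=40, offset=600)
        cohort = pheno_cohort([planted], seed=2)
        model = PhenotypeModel(cohort, "vol", extra_covariates=("status",))
        fit = model.fit()
        # refit on the same design with the unstandardized outcome
        y_raw = cohort["vol"].to_numpy(float)
        raw = sm.OLS(y_raw, model.exog).fit()
        expected = raw.params["A2"] * 1.0 / np.std(y_raw, ddof=1)
        assert fit.params["A2"] == pytest.approx(expected, abs=1e-10)

    def test_binary_outcome_nagelkerke_bounded(self):
        planted = PlantedPhenotype(name="score", betas=(("A2", 0.4),))
        cohort = pheno_cohort([planted], seed=3)
        cohort["hit"] = (cohort["score"] > cohort["score"].median()).astype(int)
        fit = PhenotypeModel(cohort, "hit", binary=True).fit()
        assert 0.0 <= fit.rsq <= 1.0
        assert fit.binary

    def test_median_split_age_coding(self):
        planted = PlantedPhenotype(name="vol")
        cohort = pheno_cohort([planted], seed=4, age_mean=50, age_sd=10, age_range=(17, 90))
        fit = PhenotypeModel(cohort, "vol", age_coding="median_split", age_split=50).fit()
        assert "age" in fit.params.index

    def test_family_fdr_per_term(self):
        planted = [
            PlantedPhenotype(name=f"v{i}", betas=(("A2", -0.3),)) for i in range(4)
        ]
        cohort = pheno_cohort(planted, seed=5)
        table = fit_phenotype_model(
            cohort, [f"v{i}" for i in range(4)], extra_covariates=("status",)
        )
        for _, sub in table.groupby("term"):
            assert (sub["q"] >= sub["p"] - 1e-12).all()
            assert (sub["q"] <= 1.0).all()

    def test_undersized_outcome_raises(self):
        planted = PlantedPhenotype(name="vol")
        cohort = pheno_cohort([planted], n_case=20, n_con=20, seed=6)
        with pytest.raises(ValueError):
            PhenotypeModel(cohort.head(20), "vol")


class TestA2SplitProfile:
    def test_homogeneous_effect_gives_flat_profile(self):
        planted = PlantedPhenotype(name="vol", betas=(("A1orth", -0.4),))
        cohort = pheno_cohort([planted], n_case=700, n_con=700, seed=7)
        prof = a2_split_profile(cohort, "vol", range(19, 24), extra_covariates=("status",))
        high = prof[prof.side == "high"].set_index("split").beta_a1orth
        assert high.max() - high.min() < 0.15

    def test_conditional_effect_localized(self):
        planted = PlantedPhenotype(
            name="vol", conditional_threshold=21, conditional_beta=-0.5
        )
        cohort = pheno_cohort([planted], n_case=700, n_con=700, seed=8)
        prof = a2_split_profile(cohort, "vol", range(17, 26), extra_covariates=("status",))
        wide = prof.pivot_table(index="split", columns="side", values="beta_a1orth")
        gap = wide["high"].abs() - wide["low"].abs()
        assert gap.idxmax() in (20, 21, 22)

    def test_split_below_data_minimum_skipped(self, null_cohort):
        df = null_cohort.copy()
        df["vol"] = np.random.default_rng(0).normal(size=len(df))
        df["status"] = 0
        prof = a2_split_profile(df, "vol", [5, 21])
        assert set(prof.split) == {21} or 5 not in set(prof[prof.side == "low"].split)


def test_item_subset_score():
    items = pd.DataFrame({"i1": [1, 2], "i2": [0, 1], "i3": [3, 0]})
    score = item_subset_score(items, ["i1", "i3"], name="anhedonia")
    assert list(score) == [4, 2]
    assert score.name == "anhedonia"
    with pytest.raises(KeyError):
        item_subset_score(items, ["i9"])
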