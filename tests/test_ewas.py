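"""Per-CpG association: OLS closed forms, estimating-equation oracle
checks against statsmodels, residualization, label-swap antisymmetry."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from twinewas.datatypes import DataError, ModelSpec
from twinewas.ewas import build_design, residualize, run_ewas

from conftest import toy_dataset


class TestOls:
    def test_two_group_closed_form(self):
        """4 samples, two per group: effect = group mean difference,
        se = sqrt(s2_pooled * (1/2 + 1/2))."""
        ds = toy_dataset([[0.50, 0.52, 0.60, 0.62]], [0, 0, 1, 1])
        s = run_ewas(ds, ModelSpec(estimator="ols"))
        assert s["beta"].iloc[0] == pytest.approx(0.10, abs=1e-12)
        assert s["se"].iloc[0] == pytest.approx(0.014142135, rel=1e-6)

    def test_constant_predictor_fails(self):
        ds = toy_dataset([[0.5, 0.6, 0.7, 0.4]], [1, 1, 1, 1])
        with pytest.raises(DataError):
            run_ewas(ds, ModelSpec(estimator="ols"))

    def test_label_swap_negates_effects(self, small_unrelated_cohort):
        ds = small_unrelated_cohort.dataset
        spec = ModelSpec(covariates=["age", "sex"], estimator="ols")
        a = run_ewas(ds, spec)
        flipped = ds.samples.copy()
        flipped["handedness"] = 1 - flipped["handedness"]
        from twinewas.datatypes import MethylationDataset

        ds2 = MethylationDataset(beta=ds.beta, manifest=ds.manifest, samples=flipped)
        b = run_ewas(ds2, spec)
        np.testing.assert_allclose(a["beta"].to_numpy(), -b["beta"].to_numpy(), atol=1e-12)
        np.testing.assert_allclose(a["se"].to_numpy(), b["se"].to_numpy(), atol=1e-12)

    def test_matches_statsmodels_ols(self, small_unrelated_cohort):
        ds = small_unrelated_cohort.dataset
        s = run_ewas(ds, ModelSpec(covariates=["age", "bmi"], estimator="ols"))
        X = sm.add_constant(
            ds.samples[["handedness", "age", "bmi"]].to_numpy(dtype=float))
        for j in [0, 50, 123]:
            fit = sm.OLS(ds.beta.iloc[j].to_numpy(), X).fit()
            assert s["beta"].iloc[j] == pytest.approx(fit.params[1], abs=1e-10)
            assert s["se"].iloc[j] == pytest.approx(fit.bse[1], abs=1e-10)
            assert s["p"].iloc[j] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_missing_beta_handled_per_cpg(self, small_unrelated_cohort):
        ds = small_unrelated_cohort.dataset
        beta = ds.beta.copy()
        beta.iloc[3, :150] = np.nan  # 250 complete
        beta.iloc[4, :395] = np.nan  # 5 complete -> missing stats
        from twinewas.datatypes import MethylationDataset

        ds2 = MethylationDataset(beta=beta, manifest=ds.manifest, samples=ds.samples)
        s = run_ewas(ds2, ModelSpec(estimator="ols"))
        assert s["n"].iloc[3] == 250 and np.isfinite(s["beta"].iloc[3])
        assert s["n"].iloc[4] == 5 and np.isnan(s["beta"].iloc[4])


class TestClusterExchangeable:
    def test_all_singletons_equals_ols(self, small_unrelated_cohort):
        ds = small_unrelated_cohort.dataset
        a = run_ewas(ds, ModelSpec(covariates=["age"], estimator="ols"))
        b = run_ewas(ds, ModelSpec(covariates=["age"], estimator="cluster-exchangeable"))
        np.testing.assert_allclose(a["beta"].to_numpy(), b["beta"].to_numpy(), atol=1e-8)

    def test_duplicated_samples_match_deduplicated_fit(self):
        """Duplicating every sample as a fake MZ pair leaves the point
        estimate at the deduplicated OLS value and the raw sandwich SE at
        the deduplicated HC0 value; the default df-corrected SE differs by
        exactly sqrt(G/(G-p))."""
        rng = np.random.default_rng(42)
        n, m = 80, 12
        beta = rng.uniform(0.2, 0.8, size=(m, n))
        h = (rng.random(n) < 0.3).astype(float)
        age = rng.uniform(20, 60, n)
        dup = np.repeat(np.arange(n), 2)
        ds = toy_dataset(
            beta[:, dup], h[dup], covariates={"age": age[dup]},
            family=[f"f{i}" for i in dup], zygosity=["MZ"] * (2 * n),
        )
        spec = ModelSpec(covariates=["age"], estimator="cluster-exchangeable")
        s = run_ewas(ds, spec, gee_df_correction=False)
        s_corr = run_ewas(ds, spec)
        factor = np.sqrt(n / (n - 3))  # G clusters, p = 3 parameters
        X = sm.add_constant(np.column_stack([h, age]))
        for j in range(m):
            fit = sm.OLS(beta[j], X).fit(cov_type="HC0")
            assert s["beta"].iloc[j] == pytest.approx(fit.params[1], abs=1e-6)
            assert s["se"].iloc[j] == pytest.approx(fit.bse[1], rel=1e-6)
            assert s_corr["se"].iloc[j] == pytest.approx(fit.bse[1] * factor, rel=1e-6)

    def test_matches_statsmodels_gee(self, small_twin_cohort):
        """Raw (uncorrected) sandwich matches statsmodels.GEE exactly."""
        ds = small_twin_cohort.dataset
        s = run_ewas(ds, ModelSpec(covariates=["age", "sex"],
                                   estimator="cluster-exchangeable"),
                     gee_df_correction=False)
        fam, _ = pd.factorize(ds.samples["family_id"])
        X = sm.add_constant(ds.samples[["handedness", "age", "sex"]].to_numpy(dtype=float))
        for j in [1, 77, 200]:
            fit = sm.GEE(ds.beta.iloc[j].to_numpy(), X, groups=fam,
                         cov_struct=sm.cov_struct.Exchangeable(),
                         family=sm.families.Gaussian()).fit(maxiter=200)
            assert s["beta"].iloc[j] == pytest.approx(fit.params[1], abs=1e-8)
            assert s["se"].iloc[j] == pytest.approx(fit.bse[1], rel=1e-6)

    def test_df_correction_factor(self, small_twin_cohort):
        ds = small_twin_cohort.dataset
        spec = ModelSpec(covariates=["age"], estimator="cluster-exchangeable")
        raw = run_ewas(ds, spec, gee_df_correction=False)
        corr = run_ewas(ds, spec)
        G = ds.samples["family_id"].nunique()
        factor = np.sqrt(G / (G - 3))
        np.testing.assert_allclose(corr["se"], raw["se"] * factor, rtol=1e-10)
        np.testing.assert_allclose(corr["beta"], raw["beta"], rtol=1e-12)


class TestResidualize:
    def test_intercept_only_centres(self, small_unrelated_cohort):
        ds = small_unrelated_cohort.dataset
        res = residualize(ds, [])
        expected = ds.beta.to_numpy() - ds.beta.to_numpy().mean(axis=1, keepdims=True)
        np.testing.assert_allclose(res.to_numpy(), expected, atol=1e-12)

    def test_perfect_covariate_gives_zero_residuals(self):
        beta = np.array([[0.3, 0.5, 0.7, 0.4, 0.6]])
        ds = toy_dataset(beta, [0, 0, 1, 1, 0], covariates={"self": beta[0]})
        res = residualize(ds, ["self"])
        np.testing.assert_allclose(res.to_numpy(), 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        n, m = 50, 6
        beta = rng.uniform(0.1, 0.9, (m, n))
        covs = {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}
        ds = toy_dataset(beta, rng.integers(0, 2, n), covariates=covs)
        res = residualize(ds, ["a", "b"])
        X = np.column_stack([np.ones(n), covs["a"], covs["b"]])
        oracle = beta.T - X @ np.linalg.solve(X.T @ X, X.T @ beta.T)
        np.testing.assert_allclose(res.to_numpy(), oracle.T, atol=1e-8)
        # residuals orthogonal to design
        assert np.abs(X.T @ res.to_numpy().T).max() < 1e-8

    def test_rank_deficient_design_names_columns(self):
        n = 30
        rng = np.random.default_rng(1)
        x = rng.standard_normal(n)
        ds = toy_dataset(rng.uniform(0.2, 0.8, (3, n)), rng.integers(0, 2, n),
                         covariates={"x1": x, "x2": 2 * x})
        with pytest.raises(DataError, match="x2"):
            residualize(ds, ["x1", "x2"])


class TestDesign:
    def test_categorical_expanded_reference_first(self):
        samples = pd.DataFrame(
            {"handedness": [0, 1, 0], "plate": ["A", "B", "C"]},
            index=["s1", "s2", "s3"],
        )
        X = build_design(samples, ["plate"])
        assert list(X.columns) == ["handedness", "plate[B]", "plate[C]"]

    def test_unknown_covariate_rejected(self):
        samples = pd.DataFrame({"handedness": [0, 1]}, index=["a", "b"])
        with pytest.raises(DataError, match="nope"):
            build_design(samples, ["nope"])
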