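import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurocoex.diffexpr import (ModeratedLinearModel, build_design,
                                call_degs, compare_disorders, ebayes_moderate,
                                fit_linear)
from neurocoex.synth import SynthSpec, generate_case_control
from tests.conftest import make_dataset


def small_cohort_meta(n_per_group=6, seed=0):
    rng = np.random.default_rng(seed)
    n = 3 * n_per_group
    groups = (["control"] * n_per_group + ["ED"] * n_per_group
              + ["OCD"] * n_per_group)
    return pd.DataFrame({
        "group": groups,
        "RIN": rng.uniform(5, 9, n),
        "pH": rng.uniform(6, 7, n),
        "age": rng.uniform(16, 70, n),
        "PMI": rng.uniform(5, 40, n),
        "sex": rng.integers(0, 2, n),
    }, index=pd.Index([f"s{i}" for i in range(n)], name="sample"))


class TestDesign:
    def test_column_count_three_groups_five_covariates(self):
        design = build_design(small_cohort_meta())
        assert len(design.names) == 8  # intercept + 2 groups + 5 covariates
        assert design.contrasts == ["group[ED]", "group[OCD]"]

    def test_constant_covariate_named_in_error(self):
        meta = small_cohort_meta()
        meta["sex"] = 1
        with pytest.raises(ValueError, match="sex"):
            build_design(meta)

    def test_synthetic_defaults_have_133_rows(self, tiny_spec):
        cc, _ = generate_case_control(tiny_spec)
        design = build_design(cc.metadata)
        assert design.matrix.shape[0] == 133

    def test_missing_control_group_rejected(self):
        meta = small_cohort_meta()
        meta["group"] = "ED"
        with pytest.raises(ValueError):
            build_design(meta)


class TestLinearFit:
    def test_exact_linear_gene_has_zero_variance(self):
        meta = small_cohort_meta()
        design = build_design(meta)
        y = design.matrix @ np.array([1.0, 2.0, -1.0, 0.5, 0, 0.1, 0, 0.3])
        ds = make_dataset(y[None, :], samples=list(meta.index), metadata=meta)
        fits = fit_linear(ds, design)
        assert fits.sigma_sq[0] == pytest.approx(0.0, abs=1e-18)
        assert fits.coef.iloc[0, 1] == pytest.approx(2.0)

    def test_matches_hand_normal_equations(self):
        rng = np.random.default_rng(1)
        meta = small_cohort_meta(seed=1)
        design = build_design(meta)
        y = rng.standard_normal(len(meta))
        ds = make_dataset(y[None, :], samples=list(meta.index), metadata=meta)
        fits = fit_linear(ds, design)
        X = design.matrix
        beta_hand = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fits.coef.iloc[0], beta_hand, atol=1e-10)
        resid = y - X @ beta_hand
        s2_hand = resid @ resid / (len(y) - X.shape[1])
        assert fits.sigma_sq[0] == pytest.approx(s2_hand, rel=1e-10)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        meta = small_cohort_meta(seed=2)
        design = build_design(meta)
        y = rng.standard_normal(len(meta))
        res = sm.OLS(y, design.matrix).fit()
        ds = make_dataset(y[None, :], samples=list(meta.index), metadata=meta)
        fits = fit_linear(ds, design)
        np.testing.assert_allclose(fits.coef.iloc[0], res.params, atol=1e-10)

    def test_underdetermined_rejected(self):
        meta = small_cohort_meta(n_per_group=2)
        design = build_design(meta, covariates=("RIN", "pH", "age"))
        ds = make_dataset(np.random.default_rng(0).random((2, len(meta))),
                          samples=list(meta.index), metadata=meta)
        with pytest.raises(ValueError, match="coefficients"):
            fit_linear(ds, design)


@pytest.fixture(scope="module")
def fitted(tiny_spec):
    cc, _ = generate_case_control(tiny_spec)
    design = build_design(cc.metadata)
    return fit_linear(cc, design)


class TestEbayes:
    def test_prior_off_recovers_ordinary_t(self, fitted):
        mod = ebayes_moderate(fitted, prior_df=0.0)
        d = fitted.df_residual
        for con_coef in ("group[ED]",):
            logfc = fitted.coef[con_coef].to_numpy()
            se = fitted.stdev_unscaled[con_coef].to_numpy() \
                * np.sqrt(fitted.sigma_sq)
            t_ord = logfc / se
            t_mod = mod.tables["ED"]["t"].to_numpy()
            assert np.abs(t_mod - t_ord).max() < 1e-10
            p_ord = 2 * stats.t.sf(np.abs(t_ord), d)
            np.testing.assert_allclose(mod.tables["ED"]["p"], p_ord,
                                       atol=1e-12)

    def test_infinite_prior_pools_variances(self, fitted):
        mod = ebayes_moderate(fitted, prior_df=np.inf)
        assert np.unique(mod.tables["ED"]["s2_post"]).size == 1

    def test_posterior_variance_between_extremes(self, fitted):
        mod = ebayes_moderate(fitted)
        s2 = mod.tables["ED"]["s2"].to_numpy()
        post = mod.tables["ED"]["s2_post"].to_numpy()
        lo = np.minimum(s2, mod.prior_var)
        hi = np.maximum(s2, mod.prior_var)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_prior_recovery_from_planted_variance_distribution(self):
        # residual variances planted as scaled-inv-chi2(d0=4, s0^2=0.04)
        spec = SynthSpec(seed=11, n_genes=600, module_size=50)
        cc, _ = generate_case_control(spec)
        mod = ModeratedLinearModel(cc).fit()
        assert 2.0 <= mod.prior_df <= 8.0
        assert 0.02 <= mod.prior_var <= 0.06

    def test_too_few_genes_for_prior(self):
        meta = small_cohort_meta()
        ds = make_dataset(np.random.default_rng(3).random((4, len(meta))),
                          samples=list(meta.index), metadata=meta)
        fits = fit_linear(ds, build_design(meta))
        with pytest.raises(ValueError, match="10 genes"):
            ebayes_moderate(fits)


class TestDegsAndComparison:
    def test_alpha_one_calls_everything(self, tiny_spec):
        cc, _ = generate_case_control(tiny_spec)
        mod = ModeratedLinearModel(cc).fit()
        degs = call_degs(mod, alpha=1.01)
        assert len(degs["ED"]) == 600

    def test_strong_planted_effects_recalled(self):
        spec = SynthSpec(seed=12, n_genes=600, module_size=50,
                         effect_sd=1.5, de_in_module_fraction=0.0, n_de=60)
        cc, truth = generate_case_control(spec)
        mod = ModeratedLinearModel(cc).fit()
        degs = set(call_degs(mod)["ED"])
        strong = [g for g, e in truth.de_effects.items()
                  if abs(e["ED"]) >= 0.6]  # |effect| >= 3 residual sd
        recall = np.mean([g in degs for g in strong])
        assert recall >= 0.9

    def test_identical_contrasts_correlate_perfectly(self):
        spec = SynthSpec(seed=13, n_genes=600, module_size=50, rho=1.0)
        cc, _ = generate_case_control(spec)
        mod = ModeratedLinearModel(cc).fit()
        comp = compare_disorders(mod, "ED", "ED")
        assert comp.logfc_correlation == pytest.approx(1.0)
        assert comp.overlap == comp.deg_counts["ED"]

    def test_printed_overlap_bound(self):
        # DEG list sizes 1118 and 238 overlapping in 50 genes are wildly
        # beyond chance for any plausible array background; below the R
        # print floor of 2.2e-16 once the background exceeds ~21k genes
        for n_bg in (15_000, 20_000, 30_000, 47_000):
            assert stats.hypergeom.sf(49, n_bg, 1118, 238) < 1e-10
        for n_bg in (21_000, 30_000, 47_000):
            assert stats.hypergeom.sf(49, n_bg, 1118, 238) < 2.2e-16

    def test_summary_mentions_prior_and_counts(self, tiny_spec):
        cc, _ = generate_case_control(tiny_spec)
        mod = ModeratedLinearModel(cc).fit()
        text = mod.summary()
        assert "prior df" in text and "contrast ED" in text
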