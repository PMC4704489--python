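"""The weighted gamma mixed model: oracles, invariances, and pruning."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicevar.glmm import (
    GlmmFit,
    build_design,
    fit_gamma_glmm,
    lrt,
    lrt_term,
    remove_residual_outliers,
)


def two_group_table(ratio=0.5, n_exons=20):
    """Balanced two-group design with an exact multiplicative group effect."""
    rows = []
    for e in range(n_exons):
        base = 0.002 * (1 + 0.1 * e)
        for g, mult in (("conserved", ratio), ("non_conserved", 1.0)):
            rows.append(
                {"exon_id": f"{g}_{e}", "group": g, "var_t": base * mult, "weight": 1.0}
            )
    return pd.DataFrame(rows)


class TestDesign:
    def test_treatment_coding_against_first_level(self):
        tab = pd.DataFrame({"g": ["b", "a", "c"], "x": [1.0, 2.0, 3.0]})
        X, term_map = build_design(tab, ["g", "x"])
        assert list(X.columns) == ["Intercept", "g[T.b]", "g[T.c]", "x"]
        assert term_map["g"] == ["g[T.b]", "g[T.c]"]
        np.testing.assert_array_equal(X["g[T.b]"], [1.0, 0.0, 0.0])

    def test_single_level_categorical_rejected(self):
        tab = pd.DataFrame({"g": ["a", "a"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            build_design(tab, ["g"])


class TestFitOracles:
    def test_exact_two_group_ratio_recovers_log_ratio(self):
        """Responses exactly halved in one group: coefficient = -ln 2 in
        closed form for a log link on a balanced design."""
        fit = fit_gamma_glmm(two_group_table(0.5), fixed=["group"], compute_se=False)
        # treatment-coded against 'conserved', so the contrast is +ln 2
        assert fit.params["group[T.non_conserved]"] == pytest.approx(np.log(2), abs=1e-4)

    def test_matches_plain_gamma_glm_when_no_heterogeneity(self):
        """Data with no exon-level effect: random-intercept SD goes to ~0 and
        coefficients agree with a statsmodels gamma GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        rows = []
        for e in range(80):
            for c in ("A", "B"):
                x = rng.normal()
                mu = np.exp(-2 + 0.5 * x + 0.3 * (c == "B"))
                rows.append(
                    {
                        "exon_id": f"E{e}",
                        "condition": c,
                        "x": x,
                        "var_t": rng.gamma(5.0, mu / 5.0),
                    }
                )
        tab = pd.DataFrame(rows)
        fit = fit_gamma_glmm(tab, fixed=["x", "condition"], weight=None)
        X = sm.add_constant(
            pd.get_dummies(tab[["x", "condition"]], drop_first=True).astype(float)
        )
        glm = sm.GLM(
            tab["var_t"], X, family=sm.families.Gamma(sm.families.links.Log())
        ).fit()
        assert fit.sigma_re < 0.25
        np.testing.assert_allclose(fit.params.to_numpy(), glm.params.to_numpy(), atol=0.05)

    def test_agrees_with_glmmtmb_reference(self, gamma_mixed_table, tmp_path):
        """Independent R implementation (glmmTMB, Laplace) on the same data."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the reference fit")
        fixture = tmp_path / "fixture.tsv"
        gamma_mixed_table.to_csv(fixture, sep="\t", index=False)
        rscript = (
            'suppressMessages(library(glmmTMB));'
            f'd <- read.delim("{fixture}");'
            'm <- glmmTMB(var_t ~ x + condition + (1|exon_id),'
            ' family=Gamma(link="log"), data=d);'
            'cat(fixef(m)$cond, attr(VarCorr(m)$cond$exon_id, "stddev"),'
            ' as.numeric(logLik(m)), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = [float(v) for v in out.stdout.strip().splitlines()]
        fit = fit_gamma_glmm(gamma_mixed_table, fixed=["x", "condition"])
        np.testing.assert_allclose(fit.params.to_numpy(), ref[:4], atol=1e-3)
        assert fit.sigma_re == pytest.approx(ref[4], abs=1e-3)
        assert fit.loglik == pytest.approx(ref[5], abs=1e-3)

    def test_random_effect_variance_recovered(self):
        """Strong injected exon heterogeneity is estimated, absent is near 0."""
        rng = np.random.default_rng(15)
        rows = []
        for e in range(60):
            b = rng.normal(0, 0.8)
            for c in range(4):
                mu = np.exp(-2 + b)
                rows.append(
                    {"exon_id": f"E{e}", "var_t": rng.gamma(6.0, mu / 6.0)}
                )
        fit = fit_gamma_glmm(pd.DataFrame(rows), fixed=[], weight=None)
        assert 0.5 < fit.sigma_re < 1.1

    def test_positive_response_required(self):
        tab = two_group_table()
        tab.loc[0, "var_t"] = 0.0
        with pytest.raises(ValueError):
            fit_gamma_glmm(tab, fixed=["group"])


class TestInvariances:
    def test_row_order_and_weight_rescaling(self, gamma_mixed_table):
        tab = gamma_mixed_table
        fit = fit_gamma_glmm(tab, fixed=["x", "condition"], compute_se=False)
        shuffled = tab.sample(frac=1.0, random_state=1)
        fit_s = fit_gamma_glmm(shuffled, fixed=["x", "condition"], compute_se=False)
        np.testing.assert_allclose(fit.params, fit_s.params, atol=1e-6)
        scaled = tab.assign(weight=tab["weight"] * 37.0)
        fit_w = fit_gamma_glmm(scaled, fixed=["x", "condition"], compute_se=False)
        np.testing.assert_allclose(fit.params, fit_w.params, atol=1e-6)
        assert fit.loglik == pytest.approx(fit_w.loglik, abs=1e-6)


class TestLrt:
    @staticmethod
    def fake_fit(loglik, cols, spec=None):
        params = pd.Series(0.0, index=cols)
        return GlmmFit(
            params=params, se=None, tvalues=None, pvalues=None, loglik=loglik,
            shape=1.0, sigma_re=0.1, converged=True, n_obs=10, df_resid=8,
            term_map={}, random_effects=pd.Series(dtype=float),
            fitted=np.ones(10), residuals=np.zeros(10),
            table=pd.DataFrame(), spec=spec or {"group": "exon_id", "response": "var_t"},
        )

    def test_identical_models_give_p_one(self):
        f = self.fake_fit(10.0, ["Intercept", "x"])
        res = lrt(f, self.fake_fit(10.0, ["Intercept", "x"]))
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_chi_square_quantile(self):
        full = self.fake_fit(10.0 + 3.841 / 2, ["Intercept", "x"])
        res = lrt(full, self.fake_fit(10.0, ["Intercept"]))
        assert res.df == 1
        assert res.pvalue == pytest.approx(0.05, abs=2e-4)

    def test_non_nested_models_rejected(self):
        with pytest.raises(ValueError):
            lrt(self.fake_fit(10.0, ["Intercept", "x"]), self.fake_fit(9.0, ["Intercept", "z"]))

    def test_term_lrt_detects_a_real_group_effect(self):
        res, full, reduced = lrt_term(two_group_table(0.4), "group", fixed=["group"])
        assert full.loglik >= reduced.loglik  # nesting invariant
        assert res.pvalue < 1e-4

    def test_null_pvalues_are_uniform(self):
        """Group labels without effect: LRT p-values ~ U(0,1) (KS test)."""
        rng = np.random.default_rng(20)
        pvals = []
        for _ in range(250):
            rows = []
            for e in range(30):
                b = rng.normal(0, 0.4)
                g = "conserved" if e < 15 else "non_conserved"
                for c in range(3):
                    mu = np.exp(-2 + b)
                    rows.append(
                        {"exon_id": f"E{e}", "group": g, "var_t": rng.gamma(4.0, mu / 4.0)}
                    )
            res, _, _ = lrt_term(pd.DataFrame(rows), "group", fixed=["group"], weight=None)
            pvals.append(res.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestOutlierPruning:
    def test_clean_data_is_untouched(self, gamma_mixed_table):
        fit = fit_gamma_glmm(gamma_mixed_table, fixed=["x", "condition"], compute_se=False)
        _, table, removed = remove_residual_outliers(fit, alpha=0.01)
        assert removed == [] and len(table) == len(gamma_mixed_table)

    def test_inflated_row_is_found_and_removed(self, gamma_mixed_table):
        tab = gamma_mixed_table.copy()
        tab.loc[10, "var_t"] *= 100.0
        fit = fit_gamma_glmm(tab, fixed=["x", "condition"], compute_se=False)
        _, table, removed = remove_residual_outliers(fit)
        assert 10 in removed
        assert 10 not in table.index

    def test_max_iteration_guard_reports_partial_result(self, gamma_mixed_table):
        # opposite-sided outliers: one is removed, one remains when the
        # iteration budget is exhausted
        tab = gamma_mixed_table.copy()
        tab.loc[0, "var_t"] *= 100.0
        tab.loc[1, "var_t"] /= 100.0
        fit = fit_gamma_glmm(tab, fixed=["x", "condition"], compute_se=False)
        out, _, removed = remove_residual_outliers(fit, max_iter=1)
        assert len(removed) == 1
        assert "max_iter" in out.message
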