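"""Gamma log-link regression, AICc, marginal means and effect sizes."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from estuarydiet.generate import generate_gamma_responses
from estuarydiet.models import (
    ModelSpec,
    aicc_value,
    estimated_marginal_means,
    fit_gamma_loglink,
    link_scale_sigma,
    pairwise_comparisons,
)


def make_two_factor_data(n, beta, alpha, seed, p1=(0.5, 0.3, 0.2), p2=(0.6, 0.4)):
    rng = np.random.default_rng(seed)
    f1 = rng.choice(["a", "b", "c"], n, p=p1)
    f2 = rng.choice(["x", "y"], n, p=p2)
    x = np.column_stack([np.ones(n), f1 == "b", f1 == "c", f2 == "y"])
    y = generate_gamma_responses(x, beta, alpha, seed=seed + 1)
    return pd.DataFrame({"ir": y, "site": f1, "month": f2, "year": 2008})


class TestFit:
    def test_intercept_only_fitted_mean_is_sample_mean(self):
        """Gamma/log-link MLE identity: the intercept-only fitted mean
        equals the arithmetic sample mean."""
        rng = np.random.default_rng(3)
        y = rng.gamma(2.0, 0.01, size=300)
        df = pd.DataFrame({"ir": y, "site": "a", "year": 2008, "month": 5})
        fit = fit_gamma_loglink(df, ModelSpec("ir", ("site",), blocking="none"))
        assert np.exp(fit.coefficients["Intercept"]) == pytest.approx(
            y.mean(), rel=1e-8
        )

    def test_parameter_recovery_within_three_se(self):
        beta = [np.log(0.02), 0.4, -0.3]
        rng = np.random.default_rng(0)
        n = 500
        f1 = rng.choice(["a", "b"], n)
        f2 = rng.choice(["x", "y"], n)
        x = np.column_stack([np.ones(n), f1 == "b", f2 == "y"])
        y = generate_gamma_responses(x, beta, 0.5, seed=1)
        df = pd.DataFrame({"ir": y, "site": f1, "month": f2, "year": 2008})
        fit = fit_gamma_loglink(df, ModelSpec("ir", ("site", "month"), blocking="none"))
        se = np.sqrt(np.diag(fit.covariance))
        assert np.all(np.abs(fit.coefficients.to_numpy() - beta) < 3 * se)
        assert fit.alpha == pytest.approx(0.5, abs=0.1)

    def test_nonpositive_response_rejected(self):
        df = pd.DataFrame(
            {"ir": [0.1, 0.0, 0.2], "site": list("aab"), "year": 2008, "month": 5}
        )
        with pytest.raises(ValueError, match="positive"):
            fit_gamma_loglink(df, ModelSpec("ir", ("site",), blocking="none"))

    def test_row_permutation_invariance(self):
        df = make_two_factor_data(200, [np.log(0.05), 0.3, -0.2, 0.15], 0.4, seed=5)
        spec = ModelSpec("ir", ("site", "month"), blocking="none")
        fit1 = fit_gamma_loglink(df, spec)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fit2 = fit_gamma_loglink(shuffled, spec)
        assert np.allclose(
            fit1.coefficients.to_numpy(), fit2.coefficients.to_numpy(), atol=1e-10
        )

    def test_response_scaling_shifts_only_intercept(self):
        df = make_two_factor_data(200, [np.log(0.05), 0.3, -0.2, 0.15], 0.4, seed=6)
        spec = ModelSpec("ir", ("site", "month"), blocking="none")
        fit1 = fit_gamma_loglink(df, spec)
        scaled = df.copy()
        c = 37.0
        scaled["ir"] = scaled["ir"] * c
        fit2 = fit_gamma_loglink(scaled, spec)
        diff = fit2.coefficients - fit1.coefficients
        assert diff["Intercept"] == pytest.approx(np.log(c), abs=1e-8)
        assert np.allclose(diff.drop("Intercept").to_numpy(), 0.0, atol=1e-8)
        # contrasts and effect sizes unchanged
        cmp1 = pairwise_comparisons(
            estimated_marginal_means(fit1, "site"), fit1
        )
        cmp2 = pairwise_comparisons(
            estimated_marginal_means(fit2, "site"), fit2
        )
        assert np.allclose(cmp1["difference"], cmp2["difference"], atol=1e-8)
        assert np.allclose(cmp1["cohens_d"], cmp2["cohens_d"], atol=1e-6)

    def test_aliased_interaction_dropped_main_effects_fit(self):
        """When a site is never sampled in some months, a site-by-month
        interaction factor is rank deficient; aliased columns are dropped
        and the main-effects part still fits."""
        df = make_two_factor_data(300, [np.log(0.05), 0.3, -0.2, 0.15], 0.4, seed=7)
        df = df[~((df["site"] == "c") & (df["month"] == "y"))].reset_index(drop=True)
        df["site_month"] = df["site"] + ":" + df["month"]
        fit = fit_gamma_loglink(
            df, ModelSpec("ir", ("site", "month", "site_month"), blocking="none")
        )
        assert fit.converged
        assert len(fit.dropped_columns) > 0
        assert "Intercept" in fit.coefficients.index

    def test_blocking_adds_year_dummies(self):
        df = make_two_factor_data(200, [np.log(0.05), 0.3, -0.2, 0.15], 0.4, seed=8)
        rng = np.random.default_rng(0)
        df["year"] = rng.choice([2008, 2009, 2010], len(df))
        fit = fit_gamma_loglink(df, ModelSpec("ir", ("site",), blocking="year"))
        year_cols = [c for c in fit.coefficients.index if "year_block" in c]
        assert len(year_cols) == 2


class TestAicc:
    def test_hand_value(self):
        # k=2, n=100, ll=-50: 100 + 4 + 12/97
        assert aicc_value(-50.0, 2, 100) == pytest.approx(104.124, abs=5e-4)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc_value(-50.0, 5, 6)

    def test_exceeds_aic_for_finite_n(self):
        for k, n in [(2, 20), (5, 50), (10, 200)]:
            aic = -2 * (-30.0) + 2 * k
            assert aicc_value(-30.0, k, n) > aic

    def test_nested_models_likelihood_monotone(self):
        df = make_two_factor_data(300, [np.log(0.05), 0.3, -0.2, 0.15], 0.4, seed=9)
        small = fit_gamma_loglink(df, ModelSpec("ir", ("site",), blocking="none"))
        big = fit_gamma_loglink(
            df, ModelSpec("ir", ("site", "month"), blocking="none")
        )
        assert big.log_likelihood >= small.log_likelihood - 1e-8


class TestEmm:
    def test_balanced_one_factor_equals_group_log_means(self):
        rng = np.random.default_rng(10)
        y = rng.gamma(4.0, 0.01, size=120)
        f = np.repeat(["a", "b", "c"], 40)
        df = pd.DataFrame({"ir": y, "site": f, "year": 2008, "month": 5})
        fit = fit_gamma_loglink(df, ModelSpec("ir", ("site",), blocking="none"))
        emm = estimated_marginal_means(fit, "site")
        for level in "abc":
            assert emm.emm(level) == pytest.approx(
                np.log(y[f == level].mean()), abs=1e-7
            )

    def test_two_factor_emm_invariant_to_relabeling_other(self):
        df = make_two_factor_data(
            400, [np.log(0.05), 0.3, -0.2, 0.15], 0.4, seed=11, p2=(0.5, 0.5)
        )
        spec = ModelSpec("ir", ("site", "month"), blocking="none")
        emm1 = estimated_marginal_means(fit_gamma_loglink(df, spec), "site")
        relabeled = df.copy()
        relabeled["month"] = relabeled["month"].map({"x": "q", "y": "p"})
        emm2 = estimated_marginal_means(fit_gamma_loglink(relabeled, spec), "site")
        assert np.allclose(
            emm1.table["emm"].to_numpy(), emm2.table["emm"].to_numpy(), atol=1e-8
        )

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_unbalanced_emm_matches_r_emmeans(self, tmp_path):
        """Cross-implementation oracle: link-scale EMMs from an unbalanced
        two-factor gamma fit agree with R's emmeans within 1e-6."""
        df = make_two_factor_data(240, [np.log(0.05), 0.3, -0.2, 0.15], 0.4, seed=11)
        fit = fit_gamma_loglink(df, ModelSpec("ir", ("site", "month"), blocking="none"))
        emm = estimated_marginal_means(fit, "site")
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "emm.R"
        out = tmp_path / "ref.csv"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(emmeans))
                d <- read.csv("{csv}")
                fit <- glm(ir ~ site + month, family=Gamma(link="log"), data=d,
                           control=glm.control(epsilon=1e-12, maxit=100))
                e <- summary(emmeans(fit, "site"))
                write.csv(e[, c("site", "emmean")], "{out}", row.names=FALSE)
                """
            )
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, timeout=300
        )
        ref = pd.read_csv(out).set_index("site")["emmean"]
        for level in "abc":
            assert emm.emm(level) == pytest.approx(ref[level], abs=1e-6)

    def test_absent_level_flagged_non_estimable(self):
        df = make_two_factor_data(200, [np.log(0.05), 0.3, -0.2, 0.15], 0.4, seed=12)
        spec = ModelSpec(
            "ir", ("site", "month"), blocking="none",
            reference_levels={"site": "a"},
        )
        fit = fit_gamma_loglink(df, spec)
        # grid restricted to observed combos: all levels present here
        emm = estimated_marginal_means(fit, "site")
        assert emm.table["estimable"].all()


class TestPairwise:
    def test_identical_groups_give_null_comparison(self):
        rng = np.random.default_rng(13)
        y = rng.gamma(4.0, 0.01, size=400)
        f = np.tile(["a", "b"], 200)  # identical distributions
        df = pd.DataFrame({"ir": y, "site": f, "year": 2008, "month": 5})
        fit = fit_gamma_loglink(df, ModelSpec("ir", ("site",), blocking="none"))
        row = pairwise_comparisons(estimated_marginal_means(fit, "site"), fit).iloc[0]
        assert abs(row["cohens_d"]) < 0.3
        assert row["lower"] < 0 < row["upper"]
        assert not row["flagged"]

    def test_d_sign_antisymmetric(self):
        df = make_two_factor_data(300, [np.log(0.05), 0.6, -0.2, 0.15], 0.4, seed=14)
        spec = ModelSpec("ir", ("site", "month"), blocking="none")
        fit = fit_gamma_loglink(df, spec)
        flipped = fit_gamma_loglink(
            df, ModelSpec("ir", ("site", "month"), blocking="none",
                          reference_levels={"site": "b"})
        )
        t1 = pairwise_comparisons(estimated_marginal_means(fit, "site"), fit)
        t2 = pairwise_comparisons(
            estimated_marginal_means(flipped, "site"), flipped
        )
        d1 = t1.set_index(["level_a", "level_b"])["cohens_d"]
        d2 = t2.set_index(["level_a", "level_b"])["cohens_d"]
        assert d1[("a", "b")] == pytest.approx(-d2[("b", "a")], abs=1e-6)

    def test_d_estimates_standardized_gap_at_large_n(self):
        """Two-group gamma data with known log-mean gap: d converges to
        gap / sqrt(trigamma(1/alpha))."""
        alpha, gap, n = 0.4, 0.5, 2000
        rng = np.random.default_rng(15)
        f = rng.choice(["a", "b"], n)
        x = np.column_stack([np.ones(n), f == "b"])
        y = generate_gamma_responses(x, [np.log(0.05), gap], alpha, seed=16)
        df = pd.DataFrame({"ir": y, "site": f, "year": 2008, "month": 5})
        fit = fit_gamma_loglink(df, ModelSpec("ir", ("site",), blocking="none"))
        row = pairwise_comparisons(estimated_marginal_means(fit, "site"), fit).iloc[0]
        expected = -gap / link_scale_sigma(alpha)  # a minus b
        assert row["cohens_d"] == pytest.approx(expected, abs=0.05)

    def test_flag_rule_type_i_error_near_nominal(self):
        """Null simulations (no group effect): the 'd CI excludes 0' flag
        fires at close to the nominal 5% rate."""
        n_reps, n = 500, 120
        hits = 0
        rng = np.random.default_rng(17)
        for rep in range(n_reps):
            f = np.repeat(["a", "b"], n // 2)
            y = rng.gamma(1.0 / 0.4, 0.05 * 0.4, size=n)
            df = pd.DataFrame({"ir": y, "site": f, "year": 2008, "month": 5})
            fit = fit_gamma_loglink(df, ModelSpec("ir", ("site",), blocking="none"))
            row = pairwise_comparisons(
                estimated_marginal_means(fit, "site"), fit
            ).iloc[0]
            hits += int(row["flagged"])
        rate = hits / n_reps
        # binomial 95% envelope around 0.05 at 500 reps: ~ +/- 0.019
        assert 0.05 - 0.02 <= rate <= 0.05 + 0.02

    def test_single_level_yields_empty_table(self):
        rng = np.random.default_rng(18)
        df = pd.DataFrame(
            {
                "ir": rng.gamma(2.0, 0.01, 50),
                "site": "a",
                "year": 2008,
                "month": 5,
            }
        )
        fit = fit_gamma_loglink(df, ModelSpec("ir", ("site",), blocking="none"))
        table = pairwise_comparisons(estimated_marginal_means(fit, "site"), fit)
        assert len(table) == 0
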