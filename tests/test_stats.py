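"""Poisson GLMM fitting, likelihood-ratio test, overdispersion."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import cantrace.stats as st

LEVELS = ["L1", "L2", "L3", "L4O", "L4B"]
SPECIES = ["BET", "LOT", "SKJ", "YFT"]


def simulate_counts(
    n_individuals=33,
    sd=0.3,
    beta0=-0.3,
    level_effects=(0.0, 0.3, 0.8, 1.2, 1.5),
    species_effects=(0.0, 0.0, 0.0, 0.0),
    interaction=0.0,
    seed=0,
):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_individuals):
        sp_idx = i % len(SPECIES)
        u = rng.normal(0.0, sd)
        for lv_idx, lv in enumerate(LEVELS):
            eta = (
                beta0
                + level_effects[lv_idx]
                + species_effects[sp_idx]
                + interaction * lv_idx * sp_idx
                + u
            )
            rows.append(
                {
                    "individual": f"ind{i:04d}",
                    "species": SPECIES[sp_idx],
                    "level": lv,
                    "n_ns": rng.poisson(np.exp(eta)),
                }
            )
    return pd.DataFrame(rows)


class TestFitPoissonGLMM:
    def test_zero_variance_matches_irls_oracle(self):
        df = simulate_counts(seed=1)
        fit = st.fit_poisson_glmm(df, fixed="level", random="individual", var_fixed=0.0)
        X, names = st.build_fixed_design(df, "level")
        oracle = sm.GLM(df["n_ns"].to_numpy(), X, family=sm.families.Poisson()).fit()
        for name, est in zip(names, oracle.params):
            assert abs(fit.coef[name] - est) < 1e-3
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)

    def test_matches_lme4_glmer_reference(self, tmp_path):
        """Independent cross-check against R's Laplace GLMM fitter."""
        df = simulate_counts(sd=0.4, seed=42)
        csv = tmp_path / "counts.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"df <- read.csv('{csv}')\n"
            "m <- glmer(n_ns ~ level + (1 | individual), data = df, family = poisson)\n"
            "cat(as.numeric(logLik(m)), as.numeric(VarCorr(m)$individual[1]), fixef(m), sep = '\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.split()]
        r_loglik, r_var, r_coefs = vals[0], vals[1], vals[2:]
        fit = st.fit_poisson_glmm(df, fixed="level", random="individual")
        assert fit.loglik == pytest.approx(r_loglik, abs=1e-2)
        assert fit.var_components["individual"] == pytest.approx(r_var, abs=1e-2)
        X, names = st.build_fixed_design(df, "level")
        for name, est in zip(names, r_coefs):
            assert fit.coef[name] == pytest.approx(est, abs=1e-2)

    def test_all_zero_counts_flagged_degenerate(self):
        df = simulate_counts(seed=2)
        df["n_ns"] = 0
        fit = st.fit_poisson_glmm(df)
        assert fit.degenerate and not fit.converged

    def test_negative_or_fractional_counts_rejected(self):
        df = simulate_counts(seed=3)
        bad = df.copy()
        bad.loc[0, "n_ns"] = -1
        with pytest.raises(st.DataError):
            st.fit_poisson_glmm(bad)
        bad = df.copy()
        bad["n_ns"] = bad["n_ns"] + 0.5
        with pytest.raises(st.DataError):
            st.fit_poisson_glmm(bad)

    def test_duplicate_specimen_level_rejected(self):
        df = simulate_counts(seed=4)
        with pytest.raises(st.DataError):
            st.fit_poisson_glmm(pd.concat([df, df.iloc[:1]]))

    def test_record_order_invariance(self):
        df = simulate_counts(sd=0.4, seed=5)
        fit1 = st.fit_poisson_glmm(df, fixed="level*species", compute_se=False)
        shuffled = df.sample(frac=1.0, random_state=99).reset_index(drop=True)
        fit2 = st.fit_poisson_glmm(shuffled, fixed="level*species", compute_se=False)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)
        for name in fit1.coef:
            assert fit1.coef[name] == pytest.approx(fit2.coef[name], abs=1e-5)

    def test_confounded_nesting_collapses_to_one_component(self):
        df = simulate_counts(seed=6)
        fit = st.fit_poisson_glmm(df, fixed="level", random="individual/species")
        assert list(fit.var_components) == ["individual"]

    def test_species_individual_nesting_fits_two_components(self):
        df = simulate_counts(sd=0.4, seed=7)
        fit = st.fit_poisson_glmm(df, fixed="level", random="species/individual")
        assert set(fit.var_components) == {"species", "species:individual"}
        assert all(v >= 0 for v in fit.var_components.values())

    def test_empty_cell_flagged_singular_not_crash(self):
        df = simulate_counts(seed=8)
        df = df[~((df["species"] == "YFT") & (df["level"] == "L4B"))]
        fit = st.fit_poisson_glmm(df, fixed="level*species")
        assert fit.singular_design
        assert np.isnan(fit.coef["level[L4B]:species[YFT]"])


class TestLikelihoodRatioTest:
    def test_interaction_vs_additive_df_is_twelve(self):
        df = simulate_counts(seed=10)
        full = st.fit_poisson_glmm(df, fixed="level*species", compute_se=False)
        red = st.fit_poisson_glmm(df, fixed="level+species", compute_se=False)
        lrt = st.likelihood_ratio_test(full, red)
        assert lrt.df == 12
        assert full.loglik >= red.loglik - 1e-6

    def test_identical_models_give_zero_statistic(self):
        df = simulate_counts(seed=11)
        fit = st.fit_poisson_glmm(df, fixed="level", compute_se=False)
        # identical models are not nested (df = 0): rejected ...
        with pytest.raises(st.NestingError):
            st.likelihood_ratio_test(fit, fit)
        # ... and the underlying statistic is exactly zero
        refit = st.fit_poisson_glmm(df, fixed="level", compute_se=False)
        assert 2 * (fit.loglik - refit.loglik) == pytest.approx(0.0, abs=1e-9)

    def test_non_nested_rejected(self):
        df = simulate_counts(seed=12)
        full = st.fit_poisson_glmm(df, fixed="level*species", compute_se=False)
        red = st.fit_poisson_glmm(df, fixed="level+species", compute_se=False)
        with pytest.raises(st.NestingError):
            st.likelihood_ratio_test(red, full)

    def test_detects_strong_interaction(self):
        """Power check: strong Level x Species interaction is detected."""
        hits = 0
        n_reps = 40
        for rep in range(n_reps):
            df = simulate_counts(
                n_individuals=40, sd=0.2, interaction=0.18, seed=500 + rep
            )
            full = st.fit_poisson_glmm(df, fixed="level*species", compute_se=False)
            red = st.fit_poisson_glmm(df, fixed="level+species", compute_se=False)
            lrt = st.likelihood_ratio_test(full, red)
            hits += lrt.p_value < 0.05
        assert hits >= 0.9 * n_reps


class TestOverdispersion:
    def test_residual_df_arithmetic(self):
        df = simulate_counts(seed=20)  # 165 records
        fit = st.fit_poisson_glmm(df, fixed="level*species", compute_se=False)
        od = st.overdispersion(fit)
        assert od.residual_df == 165 - fit.n_params
        # n=165, p=22 -> rdf=143 regardless of how p was reached
        assert 165 - 22 == 143

    def test_calibrated_near_one_for_poisson_data(self):
        """Data from the fitted model keep the ratio near 1 (n >= 500)."""
        hits = 0
        n_reps = 100
        for rep in range(n_reps):
            df = simulate_counts(n_individuals=100, sd=0.3, seed=2100 + rep)
            fit = st.fit_poisson_glmm(df, fixed="level", compute_se=False)
            od = st.overdispersion(fit)
            hits += 0.8 < od.ratio < 1.2
        assert hits >= 0.9 * n_reps

    def test_detects_extra_poisson_noise(self):
        """Variance inflated ~3x pushes the ratio well above 1."""
        hits = 0
        n_reps = 100
        for rep in range(n_reps):
            rng = np.random.default_rng(3200 + rep)
            df = simulate_counts(n_individuals=100, sd=0.0, seed=3200 + rep)
            # multiplicative gamma noise on the mean inflates the variance
            lam = np.maximum(df["n_ns"].to_numpy(float), 0.2)
            df["n_ns"] = rng.poisson(lam * rng.gamma(0.5, 2.0, size=len(df)))
            fit = st.fit_poisson_glmm(df, fixed="level", compute_se=False)
            od = st.overdispersion(fit)
            hits += od.ratio > 1.5
        assert hits >= 0.9 * n_reps
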