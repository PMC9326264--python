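"""Statistical workflow: AIC selection, LRT, the Laplace GLMM (including a
cross-check against lme4's glmer via Rscript), Type III tests, moonlight
slopes and prediction intervals."""

import subprocess
import textwrap
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from moonsim import foraging_stats as fs
from moonsim.foraging_synth import (
    ForagingParams,
    generate_dataset,
    null_params,
    reversal_params,
    study_design,
)


@pytest.fixture(scope="module")
def glmm_fit(reversal_data):
    return fs.fit_glmm(reversal_data, fs.ModelSpec(fs.SELECTED_TERMS, random=True))


class TestSelection:
    def test_candidate_space_respects_marginality(self):
        sets = fs._candidate_term_sets()
        assert len(sets) == 35  # 8 without ALAN + 27 with
        assert all(fs._respects_marginality(s) for s in sets)

    def test_weights_normalize_and_table_sorted(self, reversal_data):
        tab, best = fs.fit_global_and_select(reversal_data)
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(tab["AIC"]) >= 0).all()
        assert tab["selected"].iloc[0]
        assert tab.loc[tab["selected"], "weight"].sum() >= 0.99 - 1e-9

    def test_reversal_scenario_keeps_interaction(self, reversal_data):
        _, best = fs.fit_global_and_select(reversal_data)
        assert "ALAN:Moonlight" in best.fixed_terms

    def test_null_data_prefers_small_models(self):
        """With no true effects the intercept-only model sits at or within 2
        AIC of the best of the 35 candidates in roughly three runs out of
        four (Monte-Carlo reference rate 0.795 over 200 seeds: the minimum
        AIC over 34 competing submodels beats the true model by more than 2
        in about a fifth of null datasets — ordinary selection noise)."""
        hits = 0
        for seed in range(20):
            d = generate_dataset(study_design(), null_params(seed=seed))
            tab, _ = fs.fit_global_and_select(d)
            aic0 = tab.loc[tab["terms"] == "(Intercept)", "AIC"].iloc[0]
            if aic0 <= tab["AIC"].iloc[0] + 2.0:
                hits += 1
        assert hits >= 13


class TestLRT:
    def test_identical_fits_give_zero(self, reversal_data):
        fit = fs.fit_glm(reversal_data, ("Moonlight",))
        t = fs.lrt(fit, fit)
        assert t.chi_sq == 0.0 and t.p_value == 1.0

    def test_global_vs_intercept_is_decisive_under_reversal(self, reversal_data):
        full = fs.fit_glm(reversal_data, fs.GLOBAL_TERMS)
        null = fs.fit_glm(reversal_data, ())
        t = fs.lrt(full, null)
        assert t.df == full.n_params - 1
        assert t.p_value < 1e-6

    def test_non_nested_rejected(self, reversal_data):
        a = fs.fit_glm(reversal_data, ("Moonlight",))
        b = fs.fit_glm(reversal_data, ("Night",))
        with pytest.raises(ValueError):
            fs.lrt(a, b)


class TestGLMM:
    def test_degenerate_random_effects_match_glm(self):
        """Data generated without group effects: the GLMM collapses to the
        GLM (variance components at the boundary, coefficients equal)."""
        d = generate_dataset(
            study_design(),
            replace(reversal_params(seed=5), sigma_tank=0.0, sigma_snail=0.0),
        )
        glmm = fs.fit_glmm(d, fs.ModelSpec(fs.SELECTED_TERMS, random=True))
        glm = fs.fit_glm(d, fs.SELECTED_TERMS)
        assert glmm.singular
        assert max(glmm.variance_components.values()) < 1e-2
        assert np.allclose(glmm.params, glm.params, atol=1e-3)
        assert glmm.loglik == pytest.approx(glm.loglik, abs=1e-2)

    def test_snail_variance_recovered(self):
        """sigma_snail = 1 in the generator is recovered within a factor
        consistent with 84 groups."""
        for seed in (0, 1, 2):
            d = generate_dataset(
                study_design(),
                replace(reversal_params(seed=seed), sigma_tank=0.0, sigma_snail=1.0),
            )
            fit = fs.fit_glmm(d, fs.ModelSpec(fs.SELECTED_TERMS, random=True))
            assert 0.7 < fit.variance_components["sigma_snail"] < 1.35

    def test_matches_glmer_reference(self, reversal_data, tmp_path):
        """Coefficients and Laplace log-likelihood agree with lme4::glmer on
        the same data (independent implementation, same approximation)."""
        ours = fs.fit_glmm(
            reversal_data, fs.ModelSpec(fs.SELECTED_TERMS, random=True)
        )
        csv = tmp_path / "d.csv"
        reversal_data.to_csv(csv, index=False)
        out = tmp_path / "r.csv"
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$treatment <- factor(d$treatment, levels=c("control","0.1lx",
              "0.5lx","1lx","10lx","10lx-mit","50lx"))
            d$time_of_day <- factor(d$time_of_day, levels=c("day","night"))
            m <- glmer(foraging ~ treatment*nightly_max_moon_lux
                       + treatment*night_index + time_of_day
                       + (1|tank_id) + (1|snail_id),
                       data=d, family=binomial,
                       control=glmerControl(optimizer="bobyqa",
                                            optCtrl=list(maxfun=100000)))
            write.csv(data.frame(est=fixef(m), ll=as.numeric(logLik(m))),
                      "{out}", row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)
        assert ours.loglik == pytest.approx(ref["ll"].iloc[0], abs=0.1)
        # same column order by construction (treatment coding, control ref);
        # optimizers differ slightly, so allow a small relative slack on the
        # larger slope coefficients
        assert np.allclose(
            ours.params.to_numpy(), ref["est"].to_numpy(), atol=0.05, rtol=0.03
        )

    def test_missing_grouping_columns_rejected(self, reversal_data):
        with pytest.raises(ValueError):
            fs.fit_glmm(
                reversal_data.drop(columns=["tank_id"]),
                fs.ModelSpec(fs.SELECTED_TERMS, random=True),
            )


class TestType3:
    def test_interaction_df_is_six_and_detected(self, reversal_data):
        tests = {
            t.term: t for t in fs.type3_tests(
                reversal_data, fs.ModelSpec(fs.SELECTED_TERMS, random=False)
            )
        }
        assert tests["ALAN:Moonlight"].df == 6
        assert tests["ALAN"].df == 6
        assert tests["Moonlight"].df == 1
        assert tests["TimeOfDay"].df == 1
        assert tests["ALAN:Moonlight"].p_value < 0.05
        assert all(t.chi_sq >= 0 for t in tests.values())

    def test_glmm_route_agrees_on_strong_interaction(self, reversal_data):
        tests = {
            t.term: t for t in fs.type3_tests(
                reversal_data, fs.ModelSpec(fs.SELECTED_TERMS, random=True)
            )
        }
        assert tests["ALAN:Moonlight"].df == 6
        assert tests["ALAN:Moonlight"].p_value < 0.05


class TestSlopes:
    def test_reversal_signs_recovered(self, glmm_fit):
        slopes, pairs = fs.moonlight_slopes(glmm_fit)
        s = dict(zip(slopes["treatment"], slopes["slope"]))
        assert s["control"] < 0
        assert s["50lx"] > 0 and s["10lx"] > 0
        assert len(pairs) == 21  # all unordered treatment pairs

    def test_pairwise_antisymmetry(self, glmm_fit):
        slopes, pairs = fs.moonlight_slopes(glmm_fit)
        s = dict(zip(slopes["treatment"], slopes["slope"]))
        from scipy import stats as sps

        for p in pairs:
            assert p.difference == pytest.approx(s[p.pair[0]] - s[p.pair[1]], abs=1e-9)
            assert p.p_value == pytest.approx(2 * sps.norm.sf(abs(p.z)), abs=1e-12)

    def test_model_without_interaction_rejected(self, reversal_data):
        fit = fs.fit_glm(reversal_data, ("ALAN", "Moonlight"))
        with pytest.raises(ValueError):
            fs.moonlight_slopes(fit)


class TestPredictIntervals:
    def test_zero_variance_gives_zero_width(self, reversal_data):
        fit = fs.fit_glm(reversal_data, fs.SELECTED_TERMS)
        fit.cov.iloc[:, :] = 0.0
        new = reversal_data.head(5)
        out = fs.predict_intervals(fit, new, n_draws=200, seed=0)
        assert np.allclose(out["upper"] - out["lower"], 0.0, atol=1e-12)

    def test_interval_contains_point_and_monotone_link(self, glmm_fit, reversal_data):
        new = reversal_data.groupby("treatment", sort=False).head(8)
        out = fs.predict_intervals(glmm_fit, new, n_draws=500, seed=1)
        assert ((out["lower"] - 1e-12 <= out["predicted"])
                & (out["predicted"] <= out["upper"] + 1e-12)).all()
        X = fs.build_design(new, glmm_fit.terms)[list(glmm_fit.params.index)]
        eta = X.to_numpy() @ glmm_fit.params.to_numpy()
        order = np.argsort(eta)
        assert (np.diff(out["predicted"].to_numpy()[order]) >= -1e-12).all()

    def test_extrapolation_flagged_not_rejected(self, glmm_fit, reversal_data):
        new = reversal_data.head(3).copy()
        new["nightly_max_moon_lux"] = 5.0  # far beyond any modeled night
        out = fs.predict_intervals(glmm_fit, new, n_draws=100, seed=2)
        assert out["extrapolated"].all()

    def test_coverage_close_to_nominal(self):
        """Across repeated datasets with no random effects the 95% interval
        covers the generating probability about 95% of the time."""
        base = replace(
            reversal_params(seed=0), sigma_tank=0.0, sigma_snail=0.0
        )
        design = study_design()
        template = generate_dataset(design, base)
        grid = template.drop_duplicates(["treatment", "time_of_day"]).copy()
        ti = grid["treatment"].map(
            {t: i for i, t in enumerate(fs.TREATMENT_ORDER)}
        ).to_numpy()
        eta = (
            base.beta0
            + np.asarray(base.beta_moon)[ti] * grid["nightly_max_moon_lux"].to_numpy()
            + base.gamma_night * grid["night_index"].to_numpy()
        )
        truth = 1 / (1 + np.exp(-eta))
        covered = []
        for seed in range(100):
            d = generate_dataset(design, replace(base, seed=seed))
            fit = fs.fit_glm(d, fs.SELECTED_TERMS)
            out = fs.predict_intervals(fit, grid, n_draws=1000, seed=seed)
            covered.append((out["lower"] <= truth) & (truth <= out["upper"]))
        rate = np.mean(covered)
        assert abs(rate - 0.95) <= 0.03


class TestModelSpec:
    def test_marginality_enforced(self):
        with pytest.raises(ValueError):
            fs.ModelSpec(fixed_terms=("ALAN:Moonlight", "ALAN"))

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            fs.ModelSpec(fixed_terms=("Tide",))
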