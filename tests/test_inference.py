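"""Mixed-model battery: LMM wrapper, LRT, Nakagawa R2, backward selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from airbreath.inference import (
    MODEL_BATTERY,
    ModelSpec,
    R2Result,
    fit_lmm,
    fit_nb_glmm,
    likelihood_ratio_test,
    nakagawa_r2,
    select_model,
)


def _balanced_oneway(rng, k=8, n=10, sd_group=2.0, sd_resid=1.0):
    g = np.repeat(np.arange(k), n)
    u = rng.normal(0, sd_group, k)
    y = 5.0 + u[g] + rng.normal(0, sd_resid, k * n)
    return pd.DataFrame({"y": y, "group": g})


class TestFitLMM:
    def test_balanced_reml_matches_method_of_moments(self, rng):
        """Balanced one-way design: REML variance components equal the
        closed-form ANOVA method-of-moments estimators."""
        df = _balanced_oneway(rng)
        k, n = 8, 10
        res = fit_lmm(
            ModelSpec("ow", "y ~ 1", groups="group"), df, reml=True,
            method="bfgs", gtol=1e-10,
        )
        gm = df.groupby("group")["y"].mean()
        msb = n * ((gm - df.y.mean()) ** 2).sum() / (k - 1)
        msw = sum(
            ((df[df.group == i].y - gm[i]) ** 2).sum() for i in range(k)
        ) / (k * (n - 1))
        assert res.vc["group"] == pytest.approx((msb - msw) / n, abs=1e-6)
        assert res.scale == pytest.approx(msw, abs=1e-6)

    def test_zero_between_group_variance_matches_ols(self, rng):
        """Group-variance MLE on the zero boundary: the mixed fit collapses
        to ordinary least squares."""
        df = _balanced_oneway(rng, sd_group=0.0)
        df["x"] = rng.normal(size=len(df))
        e = rng.normal(0, 1.0, len(df))
        # remove all between-group structure so the variance MLE sits at 0
        e -= pd.Series(e).groupby(df.group).transform("mean").to_numpy()
        df["y"] = 2.0 + 0.7 * df.x + e
        res = fit_lmm(ModelSpec("z", "y ~ x", groups="group"), df)
        ols = np.polyfit(df.x, df.y, 1)
        assert res.vc["group"] == pytest.approx(0.0, abs=1e-6)
        assert res.params["x"] == pytest.approx(ols[0], abs=1e-6)
        assert res.params["Intercept"] == pytest.approx(ols[1], abs=1e-6)

    def test_temperature_effect_recovery_coverage(self):
        """Known temperature effect on log SMR falls inside its 95% interval
        in at least 90% of seeded replicates."""
        from airbreath.synth import EffectConfig, StudyDesign, _fish_table

        design = StudyDesign()
        effects = EffectConfig()
        beta_true = np.log(effects.temp_factor)
        spec = MODEL_BATTERY["smr"]
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            fish = _fish_table(design, effects, np.random.default_rng(1000 + s))
            fish = fish.rename(columns={"smr_true": "smr"})
            res = fit_lmm(spec, fish)
            lo, hi = res.conf_int().loc["C(temp)[T.30]"]
            hits += lo <= beta_true <= hi
        assert hits / n_rep >= 0.90

    def test_log_of_nonpositive_reports_rows(self):
        df = pd.DataFrame(
            {"smr": [0.2, -0.1, 0.3], "mass": [1.0, 1.0, 1.0],
             "temp": [25, 25, 30], "group": ["a", "a", "b"],
             "fish_id": ["f1", "f2", "f3"]}
        )
        with pytest.raises(ValueError, match=r"log\(smr\).*\[1\]"):
            fit_lmm(MODEL_BATTERY["smr"], df)


class TestLRT:
    def test_identical_models_statistic_zero(self, rng):
        df = _balanced_oneway(rng)
        df["x"] = rng.normal(size=len(df))
        a = fit_lmm(ModelSpec("a", "y ~ x", groups="group"), df)
        b = fit_lmm(ModelSpec("b", "y ~ 0 + x + 1", groups="group"), df)
        b = b.__class__(**{**b.__dict__, "n_params": b.n_params - 1})
        lrt = likelihood_ratio_test(a, b)
        assert lrt.statistic == pytest.approx(0.0, abs=1e-6)
        assert lrt.p_value == pytest.approx(1.0, abs=1e-4)

    def test_chi_square_quantile(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.0500, abs=5e-4)

    def test_p_values_uniform_under_null(self):
        """LRT p-values for a truly null covariate are approximately uniform
        (KS distance < 0.08 over 500 seeded replicates)."""
        pvals = []
        for s in range(500):
            rng = np.random.default_rng(5000 + s)
            df = _balanced_oneway(rng, k=6, n=6, sd_group=1.0)
            df["x"] = rng.normal(size=len(df))
            full = fit_lmm(ModelSpec("f", "y ~ x", groups="group"), df)
            red = fit_lmm(ModelSpec("r", "y ~ 1", groups="group"), df)
            pvals.append(likelihood_ratio_test(full, red).p_value)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.08

    def test_not_nested_raises(self, rng):
        df = _balanced_oneway(rng)
        df["x"] = rng.normal(size=len(df))
        full = fit_lmm(ModelSpec("f", "y ~ 1", groups="group"), df)
        red = fit_lmm(ModelSpec("r", "y ~ x", groups="group"), df)
        with pytest.raises(ValueError):
            likelihood_ratio_test(full, red)


class TestNBRecovery:
    def test_oxygen_rate_ratio_coverage(self):
        """True severe-hypoxia rate multiplier on group breath counts is
        recovered inside its 95% interval in >= 90% of replicates."""
        from airbreath.synth import EffectConfig, StudyDesign, simulate_tidy_dataset

        design = StudyDesign()
        effects = EffectConfig()
        # reference level is o2=20 (lowest), so the 100% coefficient is
        # -log(multiplier at 20%)
        beta_true = -np.log(effects.o2_rate_multipliers[20])
        spec = ModelSpec(
            "g", "abf_group ~ C(temp) + C(o2)", groups="group", family="negbinom"
        )
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            _, per_trial, _ = simulate_tidy_dataset(
                design, effects, np.random.default_rng(3000 + s)
            )
            res = fit_nb_glmm(spec, per_trial)
            lo, hi = res.conf_int().loc["C(o2)[T.100]"]
            hits += lo <= beta_true <= hi
        assert hits / n_rep >= 0.90

    def test_unmixed_limit_matches_single_level_fit(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.normal(size=n)
        theta = 2.5
        mu = np.exp(1.2 + 0.3 * x)
        y = rng.negative_binomial(theta, theta / (theta + mu))
        df = pd.DataFrame({"y": y, "x": x, "g": ["only"] * n})
        mixed = fit_nb_glmm(
            ModelSpec("m", "y ~ x", groups="g", family="negbinom"), df
        )
        plain = fit_nb_glmm(ModelSpec("p", "y ~ x", groups=None, family="negbinom"), df)
        np.testing.assert_allclose(
            mixed.params.to_numpy(), plain.params.to_numpy(), atol=1e-3
        )


class TestNakagawaR2:
    def test_arithmetic_example(self):
        fit = _FakeFit(var_fixed=2.0, vc={"g": 1.0}, scale=1.0)
        r2 = nakagawa_r2(fit)
        assert r2.r2_marginal == pytest.approx(0.5)
        assert r2.r2_conditional == pytest.approx(0.75)

    def test_no_random_effects_marginal_equals_conditional(self):
        fit = _FakeFit(var_fixed=2.0, vc={}, scale=1.0)
        r2 = nakagawa_r2(fit)
        assert r2.r2_marginal == r2.r2_conditional

    def test_self_consistency_on_gaussian_fit(self, rng):
        df = _balanced_oneway(rng)
        df["x"] = rng.normal(size=len(df))
        res = fit_lmm(ModelSpec("s", "y ~ x", groups="group"), df)
        r2 = nakagawa_r2(res)
        # independent recomputation from the fit's own components
        vf = np.var(res.fitted_fixed)
        vr = sum(res.vc.values())
        ve = res.scale
        assert r2.r2_marginal == pytest.approx(vf / (vf + vr + ve), abs=1e-8)
        assert r2.r2_conditional == pytest.approx((vf + vr) / (vf + vr + ve), abs=1e-8)

    def test_ordering_invariant(self, rng):
        df = _balanced_oneway(rng)
        df["x"] = rng.normal(size=len(df))
        r2 = nakagawa_r2(fit_lmm(ModelSpec("s", "y ~ x", groups="group"), df))
        assert 0.0 <= r2.r2_marginal <= r2.r2_conditional <= 1.0

    def test_trigamma_variant_close_to_lognormal_for_large_lambda(self):
        fit = _FakeFit(
            var_fixed=1.0, vc={"g": 0.2}, scale=None, family="negbinom",
            theta=5.0, fitted_fixed=np.full(50, np.log(40.0)),
        )
        a = nakagawa_r2(fit, nb_resid="lognormal")
        b = nakagawa_r2(fit, nb_resid="trigamma")
        assert a.r2_marginal == pytest.approx(b.r2_marginal, rel=0.1)


class _FakeFit:
    """Minimal FitResult stand-in for the R2 arithmetic checks."""

    def __init__(self, var_fixed, vc, scale, family="gaussian", theta=None,
                 fitted_fixed=None):
        n = 1000
        if fitted_fixed is None:
            rng = np.random.default_rng(0)
            fitted_fixed = rng.normal(0.0, np.sqrt(var_fixed), 200_000)
            fitted_fixed *= np.sqrt(var_fixed / np.var(fitted_fixed))
        self.fitted_fixed = fitted_fixed
        self.vc = vc
        self.scale = scale
        self.theta = theta
        self.spec = ModelSpec("fake", "y ~ x", family=family)


class TestSelection:
    def test_null_terms_eliminated_in_majority(self):
        kept = 0
        n_rep = 40
        for s in range(n_rep):
            rng = np.random.default_rng(7000 + s)
            df = _balanced_oneway(rng, k=6, n=6, sd_group=1.0)
            df["x"] = rng.normal(size=len(df))
            df["z"] = rng.normal(size=len(df))
            final, _ = select_model(
                ModelSpec("n", "y ~ x + z", groups="group"), df
            )
            kept += set(final.params.index) == {"Intercept"}
        assert kept / n_rep > 0.5

    def test_strong_term_retained(self):
        retained = 0
        n_rep = 40
        for s in range(n_rep):
            rng = np.random.default_rng(8000 + s)
            df = _balanced_oneway(rng, k=6, n=6, sd_group=1.0)
            df["x"] = rng.normal(size=len(df))
            df["y"] = df["y"] + 1.5 * df["x"]
            final, _ = select_model(
                ModelSpec("s", "y ~ x", groups="group"), df
            )
            retained += "x" in final.params.index
        assert retained / n_rep >= 0.95

    def test_mass_retained_while_smr_significant(self):
        """The allometry guard: mass stays in the model as long as SMR does,
        even when mass itself is null."""
        rng = np.random.default_rng(1)
        n = 240
        g = np.repeat(np.arange(8), 30)
        smr = rng.lognormal(-1.5, 0.3, n)
        mass = rng.lognormal(0.5, 0.2, n)  # no true effect
        y = rng.poisson(np.exp(1.0 + 1.2 * np.log(smr)))
        df = pd.DataFrame(
            {"abf": y, "smr": smr, "mass": mass, "group": g}
        )
        spec = ModelSpec(
            "ind", "abf ~ np.log(mass) + np.log(smr)", groups="group",
            family="negbinom",
            forced_while={"np.log(mass)": "np.log(smr)"},
        )
        final, trace = select_model(spec, df)
        assert "np.log(smr)" in final.params.index
        assert "np.log(mass)" in final.params.index

    def test_interaction_blocks_main_effect_drop(self, rng):
        df = _balanced_oneway(rng, k=6, n=12)
        df["temp"] = np.tile([25, 30], len(df) // 2)
        df["o2"] = np.tile([100, 60, 20], len(df) // 3)
        final, trace = select_model(
            ModelSpec("i", "y ~ C(temp) * C(o2)", groups="group"), df
        )
        # whenever the interaction was tested, its main effects were not
        tested_while_interaction = [
            t["term"] for t in trace
            if t["term"] in ("C(temp)", "C(o2)")
        ]
        dropped_terms = [t["term"] for t in trace if t["dropped"]]
        if "C(temp):C(o2)" not in dropped_terms:
            assert not tested_while_interaction

    def test_empty_formula_rejected(self, rng):
        df = _balanced_oneway(rng)
        with pytest.raises(ValueError, match="empty candidate"):
            select_model(ModelSpec("e", "y ~ 1", groups="group"), df)
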