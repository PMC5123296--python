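import numpy as np
import pandas as pd
import pytest

import varipart as vp
from varipart.lmm import IdentifiabilityError


def ml_oneway_oracle(y, codes, g, m):
    """Closed-form ML for the balanced one-way random model, from ANOVA
    sums of squares (independent of the iterative fitter)."""
    n = g * m
    gm = np.array([y[codes == k].mean() for k in range(g)])
    ssb = m * np.sum((gm - y.mean()) ** 2)
    ssw = np.sum((y - gm[codes]) ** 2)
    s2e = ssw / (n - g)
    s2a = (ssb / g - s2e) / m
    if s2a < 0:
        s2a, s2e = 0.0, (ssw + ssb) / n
    return s2a, s2e


def reml_oneway_oracle(y, codes, g, m):
    """Closed-form REML: mean squares with their usual degrees of freedom."""
    n = g * m
    gm = np.array([y[codes == k].mean() for k in range(g)])
    msb = m * np.sum((gm - y.mean()) ** 2) / (g - 1)
    msw = np.sum((y - gm[codes]) ** 2) / (n - g)
    s2a = (msb - msw) / m
    if s2a < 0:
        s2a, msw = 0.0, (np.sum((y - y.mean()) ** 2)) / (n - 1)
    return s2a, msw


def _intercept_only_design(n):
    meta = pd.DataFrame(index=pd.Index([f"s{i}" for i in range(n)]))
    meta["dummy"] = 1.0  # unused
    return vp.build_design(meta, vp.ModelSpec())


class TestMLFits:
    def test_intercept_only_matches_ml_variance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 1.5, size=40)
        fit = vp.fit_lmm_ml(y, _intercept_only_design(40))
        assert fit.var_resid == pytest.approx(np.var(y, ddof=0), rel=1e-12)
        assert fit.intercept == pytest.approx(y.mean(), rel=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_balanced_oneway_ml_oracle(self, oneway_design, seed):
        g, m = 30, 5
        meta, designs, codes = oneway_design(g, m)
        rng = np.random.default_rng(seed)
        y = np.sqrt(3.0) * rng.normal(size=g)[codes] + rng.normal(size=g * m)
        fit = vp.fit_lmm_ml(y, designs)
        oa, oe = ml_oneway_oracle(y, codes, g, m)
        assert fit.var_random["grp"] == pytest.approx(oa, rel=1e-6)
        assert fit.var_resid == pytest.approx(oe, rel=1e-6)

    def test_matches_balanced_oneway_reml_oracle(self, oneway_design):
        g, m = 25, 4
        meta, designs, codes = oneway_design(g, m)
        rng = np.random.default_rng(5)
        y = np.sqrt(2.0) * rng.normal(size=g)[codes] + rng.normal(size=g * m)
        fit = vp.fit_lmm_ml(y, designs, method="REML")
        oa, oe = reml_oneway_oracle(y, codes, g, m)
        assert fit.var_random["grp"] == pytest.approx(oa, rel=1e-6)
        assert fit.var_resid == pytest.approx(oe, rel=1e-6)

    def test_matches_statsmodels_mixedlm(self, oneway_design):
        import statsmodels.formula.api as smf

        g, m = 20, 4
        meta, designs, codes = oneway_design(g, m)
        rng = np.random.default_rng(9)
        y = 1.3 * rng.normal(size=g)[codes] + rng.normal(size=g * m)
        fit = vp.fit_lmm_ml(y, designs)
        df = pd.DataFrame({"y": y, "grp": meta["grp"].to_numpy()})
        sm_fit = smf.mixedlm("y ~ 1", df, groups=df["grp"]).fit(reml=False)
        assert fit.var_random["grp"] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-4
        )
        assert fit.var_resid == pytest.approx(float(sm_fit.scale), rel=1e-4)

    def test_scale_equivariance_and_shift_invariance(self, oneway_design):
        g, m = 12, 4
        meta, designs, codes = oneway_design(g, m)
        rng = np.random.default_rng(2)
        y = rng.normal(size=g)[codes] + rng.normal(size=g * m)
        f0 = vp.fit_lmm_ml(y, designs)
        fc = vp.fit_lmm_ml(3.0 * y, designs)
        assert fc.var_random["grp"] == pytest.approx(9 * f0.var_random["grp"], rel=1e-5)
        assert fc.var_resid == pytest.approx(9 * f0.var_resid, rel=1e-5)
        fs = vp.fit_lmm_ml(y + 7.0, designs)
        assert fs.intercept == pytest.approx(f0.intercept + 7.0, rel=1e-6)
        assert fs.var_random["grp"] == pytest.approx(f0.var_random["grp"], rel=1e-6)
        assert fs.var_resid == pytest.approx(f0.var_resid, rel=1e-6)

    def test_loglik_beats_pinned_null(self, oneway_design):
        """Fitted ML log-likelihood >= the nested model with the random
        component pinned at zero (plain OLS)."""
        g, m = 15, 3
        meta, designs, codes = oneway_design(g, m)
        rng = np.random.default_rng(4)
        y = 2.0 * rng.normal(size=g)[codes] + rng.normal(size=g * m)
        fit = vp.fit_lmm_ml(y, designs)
        null = vp.fit_lmm_ml(y, _intercept_only_design(g * m))
        assert fit.loglik >= null.loglik - 1e-8

    def test_nonfinite_y_rejected(self, oneway_design):
        _, designs, _ = oneway_design(4, 2)
        y = np.zeros(8)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            vp.fit_lmm_ml(y, designs)

    def test_more_fixed_columns_than_samples_rejected(self):
        meta = pd.DataFrame(
            {"ind": [f"i{i}" for i in range(6)]},
            index=[f"s{i}" for i in range(6)],
        )
        designs = vp.build_design(meta, vp.parse_formula("ind"))
        with pytest.raises(ValueError, match="ind"):
            vp.fit_lmm_ml(np.zeros(6), designs)


class TestWeights:
    def test_constant_weights_match_unweighted(self, oneway_design):
        g, m = 10, 4
        meta, designs, codes = oneway_design(g, m)
        rng = np.random.default_rng(7)
        y = rng.normal(size=g)[codes] + rng.normal(size=g * m)
        f0 = vp.partition_fractions(vp.fit_lmm_ml(y, designs), designs)
        fw = vp.partition_fractions(
            vp.fit_lmm_ml(y, designs, weights=np.full(g * m, 5.5)), designs
        )
        for t in f0.fractions:
            assert fw[t] == pytest.approx(f0[t], abs=1e-8)

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.inf])
    def test_invalid_weights_rejected(self, oneway_design, bad):
        _, designs, _ = oneway_design(4, 2)
        w = np.ones(8)
        w[0] = bad
        with pytest.raises(ValueError, match="weights"):
            vp.fit_lmm_ml(np.arange(8.0), designs, weights=w)

    def test_weight_conventions_are_reciprocal(self, oneway_design):
        g, m = 8, 3
        meta, designs, codes = oneway_design(g, m)
        rng = np.random.default_rng(8)
        y = rng.normal(size=g)[codes] + rng.normal(size=g * m)
        w = rng.uniform(0.5, 2.0, size=g * m)
        f1 = vp.fit_lmm_ml(y, designs, weights=w, weight_convention="precision")
        f2 = vp.fit_lmm_ml(y, designs, weights=1 / w, weight_convention="variance")
        assert f1.var_random["grp"] == pytest.approx(f2.var_random["grp"], rel=1e-6)
        assert f1.var_resid == pytest.approx(f2.var_resid, rel=1e-6)

    def test_duplicating_sample_equals_doubling_precision(self, hand_meta):
        """In a weighted fixed-effects fit, a duplicated row and a doubled
        precision weight give the same estimating equations (same beta)."""
        spec = vp.parse_formula("age + sex")
        d1 = vp.build_design(hand_meta, spec)
        rng = np.random.default_rng(3)
        y = rng.normal(size=8)
        w = np.ones(8)
        w[2] = 2.0
        fit_w = vp.fit_lmm_ml(y, d1, weights=w)
        meta2 = pd.concat([hand_meta, hand_meta.iloc[[2]].set_axis(["s2b"])])
        d2 = vp.build_design(meta2, spec)
        fit_d = vp.fit_lmm_ml(np.append(y, y[2]), d2)
        assert fit_d.intercept == pytest.approx(fit_w.intercept, rel=1e-9)
        for t in fit_w.beta:
            np.testing.assert_allclose(fit_d.beta[t], fit_w.beta[t], rtol=1e-9)


class TestOLSComparator:
    def test_perfect_separation_gives_full_fraction(self):
        meta = pd.DataFrame(
            {"grp": ["a", "a", "b", "b"]}, index=[f"s{i}" for i in range(4)]
        )
        d = vp.build_design(meta, vp.parse_formula("(1|grp)"))
        y = np.array([0.0, 0.0, 1.0, 1.0])
        row = vp.partition_fractions(vp.fit_ols_anova(y, d), d)
        assert row["grp"] == pytest.approx(1.0)
        assert row["residual"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_invariant_design_not_identifiable(self, study_data):
        """Sex and ancestry are constant within individual, so the combined
        fixed-effects design is singular."""
        _, meta, _ = study_data
        d = vp.build_design(
            meta, vp.parse_formula("(1|individual) + (1|sex) + (1|ancestry)")
        )
        with pytest.raises(IdentifiabilityError, match="not identifiable"):
            vp.fit_ols_anova(meta.index.to_series().rank().to_numpy(), d)

    def test_matches_ml_on_fixed_only_spec(self, hand_meta):
        spec = vp.parse_formula("age + sex")
        d = vp.build_design(hand_meta, spec)
        rng = np.random.default_rng(6)
        y = rng.normal(size=8) + hand_meta["age"].to_numpy() * 0.1
        r_ols = vp.partition_fractions(vp.fit_ols_anova(y, d), d)
        r_ml = vp.partition_fractions(vp.fit_lmm_ml(y, d), d)
        for t in r_ols.fractions:
            assert r_ols[t] == pytest.approx(r_ml[t], abs=1e-10)

    def test_varying_spec_rejected(self, hand_meta):
        d = vp.build_design(hand_meta, vp.parse_formula("(batch|individual)"))
        with pytest.raises(ValueError, match="varying"):
            vp.fit_ols_anova(np.zeros(8), d)


def test_ols_overfits_many_categories_ml_does_not():
    """With a many-level factor, the OLS/ANOVA fraction inflates above the
    generating value while the ML mixed-model estimate stays close."""
    n, true_f = 200, 0.2
    inflations, ml_errs = [], []
    for L in (10, 80):
        scen = vp.SimScenario(
            n_samples=n, factors=(vp.FactorSpec("batch", L),),
            fractions={"batch": true_f}, n_genes=3, seed=100 + L,
        )
        expr, meta, _ = vp.simulate_dataset(scen)
        d = vp.build_design(meta, vp.parse_formula("(1|batch)"))
        ml = np.median([
            vp.partition_fractions(vp.fit_lmm_ml(e, d), d)["batch"]
            for e in expr.to_numpy()
        ])
        ols = np.median([
            vp.partition_fractions(vp.fit_ols_anova(e, d), d)["batch"]
            for e in expr.to_numpy()
        ])
        inflations.append(ols - true_f)
        ml_errs.append(abs(ml - true_f))
    assert inflations[1] > inflations[0] > 0
    assert max(ml_errs) < 0.1
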