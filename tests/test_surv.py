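import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from iescore import GeneratorConfig, generate
from iescore.ies import DEFAULT_SIGNATURES, build_ies
from iescore.ssgsea import score_all
from iescore.survival import CoxPH, cox_fit, km_fit, prognostic_report


def sim_survival(rng, n, beta, censor=30.0, rate0=0.05):
    x = rng.standard_normal(n)
    t = rng.exponential(1.0 / (rate0 * np.exp(beta * x)))
    c = rng.uniform(0, censor, n)
    return np.minimum(t, c), (t <= c).astype(int), pd.DataFrame({"x": x})


class TestKM:
    def test_no_censoring_equals_empirical_survival(self):
        fit = km_fit([1, 2, 3, 4], [1, 1, 1, 1], ["a"] * 4)
        tab = fit.tables["a"]
        np.testing.assert_allclose(
            tab.loc[tab["time"] > 0, "survival"], [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            km_fit([1, 2, 3], [0, 0, 0], ["a"] * 3)

    def test_identical_groups_logrank_null(self):
        t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0] * 2
        g = ["a"] * 5 + ["b"] * 5
        fit = km_fit(t, e, g)
        assert fit.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert fit.logrank_p == pytest.approx(1.0)

    def test_logrank_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        e[0] = 1
        g = np.repeat(["a", "b"], 20)
        a = km_fit(t, e, g)
        b = km_fit(np.sqrt(t), e, g)
        assert a.logrank_chi2 == pytest.approx(b.logrank_chi2, rel=1e-10)

    def test_greenwood_se_zero_at_start(self):
        fit = km_fit([1, 2, 3, 4], [1, 1, 0, 1], ["a"] * 4)
        tab = fit.tables["a"]
        assert tab.iloc[0]["greenwood_se"] == 0.0
        assert (np.diff(tab["survival"]) <= 1e-12).all()


class TestCox:
    def test_matches_lifelines_tie_free(self):
        rng = np.random.default_rng(1)
        t, e, cov = sim_survival(rng, 150, 0.5)
        res = cox_fit(t, e, cov)
        df = cov.assign(T=t, E=e)
        ll = CoxPHFitter().fit(df, "T", "E")
        assert np.abs(res.coef - ll.params_.to_numpy()).max() < 1e-4
        assert np.abs(res.se - ll.standard_errors_.to_numpy()).max() < 1e-4

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(2)
        t, e, cov = sim_survival(rng, 120, -0.4)
        t = np.ceil(t)  # heavy ties
        res = cox_fit(t, e, cov, ties="efron")
        ll = CoxPHFitter().fit(cov.assign(T=t, E=e), "T", "E")
        assert np.abs(res.coef - ll.params_.to_numpy()).max() < 1e-4

    def test_efron_equals_breslow_tie_free(self):
        rng = np.random.default_rng(3)
        t, e, cov = sim_survival(rng, 100, 0.3)
        a = cox_fit(t, e, cov, ties="efron")
        b = cox_fit(t, e, cov, ties="breslow")
        assert np.abs(a.coef - b.coef).max() < 1e-8

    def test_centering_invariance(self):
        rng = np.random.default_rng(4)
        t, e, cov = sim_survival(rng, 100, 0.3)
        a = cox_fit(t, e, cov)
        b = cox_fit(t, e, cov + 57.0)
        assert np.abs(a.coef - b.coef).max() < 1e-10

    def test_null_recovery(self):
        """Two identical exponential arms: mean estimated HR near 1."""
        rng = np.random.default_rng(5)
        hrs = []
        for _ in range(200):
            x = rng.integers(0, 2, 200).astype(float)
            t = rng.exponential(10.0, 200)
            c = rng.uniform(0, 30, 200)
            res = cox_fit(np.minimum(t, c), (t <= c).astype(int), pd.DataFrame({"x": x}))
            hrs.append(res.hr[0])
        assert 0.93 <= np.mean(hrs) <= 1.07

    def test_coefficient_recovery_moderate_effect(self):
        rng = np.random.default_rng(6)
        betas = []
        for _ in range(50):
            t, e, cov = sim_survival(rng, 500, -0.4, censor=40.0)
            betas.append(cox_fit(t, e, cov).coef[0])
        assert abs(np.mean(betas) - (-0.4)) < 0.05

    def test_hr_ci_consistency(self):
        rng = np.random.default_rng(7)
        t, e, cov = sim_survival(rng, 100, 0.4)
        res = cox_fit(t, e, cov)
        assert np.allclose(res.hr, np.exp(res.coef))
        assert (res.ci95[:, 0] <= res.hr).all() and (res.hr <= res.ci95[:, 1]).all()
        assert res.converged

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 0, 1], pd.DataFrame({"x": [1.0] * 4}))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit([1, 2, 3], [0, 0, 0], pd.DataFrame({"x": [1.0, 2.0, 3.0]}))

    def test_separation_warns(self):
        t = np.concatenate([np.arange(1, 21), np.arange(100, 120)])
        e = np.ones(40, dtype=int)
        x = np.concatenate([np.ones(20), np.zeros(20)])
        with pytest.warns(UserWarning, match="separation"):
            cox_fit(t, e, pd.DataFrame({"x": x}), ties="breslow")

    def test_categorical_covariate_reference_coded(self):
        rng = np.random.default_rng(8)
        t, e, cov = sim_survival(rng, 90, 0.2)
        cov["stage"] = rng.choice(["I", "II", "III"], 90)
        res = cox_fit(t, e, cov)
        assert "stage_II" in res.terms and "stage_III" in res.terms
        assert "stage_I" not in res.terms

    def test_sklearn_estimator_surface(self):
        rng = np.random.default_rng(9)
        t, e, cov = sim_survival(rng, 80, 0.5)
        model = CoxPH().fit(cov, np.column_stack([t, e]))
        assert model.get_params()["ties"] == "efron"
        lp = model.predict(cov)
        assert lp.shape == (80,)
        np.testing.assert_allclose(lp, cov["x"].to_numpy() * model.coef_[0])


@pytest.fixture(scope="module")
def cohort_model():
    coh = generate(GeneratorConfig(seed=11, n_samples=123, n_genes=800))
    scores = score_all(coh.expr, {k: coh.sets[k] for k in DEFAULT_SIGNATURES})
    return coh, build_ies(scores)


class TestPrognosticReport:
    def test_empty_covariates_matches_univariate(self, cohort_model):
        coh, m = cohort_model
        rep = prognostic_report(m.ies_, m.groups_, coh.clinical, "OS", covariates=[])
        multi = rep.multivariate.summary().loc["ies"]
        uni = rep.univariate["ies"].summary().loc["ies"]
        assert multi["coef"] == pytest.approx(uni["coef"], abs=1e-10)

    def test_covariates_enter_multivariate(self, cohort_model):
        coh, m = cohort_model
        rep = prognostic_report(m.ies_, m.groups_, coh.clinical, "OS",
                                covariates=["age", "stage"])
        assert "age" in rep.multivariate.terms
        assert any(t.startswith("stage_") for t in rep.multivariate.terms)
        forest = rep.forest_table()
        assert {"hr", "q_value"} <= set(forest.columns)

    def test_protective_effect_orders_km_curves(self):
        """Strong protective hazard link: high-IES curve sits above low-IES
        at the quartiles of the event-time distribution in >=90% of seeds."""
        def stepval(tab, grid):
            idx = np.searchsorted(tab["time"].to_numpy(), grid, side="right") - 1
            return tab["survival"].to_numpy()[np.clip(idx, 0, len(tab) - 1)]

        ok = 0
        n_seeds = 50
        for seed in range(n_seeds):
            coh = generate(GeneratorConfig(seed=seed, n_samples=123, n_genes=600,
                                           delta=1.0))
            scores = score_all(coh.expr, {k: coh.sets[k] for k in DEFAULT_SIGNATURES})
            m = build_ies(scores)
            t = coh.clinical["os_time"]
            e = coh.clinical["os_event"]
            fit = km_fit(t, e, m.groups_.to_numpy())
            qs = np.quantile(t[e == 1], [0.25, 0.5, 0.75])
            if np.all(stepval(fit.tables["high"], qs) >= stepval(fit.tables["low"], qs)):
                ok += 1
        assert ok >= 0.9 * n_seeds

    def test_all_events_at_zero_rejected(self, cohort_model):
        coh, m = cohort_model
        clin = coh.clinical.copy()
        clin["os_time"] = 0.0
        clin["os_event"] = 1
        with pytest.raises(ValueError, match="degenerate"):
            prognostic_report(m.ies_, m.groups_, clin, "OS")

    def test_missing_endpoint_columns(self, cohort_model):
        coh, m = cohort_model
        with pytest.raises(ValueError, match="pfi_time"):
            prognostic_report(m.ies_, m.groups_, coh.clinical.drop(columns=["pfi_time"]), "PFI")
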