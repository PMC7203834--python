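"""Spatial AFT model: design coding, sampler correctness, DIC, transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geoaft import aft, graphs, simulate
from geoaft.aft import (
    AFTModelSpec,
    acceleration_factor,
    build_design,
    dic,
    export_frailty_field,
    fit_spatial_aft,
    summarize_posterior,
)
from geoaft.aft import _rtruncnorm_lower
from conftest import toy_cases


def _fit_recovery(grid16, n=4000, n_iter=2500, burn_in=800, seed=1,
                  error_law="lognormal", tau=4.0, sim_seed=7):
    truth = simulate.SimulationTruth(
        beta=np.array([-0.5, 0.8]), sigma=1.0, tau=tau, mu=4.0,
        target_censor_frac=0.30, seed=sim_seed, error_law=error_law)
    spec_cov = {"x1": (["a", "b"], [0.5, 0.5]), "x2": (["c", "d"], [0.5, 0.5])}
    cases, echo = simulate.simulate_registry(grid16, truth, n, covariate_spec=spec_cov)
    mspec = AFTModelSpec(covariates={"x1": "a", "x2": "c"}, error_law=error_law)
    design = build_design(cases, grid16, mspec)
    draws = fit_spatial_aft(design, grid16, mspec, n_iter=n_iter,
                            burn_in=burn_in, thin=2, seed=seed)
    return draws, echo


class TestBuildDesign:
    def test_hand_coded_dummy_table(self, grid16):
        rows = [
            {"race": "white", "insurance": "insured"},
            {"race": "black", "insurance": "insured"},
            {"race": "black", "insurance": "uninsured"},
            {"race": "asian", "insurance": "insured"},
            {"race": "white", "insurance": "uninsured"},
        ]
        spec = AFTModelSpec(covariates={"race": "white", "insurance": "insured"})
        d = build_design(toy_cases(rows), grid16, spec)
        assert d.colnames == ["race:asian", "race:black", "insurance:uninsured"]
        expected = np.array([
            [0, 0, 0],
            [0, 1, 0],
            [0, 1, 1],
            [1, 0, 0],
            [0, 0, 1],
        ], dtype=float)
        assert np.array_equal(d.X, expected)

    def test_all_reference_row_is_zero(self, grid16):
        rows = [{"race": "white"}, {"race": "black"}]
        d = build_design(toy_cases(rows), grid16,
                         AFTModelSpec(covariates={"race": "white"}))
        assert np.array_equal(d.X[0], np.zeros(1))

    def test_unknowns_removed_complete_case(self, grid16):
        rows = [{"insurance": "insured"}, {"insurance": "unknown"},
                {"insurance": "uninsured"}]
        d = build_design(toy_cases(rows), grid16,
                         AFTModelSpec(covariates={"insurance": "insured"}))
        assert d.n == 2

    def test_rank_deficiency_names_columns(self, grid16):
        rows = [{"race": "white", "ethnicity": "non_hispanic"},
                {"race": "black", "ethnicity": "hispanic"}] * 3
        spec = AFTModelSpec(covariates={"race": "white",
                                        "ethnicity": "non_hispanic"})
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(toy_cases(rows), grid16, spec)

    def test_zero_times_floored(self, grid16):
        rows = [{"followup_months": 0.0}, {"followup_months": 12.0}]
        d = build_design(toy_cases(rows), grid16, AFTModelSpec(covariates={}))
        assert d.y[0] == pytest.approx(np.log(0.5))

    def test_event_coding_other_death_censored(self, grid16):
        rows = [{"event": "pc_death"}, {"event": "other_death"},
                {"event": "censored"}]
        d = build_design(toy_cases(rows), grid16, AFTModelSpec(covariates={}))
        assert list(d.delta) == [1, 0, 0]


class TestTruncatedNormal:
    @pytest.mark.parametrize("a", [-5.0, -1.0, 0.0, 2.0, 4.0, 7.0, 12.0])
    def test_samples_exceed_threshold(self, a):
        rng = np.random.default_rng(0)
        x = _rtruncnorm_lower(np.full(4000, a), rng)
        assert (x >= a).all()
        assert np.isfinite(x).all()

    def test_deep_tail_mean(self):
        # E[X | X > a] ~ a + 1/a for large a
        rng = np.random.default_rng(1)
        x = _rtruncnorm_lower(np.full(20000, 8.0), rng)
        assert x.mean() == pytest.approx(8.0 + 1 / 8.0, abs=0.01)

    def test_body_mean_matches_closed_form(self):
        rng = np.random.default_rng(2)
        a = 1.0
        x = _rtruncnorm_lower(np.full(40000, a), rng)
        expected = stats.norm.pdf(a) / stats.norm.sf(a)
        assert x.mean() == pytest.approx(expected, abs=0.01)


class TestSamplerCorrectness:
    def test_conjugate_normal_inverse_gamma_limit(self, grid16):
        """Uncensored, intercept-only, frailty pinned to zero: the sampler's
        posterior for (mu, sigma^2) must match the closed-form
        normal-inverse-gamma posterior moments."""
        rng = np.random.default_rng(3)
        n = 400
        yv = rng.normal(3.0, 0.7, n)
        rows = [{"followup_months": float(np.exp(v)), "event": "pc_death",
                 "county_fips": f"g{i % 16:05d}"} for i, v in enumerate(yv)]
        d = build_design(toy_cases(rows), grid16, AFTModelSpec(covariates={}))
        draws = fit_spatial_aft(d, grid16, AFTModelSpec(covariates={}),
                                n_iter=22000, burn_in=2000, thin=1, seed=4,
                                fix_tau=1e10)
        ybar, ss = yv.mean(), ((yv - yv.mean()) ** 2).sum()
        a_n = 0.01 + n / 2
        b_n = 0.01 + ss / 2
        sigma2_mean = b_n / (a_n - 1)
        assert draws.mu.mean() == pytest.approx(ybar, abs=4 * 0.7 / np.sqrt(n))
        assert (draws.sigma**2).mean() == pytest.approx(sigma2_mean, rel=0.03)
        assert draws.mu.var() == pytest.approx(sigma2_mean / n, rel=0.15)

    def test_beta_recovery_within_three_posterior_sd(self, grid16):
        draws, echo = self._recovery(grid16)
        for j, truth_b in enumerate([-0.5, 0.8]):
            m, s = draws.beta[:, j].mean(), draws.beta[:, j].std()
            assert abs(m - truth_b) < 3 * s

    def test_frailty_field_rank_correlation(self, grid16):
        draws, echo = self._recovery(grid16)
        w_true = np.array([echo["frailty"][c] for c in grid16.nodes])
        rho = stats.spearmanr(w_true, draws.W.mean(axis=0)).statistic
        assert rho > 0.7

    _cache = {}

    def _recovery(self, grid16):
        if "draws" not in self._cache:
            self._cache["draws"] = _fit_recovery(grid16)
        return self._cache["draws"]

    def test_large_tau_shrinks_frailty_and_matches_nonspatial_mle(self, grid16):
        """Pinning the spatial precision very high forces W to ~0 and the
        coefficients to agree with an independent maximum-likelihood
        log-normal AFT fit (lifelines)."""
        truth = simulate.SimulationTruth(
            beta=np.array([-0.5]), sigma=1.0, tau=4.0, mu=4.0,
            frailty=np.zeros(16), target_censor_frac=0.3, seed=5)
        cases, _ = simulate.simulate_registry(
            grid16, truth, 3000, covariate_spec={"x": (["a", "b"], [0.5, 0.5])})
        mspec = AFTModelSpec(covariates={"x": "a"})
        design = build_design(cases, grid16, mspec)
        draws = fit_spatial_aft(design, grid16, mspec, n_iter=2500, burn_in=500,
                                seed=6, fix_tau=1e10)
        assert np.abs(draws.W.mean(axis=0)).max() < 0.05

        from lifelines import LogNormalAFTFitter
        df = pd.DataFrame({"t": np.maximum(cases["followup_months"], 0.5),
                           "e": (cases["event"] == "pc_death").astype(int),
                           "x": (cases["x"] == "b").astype(float)})
        lf = LogNormalAFTFitter().fit(df, "t", "e")
        mle = lf.params_[("mu_", "x")]
        se = lf.standard_errors_[("mu_", "x")]
        assert draws.beta[:, 0].mean() == pytest.approx(mle, abs=3 * se)

    def test_every_retained_frailty_draw_sums_to_zero(self, grid16):
        draws, _ = self._recovery(grid16)
        assert np.abs(draws.W.sum(axis=1)).max() < 1e-8

    def test_seeded_determinism(self, grid16):
        a, _ = _fit_recovery(grid16, n=600, n_iter=400, burn_in=100, seed=9)
        b, _ = _fit_recovery(grid16, n=600, n_iter=400, burn_in=100, seed=9)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.loglik, b.loglik)

    def test_weibull_baseline_recovers_effect_direction(self, grid16):
        draws, _ = _fit_recovery(grid16, n=1500, n_iter=1500, burn_in=600,
                                 error_law="weibull", seed=2)
        m0, s0 = draws.beta[:, 0].mean(), draws.beta[:, 0].std()
        m1 = draws.beta[:, 1].mean()
        assert abs(m0 - (-0.5)) < max(4 * s0, 0.2)
        assert m1 > 0.4


class TestSummaries:
    def _draws_from(self, grid16, beta_draws):
        rows = [{"followup_months": 10.0, "event": "pc_death"}] * 3
        d = build_design(toy_cases(rows), grid16, AFTModelSpec(covariates={}))
        n = len(beta_draws)
        return aft.PosteriorDraws(
            beta=np.asarray(beta_draws).reshape(n, 1), mu=np.zeros(n),
            W=np.zeros((n, 16)), sigma=np.ones(n), tau=np.ones(n),
            loglik=np.zeros(n), colnames=["x"], counties=grid16.nodes,
            design=d, spec=AFTModelSpec(covariates={}))

    def test_constant_draws(self, grid16):
        s = summarize_posterior(self._draws_from(grid16, np.full(200, 2.5)))
        row = s.set_index("term").loc["x"]
        assert row["mean"] == row["lower"] == row["upper"] == 2.5
        assert row["significant"]
        s0 = summarize_posterior(self._draws_from(grid16, np.zeros(200)))
        assert not s0.set_index("term").loc["x"]["significant"]

    def test_standard_normal_quantiles(self, grid16):
        rng = np.random.default_rng(7)
        s = summarize_posterior(self._draws_from(grid16, rng.standard_normal(10000)))
        row = s.set_index("term").loc["x"]
        assert row["lower"] == pytest.approx(-1.96, abs=0.05)
        assert row["upper"] == pytest.approx(1.96, abs=0.05)

    def test_interval_nesting(self, grid16):
        rng = np.random.default_rng(8)
        d = self._draws_from(grid16, rng.standard_normal(5000))
        wide = summarize_posterior(d, prob=0.95).set_index("term").loc["x"]
        narrow = summarize_posterior(d, prob=0.5).set_index("term").loc["x"]
        assert narrow["upper"] - narrow["lower"] < wide["upper"] - wide["lower"]

    def test_too_few_draws_rejected(self, grid16):
        with pytest.raises(ValueError):
            summarize_posterior(self._draws_from(grid16, np.zeros(50)))


class TestAccelerationFactor:
    def test_published_reduction_identity(self):
        r = acceleration_factor(-0.221)
        assert round(r["percent_change"]) == 20
        assert r["direction"] == "reduction"

    def test_published_increase_identity(self):
        r = acceleration_factor(1.134)
        assert round(r["factor"], 2) == 3.11
        assert r["direction"] == "increase"

    def test_zero_identity(self):
        r = acceleration_factor(0.0)
        assert r["factor"] == 1.0 and r["percent_change"] == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            acceleration_factor(float("nan"))


class TestDIC:
    def test_degenerate_posterior_pd_zero(self, grid16):
        rows = [{"followup_months": 10.0, "event": "pc_death"}] * 5
        d = build_design(toy_cases(rows), grid16, AFTModelSpec(covariates={}))
        n = 150
        from geoaft.aft import _loglik_lognormal
        ll = _loglik_lognormal(d.y, d.delta, np.full(d.n, 2.0), 1.0)
        draws = aft.PosteriorDraws(
            beta=np.empty((n, 0)), mu=np.full(n, 2.0), W=np.zeros((n, 16)),
            sigma=np.ones(n), tau=np.ones(n), loglik=np.full(n, ll),
            colnames=[], counties=grid16.nodes, design=d,
            spec=AFTModelSpec(covariates={}))
        r = dic(draws)
        assert r["pD"] == pytest.approx(0.0, abs=1e-8)
        assert r["DIC"] == pytest.approx(r["Dbar"], abs=1e-8)

    def test_informative_covariate_lowers_dic(self, grid16):
        truth = simulate.SimulationTruth(
            beta=np.array([-1.0]), sigma=0.8, tau=4.0, mu=4.0,
            target_censor_frac=0.3, seed=21)
        cases, _ = simulate.simulate_registry(
            grid16, truth, 1500, covariate_spec={"x": (["a", "b"], [0.5, 0.5])})
        d1 = build_design(cases, grid16, AFTModelSpec(covariates={"x": "a"}))
        d0 = build_design(cases, grid16, AFTModelSpec(covariates={}))
        kw = dict(n_iter=1500, burn_in=500, seed=3)
        dic1 = dic(fit_spatial_aft(d1, grid16, AFTModelSpec(covariates={"x": "a"}), **kw))
        dic0 = dic(fit_spatial_aft(d0, grid16, AFTModelSpec(covariates={}), **kw))
        assert dic1["DIC"] < dic0["DIC"] - 50


class TestFrailtyField:
    def test_field_sums_to_zero_and_classes_cover(self, grid16):
        draws, _ = _fit_recovery(grid16, n=800, n_iter=600, burn_in=200)
        field = export_frailty_field(draws, grid16)
        assert abs(field.values.sum()) < 1e-6
        assert set(field.classes.unique()) <= {1, 2, 3, 4, 5}
        assert not field.low_information.any()

    def test_county_without_cases_flagged(self, grid16):
        truth = simulate.SimulationTruth(
            beta=np.array([0.0]), sigma=1.0, tau=4.0, mu=4.0,
            target_censor_frac=0.3, seed=2)
        weights = {c: 1.0 for c in grid16.nodes}
        weights["g00000"] = 0.0
        cases, _ = simulate.simulate_registry(
            grid16, truth, 400,
            covariate_spec={"x": (["a", "b"], [0.5, 0.5])},
            county_weights=weights)
        d = build_design(cases, grid16, AFTModelSpec(covariates={}))
        draws = fit_spatial_aft(d, grid16, AFTModelSpec(covariates={}),
                                n_iter=400, burn_in=100, seed=1)
        field = export_frailty_field(draws, grid16)
        assert field.low_information["g00000"]
        assert np.isfinite(field.values["g00000"])


def test_fit_rejects_bad_iteration_counts(grid16):
    rows = [{"followup_months": 10.0, "event": "pc_death"}] * 3
    d = build_design(toy_cases(rows), grid16, AFTModelSpec(covariates={}))
    with pytest.raises(ValueError):
        fit_spatial_aft(d, grid16, AFTModelSpec(covariates={}), n_iter=100,
                        burn_in=100)
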