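"""Hierarchical model: densities, sampler contracts, shrinkage, recovery."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit, logit
from scipy.stats import norm, t as student_t

import maihda as m
from maihda.model import DegenerateOutcomeError, _log_half_t
from maihda.survey import ValidationError


@pytest.fixture(scope="module")
def small_model():
    scheme = m.stress_scheme((2, 2, 2))
    prev = {f.name: (0.5, 0.5) for f in scheme.factors}
    truth = m.SimulationTruth(
        scheme=scheme, factor_prevalences=prev, intercept=-0.3,
        main_effects={("f1", "c1"): 0.4}, sigma_u=0.4, n=200, seed=30,
    )
    ds, _ = m.simulate_survey(truth)
    return m.MAIHDAModel(ds, "hu_within", tier="model2_main")


class TestLinearPredictor:
    def test_all_zero_parameters(self, small_model):
        rec = small_model.frame.iloc[0]
        p = len(small_model.fixed_effect_names)
        eta = small_model.linear_predictor(rec, beta0=0.0, beta=np.zeros(p), u_value=0.0)
        assert eta == 0.0
        assert expit(eta) == 0.5

    def test_additivity_null_model(self, small_model):
        rec = small_model.frame.iloc[0]
        eta = small_model.linear_predictor(rec, beta0=-0.5, beta=np.zeros(
            len(small_model.fixed_effect_names)), u_value=0.5)
        assert eta == pytest.approx(0.0)

    def test_reference_record_gets_no_dummy(self, small_model):
        rec = {name: small_model.scheme[name].reference for name in small_model.scheme.names}
        beta = {n: 5.0 for n in small_model.fixed_effect_names}
        eta = small_model.linear_predictor(rec, beta0=1.25, beta=beta, u_value=0.5)
        assert eta == pytest.approx(1.75)

    def test_unknown_stratum_raises(self):
        """A record whose (valid) combination was never observed has no
        stratum effect; looking one up is an error, not a silent zero."""
        truth = m.stress_truth(sigma_u=0.0, n=40, seed=44)
        ds, _ = m.simulate_survey(truth)
        for f in ds.scheme.factors:  # collapse everything onto one combination
            ds.frame[f.name] = f.categories[0]
        model = m.MAIHDAModel(ds, "hu_within", tier="model1_null")
        unobserved = {name: ds.scheme[name].categories[1] for name in ds.scheme.names}
        with pytest.raises(KeyError):
            model.linear_predictor(unobserved, beta0=0.0, beta=np.zeros(0),
                                   u=np.zeros(model.n_strata))


class TestLogPrior:
    def test_matches_scipy_composition(self, small_model):
        """Dual route: our closed-form prior equals the scipy density sum."""
        beta0, sigma = 0.3, 1.7
        beta = np.array([0.5, -0.2, 0.1])[: len(small_model.fixed_effect_names)]
        beta = np.resize(beta, len(small_model.fixed_effect_names))
        u = np.linspace(-1, 1, small_model.n_strata)
        got = small_model.log_prior(beta0, beta, sigma, u)
        pr = small_model.spec.priors
        expected = (
            norm.logpdf(beta0) + norm.logpdf(beta).sum()
            + math.log(2.0) + student_t.logpdf(sigma, pr.sigma_df, scale=pr.sigma_scale)
            + norm.logpdf(u, scale=sigma).sum()
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_standard_normal_mode_contribution(self, small_model):
        p = len(small_model.fixed_effect_names)
        base = small_model.log_prior(0.0, np.zeros(p), 1.0, np.zeros(0)[:0])
        # moving one fixed effect from its mode changes the prior by the
        # standard-normal log-density difference
        shifted = np.zeros(p)
        shifted[0] = 1.0
        diff = small_model.log_prior(0.0, shifted, 1.0, np.zeros(0)[:0]) - base
        assert diff == pytest.approx(norm.logpdf(1.0) - norm.logpdf(0.0))
        # and the per-effect mode contribution is -0.5*log(2*pi)
        assert norm.logpdf(0.0) == pytest.approx(-0.9189385332046727)

    def test_symmetry_in_beta(self, small_model):
        p = len(small_model.fixed_effect_names)
        beta = np.full(p, 0.7)
        u = np.zeros(small_model.n_strata)
        assert small_model.log_prior(0.4, beta, 0.9, u) == pytest.approx(
            small_model.log_prior(-0.4, -beta, 0.9, u))

    def test_nonpositive_sigma_rejected(self, small_model):
        p = len(small_model.fixed_effect_names)
        assert small_model.log_prior(0.0, np.zeros(p), 0.0,
                                     np.zeros(small_model.n_strata)) == -math.inf

    def test_half_t_density_normalised(self):
        """Quadrature oracle: the half-t density integrates to 1 on (0, inf)."""
        total, _ = quad(lambda x: math.exp(_log_half_t(x, 2.0, 10.0)), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)
        # spot value at sigma = scale
        expected = math.log(2.0) + student_t.logpdf(10.0, 2.0, scale=10.0)
        assert _log_half_t(10.0, 2.0, 10.0) == pytest.approx(expected)


def test_loglike_matches_per_record_loop(small_model):
    """Aggregated binomial likelihood equals the naive Bernoulli sum."""
    rng = np.random.default_rng(0)
    beta0 = -0.2
    beta = 0.3 * rng.standard_normal(len(small_model.fixed_effect_names))
    u = 0.5 * rng.standard_normal(small_model.n_strata)
    fast = small_model.loglike(beta0, beta, u)
    slow = small_model.loglike_records(beta0, beta, u)
    assert fast == pytest.approx(slow, rel=1e-10)


def test_retained_draw_accounting(small_fit):
    cfg = small_fit.config
    assert small_fit.n_retained == cfg.chains * (cfg.iterations - cfg.burn_in)
    assert small_fit.draws.shape == (
        cfg.chains, cfg.iterations - cfg.burn_in, len(small_fit.param_names))


def test_fit_deterministic_under_seed(small_model):
    cfg = m.McmcConfig(chains=2, iterations=300, burn_in=100, seed=77)
    r1 = small_model.fit(cfg, check_convergence=False)
    r2 = small_model.fit(cfg, check_convergence=False)
    np.testing.assert_array_equal(r1.draws, r2.draws)


def test_record_permutation_leaves_posterior_unchanged():
    """Canonical aggregation makes the fit exactly order-independent."""
    truth = m.stress_truth(sigma_u=0.3, n=400, seed=31)
    ds, _ = m.simulate_survey(truth)
    shuffled = ds.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
    ds2 = m.SurveyDataset(shuffled, ds.scheme, {})
    cfg = m.McmcConfig(chains=2, iterations=300, burn_in=100, seed=5)
    r1 = m.MAIHDAModel(ds, "hu_within", tier="model1_null").fit(cfg, check_convergence=False)
    r2 = m.MAIHDAModel(ds2, "hu_within", tier="model1_null").fit(cfg, check_convergence=False)
    np.testing.assert_array_equal(r1.draws, r2.draws)


def test_degenerate_outcome_raises():
    truth = m.stress_truth(sigma_u=0.0, n=60, seed=32)
    ds, _ = m.simulate_survey(truth)
    ds.frame["hu_within"] = 1
    with pytest.raises(DegenerateOutcomeError):
        m.MAIHDAModel(ds, "hu_within", tier="model1_null")


def test_model1_has_intercept_only(stress_fit_m1):
    assert stress_fit_m1.fixed_effect_names == []
    assert stress_fit_m1.param_names[0] == "intercept"
    assert stress_fit_m1.param_names[1] == "sigma_u"


def test_sigma_draws_positive(stress_fit_m1, stress_fit_m2):
    for fit in (stress_fit_m1, stress_fit_m2):
        assert (fit.sigma_draws > 0).all()
        assert np.isfinite(fit.draws).all()


def test_shrinkage_toward_grand_mean(stress_fit_m1, stress_dataset):
    """Posterior-mean stratum effects lie between zero and the raw empirical
    log-odds deviation for well-populated strata (partial pooling)."""
    _, dataset, _ = stress_dataset
    model = stress_fit_m1.model
    y = model.frame["hu_within"].to_numpy(dtype=float)
    grand = logit(y.mean())
    checked = 0
    for _, row in model.strata.table.iterrows():
        n_j = row["n_households"]
        if n_j < 50:
            continue
        sel = model.strata.assignments.to_numpy() == row["stratum_id"]
        p_j = y[sel].mean()
        if p_j in (0.0, 1.0):
            continue
        d_j = logit(p_j) - grand
        u_j = float(stress_fit_m1.get(f"u[{row['stratum_id']}]").mean())
        if abs(d_j) < 0.2:
            continue
        assert abs(u_j) <= abs(d_j) + 0.1
        assert np.sign(u_j) == np.sign(d_j)
        checked += 1
    assert checked >= 10


def test_fixture_diagnostics_meet_thresholds(stress_fit_m2):
    """Test-scale fits of the stress fixture satisfy the convergence bar:
    Rhat < 1.01 and bulk/tail ESS >= 1000 for every parameter."""
    report = stress_fit_m2.diagnostics()
    assert report.passed, str(report)
    assert stress_fit_m2.warnings == []


def test_sigma_recovery_single_fit(stress_fit_m2, stress_dataset):
    truth, _, _ = stress_dataset
    lo, hi = stress_fit_m2.credible_interval("sigma_u")
    assert lo < truth.sigma_u < hi


def test_nonconvergence_recorded_not_silent(small_model):
    """An absurdly short run leaves a convergence warning on the result."""
    cfg = m.McmcConfig(chains=2, iterations=30, burn_in=10, seed=123)
    fit = small_model.fit(cfg)
    assert any("Rhat" in w or "divergent" in w for w in fit.warnings)


def test_covariates_only_for_model3():
    truth = m.default_truth(n=300, seed=33)
    ds, _ = m.simulate_survey(truth)
    with pytest.raises(ValidationError):
        m.MAIHDAModel(ds, "hu_within", tier="model2_main", covariates=["tenure"])


def test_summary_has_expected_columns(small_fit):
    s = small_fit.summary()
    assert {"parameter", "median", "ci95_lo", "ci95_hi", "rhat", "ess_bulk"} <= set(s.columns)
    assert (s["ci95_lo"] <= s["median"]).all() and (s["median"] <= s["ci95_hi"]).all()


def test_caterpillar_plot_export(tmp_path, small_fit):
    """The caterpillar plot renders and saves without a display."""
    out = tmp_path / "caterpillar.png"
    small_fit.plot_caterpillar(path=out)
    assert out.exists() and out.stat().st_size > 0
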