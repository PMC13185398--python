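"""VPC/PCV arithmetic, OR summaries, residual ranking and the joint report."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import maihda as m
from maihda.metrics import LOGISTIC_LEVEL1_VARIANCE, metrics_report, or_summary
from maihda.survey import ValidationError
from oracles import sorted_quantiles


class TestVpcLatent:
    def test_zero_variance(self):
        assert m.vpc_latent(0.0) == 0.0

    def test_symmetry_point(self):
        assert m.vpc_latent(LOGISTIC_LEVEL1_VARIANCE) == pytest.approx(0.5)

    def test_printed_null_model_value(self):
        # 0.73 / (0.73 + pi^2/3)
        assert m.vpc_latent(0.73) == pytest.approx(0.18158, abs=5e-5)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            m.vpc_latent(-0.01)

    def test_vectorised(self):
        out = m.vpc_latent(np.array([0.0, 0.73]))
        assert out.shape == (2,)
        assert out[0] == 0.0

    @given(st.floats(min_value=0.0, max_value=50.0),
           st.floats(min_value=1e-6, max_value=5.0))
    def test_strictly_increasing_and_bounded(self, s2, step):
        lo, hi = m.vpc_latent(s2), m.vpc_latent(s2 + step)
        assert 0.0 <= lo < hi < 1.0


class TestPcv:
    def test_printed_value(self):
        assert 100 * m.pcv(0.73, 0.18) == pytest.approx(75.342, abs=1e-2)

    @given(st.floats(min_value=1e-6, max_value=100.0))
    def test_self_comparison_zero(self, v):
        assert m.pcv(v, v) == 0.0

    @given(st.floats(min_value=1e-6, max_value=100.0))
    def test_full_explanation_one(self, v):
        assert m.pcv(v, 0.0) == 1.0

    def test_negative_when_variance_grows(self):
        assert m.pcv(0.5, 0.75) == pytest.approx(-0.5)

    def test_invalid_reference(self):
        with pytest.raises(ValidationError):
            m.pcv(0.0, 0.1)


class _StubModel:
    def __init__(self, tier, outcome, strata, scheme):
        self.spec = type("S", (), {"tier": tier, "outcome": outcome})()
        self.strata = strata
        self.scheme = scheme
        self.n_strata = strata.n_observed


class _StubResults:
    """Minimal posterior container for exact-value metric tests."""

    def __init__(self, draws_by_name, fixed_names, strata=None, scheme=None,
                 tier="model1_null", outcome="hu_within"):
        self._d = {k: np.asarray(v, dtype=float) for k, v in draws_by_name.items()}
        self.fixed_effect_names = fixed_names
        if strata is not None:
            self.model = _StubModel(tier, outcome, strata, scheme)

    def get(self, name):
        return self._d[name]

    @property
    def sigma_draws(self):
        return self._d["sigma_u"]

    @property
    def u_draws(self):
        return self._d["u"]

    def posterior_median(self, name):
        return float(np.median(self._d[name]))


def _stub_strata(n=3):
    scheme = m.stress_scheme((2, 2))
    combos = list(scheme.combinations())[:n]
    rows = []
    for i, c in enumerate(combos):
        row = {"stratum_id": i + 1, "n_households": 10 * (i + 1)}
        row.update(dict(zip(scheme.names, c)))
        rows.append(row)
    return m.StratumTable(pd.DataFrame(rows), scheme, pd.Series(dtype=int)), scheme


class TestOrSummary:
    def test_constant_draws(self):
        res = _StubResults(
            {"intercept": np.full(100, 0.0), "b": np.full(100, math.log(2.0))}, ["b"])
        table = or_summary(res).set_index("parameter")
        assert table.loc["b", "or_median"] == pytest.approx(2.0)
        assert table.loc["b", "or_lo95"] == pytest.approx(2.0)
        assert table.loc["b", "or_hi95"] == pytest.approx(2.0)
        assert not table.loc["intercept", "significant"]

    def test_symmetric_draws_median_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20_001)
        draws = np.concatenate([x, -x, [0.0]])  # exactly symmetric, odd count
        res = _StubResults({"intercept": draws, "b": draws}, ["b"])
        table = or_summary(res).set_index("parameter")
        assert table.loc["b", "or_median"] == pytest.approx(1.0, abs=1e-12)

    def test_quantiles_match_sort_oracle(self):
        rng = np.random.default_rng(2)
        draws = rng.gamma(2.0, 1.0, size=1000) - 1.0
        res = _StubResults({"intercept": draws, "b": draws}, ["b"])
        table = or_summary(res).set_index("parameter")
        lo, med, hi = sorted_quantiles(np.exp(draws), [0.025, 0.5, 0.975])
        assert table.loc["b", "or_lo95"] == pytest.approx(lo)
        assert table.loc["b", "or_median"] == pytest.approx(med)
        assert table.loc["b", "or_hi95"] == pytest.approx(hi)


class TestStratumResiduals:
    def test_all_zero_draws(self):
        strata, scheme = _stub_strata()
        res = _StubResults(
            {"intercept": np.zeros(50), "sigma_u": np.full(50, 0.1),
             "u": np.zeros((50, 3))},
            [], strata=strata, scheme=scheme)
        out = m.stratum_residuals(res)
        assert (out["median"] == 0.0).all()
        assert not out["significant"].any()
        assert sorted(out["rank"]) == [1, 2, 3]
        # ties in median are broken by stratum id
        assert out.sort_values("rank")["stratum_id"].tolist() == [1, 2, 3]

    def test_ranking_and_flags(self):
        strata, scheme = _stub_strata()
        rng = np.random.default_rng(3)
        u = np.column_stack([
            rng.normal(-1.0, 0.05, 400),
            rng.normal(0.0, 0.05, 400),
            rng.normal(1.0, 0.05, 400),
        ])
        res = _StubResults(
            {"intercept": np.zeros(400), "sigma_u": np.full(400, 1.0), "u": u},
            [], strata=strata, scheme=scheme)
        out = m.stratum_residuals(res).set_index("stratum_id")
        assert out.loc[1, "rank"] == 1 and out.loc[3, "rank"] == 3
        assert out.loc[1, "significant"] and out.loc[3, "significant"]
        assert not out.loc[2, "significant"]
        assert (out["lo95"] <= out["median"]).all()
        assert (out["median"] <= out["hi95"]).all()
        # predicted probability at reference covariates is logistic(b0 + u)
        assert out.loc[2, "pred_prob"] == pytest.approx(0.5, abs=0.01)


def _const_sigma_results(var, tier, strata, scheme, outcome="hu_within"):
    sigma = math.sqrt(var)
    return _StubResults(
        {"intercept": np.zeros(10), "sigma_u": np.full(10, sigma),
         "u": np.zeros((10, strata.n_observed))},
        [], strata=strata, scheme=scheme, tier=tier, outcome=outcome)


class TestMetricsReport:
    def test_printed_table_values(self):
        """Variances 0.73/0.18/0.13 reproduce the printed VPC and PCV rows
        up to the 2-dp rounding of the inputs."""
        strata, scheme = _stub_strata()
        r1 = _const_sigma_results(0.73, "model1_null", strata, scheme)
        r2 = _const_sigma_results(0.18, "model2_main", strata, scheme)
        r3 = _const_sigma_results(0.13, "model3_adjusted", strata, scheme)
        report = metrics_report(r1, r2, r3)
        t = report.variance_table.set_index("tier")
        assert t.loc["model1_null", "vpc_pct"] == pytest.approx(18.16, abs=0.05)
        assert t.loc["model2_main", "vpc_pct"] == pytest.approx(5.19, abs=0.05)
        assert t.loc["model3_adjusted", "vpc_pct"] == pytest.approx(3.80, abs=0.05)
        assert t.loc["model2_main", "pcv_pct"] == pytest.approx(75.34, abs=0.05)
        assert t.loc["model3_adjusted", "pcv_pct"] == pytest.approx(82.19, abs=0.05)
        assert math.isnan(t.loc["model1_null", "pcv_pct"])

    def test_identical_models_give_zero_pcv(self):
        strata, scheme = _stub_strata()
        r1 = _const_sigma_results(0.4, "model1_null", strata, scheme)
        r2 = _const_sigma_results(0.4, "model2_main", strata, scheme)
        report = metrics_report(r1, r2)
        assert report.variance_table.set_index("tier").loc["model2_main", "pcv"] == 0.0

    def test_vpc_method_consistency(self):
        """The VPC-difference variant gives a smaller PCV than the variance
        variant whenever variance shrinks (denominator includes pi^2/3)."""
        strata, scheme = _stub_strata()
        r1 = _const_sigma_results(0.73, "model1_null", strata, scheme)
        r2 = _const_sigma_results(0.18, "model2_main", strata, scheme)
        a = metrics_report(r1, r2, method="variance").variance_table
        b = metrics_report(r1, r2, method="vpc").variance_table
        assert b.set_index("tier").loc["model2_main", "pcv"] < \
               a.set_index("tier").loc["model2_main", "pcv"]

    def test_mismatched_outcome_rejected(self):
        strata, scheme = _stub_strata()
        r1 = _const_sigma_results(0.4, "model1_null", strata, scheme)
        r2 = _const_sigma_results(0.3, "model2_main", strata, scheme, outcome="hu_outside")
        with pytest.raises(ValidationError):
            metrics_report(r1, r2)

    def test_point_and_perdraw_vpc_agree_on_fit(self, stress_fit_m2):
        row = metrics_report(stress_fit_m2, stress_fit_m2).variance_table.iloc[0]
        assert row["vpc"] == pytest.approx(row["vpc_draw_median"], rel=0.10)


def test_serialisation_roundtrip(tmp_path, small_fit):
    """Draws persisted to the flat CSV reload to the identical array."""
    path = tmp_path / "draws.csv"
    small_fit.to_csv(path)
    arr, names = m.MAIHDAResults.draws_from_csv(path)
    assert names == small_fit.param_names
    np.testing.assert_allclose(arr, small_fit.draws, rtol=0, atol=1e-12)


def test_residuals_on_real_fit(small_fit):
    out = small_fit.stratum_residuals()
    assert sorted(out["rank"]) == list(range(1, small_fit.model.n_strata + 1))
    assert (out["significant"] == ((out["hi95"] < 0) | (out["lo95"] > 0))).all()


def test_null_flag_rate_is_modest():
    """Without injections, flagged strata are the minority: the marginal
    flag rate over well-populated strata stays well below one third."""
    from maihda.experiments import null_flag_rate

    df = null_flag_rate(n_replicates=3, seed=104)
    assert df["flag_rate"].mean() < 0.30
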