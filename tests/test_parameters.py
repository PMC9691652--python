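"""Input validation, cost-derivation arithmetic and uncertainty distributions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teer_cea.parameters import (
    ParameterError,
    convert_currency,
    default_parameters,
    derive_distribution,
    get_path,
    inflate_cpi,
    load_parameters,
    monthly_from_annual,
    set_path,
    to_document,
    weighted_mean,
    write_parameters,
)

CPI_2018_2021 = [1.043, 1.024, 1.018, 1.004]


@pytest.mark.parametrize(
    "values, weights, expected",
    [
        # pooled monthly OMT drug cost across two source sub-cohorts (USD)
        ([679, 711.1], [14.5, 19.2], 697.29),
        ([42], [3], 42.0),
        # pooled HF-hospitalization cost across two source sub-cohorts (USD)
        ([1218.4, 1646.8], [18.35, 29.6], 1482.8555),
    ],
)
def test_weighted_mean(values, weights, expected):
    assert weighted_mean(values, weights) == pytest.approx(expected, abs=0.01)


@pytest.mark.parametrize(
    "values, weights",
    [([], []), ([1.0, 2.0], [0.0, 0.0]), ([1.0], [1.0, 2.0])],
)
def test_weighted_mean_invalid(values, weights):
    with pytest.raises(ParameterError):
        weighted_mean(values, weights)


def test_inflate_cpi_edge_cases():
    assert inflate_cpi(100, []) == 100
    assert inflate_cpi(100, [1.05]) == pytest.approx(105)
    with pytest.raises(ParameterError):
        inflate_cpi(-1, [1.05])


def test_annual_omt_cost_derivation():
    """Pooled USD cost -> CNY at the source-era rate -> CPI-inflated to 2021."""
    pooled_usd = weighted_mean([679, 711.1], [29 / 2, 19.2])
    annual_cny = inflate_cpi(pooled_usd * 6.75, CPI_2018_2021)
    assert round(annual_cny) == 5138
    assert monthly_from_annual(annual_cny) == pytest.approx(428, abs=0.5)


def test_hf_hospitalization_cost_derivation():
    pooled_usd = weighted_mean([1218.4, 1646.8], [36.7 / 2, 29.6])
    assert round(inflate_cpi(pooled_usd * 6.75, CPI_2018_2021)) == 10926


@given(st.permutations(CPI_2018_2021))
def test_inflate_cpi_commutative(factors):
    baseline = inflate_cpi(4706.71, CPI_2018_2021)
    assert inflate_cpi(4706.71, factors) == pytest.approx(baseline, rel=1e-9)


def test_convert_currency():
    assert round(convert_currency(322_000, 6.45)) == 49_922
    assert convert_currency(0, 6.45) == 0
    # the published USD/QALY figure is reproduced to within 1 USD
    assert abs(convert_currency(754_410, 6.45) - 116_963) <= 1
    with pytest.raises(ParameterError):
        convert_currency(100, 0)


def test_monthly_utility_from_annual():
    assert round(monthly_from_annual(0.780), 3) == 0.065


class TestDeriveDistribution:
    def test_gamma_moment_matching(self):
        spec = derive_distribution("device", "gamma", 322_000, 161_000, 386_400)
        assert spec.sd == pytest.approx(57_500, rel=1e-3)
        assert spec.gamma_shape == pytest.approx(31.36, rel=1e-3)
        assert spec.gamma_rate == pytest.approx(9.74e-5, rel=1e-2)

    def test_beta_moment_matching(self):
        spec = derive_distribution("u_nyha1", "beta", 0.065, 0.062, 0.068)
        assert spec.sd == pytest.approx(0.001531, rel=1e-3)
        a, b = spec.beta_ab
        # fitted beta reproduces the requested mean and variance
        assert a / (a + b) == pytest.approx(0.065, rel=1e-9)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx(spec.sd**2, rel=1e-9)

    def test_degenerate_is_fixed(self):
        spec = derive_distribution("x", "gamma", 5, 5, 5)
        assert spec.family == "fixed"
        assert spec.sample(np.random.default_rng(0)) == 5

    @pytest.mark.parametrize(
        "family, base, low, high",
        [
            ("beta", 1.5, 0.5, 2.0),  # base outside (0,1)
            ("beta", 0.01, 0.0, 1.0),  # implied variance >= base*(1-base)
            ("gamma", 5.0, 6.0, 7.0),  # bounds do not bracket base
        ],
    )
    def test_invalid_requests(self, family, base, low, high):
        with pytest.raises(ParameterError):
            derive_distribution("x", family, base, low, high)

    @pytest.mark.parametrize(
        "name",
        ["costs.device", "costs.omt_monthly", "utilities.nyha3",
         "utilities.disutility_hf_hospitalization"],
    )
    def test_sampling_recovers_base(self, params, name):
        """Monte Carlo mean of 1e5 draws sits within 3 standard errors of base."""
        spec = params.uncertainty[name]
        draws = spec.sample(np.random.default_rng(12345), 100_000)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - spec.base) < 3 * se


class TestLoadParameters:
    def test_default_loads_and_derives(self, params):
        assert params.model.n_cycles == 336
        assert params.econ.wtp == pytest.approx(242_928)
        assert params.costs.one_time_total == pytest.approx(395_659)

    def test_round_trip(self, tmp_path, params):
        path = write_parameters(params, tmp_path / "config.yaml")
        assert load_parameters(path) == params

    def test_transition_row_not_stochastic(self, document):
        document["transitions"]["matrices"]["mitraclip"]["nyha3"] = [
            0.0, 0.025, 0.885, 0.070, 0.010]  # sums to 0.99
        with pytest.raises(ParameterError, match="nyha3"):
            load_parameters(document)

    def test_missing_cost_key(self, document):
        del document["costs"]["hf_hospitalization"]
        with pytest.raises(ParameterError, match="hf_hospitalization"):
            load_parameters(document)

    def test_probability_outside_unit_interval(self, document):
        document["transitions"]["hospitalization"]["omt"]["nyha4"] = 1.2
        with pytest.raises(ParameterError, match="nyha4"):
            load_parameters(document)

    def test_negative_cost(self, document):
        document["costs"]["device"] = -1.0
        with pytest.raises(ParameterError, match="device"):
            load_parameters(document)

    def test_utility_ordering_enforced(self, document):
        document["utilities"]["nyha4"] = 0.07  # above NYHA III
        with pytest.raises(ParameterError):
            load_parameters(document)

    def test_unknown_uncertainty_name_rejected(self, document):
        document["uncertainty"]["costs.nonexistent"] = {
            "family": "gamma", "base": 1.0, "low": 0.5, "high": 2.0}
        with pytest.raises(ParameterError, match="nonexistent"):
            load_parameters(document)


def test_path_access(params):
    assert get_path(params, "costs.device") == 322_000
    changed = set_path(params, "costs.device", 100.0)
    assert get_path(changed, "costs.device") == 100.0
    assert get_path(params, "costs.device") == 322_000  # original untouched


def test_default_utilities_nyha1_equals_nyha2(params):
    # the published monthly utilities for NYHA I and II are both 0.065
    assert params.utilities.nyha1 == params.utilities.nyha2 == 0.065
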