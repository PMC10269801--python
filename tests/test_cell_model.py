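"""Carbon-budget arithmetic: quotas, cost factors, growth, fate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfm_diatom.cell_model import (
    PG_C_TO_MOL_C,
    CarbonBudget,
    CellParameters,
    TaxonGroup,
    carbon_fate,
    carbon_quota,
    growth_rate,
    silica_cost_factor,
    silica_fraction_of_cost,
    total_cost_factor,
)

DIATOM = CellParameters(group="diatom", a_c=10**-0.933, b_c=0.881, r_sic=0.163)


class TestCarbonQuota:
    def test_unit_volume_returns_converted_prefactor(self, diatom):
        assert carbon_quota(1.0, diatom) == pytest.approx(diatom.a_c * PG_C_TO_MOL_C)

    def test_linear_when_exponent_is_one(self):
        p = CellParameters(group="other", a_c=0.2, b_c=1.0)
        assert carbon_quota(14.0, p) == pytest.approx(2 * carbon_quota(7.0, p), rel=1e-15)

    def test_log_space_power_law(self, diatom):
        # oracle: evaluate the power law in log10 space
        expected = 10 ** (math.log10(diatom.a_c * PG_C_TO_MOL_C) + 3 * diatom.b_c)
        assert carbon_quota(1e3, diatom) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=1e7))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_and_density_decreasing(self, v):
        p = DIATOM  # b_c < 1
        assert carbon_quota(2 * v, p) > carbon_quota(v, p)
        assert carbon_quota(2 * v, p) / (2 * v) < carbon_quota(v, p) / v

    @pytest.mark.parametrize("v", [0.0, -1.0])
    def test_rejects_non_positive_volume(self, v, diatom):
        with pytest.raises(ValueError):
            carbon_quota(v, diatom)


class TestCostFactors:
    def test_silica_cost_is_product_of_cost_per_si_and_ratio(self, diatom):
        assert silica_cost_factor(diatom) == pytest.approx(0.167 * 0.163, rel=1e-12)

    def test_no_silica_no_cost(self, other):
        assert silica_cost_factor(other) == 0.0

    def test_counterfactual_prices_silica_as_biomass(self, diatom_no_si):
        assert silica_cost_factor(diatom_no_si) == pytest.approx(1.691 * 0.163, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(group="other", a_c=0.2, b_c=0.9, e_mu=0.691), 1.691),
            (dict(group="diatom", a_c=0.1, b_c=0.9, r_sic=0.163), 1.0 + 0.691 + 0.167 * 0.163),
            (dict(group="other", a_c=0.2, b_c=0.9, e_mu=0.0), 1.0),
        ],
    )
    def test_total_cost_factor(self, kwargs, expected):
        assert total_cost_factor(CellParameters(**kwargs)) == pytest.approx(expected, rel=1e-12)

    def test_excretion_adds_to_cost(self, diatom):
        from dataclasses import replace

        leaky = replace(diatom, e_ex=0.1)
        assert total_cost_factor(leaky) == pytest.approx(total_cost_factor(diatom) + 0.1)


class TestSilicaFraction:
    def test_default_share_is_about_1_6_percent(self, diatom):
        frac = silica_fraction_of_cost(diatom)
        assert frac == pytest.approx(0.167 * 0.163 / (1.691 + 0.167 * 0.163), rel=1e-12)
        assert frac == pytest.approx(0.0158, abs=5e-5)

    def test_zero_without_silica(self):
        p = CellParameters(group="diatom", a_c=0.1, b_c=0.9, r_sic=0.0)
        assert silica_fraction_of_cost(p) == 0.0

    def test_doubled_si_content(self):
        p = CellParameters(group="diatom", a_c=0.1, b_c=0.9, r_sic=0.326)
        expected = (0.167 * 0.326) / (1.691 + 0.167 * 0.326)
        assert silica_fraction_of_cost(p) == pytest.approx(expected, rel=1e-12)
        assert silica_fraction_of_cost(p) == pytest.approx(0.03119, rel=1e-3)

    @pytest.mark.parametrize("group", ["other", "diatom_no_si"])
    def test_undefined_for_non_diatoms(self, group):
        p = CellParameters(group=group, a_c=0.1, b_c=0.9, r_sic=0.163 if group != "other" else 0.0)
        with pytest.raises(ValueError):
            silica_fraction_of_cost(p)


class TestGrowthRate:
    def test_zero_photosynthesis_means_no_growth(self, diatom):
        assert growth_rate(0.0, 50.0, diatom) == 0.0

    def test_inverse_construction_gives_unit_rate(self, diatom):
        v = 123.0
        f = carbon_quota(v, diatom) * total_cost_factor(diatom)
        assert growth_rate(f, v, diatom) == pytest.approx(1.0, rel=1e-15)

    def test_counterfactual_rate_ratio_is_cost_ratio(self, diatom, diatom_no_si):
        f, v = 1e-12, 500.0
        ratio = growth_rate(f, v, diatom_no_si) / growth_rate(f, v, diatom)
        assert ratio == pytest.approx(1.718221 / 1.966633, rel=1e-6)

    def test_rejects_negative_photosynthesis(self, diatom):
        with pytest.raises(ValueError):
            growth_rate(-1e-15, 10.0, diatom)

    @given(
        e_mu=st.floats(0.0, 2.0),
        e_si=st.floats(0.0, 2.0),
        r_sic=st.floats(0.0, 0.5),
        e_ex=st.floats(0.0, 0.5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_each_cost_term_depresses_growth(self, e_mu, e_si, r_sic, e_ex):
        base = CellParameters(
            group="diatom", a_c=0.1, b_c=0.9, e_mu=e_mu,
            e_si_per_si=e_si, r_sic=r_sic, e_ex=e_ex,
        )
        f, v = 1e-13, 100.0
        mu = growth_rate(f, v, base)
        from dataclasses import replace

        for bump in (
            replace(base, e_mu=e_mu + 0.1),
            replace(base, e_si_per_si=e_si + 0.1, r_sic=max(r_sic, 0.01)),
            replace(base, r_sic=r_sic + 0.1, e_si_per_si=max(e_si, 0.01)),
            replace(base, e_ex=e_ex + 0.1),
        ):
            assert growth_rate(f, v, bump) < mu


class TestCarbonFate:
    def test_no_growth_no_fluxes(self, diatom):
        fate = carbon_fate(0.0, 100.0, diatom)
        assert fate.f_pho == 0.0
        assert fate.flux_biosynthesis == fate.flux_respiration == 0.0
        assert fate.flux_silica_cost == fate.flux_excretion == 0.0

    def test_fluxes_linear_in_growth_rate(self, diatom):
        half = carbon_fate(0.5, 100.0, diatom)
        full = carbon_fate(1.0, 100.0, diatom)
        for name in ("flux_biosynthesis", "flux_respiration", "flux_silica_cost", "f_pho"):
            assert getattr(full, name) == pytest.approx(2 * getattr(half, name), rel=1e-15)

    def test_silica_share_of_total_flux(self, diatom):
        fate = carbon_fate(0.7, 300.0, diatom)
        share = fate.flux_silica_cost / fate.f_pho
        assert share == pytest.approx(silica_fraction_of_cost(diatom), rel=1e-12)

    def test_rejects_negative_growth(self, diatom):
        with pytest.raises(ValueError):
            carbon_fate(-0.1, 100.0, diatom)

    @given(
        v=st.floats(0.5, 1e8),
        f=st.floats(1e-16, 1e-8),
        e_mu=st.floats(0.0, 2.0),
        r_sic=st.floats(0.0, 0.5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_steady_state_closure(self, v, f, e_mu, r_sic):
        """growth_rate then carbon_fate reproduces the photosynthesis
        rate that generated the growth rate (steady-state budget)."""
        p = CellParameters(group="diatom", a_c=0.12, b_c=0.88, e_mu=e_mu, r_sic=r_sic)
        fate = carbon_fate(growth_rate(f, v, p), v, p)
        assert fate.f_pho == pytest.approx(f, rel=1e-12)


def test_other_group_must_have_zero_si():
    with pytest.raises(ValueError):
        CellParameters(group="other", a_c=0.2, b_c=0.9, r_sic=0.1)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(a_c=-0.1, b_c=0.9),
        dict(a_c=0.1, b_c=2.5),
        dict(a_c=0.1, b_c=0.9, e_mu=-0.1),
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        CellParameters(group="diatom", **kwargs)
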