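"""Valuation chain: benefit transfer, annualization, monetization, shares."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vlwkit import (
    CAUSE_OVERALL,
    CAUSE_T1DM,
    CAUSE_T2DM,
    ValidationError,
    ValuationParams,
    annualize_vsl,
    benefit_transfer_vsl,
    gdp_share,
    monetize,
    run_valuation,
    sensitivity_sweep,
)


class TestBenefitTransfer:
    def test_reference_income_returns_reference_vsl(self):
        for ie in (0.55, 1.0, 1.5):
            params = ValuationParams(gdp_pc_ref=70000.0, income_elasticity=ie)
            assert benefit_transfer_vsl(70000.0, params) == pytest.approx(11.8e6)

    def test_unit_elasticity_is_proportional(self):
        params = ValuationParams(gdp_pc_ref=70000.0, income_elasticity=1.0)
        assert benefit_transfer_vsl(35000.0, params) == pytest.approx(5.9e6)

    def test_sub_unit_elasticity_log_space_oracle(self):
        # oracle: 11.8e6 * exp(0.55 * ln 0.25), evaluated in log space
        params = ValuationParams(gdp_pc_ref=80000.0, income_elasticity=0.55)
        expected = 11.8e6 * math.exp(0.55 * math.log(0.25))
        assert benefit_transfer_vsl(20000.0, params) == pytest.approx(expected)
        assert expected == pytest.approx(5.505e6, rel=1e-3)

    def test_strictly_increasing_in_income(self):
        params = ValuationParams(gdp_pc_ref=70000.0, income_elasticity=0.55)
        incomes = np.array([1000.0, 5000.0, 20000.0, 70000.0, 150000.0])
        vsls = benefit_transfer_vsl(incomes, params)
        assert (np.diff(vsls) > 0).all()

    def test_non_positive_income_rejected(self):
        params = ValuationParams(gdp_pc_ref=70000.0)
        with pytest.raises(ValidationError):
            benefit_transfer_vsl(0.0, params)

    def test_elasticity_outside_band_rejected(self):
        with pytest.raises(ValidationError):
            ValuationParams(gdp_pc_ref=1.0, income_elasticity=5.0)


class TestAnnualize:
    def test_unit_fle(self):
        params = ValuationParams(gdp_pc_ref=1.0)
        fle, vsly = annualize_vsl(1e6, 2.0, params)
        assert fle == 1.0
        assert vsly == 1e6

    def test_long_division_oracle(self):
        params = ValuationParams(gdp_pc_ref=1.0)
        fle, vsly = annualize_vsl(11.8e6, 65.0, params)
        assert fle == 32.5
        assert vsly == pytest.approx(363076.92, abs=0.01)

    def test_doubling_hale_halves_vsly(self):
        params = ValuationParams(gdp_pc_ref=1.0)
        _, v1 = annualize_vsl(5e6, 30.0, params)
        _, v2 = annualize_vsl(5e6, 60.0, params)
        assert v1 == pytest.approx(2 * v2)

    def test_non_positive_hale_rejected(self):
        params = ValuationParams(gdp_pc_ref=1.0)
        with pytest.raises(ValidationError):
            annualize_vsl(1e6, 0.0, params)


class TestMonetizeAndShare:
    def test_zero_burden(self):
        assert monetize(0.0, 0.0, 0.0, 3.6e5) == (0.0, 0.0, 0.0)

    def test_three_independent_multiplications(self):
        vsly = 363076.92
        val, lo, up = monetize(1000.0, 800.0, 1300.0, vsly)
        assert val / 1e6 == pytest.approx(363.08, abs=0.01)
        assert lo / 1e6 == pytest.approx(290.46, abs=0.01)
        assert up / 1e6 == pytest.approx(472.00, abs=0.01)

    def test_linearity_in_burden(self):
        a = monetize(100.0, 80.0, 130.0, 5e5)
        b = monetize(300.0, 240.0, 390.0, 5e5)
        assert b == tuple(3 * x for x in a)

    def test_share_of_whole_economy_is_100(self):
        assert gdp_share(5e9, 5e9) == 100.0

    def test_zero_loss_is_zero_share(self):
        assert gdp_share(0.0, 5e9) == 0.0

    def test_printed_subtype_shares_reconstruct_overall(self):
        # global decomposition: 0.61% (T2) + 0.15% (T1) = 0.76% overall
        assert 0.61 + 0.15 == pytest.approx(0.76)

    def test_non_positive_gdp_rejected(self):
        with pytest.raises(ValidationError):
            gdp_share(1.0, 0.0)


def _single_country_inputs():
    burden = pd.DataFrame(
        {
            "location_id": ["Atlantis"] * 3,
            "year": 2021,
            "cause": [CAUSE_OVERALL, CAUSE_T1DM, CAUSE_T2DM],
            "age_band": "15-39 years",
            "dalys_val": [1000.0, 200.0, 800.0],
            "dalys_lower": [900.0, 150.0, 750.0],
            "dalys_upper": [1200.0, 260.0, 940.0],
        }
    )
    econ = pd.DataFrame(
        {
            "location_id": ["Atlantis"],
            "year": [2021],
            "gdp_pc": [20000.0],
            "gdp_total": [4.0e10],
            "hale": [64.0],
            "population": [2.0e6],
            "gdp_pc_imputed": False,
            "gdp_total_imputed": False,
            "hale_imputed": False,
        }
    )
    return burden, econ


class TestRunValuation:
    def test_single_country_matches_manual_chain(self):
        burden, econ = _single_country_inputs()
        params = ValuationParams(gdp_pc_ref=80000.0, income_elasticity=1.0)
        res = run_valuation(burden, econ, None, params)
        # manual composition: VSL = 11.8e6 * 0.25 = 2.95e6; FLE = 32;
        # VSLY = 92187.5; VLW(overall) = 1000 * 92187.5 = 9.21875e7;
        # share = 100 * 9.21875e7 / 4e10 = 0.23046875 %
        overall = res[res["cause"] == CAUSE_OVERALL].iloc[0]
        assert overall["vsl"] == pytest.approx(2.95e6)
        assert overall["fle"] == pytest.approx(32.0)
        assert overall["vsly"] == pytest.approx(92187.5)
        assert overall["vlw_val"] == pytest.approx(9.21875e7)
        assert overall["gdp_share_val"] == pytest.approx(0.23046875)

    def test_empty_burden_gives_empty_result(self):
        burden, econ = _single_country_inputs()
        params = ValuationParams(gdp_pc_ref=80000.0)
        res = run_valuation(burden.iloc[0:0], econ, None, params)
        assert res.empty

    def test_row_order_invariance(self, world):
        burden = world.burden[world.burden["year"] == 2021]
        shuffled = burden.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = run_valuation(burden, world.econ, world.hierarchy, world.params)
        b = run_valuation(shuffled, world.econ, world.hierarchy, world.params)
        pd.testing.assert_frame_equal(a, b)

    def test_unmatched_location_errors_with_names(self):
        burden, econ = _single_country_inputs()
        burden.loc[:, "location_id"] = "Nowhere"
        params = ValuationParams(gdp_pc_ref=80000.0)
        with pytest.raises(ValidationError, match="Nowhere"):
            run_valuation(burden, econ, None, params)

    def test_ui_ordering_preserved(self, world):
        res = run_valuation(
            world.burden[world.burden["year"] == 2021],
            world.econ, world.hierarchy, world.params,
        )
        assert (res["vlw_lower"] <= res["vlw_val"]).all()
        assert (res["vlw_val"] <= res["vlw_upper"]).all()
        assert (res["gdp_share_lower"] <= res["gdp_share_val"]).all()
        assert (res["gdp_share_val"] <= res["gdp_share_upper"]).all()

    def test_subtype_additivity_flows_through(self):
        burden, econ = _single_country_inputs()
        params = ValuationParams(gdp_pc_ref=80000.0)
        res = run_valuation(burden, econ, None, params).set_index("cause")
        assert res.loc[CAUSE_OVERALL, "vlw_val"] == pytest.approx(
            res.loc[CAUSE_T1DM, "vlw_val"] + res.loc[CAUSE_T2DM, "vlw_val"]
        )


class TestSensitivitySweep:
    def test_singleton_sweep_reproduces_run_valuation(self):
        burden, econ = _single_country_inputs()
        params = ValuationParams(gdp_pc_ref=80000.0)
        swept = sensitivity_sweep(burden, econ, None, params, ie_values=[1.0])
        pd.testing.assert_frame_equal(
            swept[1.0], run_valuation(burden, econ, None, params)
        )

    def test_reference_income_invariant_across_ies(self):
        burden, econ = _single_country_inputs()
        params = ValuationParams(gdp_pc_ref=20000.0)  # country at the reference
        swept = sensitivity_sweep(burden, econ, None, params)
        vlws = [r["vlw_val"].sum() for r in swept.values()]
        assert vlws[0] == pytest.approx(vlws[1]) == pytest.approx(vlws[2])

    def test_poor_country_vlw_decreasing_in_ie(self):
        burden, econ = _single_country_inputs()
        econ.loc[:, "gdp_pc"] = 8000.0  # ratio 0.1 vs reference
        econ.loc[:, "gdp_total"] = 8000.0 * 2.0e6
        params = ValuationParams(gdp_pc_ref=80000.0)
        swept = sensitivity_sweep(burden, econ, None, params, [0.55, 1.0, 1.5])
        v = {ie: r["vlw_val"].sum() for ie, r in swept.items()}
        # oracle: 0.1**0.55 > 0.1**1.0 > 0.1**1.5
        assert v[0.55] > v[1.0] > v[1.5]

    def test_empty_ie_list_rejected(self):
        burden, econ = _single_country_inputs()
        params = ValuationParams(gdp_pc_ref=80000.0)
        with pytest.raises(ValidationError):
            sensitivity_sweep(burden, econ, None, params, [])


class TestScaleInvariance:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_currency_rescaling_preserves_shares(self, scale):
        burden, econ = _single_country_inputs()
        params = ValuationParams(gdp_pc_ref=80000.0)
        base = run_valuation(burden, econ, None, params)
        econ2 = econ.assign(
            gdp_pc=econ["gdp_pc"] * scale, gdp_total=econ["gdp_total"] * scale
        )
        params2 = ValuationParams(
            vsl_ref=params.vsl_ref * scale, gdp_pc_ref=params.gdp_pc_ref * scale
        )
        rescaled = run_valuation(burden, econ2, None, params2)
        assert np.allclose(rescaled["gdp_share_val"], base["gdp_share_val"])
        assert np.allclose(rescaled["vlw_val"], base["vlw_val"] * scale)
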