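"""Dose parametrization, uncertainty propagation and inverse planning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnctkit import dosimetry as dm
from bnctkit.errors import InfeasiblePlanError, InputDomainError

from conftest import SPHEROID_PLAN_ROWS


def _bisect_dose(target, rates, boron, t_irr, lo=0.0, hi=250.0, tol=1e-12):
    """Independent inverse oracle: bisection on the forward dose model."""
    for _ in range(200):
        mid = (lo + hi) / 2
        d = dm.total_dose(rates, boron, dm.IrradiationPlan(P=mid, t_irr=t_irr)).D_tot
        if d < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2


class TestTotalDose:
    @pytest.mark.parametrize("label,P,cb,scb,dtot,d0", SPHEROID_PLAN_ROWS)
    def test_reproduces_spheroid_planning_rows(self, spheroid_rates, label, P,
                                               cb, scb, dtot, d0):
        res = dm.total_dose(
            spheroid_rates, dm.BoronMeasurement(cb, scb), dm.IrradiationPlan(P=P)
        )
        assert res.D_tot == pytest.approx(dtot, rel=0.02)
        assert res.D_0 == pytest.approx(d0, rel=0.02)

    def test_zero_power_gives_zero_dose(self, spheroid_rates):
        res = dm.total_dose(
            spheroid_rates, dm.BoronMeasurement(0.0), dm.IrradiationPlan(P=0.0)
        )
        assert res.D_tot == 0 and res.D_0 == 0

    @given(
        cb=st.floats(0, 100),
        P=st.floats(0, 250),
        t=st.floats(1, 3600),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_arithmetic_oracle(self, spheroid_rates, cb, P, t):
        """Randomized inputs agree with a directly coded formula evaluation."""
        res = dm.total_dose(
            spheroid_rates, dm.BoronMeasurement(cb), dm.IrradiationPlan(P=P, t_irr=t)
        )
        expected = (14.98 + cb * 1.70) * t * P / 250.0 / 1000.0
        assert res.D_tot == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_components_sum_to_total(self, spheroid_rates):
        res = dm.total_dose(
            spheroid_rates, dm.BoronMeasurement(47.5), dm.IrradiationPlan(P=12)
        )
        assert sum(res.components.values()) == pytest.approx(res.D_tot, rel=1e-9)
        assert res.D_tot - res.D_0 == pytest.approx(res.components["boron"], rel=1e-9)
        assert all(v >= 0 for v in res.components.values())

    def test_linearity_in_time_and_power(self, spheroid_rates):
        b = dm.BoronMeasurement(30.0)
        d1 = dm.total_dose(spheroid_rates, b, dm.IrradiationPlan(P=10, t_irr=300)).D_tot
        d4 = dm.total_dose(spheroid_rates, b, dm.IrradiationPlan(P=20, t_irr=600)).D_tot
        assert d4 == pytest.approx(4 * d1, rel=1e-12)

    def test_monotone_in_boron(self, spheroid_rates):
        plan = dm.IrradiationPlan(P=20)
        doses = [
            dm.total_dose(spheroid_rates, dm.BoronMeasurement(c), plan).D_tot
            for c in np.linspace(0, 80, 9)
        ]
        assert np.all(np.diff(doses) > 0)

    def test_invalid_inputs_raise(self, spheroid_rates):
        with pytest.raises(InputDomainError):
            dm.BoronMeasurement(-1.0)
        with pytest.raises(InputDomainError):
            dm.IrradiationPlan(P=300.0)


class TestUncertainty:
    def test_wm266_lower_dose_sigma(self, spheroid_rates):
        """Propagated sigma for the 17 kW spheroid plan lands on 0.47-0.48 Gy."""
        sigma = dm.propagate_stat_uncertainty(
            spheroid_rates, dm.BoronMeasurement(36.0, 6.8), dm.IrradiationPlan(P=17)
        )
        assert 0.47 <= sigma <= 0.48

    def test_zero_uncertainties_give_zero(self, spheroid_rates):
        rates = dm.DoseRateSet(
            culture_type=dm.CultureType.spheroid,
            R_bg=14.98, R_B=1.70, R_H=0.119, R_N=4.26, R_gamma=10.6,
        )
        assert dm.propagate_stat_uncertainty(
            rates, dm.BoronMeasurement(30.0, 0.0), dm.IrradiationPlan(P=17)
        ) == 0

    def test_single_term_reduction(self, spheroid_rates):
        """Only sigma_CB nonzero: sigma = R_B * t * (P/P_max) * sigma_CB."""
        rates = dm.DoseRateSet(
            culture_type=dm.CultureType.spheroid,
            R_bg=14.98, R_B=1.70, R_H=0.119, R_N=4.26, R_gamma=10.6,
        )
        plan = dm.IrradiationPlan(P=17)
        sigma = dm.propagate_stat_uncertainty(
            rates, dm.BoronMeasurement(36.0, 6.8), plan
        )
        expected = 1.70 * 600 * (17 / 250) * 6.8 / 1000
        assert sigma == pytest.approx(expected, rel=1e-12)

    def test_boron_term_dominates(self, spheroid_rates):
        """With a 19% relative C_B error the concentration term dominates."""
        full = dm.propagate_stat_uncertainty(
            spheroid_rates, dm.BoronMeasurement(36.0, 6.8), dm.IrradiationPlan(P=17)
        )
        no_cb = dm.propagate_stat_uncertainty(
            spheroid_rates, dm.BoronMeasurement(36.0, 0.0), dm.IrradiationPlan(P=17)
        )
        assert no_cb < 0.1 * full


class TestInversePlanning:
    def test_power_round_trip(self, spheroid_rates):
        b = dm.BoronMeasurement(36.0)
        d = dm.total_dose(spheroid_rates, b, dm.IrradiationPlan(P=36)).D_tot
        assert dm.solve_power(d, spheroid_rates, b) == pytest.approx(36, rel=1e-9)

    def test_wm266_higher_dose_power(self, spheroid_rates):
        P = dm.solve_power(9.33, spheroid_rates, dm.BoronMeasurement(36.0))
        assert P == pytest.approx(51, rel=0.02)

    def test_time_round_trip_and_planning_value(self, spheroid_rates):
        b = dm.BoronMeasurement(47.5)
        t = dm.solve_time(2.78, spheroid_rates, b, P=12)
        assert t == pytest.approx(600, rel=0.02)
        d = dm.total_dose(spheroid_rates, b, dm.IrradiationPlan(P=12, t_irr=t)).D_tot
        assert d == pytest.approx(2.78, rel=1e-9)

    @given(target=st.floats(0.1, 20.0), cb=st.floats(0, 80))
    @settings(max_examples=100, deadline=None)
    def test_matches_bisection_oracle(self, spheroid_rates, target, cb):
        b = dm.BoronMeasurement(cb)
        try:
            P = dm.solve_power(target, spheroid_rates, b)
        except InfeasiblePlanError as err:
            assert err.required_power > 250
            return
        oracle = _bisect_dose(target, spheroid_rates, b, 600.0)
        assert P == pytest.approx(oracle, rel=1e-9, abs=1e-9)

    def test_infeasible_power_carries_requirement(self, spheroid_rates):
        with pytest.raises(InfeasiblePlanError) as exc:
            dm.solve_power(500.0, spheroid_rates, dm.BoronMeasurement(10.0))
        assert exc.value.required_power > 250

    def test_zero_power_time_infeasible(self, spheroid_rates):
        with pytest.raises(InfeasiblePlanError):
            dm.solve_time(2.0, spheroid_rates, dm.BoronMeasurement(10.0), P=0.0)


class TestFluxAndGroups:
    @pytest.mark.parametrize("P,flux", [(20, 9.60e8), (0, 0.0), (51, 2.448e9)])
    def test_flux_at_power(self, P, flux):
        assert dm.flux_at_power(dm.IrradiationPlan(P=P)) == pytest.approx(flux)

    @pytest.mark.parametrize(
        "dose,group",
        [(2.78, dm.DoseGroup.lower), (9.33, dm.DoseGroup.higher),
         (4.0, dm.DoseGroup.lower), (0.0, dm.DoseGroup.lower)],
    )
    def test_dose_group_classification(self, dose, group):
        assert dm.classify_dose_group(dose) is group


class TestDoseRateTable:
    def test_background_closure(self, rate_tables):
        """R_H + R_N + R_gamma recovers R_bg within 0.5% for both rows."""
        for rates in rate_tables.values():
            total = rates.R_H + rates.R_N + rates.R_gamma
            assert total == pytest.approx(rates.R_bg, rel=0.005)

    def test_closure_violation_rejected(self):
        with pytest.raises(InputDomainError):
            dm.DoseRateSet(
                culture_type=dm.CultureType.flask2D,
                R_bg=10.0, R_B=1.0, R_H=1.0, R_N=1.0, R_gamma=1.0,
            )

    def test_roundtrip_from_csv(self, tmp_path, rate_tables):
        import pandas as pd

        path = tmp_path / "rates.csv"
        pd.DataFrame(
            [{
                "culture_type": "spheroid", "R_bg": 14.98, "sigma_R_bg": 0.08,
                "R_B": 1.70, "sigma_R_B": 0.03, "R_H": 0.119, "R_N": 4.26,
                "R_gamma": 10.6,
            }]
        ).to_csv(path, index=False)
        loaded = dm.load_dose_rate_table(path)
        assert loaded[dm.CultureType.spheroid] == rate_tables[dm.CultureType.spheroid]
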