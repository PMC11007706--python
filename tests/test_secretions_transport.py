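"""Bile/gallbladder, pancreatic and intestinal secretion, transit, mucus layer."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from gutsim.core_state import SMALL_INTESTINE
from gutsim.secretions_transport import (
    BileParams,
    GallbladderState,
    MucosaParams,
    PancreasParams,
    TransitParams,
    hepatic_bile_and_gallbladder_step,
    ileal_brake_factor,
    intestinal_secretion_step,
    pancreatic_secretion_step,
    solve_brush_border_state,
    solve_brush_border_vector,
    transit_outflow_fraction,
)


class TestBile:
    def test_fasted_bile_is_stored(self):
        params = BileParams()
        state = GallbladderState(water_mass=10.0, salt_mass=0.1,
                                 hepatic_salt_pool=3.9)
        out, _ = hepatic_bile_and_gallbladder_step(
            state, cck=0.05, secretin_excess=0.0, salt_return_rate=0.0,
            dt=1.0, params=params,
        )
        assert out["water"] == 0.0 and out["bile_salt"] == 0.0
        assert state.volume > 10.0  # hepatic production filled the bladder

    def test_cck_triggers_exponential_emptying(self):
        params = BileParams(hepatic_base=0.0, per_secretin=0.0,
                            salt_synthesis_rate=0.0)
        state = GallbladderState(water_mass=30.0, salt_mass=0.5,
                                 hepatic_salt_pool=0.0)
        v0 = state.volume
        dt = 1.0 / 60.0
        for _ in range(15 * 60):  # 15 min = one emptying time constant
            hepatic_bile_and_gallbladder_step(
                state, cck=5.0, secretin_excess=0.0, salt_return_rate=0.0,
                dt=dt, params=params,
            )
        assert state.volume == pytest.approx(v0 * math.exp(-1.0), rel=1e-3)

    def test_empty_system_zero_flow(self):
        params = BileParams(hepatic_base=0.0, per_secretin=0.0,
                            salt_synthesis_rate=0.0)
        state = GallbladderState(water_mass=0.0, salt_mass=0.0,
                                 hepatic_salt_pool=0.0)
        out, created = hepatic_bile_and_gallbladder_step(
            state, cck=5.0, secretin_excess=0.0, salt_return_rate=0.0,
            dt=1.0, params=params,
        )
        assert out["water"] == 0.0 and out["bile_salt"] == 0.0
        assert created == 0.0


class TestPancreas:
    def test_baseline_is_basal(self):
        params = PancreasParams()
        juice = pancreatic_secretion_step(0.0, 0.0, 1.0, params)
        assert juice["water"] + juice["bicarbonate"] == pytest.approx(
            params.water_base
        )
        assert juice["amylase"] == pytest.approx(params.enzyme_base)

    def test_bicarbonate_linear_in_secretin(self):
        params = PancreasParams()
        base = pancreatic_secretion_step(0.0, 0.0, 1.0, params)["bicarbonate"]
        one = pancreatic_secretion_step(0.0, 1.0, 1.0, params)["bicarbonate"]
        two = pancreatic_secretion_step(0.0, 2.0, 1.0, params)["bicarbonate"]
        assert two - base == pytest.approx(2.0 * (one - base), rel=1e-9)

    def test_enzyme_output_clamped(self):
        params = PancreasParams()
        juice = pancreatic_secretion_step(1e9, 0.0, 1.0, params)
        assert juice["lipase"] == pytest.approx(params.enzyme_max)


class TestIntestinalSecretion:
    def test_neutral_unstimulated_is_zero(self):
        out = intestinal_secretion_step(0.0, 7.0, 1.0, MucosaParams())
        assert sum(out.values()) == 0.0

    def test_acidity_term(self):
        params = MucosaParams()
        at5 = intestinal_secretion_step(0.0, 5.0, 1.0, params)
        total = sum(at5.values())
        assert total == pytest.approx(2.0 * params.secretion_per_ph)

    def test_water_budget_nine_litres_per_day(self):
        params = MucosaParams()
        total = sum(params.water_flux(c) for c in SMALL_INTESTINE)
        assert total == pytest.approx(params.total_water_flux)
        assert total * 60 * 24 / 1000 == pytest.approx(9.0, rel=0.05)


class TestTransit:
    def test_ileal_brake_monotone(self):
        params = TransitParams()
        assert ileal_brake_factor(0.0, 0.0, params) == 1.0
        g1 = ileal_brake_factor(0.5, 0.0, params)
        g2 = ileal_brake_factor(1.0, 0.5, params)
        assert 0.0 < g2 < g1 < 1.0

    def test_mmc_accelerates(self):
        params = TransitParams()
        slow = transit_outflow_fraction(30.0, 1.0, 1.0, 1.0 / 60, params)
        fast = transit_outflow_fraction(30.0, 1.0, params.mmc_multiplier,
                                        1.0 / 60, params)
        assert fast > slow

    def test_fraction_capped_for_stability(self):
        params = TransitParams()
        assert transit_outflow_fraction(0.01, 1.0, 10.0, 1.0, params) == \
            params.max_step_fraction


class TestBrushBorder:
    def test_equilibrium_without_uptake(self):
        c, flux = solve_brush_border_state(
            c_lum=0.1, diffusivity=6e-4, area=500.0, thickness=0.005,
            water_flux=0.0, uptake=lambda c: 0.0,
        )
        assert c == pytest.approx(0.1, rel=1e-6)
        assert flux == pytest.approx(0.0, abs=1e-9)

    def test_transport_limited_ceiling(self):
        km = 6e-4 * 500.0 / 0.005
        c, flux = solve_brush_border_state(
            c_lum=0.1, diffusivity=6e-4, area=500.0, thickness=0.005,
            water_flux=1.0, uptake=lambda c: 1e9 * c,
        )
        assert c == pytest.approx(0.0, abs=1e-6)
        assert flux == pytest.approx((km + 1.0) * 0.1, rel=1e-3)

    def test_concentration_polarization_with_water_flux(self):
        # weak uptake + water drag -> surface concentration above luminal
        c, _ = solve_brush_border_state(
            c_lum=0.05, diffusivity=6e-4, area=100.0, thickness=0.01,
            water_flux=2.0, uptake=lambda c: 0.0,
        )
        assert c > 0.05

    def test_michaelis_menten_uptake_matches_root_oracle(self):
        d, a, h, vw = 6e-4, 400.0, 0.008, 0.6
        vmax, khalf = 0.4, 0.002
        km = d * a / h
        c_lum = 0.01

        def balance(c):
            return km * (c_lum - c) + vw * c_lum - vmax * c / (khalf + c)

        oracle = brentq(balance, 0.0, c_lum * (1 + vw / km), xtol=1e-14)
        got, _ = solve_brush_border_state(
            c_lum, d, a, h, vw, lambda c: vmax * c / (khalf + c), iters=80
        )
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(7)
        n = 12
        c_lum = rng.uniform(0, 0.05, n)
        km = rng.uniform(10.0, 300.0, n)
        vw = rng.uniform(0.0, 2.0, n)
        vmax = rng.uniform(0.0, 0.6, n)
        khalf = rng.uniform(5e-4, 0.01, n)
        passive = rng.uniform(0.0, 1.0, n)
        vec = solve_brush_border_vector(c_lum, km, vw, vmax, khalf, passive,
                                        iters=60)
        for i in range(n):
            def uptake(c, i=i):
                return vmax[i] * c / (khalf[i] + c) + passive[i] * c

            scalar, _ = solve_brush_border_state(
                c_lum[i], 1.0, km[i], 1.0, vw[i], uptake, iters=60
            )
            assert vec[i] == pytest.approx(scalar, abs=1e-8)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            solve_brush_border_state(0.1, 0.0, 1.0, 1.0, 0.0, lambda c: 0.0)
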