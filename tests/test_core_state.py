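"""Component registry, isochoric volumes, concentrations, proton balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutsim.core_state import (
    CompartmentState,
    ComponentRegistry,
    ComponentSpec,
    RegistryError,
    UndefinedConcentrationError,
    compute_pH,
    concentration_at,
    default_registry,
    mixed_volume,
    neutralize_bicarbonate,
    ph_vector,
)

REG = default_registry()


class TestMixedVolume:
    @pytest.mark.parametrize(
        "masses,expected",
        [
            ({"water": 100.0}, 100.0),
            ({}, 0.0),
            ({"water": 100.0, "triglyceride": 90.0}, 200.0),
            ({"glucose": 50.0}, 50.0 / 1.54),
        ],
    )
    def test_isochoric_sum(self, masses, expected):
        assert mixed_volume(masses, REG) == pytest.approx(expected)

    def test_hydrogen_volume_negligible(self):
        # sentinel density 1e6 g/mL makes even gram amounts of H+ tiny
        assert mixed_volume({"hydrogen_ion": 1.0}, REG) == pytest.approx(1e-6)

    def test_unknown_component_rejected(self):
        with pytest.raises(RegistryError):
            mixed_volume({"unobtainium": 1.0}, REG)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            mixed_volume({"water": -1.0}, REG)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.dictionaries(
            st.sampled_from(["water", "glucose", "protein"]),
            st.floats(0, 1e3),
            max_size=3,
        ),
        b=st.dictionaries(
            st.sampled_from(["triglyceride", "sucrose", "starch_rapid"]),
            st.floats(0, 1e3),
            max_size=3,
        ),
    )
    def test_additive_over_disjoint_ledgers(self, a, b):
        merged = {**a, **b}
        assert mixed_volume(merged, REG) == pytest.approx(
            mixed_volume(a, REG) + mixed_volume(b, REG)
        )


class TestConcentration:
    def test_glucose_drink(self):
        state = CompartmentState("x", {"water": 250.0, "glucose": 50.0})
        vol = 250.0 + 50.0 / 1.54
        assert concentration_at(state, "glucose", REG) == pytest.approx(50.0 / vol)
        assert concentration_at(state, "glucose", REG) == pytest.approx(0.177, abs=5e-4)

    def test_pure_water(self):
        state = CompartmentState("x", {"water": 123.0})
        assert concentration_at(state, "water", REG) == pytest.approx(1.0)

    def test_absent_component_is_zero(self):
        state = CompartmentState("x", {"water": 10.0})
        assert concentration_at(state, "glucose", REG) == 0.0

    def test_zero_volume_errors(self):
        with pytest.raises(UndefinedConcentrationError):
            concentration_at(CompartmentState("x"), "water", REG)

    def test_never_exceeds_pure_density(self):
        state = CompartmentState("x", {"glucose": 80.0, "water": 1.0})
        assert concentration_at(state, "glucose", REG) <= 1.54


def _oracle_ph(total_h_mol_l, buffers, tol=1e-12):
    """Independent bisection oracle on the proton balance.

    buffers: list of (g_per_L, pKa, mol groups per g); occupancies are
    referenced to the neutral state, matching the model's convention.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        ph = 0.5 * (lo + hi)
        lhs = 10.0**-ph - 1e-14 * 10.0**ph
        for g_l, pka, cap in buffers:
            occ = 1.0 / (1.0 + 10.0 ** (ph - pka))
            ref = 1.0 / (1.0 + 10.0 ** (7.0 - pka))
            lhs += g_l * cap * (occ - ref)
        if abs(lhs - total_h_mol_l) < tol:
            return ph
        if lhs > total_h_mol_l:
            lo = ph
        else:
            hi = ph
    return 0.5 * (lo + hi)


class TestComputePH:
    def test_strong_acid(self):
        # 0.1 mol H+ per litre, no buffers -> pH 1
        state = CompartmentState("x", {"water": 1000.0, "hydrogen_ion": 0.1})
        assert compute_pH(state, REG) == pytest.approx(1.0, abs=1e-5)

    def test_neutral_water(self):
        state = CompartmentState("x", {"water": 1000.0})
        assert compute_pH(state, REG) == pytest.approx(7.0, abs=1e-5)

    def test_buffered_acid_matches_bisection_oracle(self):
        # 0.1 M H+ with a protein-like buffer; the capacity is chosen so
        # a large share of the acid binds to the buffer
        reg = ComponentRegistry(
            [
                ComponentSpec("water", "water", 1.0, molar_mass=18.0),
                ComponentSpec("hydrogen_ion", "hydrogen_ion", 1e6, molar_mass=1.0),
                ComponentSpec(
                    "buffer", "protein", 1.35,
                    titration_curve=((4.0, 5.0e-3),),
                ),
            ]
        )
        state = CompartmentState(
            "x", {"water": 1000.0, "hydrogen_ion": 0.1, "buffer": 20.0}
        )
        litres = state.volume(reg) / 1000.0
        expected = _oracle_ph(0.1 / litres, [(20.0 / litres, 4.0, 5.0e-3)])
        got = compute_pH(state, reg)
        assert got == pytest.approx(expected, abs=1e-6)
        # the buffer must have raised the pH above the unbuffered value
        assert got > 1.0

    def test_zero_volume_errors(self):
        with pytest.raises(UndefinedConcentrationError):
            compute_pH(CompartmentState("x"), REG)

    @pytest.mark.parametrize("h", [0.0, 1e-4, 1e-3, 1e-2, 0.05])
    def test_monotone_in_added_acid(self, h):
        base = CompartmentState("x", {"water": 1000.0, "protein": 30.0,
                                      "hydrogen_ion": h})
        more = CompartmentState("x", {"water": 1000.0, "protein": 30.0,
                                      "hydrogen_ion": h + 1e-3})
        assert compute_pH(more, REG) <= compute_pH(base, REG)

    def test_vectorized_matches_scalar(self):
        states = [
            {"water": 500.0, "hydrogen_ion": 0.02, "protein": 10.0},
            {"water": 200.0, "hydrogen_ion": 1e-4, "citric_acid": 5.0},
            {"water": 100.0},
        ]
        reg = REG
        n = len(reg)
        conc = np.zeros((len(states), n))
        total = np.zeros(len(states))
        for i, masses in enumerate(states):
            vol = mixed_volume(masses, reg)
            for name, m in masses.items():
                conc[i, reg.index[name]] = m / vol
            total[i] = masses.get("hydrogen_ion", 0.0) / (vol / 1000.0)
        vec = ph_vector(total, conc, reg, iters=60)
        for i, masses in enumerate(states):
            scalar = compute_pH(CompartmentState("x", dict(masses)), reg)
            assert vec[i] == pytest.approx(scalar, abs=1e-5)


class TestNeutralization:
    def test_stoichiometry_and_conservation(self):
        h, b, w = neutralize_bicarbonate(0.5, 61.0)
        # 0.5 g H+ (0.5 mol) limited by 1 mol bicarbonate
        assert h == pytest.approx(0.0)
        assert b == pytest.approx(61.0 - 0.5 * 61.0)
        assert w == pytest.approx(0.5 * 62.0)
        assert h + b + w == pytest.approx(0.5 + 61.0)

    def test_bicarbonate_never_lowers_ph(self):
        state = CompartmentState("x", {"water": 1000.0, "hydrogen_ion": 0.05})
        before = compute_pH(state, REG)
        h, b, w = neutralize_bicarbonate(0.05, 2.0)
        after_state = CompartmentState(
            "x", {"water": 1000.0 + w, "hydrogen_ion": h, "bicarbonate": b}
        )
        assert compute_pH(after_state, REG) >= before


class TestRegistry:
    def test_default_densities(self):
        expected = {
            "water": 1.0, "triglyceride": 0.9, "glucose": 1.54,
            "protein": 1.35, "starch_rapid": 1.54, "fatty_acid": 0.9,
            "sucrose": 1.59, "rare_sugar": 1.69,
            "bile_salt_LCFA_complex": 1.69, "citric_acid": 1.66,
        }
        for name, rho in expected.items():
            assert REG[name].density == rho
        assert REG["hydrogen_ion"].density == 1e6

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ComponentSpec("x", "water", density=-1.0)
        with pytest.raises(ValueError):
            ComponentSpec("x", "nope", density=1.0)
        with pytest.raises(ValueError):
            ComponentSpec("x", "water", density=1.0, caloric_density=-0.1)
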