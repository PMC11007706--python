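"""Meal-plan dialect, consumption scheduling, oral processing."""

import math

import pytest

from gutsim import engine
from gutsim.core_state import CompartmentState, SolidParticle, default_registry
from gutsim.meal_io import (
    CompoundSpec,
    MealEvent,
    MealFileError,
    MealPlan,
    OralParams,
    consumption_step,
    load_plate,
    oral_process_and_swallow,
    parse_meal_file,
    plan_compound_index,
    write_meal_file,
)

REG = default_registry()

SAMPLE = """
# a one-meal plan
[meal name="breakfast" start_min=0 rate_mL_per_min=60]
[compound name="drink" pH=7 state=liquid viscosity_mPas=1 oral_break_min=0 gastric_break_min=0 decomp_min=0]
water\t250
glucose\t50
"""


class TestParsing:
    def test_simple_plan(self):
        plan = parse_meal_file(SAMPLE)
        assert len(plan.meals) == 1
        meal = plan.meals[0]
        assert meal.consumption_rate == 60.0
        assert meal.compounds[0].components == {"water": 250.0, "glucose": 50.0}

    def test_empty_file(self):
        assert parse_meal_file("") == MealPlan(())
        assert parse_meal_file("# only comments\n") == MealPlan(())

    def test_bread_fixture_composition(self):
        plan = engine.builtin_fixture("eelderink-bread")
        meal = plan.meals[0]
        bread = next(c for c in meal.compounds if c.name == "bread")
        assert bread.total_mass == pytest.approx(132.0)
        assert bread.components["water"] == 67.0
        assert bread.components["triglyceride"] == 9.0
        assert bread.components["starch_rapid"] == 50.0

    def test_roundtrip_is_lossless(self):
        for name in engine.FIXTURE_NAMES:
            plan = engine.builtin_fixture(name)
            text = write_meal_file(plan)
            assert parse_meal_file(text) == plan
            # canonical form is a fixed point of write/parse
            assert write_meal_file(parse_meal_file(text)) == text

    @pytest.mark.parametrize(
        "text,fragment",
        [
            ("[compound name=\"x\" pH=7 state=liquid viscosity_mPas=1 "
             "oral_break_min=0 gastric_break_min=0 decomp_min=0]",
             "outside of a meal"),
            ("[meal name=\"m\" start_min=0 rate_mL_per_min=60]\n"
             "[compound name=\"x\" pH=7 state=liquid viscosity_mPas=1 "
             "oral_break_min=0 gastric_break_min=0 decomp_min=0]\n"
             "unobtainium\t5", "unknown component"),
            ("[meal name=\"m\" start_min=0 rate_mL_per_min=60]\n"
             "[compound name=\"x\" pH=7 state=liquid viscosity_mPas=1 "
             "oral_break_min=0 gastric_break_min=0 decomp_min=0]\n"
             "water\t-5", "negative mass"),
            ("[meal name=\"m\" start_min=0 rate_mL_per_min=0]", "rate"),
        ],
    )
    def test_errors_carry_line_numbers(self, text, fragment):
        with pytest.raises(MealFileError) as err:
            parse_meal_file(text)
        assert fragment in str(err.value)
        assert "line" in str(err.value)

    def test_texture_attribute_exclusivity(self):
        with pytest.raises(ValueError):
            CompoundSpec("x", 7.0, "liquid", particle_size=5.0, viscosity=1.0)
        with pytest.raises(ValueError):
            CompoundSpec("x", 7.0, "solid")


class TestConsumption:
    def _drink_plan(self):
        return parse_meal_file(SAMPLE)

    def test_rate_limited_transfer(self):
        plan = self._drink_plan()
        plate = CompartmentState("plate")
        mouth = CompartmentState("mouth")
        load_plate(plan, 0.0, 1.0, plate)
        total_vol = 250.0 + 50.0 / 1.54
        moved = consumption_step(plan, 0.0, 1.0, plate, mouth, REG)
        assert moved == pytest.approx(60.0)
        remaining = sum(p.mass for p in plate.solid_particles)
        assert remaining == pytest.approx(300.0 * (1 - 60.0 / total_vol))

    def test_empty_plate_noop(self):
        plan = self._drink_plan()
        plate = CompartmentState("plate")
        mouth = CompartmentState("mouth")
        assert consumption_step(plan, 0.0, 1.0, plate, mouth, REG) == 0.0
        assert mouth.solid_particles == []

    def test_slow_rate_gives_long_window(self):
        # 300 g at 1 mL/min empties the plate in about mass/(rate*density)
        compound = CompoundSpec(
            "porridge", 7.0, "liquid", viscosity=5.0,
            components={"water": 200.0, "starch_rapid": 100.0},
        )
        plan = MealPlan((MealEvent("m", 0.0, 1.0, (compound,)),))
        plate = CompartmentState("plate")
        mouth = CompartmentState("mouth")
        load_plate(plan, 0.0, 1.0, plate)
        expected_minutes = 300.0 / (1.0 * compound.density(REG))
        t, dt = 0.0, 1.0
        while plate.solid_particles and t < 500:
            consumption_step(plan, t, dt, plate, mouth, REG)
            t += dt
        assert t == pytest.approx(expected_minutes, abs=2.0)

    def test_mass_conservation(self):
        plan = self._drink_plan()
        plate = CompartmentState("plate")
        mouth = CompartmentState("mouth")
        load_plate(plan, 0.0, 1.0, plate)
        before = sum(p.mass for p in plate.solid_particles)
        consumption_step(plan, 0.0, 1.0, plate, mouth, REG)
        after = sum(p.mass for p in plate.solid_particles) + sum(
            p.mass for p in mouth.solid_particles
        )
        assert after == pytest.approx(before)


class TestOralProcessing:
    def test_liquid_swallowed_within_one_step(self):
        plan = parse_meal_file(SAMPLE)
        mouth = CompartmentState("mouth")
        mouth.solid_particles.append(SolidParticle("drink", 100.0, 0.0))
        masses, particles = oral_process_and_swallow(mouth, 1.0 / 60, plan,
                                                     OralParams(), REG)
        assert mouth.solid_particles == []
        # instant decomposition (decomp_min=0) releases components into the bolus
        assert masses["glucose"] > 0

    def test_solid_comminution_e_folding(self):
        solid = CompoundSpec(
            "biscuit", 7.0, "solid", particle_size=8.0,
            oral_breakdown_time=0.5, gastric_breakdown_time=30.0,
            decomposition_time=1e9, components={"starch_rapid": 30.0},
        )
        plan = MealPlan((MealEvent("m", 0.0, 60.0, (solid,)),))
        mouth = CompartmentState("mouth")
        mouth.solid_particles.append(SolidParticle("biscuit", 30.0, 8.0))
        params = OralParams(swallow_size_mm=0.1, swallow_residence_factor=1e9)
        dt = 1.0 / 60.0
        for _ in range(30):  # 0.5 min = one breakdown time constant
            oral_process_and_swallow(mouth, dt, plan, params, REG)
        assert mouth.solid_particles[0].size == pytest.approx(
            8.0 * math.exp(-1.0), rel=1e-6
        )

    def test_particle_size_never_increases(self):
        solid = CompoundSpec(
            "biscuit", 7.0, "solid", particle_size=5.0,
            oral_breakdown_time=0.5, decomposition_time=1e9,
            components={"starch_rapid": 30.0},
        )
        plan = MealPlan((MealEvent("m", 0.0, 60.0, (solid,)),))
        mouth = CompartmentState("mouth")
        mouth.solid_particles.append(SolidParticle("biscuit", 30.0, 5.0))
        params = OralParams(swallow_size_mm=0.1, swallow_residence_factor=1e9)
        last = 5.0
        for _ in range(60):
            oral_process_and_swallow(mouth, 1.0 / 60, plan, params, REG)
            size = mouth.solid_particles[0].size
            assert size <= last
            last = size

    def test_saliva_addition_rate(self):
        solid = CompoundSpec(
            "biscuit", 7.0, "solid", particle_size=8.0,
            oral_breakdown_time=10.0, decomposition_time=1e9,
            components={"starch_rapid": 30.0},
        )
        plan = MealPlan((MealEvent("m", 0.0, 60.0, (solid,)),))
        mouth = CompartmentState("mouth")
        mouth.solid_particles.append(SolidParticle("biscuit", 30.0, 8.0))
        params = OralParams(saliva_eating=4.0, swallow_size_mm=0.1,
                            swallow_residence_factor=1e9)
        total = 0.0
        for _ in range(60):  # one minute of mastication
            masses, _ = oral_process_and_swallow(mouth, 1.0 / 60, plan, params, REG)
            total += masses.get("water", 0.0) + masses.get("amylase", 0.0)
        assert total == pytest.approx(4.0, rel=1e-9)

    def test_mass_conserved_through_swallowing(self):
        plan = parse_meal_file(SAMPLE)
        mouth = CompartmentState("mouth")
        mouth.solid_particles.append(SolidParticle("drink", 120.0, 0.0))
        masses, particles = oral_process_and_swallow(mouth, 1.0 / 60, plan,
                                                     OralParams(), REG)
        swallowed = sum(masses.values()) + sum(p.mass for p in particles)
        residual = sum(mouth.masses.values()) + sum(
            p.mass for p in mouth.solid_particles
        )
        saliva = 4.0 / 60.0
        assert swallowed + residual == pytest.approx(120.0 + saliva)
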