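"""Serum hormone kinetics, glucose homeostasis, sensations, MMC."""

import math

import numpy as np
import pytest

from gutsim.endocrine import (
    HORMONES,
    GlucoseParams,
    GlucoseState,
    HormoneParams,
    MMCParams,
    MMCState,
    SensationParams,
    SerumState,
    glucose_homeostasis_step,
    hormone_secretion_rates,
    mmc_controller,
    sensation_scores,
    serum_hormone_step,
)

HP = HormoneParams()


def _fit_decay_constant(hormone: str, dt_s: float = 1.0,
                        duration_min: float = 60.0) -> float:
    """Regress the decay constant out of a secretion-free simulation."""
    serum = SerumState()
    serum.levels = {h: 0.0 for h in HORMONES}
    serum.levels[hormone] = 1.0
    zero = {h: 0.0 for h in HORMONES}
    dt = dt_s / 60.0
    times, values = [0.0], [1.0]
    t = 0.0
    while t < duration_min - 1e-9:
        serum_hormone_step(serum, zero, dt, HP)
        t += dt
        times.append(t)
        values.append(serum.levels[hormone])
    slope = np.polyfit(times, np.log(values), 1)[0]
    return -slope


class TestSerumKinetics:
    def test_cck_e_folding_time(self):
        serum = SerumState()
        serum.levels["cck"] = 1.0
        zero = {h: 0.0 for h in HORMONES}
        serum_hormone_step(serum, zero, 3.3, HP)
        assert serum.levels["cck"] == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_constant_secretion_fixed_point(self):
        serum = SerumState()
        s = 0.25
        k = HP.degradation["pyy"]
        serum.levels["pyy"] = s / k
        serum_hormone_step(serum, {"pyy": s}, 7.0, HP)
        assert serum.levels["pyy"] == pytest.approx(s / k, rel=1e-12)

    def test_glp1_decays_faster_than_pyy(self):
        serum = SerumState()
        serum.levels["glp1"] = serum.levels["pyy"] = 1.0
        zero = {h: 0.0 for h in HORMONES}
        serum_hormone_step(serum, zero, 5.0, HP)
        assert serum.levels["glp1"] < serum.levels["pyy"]

    @pytest.mark.parametrize("hormone,k", [
        ("cck", 1.0 / 3.3),
        ("glp1", 1.0 / 2.3),
        ("pyy", 1.0 / 10.0),
        ("gip", 1.0 / 7.2),
        ("ghrelin", 1.0 / 10.0),
        ("motilin", 1.0 / 15.0),
        ("secretin", 1.0 / 2.5),
    ])
    def test_half_life_recovery_within_one_percent(self, hormone, k):
        fitted = _fit_decay_constant(hormone)
        assert fitted == pytest.approx(k, rel=0.01)


class TestSecretionStimuli:
    def test_fasted_state_only_motilin_ghrelin(self):
        stimuli = {"fasted_ramp": 1.0, "duodenal_ph": 7.0, "antral_ph": 2.0}
        rates = hormone_secretion_rates(stimuli, HP)
        for h in HORMONES:
            basal = HP.degradation[h] * HP.baseline[h]
            if h in ("motilin", "ghrelin"):
                assert rates[h] > basal
            else:
                assert rates[h] == pytest.approx(basal, rel=1e-9)

    def test_fat_protein_drives_cck(self):
        quiet = hormone_secretion_rates({"duodenal_ph": 7.0}, HP)
        fed = hormone_secretion_rates(
            {"fat_protein_bb": 0.01, "duodenal_ph": 7.0}, HP
        )
        assert fed["cck"] > quiet["cck"]
        assert fed["glp1"] == pytest.approx(quiet["glp1"])

    def test_ileal_nutrients_drive_brake_hormones(self):
        quiet = hormone_secretion_rates({"duodenal_ph": 7.0}, HP)
        fed = hormone_secretion_rates(
            {"ileal_nutrient": 0.05, "duodenal_ph": 7.0}, HP
        )
        assert fed["glp1"] > quiet["glp1"]
        assert fed["pyy"] > quiet["pyy"]
        assert fed["cck"] == pytest.approx(quiet["cck"])

    def test_duodenal_acid_drives_secretin(self):
        acid = hormone_secretion_rates({"duodenal_ph": 3.0}, HP)
        neutral = hormone_secretion_rates({"duodenal_ph": 7.0}, HP)
        assert acid["secretin"] > neutral["secretin"]

    def test_low_antral_ph_inhibits_gastrin(self):
        fed = {"gastric_volume": 500.0, "gastric_peptide": 0.01,
               "duodenal_ph": 7.0}
        high = hormone_secretion_rates({**fed, "antral_ph": 5.0}, HP)
        low = hormone_secretion_rates({**fed, "antral_ph": 1.0}, HP)
        assert low["gastrin"] < high["gastrin"]


class TestGlucoseHomeostasis:
    def test_basal_fixed_point(self):
        params = GlucoseParams()
        state = GlucoseState(portal=5.0, peripheral=5.0, insulin=10.0)
        for _ in range(600):
            glucose_homeostasis_step(state, 10.0, 0.0, 0.0, 1.0 / 60, params)
        assert state.portal == pytest.approx(5.0, abs=1e-9)
        assert state.peripheral == pytest.approx(5.0, abs=1e-9)
        assert state.insulin == pytest.approx(10.0, abs=1e-9)

    def test_portal_rises_before_peripheral(self):
        params = GlucoseParams()
        state = GlucoseState(portal=5.0, peripheral=5.0, insulin=10.0)
        portal_hit = peripheral_hit = None
        t = 0.0
        for _ in range(60 * 60):
            glucose_homeostasis_step(state, 10.0, 1.0, 0.0, 1.0 / 60, params)
            t += 1.0 / 60
            if portal_hit is None and state.portal > 5.5:
                portal_hit = t
            if peripheral_hit is None and state.peripheral > 5.5:
                peripheral_hit = t
        assert portal_hit is not None and peripheral_hit is not None
        assert portal_hit < peripheral_hit

    def test_delayed_insulin_suppresses_hepatic_output(self):
        params = GlucoseParams()
        suppressed = GlucoseState(portal=5.0, peripheral=5.0, insulin=10.0)
        unsuppressed = GlucoseState(portal=5.0, peripheral=5.0, insulin=10.0)
        glucose_homeostasis_step(suppressed, 40.0, 0.0, 0.0, 1.0, params)
        glucose_homeostasis_step(unsuppressed, 10.0, 0.0, 0.0, 1.0, params)
        assert suppressed.peripheral < unsuppressed.peripheral

    def test_fructose_counts_partially(self):
        params = GlucoseParams()
        a = GlucoseState(portal=5.0, peripheral=5.0, insulin=10.0)
        b = GlucoseState(portal=5.0, peripheral=5.0, insulin=10.0)
        glucose_homeostasis_step(a, 10.0, 1.0, 0.0, 1.0, params)
        glucose_homeostasis_step(b, 10.0, 0.0, 2.0, 1.0, params)
        assert a.portal == pytest.approx(b.portal, rel=1e-9)


class TestSensations:
    def test_empty_stomach_high_ghrelin(self):
        s = sensation_scores(0.0, 3.0, 5.0, SensationParams())
        assert s.fullness == pytest.approx(0.0)
        assert s.hunger > 60.0
        assert s.discomfort == 0.0

    def test_full_stomach_near_scale_top(self):
        s = sensation_scores(750.0, 3.0, 0.1, SensationParams())
        assert s.fullness > 85.0
        assert s.hunger < 10.0

    def test_bounded_scores(self):
        for v in (0.0, 100.0, 5000.0):
            for tone in (3.0, 30.0):
                s = sensation_scores(v, tone, 10.0, SensationParams())
                assert 0.0 <= s.fullness <= 100.0
                assert 0.0 <= s.hunger <= 100.0
                assert 0.0 <= s.discomfort <= 100.0

    def test_discomfort_from_overpressure(self):
        params = SensationParams()
        assert sensation_scores(100.0, 25.0, 0.0, params).discomfort > 0.0


class TestMMC:
    def test_fed_state_is_quiescent(self):
        state = MMCState(fasting_clock=500.0)
        mult = mmc_controller(state, True, 10.0, 1.0, MMCParams(), 4.0)
        assert mult == 1.0
        assert state.phase == 0
        assert state.fasting_clock == 0.0

    def test_prolonged_fast_produces_periodic_bursts(self):
        params = MMCParams()
        state = MMCState()
        burst_minutes = 0
        transitions = 0
        prev = 0
        for _ in range(400):
            mult = mmc_controller(state, False, 1.0, 1.0, params, 4.0)
            if state.phase == 3:
                burst_minutes += 1
                assert mult == 4.0
            if state.phase == 3 and prev == 0:
                transitions += 1
            prev = state.phase
        assert transitions >= 3  # periodic episodes
        assert burst_minutes == pytest.approx(
            transitions * params.phase3_duration, abs=transitions
        )

    def test_low_motilin_blocks_bursts(self):
        state = MMCState(fasting_clock=300.0)
        mult = mmc_controller(state, False, 0.01, 1.0, MMCParams(), 4.0)
        assert mult == 1.0 and state.phase == 0
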