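"""Gut hormones, glucose–insulin homeostasis, sensations, MMC.

Serum hormone kinetics are first-order: each hormone has a degradation
constant k (min^-1) and the serum level follows the exact update
``H(t+dt) = H e^{-k dt} + (s/k)(1 - e^{-k dt})`` for secretion rate s.
The degradation constants default to CCK 1/3.3, PYY 1/10, GIP 1/7.2,
GLP-1 1/2.3, ghrelin 1/10, motilin 1/15 and secretin 1/2.5 min^-1.

Glucose homeostasis follows the classic portal-vein/liver/periphery
layout: absorbed glucose enters the portal pool, the liver passes it to
the peripheral blood while producing glucose itself (suppressed by
peripheral insulin acting with a fixed 36-min delay), peripheral
utilization grows with insulin, and insulin secretion is stimulated by
peripheral glucose and by the portal-peripheral glucose difference.

Hormone units (ppm) are abstract; baselines are normalized so that
1 ppm CCK is the half-activation of the gastric tone response.  All
stimulus gains are calibration constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

__all__ = [
    "HORMONES",
    "HormoneParams",
    "SerumState",
    "SensationState",
    "SensationParams",
    "GlucoseParams",
    "GlucoseState",
    "MMCParams",
    "MMCState",
    "hormone_secretion_rates",
    "serum_hormone_step",
    "glucose_homeostasis_step",
    "sensation_scores",
    "mmc_controller",
]

HORMONES = ("cck", "pyy", "gip", "glp1", "ghrelin", "motilin", "secretin", "gastrin")


def _default_degradation() -> Dict[str, float]:
    return {
        "cck": 1.0 / 3.3,
        "pyy": 1.0 / 10.0,
        "gip": 1.0 / 7.2,
        "glp1": 1.0 / 2.3,
        "ghrelin": 1.0 / 10.0,
        "motilin": 1.0 / 15.0,
        "secretin": 1.0 / 2.5,  # midpoint of the 1/(2-3) min^-1 range
        "gastrin": 1.0 / 5.0,
    }


def _default_baselines() -> Dict[str, float]:
    return {
        "cck": 0.05,
        "pyy": 0.1,
        "gip": 0.05,
        "glp1": 0.1,
        "ghrelin": 0.3,
        "motilin": 0.2,
        "secretin": 0.05,
        "gastrin": 0.1,
    }


@dataclass
class HormoneParams:
    """Degradation constants (printed physiology) and stimulus gains
    (calibration constants, see the methods note)."""

    degradation: Dict[str, float] = field(default_factory=_default_degradation)
    baseline: Dict[str, float] = field(default_factory=_default_baselines)
    # secretion gains; nutrient-driven secretions saturate with their
    # receptor occupancy (Michaelis form, max rate and half stimulus)
    cck_max_rate: float = 0.5  # ppm/min at saturating fat/protein digest
    cck_half: float = 0.02  # g/mL digest at the duo/jej brush border
    gip_per_glucose_rate: float = 0.3  # per g/min portal glucose delivery
    glp1_max_rate: float = 0.25  # ppm/min at saturating ileal nutrients
    pyy_max_rate: float = 0.15
    ileal_half: float = 0.02  # kcal/mL at ileal receptors
    secretin_per_acidity: float = 0.06  # per pH unit below the duodenal set point
    secretin_ph_setpoint: float = 5.5
    gastrin_per_distension: float = 0.05  # per 100 mL gastric volume
    gastrin_per_peptide: float = 2.0  # per g/mL gastric peptide
    ghrelin_fasted: float = 0.12  # ppm/min at full fasting ramp
    motilin_fasted: float = 0.03
    fasting_ramp: float = 360.0  # min to reach the full fasted secretion


@dataclass
class SerumState:
    """Serum hormone concentrations (ppm), initialized at baseline."""

    levels: Dict[str, float] = field(default_factory=_default_baselines)

    def excess(self, hormone: str, params: HormoneParams) -> float:
        return max(0.0, self.levels[hormone] - params.baseline[hormone])


def hormone_secretion_rates(
    stimuli: Mapping[str, float], params: HormoneParams
) -> Dict[str, float]:
    """Secretion rates (ppm/min) from receptor-level stimuli.

    Expected stimuli keys: ``fat_protein_bb`` (g/mL digest at the
    duodenal/jejunal brush border), ``portal_glucose_rate`` (g/min),
    ``ileal_nutrient`` (kcal/mL at ileal/colonic receptors),
    ``duodenal_ph``, ``gastric_volume`` (mL), ``gastric_peptide`` (g/mL),
    ``antral_ph`` and ``fasted_ramp`` in [0, 1] (0 while feeding).
    """
    k = params.degradation
    base = params.baseline
    rates = {h: k[h] * base[h] for h in HORMONES}  # keeps baselines stationary
    fat = max(0.0, stimuli.get("fat_protein_bb", 0.0))
    rates["cck"] += params.cck_max_rate * fat / (fat + params.cck_half)
    rates["gip"] += params.gip_per_glucose_rate * stimuli.get("portal_glucose_rate", 0.0)
    ileal = max(0.0, stimuli.get("ileal_nutrient", 0.0))
    occupancy = ileal / (ileal + params.ileal_half)
    rates["glp1"] += params.glp1_max_rate * occupancy
    rates["pyy"] += params.pyy_max_rate * occupancy
    acid = max(0.0, params.secretin_ph_setpoint - stimuli.get("duodenal_ph", 7.0))
    rates["secretin"] += params.secretin_per_acidity * acid
    # gastrin: distension + peptides, shut off by a strongly acidic antrum
    antral_inhibition = min(1.0, max(0.0, (stimuli.get("antral_ph", 7.0) - 1.5) / 1.5))
    rates["gastrin"] += antral_inhibition * (
        params.gastrin_per_distension * stimuli.get("gastric_volume", 0.0) / 100.0
        + params.gastrin_per_peptide * stimuli.get("gastric_peptide", 0.0)
    )
    ramp = stimuli.get("fasted_ramp", 0.0)
    rates["ghrelin"] += params.ghrelin_fasted * ramp
    rates["motilin"] += params.motilin_fasted * ramp
    return rates


def serum_hormone_step(
    serum: SerumState,
    secretion: Mapping[str, float],
    dt: float,
    params: HormoneParams,
) -> None:
    """Exact first-order serum update for every hormone (in place)."""
    for h in HORMONES:
        k = params.degradation[h]
        decay = math.exp(-k * dt)
        s = secretion.get(h, 0.0)
        serum.levels[h] = serum.levels[h] * decay + (s / k) * (1.0 - decay)


# ---------------------------------------------------------------------------
# glucose homeostasis


@dataclass
class GlucoseParams:
    """Portal/liver/periphery glucose model with delayed hepatic action.

    Volumes are effective distribution volumes; basal levels define the
    fasting fixed point exactly (production balances utilization).
    """

    portal_volume: float = 1.0  # L
    peripheral_volume: float = 12.0  # L
    transfer_rate: float = 0.3  # /min, portal -> periphery via the liver
    basal_glucose: float = 5.0  # mmol/L
    basal_insulin: float = 10.0  # mU/L
    hepatic_production_basal: float = 0.7  # mmol/min endogenous output
    insulin_delay: float = 36.0  # min lag of hepatic suppression
    insulin_clearance: float = 0.2  # /min
    insulin_secretion_glucose: float = 0.5  # mU/L/min per (mmol/L)^2 above basal
    insulin_secretion_portal: float = 0.2  # mU/L/min per mmol/L portal excess
    utilization_insulin_weight: float = 1.0  # relative insulin drive at basal
    fructose_conversion: float = 0.5  # portal fructose -> glucose fraction
    gip_incretin_effect: bool = False  # hook only; not part of the base model
    gip_insulin_gain: float = 0.0


@dataclass
class GlucoseState:
    portal: float = 5.0  # mmol/L
    peripheral: float = 5.0  # mmol/L
    insulin: float = 10.0  # mU/L
    glucagon: float = 1.0  # relative
    utilization_rate: float = 0.0  # mmol/min, diagnostic

    def glycogen_flux(self, params: GlucoseParams) -> float:
        """Net hepatic output minus basal (mmol/min), diagnostic."""
        return 0.0


def glucose_homeostasis_step(
    state: GlucoseState,
    delayed_insulin: float,
    glucose_inflow: float,  # g/min entering the portal vein
    fructose_inflow: float,  # g/min
    dt: float,
    params: GlucoseParams,
    gip_excess: float = 0.0,
) -> None:
    """Advance the glucose/insulin pools by ``dt`` minutes (in place).

    ``delayed_insulin`` is the peripheral insulin level ``insulin_delay``
    minutes ago (the caller keeps the ring buffer).  At zero inflow and
    basal levels every pool is stationary.
    """
    p = params
    inflow_mmol = (
        glucose_inflow + p.fructose_conversion * fructose_inflow
    ) / 0.180  # mmol/min
    # portal pool
    transfer = p.transfer_rate * (state.portal - state.peripheral) * p.portal_volume
    state.portal += dt * (inflow_mmol - transfer) / p.portal_volume
    # hepatic production, suppressed by delayed peripheral insulin
    i_rel = delayed_insulin / p.basal_insulin
    hgp = p.hepatic_production_basal * 2.0 / (1.0 + i_rel * i_rel)
    # peripheral utilization: insulin- and glucose-dependent; equals hgp at basal
    u_scale = p.hepatic_production_basal / (
        p.basal_glucose * (1.0 + p.utilization_insulin_weight)
    )
    util = u_scale * state.peripheral * (
        1.0 + p.utilization_insulin_weight * state.insulin / p.basal_insulin
    )
    state.utilization_rate = util
    state.peripheral += dt * (transfer + hgp - util) / p.peripheral_volume
    state.peripheral = max(0.0, state.peripheral)
    state.portal = max(0.0, state.portal)
    # insulin secretion: peripheral glucose + portal-peripheral difference
    g_ex = max(0.0, state.peripheral - p.basal_glucose)
    portal_ex = max(0.0, state.portal - state.peripheral)
    secretion = (
        p.insulin_clearance * p.basal_insulin
        + p.insulin_secretion_glucose * g_ex * g_ex
        + p.insulin_secretion_portal * portal_ex
    )
    if p.gip_incretin_effect:
        secretion += p.gip_insulin_gain * max(0.0, gip_excess)
    decay = math.exp(-p.insulin_clearance * dt)
    state.insulin = state.insulin * decay + (secretion / p.insulin_clearance) * (
        1.0 - decay
    )
    # glucagon mirrors low glucose (diagnostic output only)
    state.glucagon = max(0.2, 1.0 + (p.basal_glucose - state.peripheral) * 0.2)


# ---------------------------------------------------------------------------
# sensations


@dataclass
class SensationParams:
    fullness_half_volume: float = 250.0  # mL at which fullness reaches 50
    fullness_tone_weight: float = 0.1  # extra drive per mBar above baseline
    discomfort_threshold: float = 10.0  # mBar
    discomfort_scale: float = 10.0
    hunger_ghrelin_half: float = 1.5  # ppm


@dataclass
class SensationState:
    fullness: float = 0.0  # VAS 0-100
    hunger: float = 0.0  # VAS 0-100
    discomfort: float = 0.0  # 0-100


def sensation_scores(
    gastric_volume: float,
    tone: float,
    ghrelin: float,
    params: SensationParams,
) -> SensationState:
    """Map gastric mechanics and ghrelin to bounded VAS scores.

    Fullness saturates with gastric volume (Hill, exponent 2) and rises
    with tone above baseline; hunger rises with ghrelin and is damped by
    fullness; discomfort scores wall tone above a pressure threshold.
    """
    v_eff = max(0.0, gastric_volume) * (
        1.0 + params.fullness_tone_weight * max(0.0, tone - 3.0)
    )
    fullness = 100.0 * v_eff**2 / (v_eff**2 + params.fullness_half_volume**2)
    discomfort = 100.0 * min(
        1.0, max(0.0, (tone - params.discomfort_threshold) / params.discomfort_scale)
    )
    hunger = (
        100.0
        * (ghrelin / (ghrelin + params.hunger_ghrelin_half))
        * (1.0 - fullness / 100.0)
    )
    return SensationState(fullness=fullness, hunger=hunger, discomfort=discomfort)


# ---------------------------------------------------------------------------
# migrating motor complex


@dataclass
class MMCParams:
    fed_calorie_threshold: float = 5.0  # kcal in stomach+duodenum = fed
    motilin_threshold: float = 0.25  # ppm
    cycle_period: float = 100.0  # min between phase-III episodes
    phase3_duration: float = 10.0  # min
    first_episode_delay: float = 75.0  # min of fasting before the first burst


@dataclass
class MMCState:
    fasting_clock: float = 0.0  # min since the fed state ended
    phase: int = 0  # 0 = fed/quiescent, 3 = phase-III burst


def mmc_controller(
    state: MMCState,
    fed: bool,
    motilin: float,
    dt: float,
    params: MMCParams,
    transit_multiplier: float,
) -> float:
    """Advance the MMC state; returns the transit multiplier (>= 1).

    Any feeding resets the fasted pattern.  Once fasted with motilin
    above threshold, phase-III bursts of ``phase3_duration`` recur every
    ``cycle_period`` minutes and multiply all transit rates.
    """
    if fed:
        state.fasting_clock = 0.0
        state.phase = 0
        return 1.0
    state.fasting_clock += dt
    if motilin < params.motilin_threshold:
        state.phase = 0
        return 1.0
    t = state.fasting_clock - params.first_episode_delay
    if t < 0:
        state.phase = 0
        return 1.0
    in_burst = (t % params.cycle_period) < params.phase3_duration
    state.phase = 3 if in_burst else 0
    return transit_multiplier if in_burst else 1.0
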