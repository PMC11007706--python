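"""Three-compartment stomach: secretion, tone, peristalsis, emptying.

The fundus is a pressure reservoir, the corpus receives swallowed food and
gastric juice, and the antrum is the grinding/emptying pump.  The three
exchange volume in a repeating peristaltic cycle (three cycles per
minute); the antrum empties through the pylorus only during the third
part of each cycle, restricted by the feedback factor F built from
emptying-inhibiting stresses (CCK, osmotic deviation, low duodenal pH,
GLP-1, antral viscosity under tone).

Gastric juice is an aqueous solution of 2 % mucus protein, 0.5 % pepsin
and 0.1 M HCl.  Secretion shuts down when the proximal duodenum is too
acidic (the R factor) and when the antrum has reached its target pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

__all__ = [
    "GastricParams",
    "GastricState",
    "gastric_secretion_rate",
    "gastric_juice_masses",
    "gastric_tone",
    "target_antral_volume",
    "emptying_restriction_F",
    "eis_terms",
    "antral_emptying_volume",
    "antral_emptying_rate",
    "grind_factor",
    "mixture_viscosity",
]

CYCLE_PERIOD = 1.0 / 3.0  # min; three peristaltic cycles per minute
PHASE_DURATION = CYCLE_PERIOD / 3.0


def _default_eis_thresholds() -> Dict[str, float]:
    return {"cck": 0.2, "osmotic": 0.05, "ph": 0.0, "glp1": 0.2, "viscosity": 0.0}


def _default_eis_scales() -> Dict[str, float]:
    return {"cck": 0.5, "osmotic": 0.08, "ph": 2.0, "glp1": 0.5, "viscosity": 0.3}


@dataclass
class GastricParams:
    """All constants of the gastric secretion/tone/emptying equations."""

    pH_antrum_target: float = 1.0
    secretion_scale: float = 1.5  # mL/min
    secretion_pH_ref: float = 5.5
    R_pH_ref: float = 2.0
    tone_base: float = 3.0  # mBar
    tone_coeff: float = 0.0117  # mBar/mL
    CCK_ref: float = 1.0  # ppm, half-activation of the tone response
    tone_exponent: float = 4.0
    Va_max: float = 60.0  # mL, maximum antral volume
    VaT_base: float = 5.0  # mL
    tone_half: float = 5.0  # mBar
    p: float = 0.6  # pyloric calibration constant, per cycle-third
    basal_fraction: float = 0.2  # background liquid emptying per cycle-third
    caloric_damping: float = 6.5  # mL/kcal; meters out energy-dense chyme
    viscosity_damping: float = 0.0  # per decade of antral viscosity
    accommodation_factor: float = 0.25  # emptying multiplier while eating
    accommodation_recovery: float = 15.0  # min for relaxation to wear off
    cycle_period: float = CYCLE_PERIOD  # min
    juice_mucus_fraction: float = 0.02
    juice_pepsin_fraction: float = 0.005
    juice_hcl_molar: float = 0.1  # mol/L
    corpus_capacity: float = 250.0  # mL before overflow into the fundus
    fundus_return_rate: float = 30.0  # mL/min back into the corpus
    backflow_fraction: float = 0.3  # antral share returned per cycle
    sieve_mm: float = 2.0  # pyloric sieve size
    eis_threshold: Dict[str, float] = field(default_factory=_default_eis_thresholds)
    eis_scale: Dict[str, float] = field(default_factory=_default_eis_scales)


@dataclass
class GastricState:
    """Derived mechanical state of the stomach."""

    tone: float = 3.0  # mBar
    cycle_time: float = 0.0  # min within the current peristaltic cycle

    @property
    def cycle_phase(self) -> int:
        return min(2, int(self.cycle_time / PHASE_DURATION)) + 1

    def advance(self, dt: float) -> None:
        self.cycle_time = (self.cycle_time + dt) % CYCLE_PERIOD


def gastric_secretion_rate(
    pH_antrum: float, pH_duodenum: float, params: GastricParams
) -> float:
    """Gastric juice flow (mL/min) toward the antral target pH.

    rate = R * 1.5 * (1 - (5.5 - pH_antrum) / (5.5 - pH_target)), clamped
    at zero, with the duodenal protection factor
    R = clamp_[0,1](1 - exp(2 - pH_duodenum)) suppressing secretion when
    the proximal duodenum is acidic.
    """
    r = 1.0 - math.exp(params.R_pH_ref - pH_duodenum)
    r = min(1.0, max(0.0, r))
    bracket = 1.0 - (params.secretion_pH_ref - pH_antrum) / (
        params.secretion_pH_ref - params.pH_antrum_target
    )
    return max(0.0, r * params.secretion_scale * bracket)


def gastric_juice_masses(volume_ml: float, params: GastricParams) -> Dict[str, float]:
    """Component masses (g) of ``volume_ml`` of gastric juice."""
    h = volume_ml / 1000.0 * params.juice_hcl_molar * 1.0  # g of H+ (1 g/mol)
    mucus = volume_ml * params.juice_mucus_fraction
    pepsin = volume_ml * params.juice_pepsin_fraction
    water = volume_ml - mucus - pepsin  # HCl counter-ion mass neglected
    return {
        "water": max(0.0, water),
        "mucus_protein": mucus,
        "pepsin": pepsin,
        "hydrogen_ion": h,
    }


def gastric_tone(v_stomach: float, cck: float, params: GastricParams) -> float:
    """Tonic gastric wall pressure (mBar).

    tone = 3 + 0.0117 * V_stomach * (CCK / (CCK + 1 ppm))^4
    """
    hill = (cck / (cck + params.CCK_ref)) ** params.tone_exponent if cck > 0 else 0.0
    return params.tone_base + params.tone_coeff * v_stomach * hill


def target_antral_volume(tone: float, params: GastricParams) -> float:
    """Target antral volume VaT = 5 + 60 * tone / (5 + tone) mL."""
    return params.VaT_base + params.Va_max * tone / (params.tone_half + tone)


def eis_terms(signals: Mapping[str, float], params: GastricParams) -> Dict[str, float]:
    """Dimensionless emptying-inhibiting stresses from raw signals.

    Each term is ``max(0, (signal - threshold) / scale)`` with per-stimulus
    threshold and scale; a term can be disabled by setting its scale to
    ``inf``.
    """
    out = {}
    for key, value in signals.items():
        thr = params.eis_threshold.get(key, 0.0)
        scale = params.eis_scale.get(key, 1.0)
        out[key] = max(0.0, (value - thr) / scale)
    return out


def emptying_restriction_F(
    eis: Mapping[str, float], params: GastricParams
) -> float:
    """Pyloric restriction F = p / sum(EIS), with the sum floored at 1."""
    total = max(1.0, sum(eis.values()))
    return params.p / total


def antral_emptying_volume(
    v_antrum: float, vat: float, f: float, phase: int
) -> float:
    """Volume (mL) emptied through the pylorus during one cycle-third.

    Nonzero only in phase 3 of the peristaltic cycle; the antrum empties
    its excess over the target volume, J = max(0, V_antrum - VaT) * F.
    """
    if phase != 3:
        return 0.0
    return max(0.0, v_antrum - vat) * f


def antral_emptying_rate(
    v_antrum: float, vat: float, f: float, phase: int
) -> float:
    """Instantaneous pyloric outflow (mL/min) during phase 3."""
    return antral_emptying_volume(v_antrum, vat, f, phase) / PHASE_DURATION


def grind_factor(dt: float, gastric_breakdown_time: float) -> float:
    """Multiplicative particle-size reduction for ``dt`` min of grinding."""
    if gastric_breakdown_time <= 0:
        return 0.0
    return math.exp(-dt / gastric_breakdown_time)


def mixture_viscosity(polymer_concentration: float) -> float:
    """Liquid-phase viscosity (mPa·s) from dissolved polymer content.

    Thickener-dominant power blend: water (1 mPa·s) plus a polymer term
    that grows super-linearly with the summed concentration of dissolved
    polymers (starch, maltodextrin, protein, mucus) in g/mL.
    """
    c = max(0.0, polymer_concentration)
    return 1.0 + (c / 0.01) ** 1.5
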