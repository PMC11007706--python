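"""Secretions, intestinal transit and transport to the brush border.

Covers hepatic bile production and CCK-driven gallbladder emptying (with
enterohepatic recycling of bile salts), pancreatic juice (bicarbonate
driven by secretin, enzymes by CCK), the intestinal bicarbonate/mucus
guess functions, compartment-to-compartment transit with the ileal-brake
slowing and MMC acceleration, and the quasi-steady solution of solute
concentrations at the epithelial surface behind the unstirred mucus
layer (Fick diffusion plus water-flux convection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .core_state import SMALL_INTESTINE

__all__ = [
    "BileParams",
    "GallbladderState",
    "PancreasParams",
    "MucosaParams",
    "TransitParams",
    "hepatic_bile_and_gallbladder_step",
    "pancreatic_secretion_step",
    "intestinal_secretion_step",
    "ileal_brake_factor",
    "transit_outflow_fraction",
    "solve_brush_border_state",
    "solve_brush_border_vector",
]


# ---------------------------------------------------------------------------
# bile


@dataclass
class BileParams:
    """Hepatic bile flow and gallbladder behavior.

    Hepatic production has a salt-independent part (basal + secretin
    driven) and a salt-dependent part proportional to the returning
    (recycled) bile-salt flux.  Fasted bile fills the gallbladder; above
    the CCK threshold the gallbladder empties exponentially into the
    post-Oddi duodenum.
    """

    hepatic_base: float = 0.25  # mL/min, salt-independent
    per_secretin: float = 0.6  # mL/min per ppm secretin above baseline
    per_salt_return: float = 10.0  # mL bile per g returning bile salt
    bile_salt_concentration: float = 0.01  # g salt per mL bile
    gallbladder_capacity: float = 50.0  # mL
    emptying_time_constant: float = 15.0  # min
    cck_threshold: float = 0.3  # ppm
    salt_pool_target: float = 4.0  # g circulating bile-salt pool
    salt_synthesis_rate: float = 0.02  # g/min toward the pool target


@dataclass
class GallbladderState:
    water_mass: float = 19.7  # g water stored as bile
    salt_mass: float = 0.4  # g bile salt in the stored bile
    hepatic_salt_pool: float = 3.6  # g available to the liver

    @property
    def volume(self) -> float:
        return self.water_mass + self.salt_mass / 1.2  # mL (bile salt at 1.2 g/mL)


def hepatic_bile_and_gallbladder_step(
    state: GallbladderState,
    cck: float,
    secretin_excess: float,
    salt_return_rate: float,
    dt: float,
    params: BileParams,
) -> Tuple[Dict[str, float], float]:
    """One bile step; returns (duodenal bile masses in g, de-novo mass g).

    ``salt_return_rate`` is the enterohepatic bile-salt return (g/min)
    from ileal resorption, already credited to ``hepatic_salt_pool`` by
    the caller.  The de-novo mass (secreted water plus newly synthesized
    bile salt) lets the caller keep the global ledger balanced.
    """
    # de novo synthesis keeps the circulating salt pool topped up
    synth = min(
        params.salt_synthesis_rate * dt,
        max(0.0, params.salt_pool_target - state.hepatic_salt_pool
            - state.salt_mass),
    )
    state.hepatic_salt_pool += synth

    flow = (
        params.hepatic_base
        + params.per_secretin * max(0.0, secretin_excess)
        + params.per_salt_return * salt_return_rate
    ) * dt  # mL produced this step
    salt = min(flow * params.bile_salt_concentration, state.hepatic_salt_pool)
    state.hepatic_salt_pool -= salt
    water = max(0.0, flow - salt / 1.2)  # de-novo bile water mass (1 g/mL)

    out_water = 0.0
    out_salt = 0.0
    if cck > params.cck_threshold:
        # fed: hepatic bile passes straight through, gallbladder contracts
        frac = 1.0 - math.exp(-dt / params.emptying_time_constant)
        out_water = water + state.water_mass * frac
        out_salt = salt + state.salt_mass * frac
        state.water_mass *= 1.0 - frac
        state.salt_mass *= 1.0 - frac
    else:
        # fasted: store; overflow trickles into the duodenum
        state.water_mass += water
        state.salt_mass += salt
        if state.volume > params.gallbladder_capacity:
            f = (state.volume - params.gallbladder_capacity) / state.volume
            out_water = state.water_mass * f
            out_salt = state.salt_mass * f
            state.water_mass -= out_water
            state.salt_mass -= out_salt
    return {"water": out_water, "bile_salt": out_salt}, water + synth


# ---------------------------------------------------------------------------
# pancreas


@dataclass
class PancreasParams:
    """Pancreatic juice: secretin-driven bicarbonate, CCK-driven enzymes."""

    water_base: float = 0.4  # mL/min
    water_per_secretin: float = 2.0  # mL/min per ppm above baseline
    water_max: float = 4.5  # mL/min
    bicarbonate_fraction: float = 0.012  # g per mL juice (~140 mM)
    enzyme_base: float = 0.0005  # g/min each of amylase/protease/lipase
    enzyme_per_cck: float = 0.02  # g/min per ppm CCK above baseline
    enzyme_max: float = 0.05  # g/min each
    tracer_rate: float = 0.0002  # g/min tracer peptide


def pancreatic_secretion_step(
    cck_excess: float, secretin_excess: float, dt: float, params: PancreasParams
) -> Dict[str, float]:
    """Masses (g) of pancreatic juice delivered past the sphincter of Oddi."""
    flow = min(
        params.water_max,
        params.water_base + params.water_per_secretin * max(0.0, secretin_excess),
    ) * dt
    bicarb = flow * params.bicarbonate_fraction
    enz = min(
        params.enzyme_max,
        params.enzyme_base + params.enzyme_per_cck * max(0.0, cck_excess),
    ) * dt
    tracer = params.tracer_rate * dt
    return {
        "water": max(0.0, flow - bicarb),
        "bicarbonate": bicarb,
        "amylase": enz,
        "protease": enz,
        "lipase": enz,
        "tracer_peptide": tracer,
    }


# ---------------------------------------------------------------------------
# mucosa: intestinal secretion, mucus barrier, water flux


def _si_thickness() -> Dict[str, float]:
    # mucus thickens distally: ~50 um in the duodenum to ~200 um in the colon
    thick = {}
    for i, name in enumerate(SMALL_INTESTINE):
        thick[name] = 0.005 + 0.010 * i / (len(SMALL_INTESTINE) - 1)  # cm
    return thick


def _si_areas() -> Dict[str, float]:
    # smooth (pre-villi) luminal areas per compartment, cm^2
    areas = {"duodenum_pre_oddi": 200.0, "duodenum_post_oddi": 200.0}
    for name in SMALL_INTESTINE:
        if name.startswith("jejunum"):
            areas[name] = 700.0
        elif name.startswith("ileum"):
            areas[name] = 450.0
    return areas


@dataclass
class MucosaParams:
    """Unstirred-layer and intestinal wall-secretion settings.

    ``villi_enhancement`` multiplies the diffusive mucus permeability to
    fold in the convective stirring by villous motion.  The per-
    compartment water fluxes toward the epithelium sum to
    ``total_water_flux`` (about 9 L/day) and are distributed
    proportionally to compartment area.
    """

    villi_enhancement: float = 3.0
    total_water_flux: float = 6.25  # mL/min over the small intestine (~9 L/day)
    colon_water_flux: float = 1.2  # mL/min
    secretion_base: float = 0.05  # mL/min basal wall secretion per compartment
    secretion_per_secretin: float = 0.25  # mL/min per ppm, per compartment
    secretion_per_ph: float = 0.3  # mL/min per pH unit below 7
    secretion_bicarbonate_fraction: float = 0.01
    secretion_mucus_fraction: float = 0.005
    mucus_thickness: Dict[str, float] = field(default_factory=_si_thickness)
    area: Dict[str, float] = field(default_factory=_si_areas)

    def water_flux(self, compartment: str) -> float:
        total_area = sum(self.area.values())
        return self.total_water_flux * self.area[compartment] / total_area


def intestinal_secretion_step(
    secretin: float, ph_brush: float, dt: float, params: MucosaParams
) -> Dict[str, float]:
    """Gut-wall bicarbonate/mucus guess-function secretion for one unit.

    rate = k1 * secretin + k2 * max(0, 7 - pH at the brush border).
    """
    rate = params.secretion_per_secretin * max(
        0.0, secretin
    ) + params.secretion_per_ph * max(0.0, 7.0 - ph_brush)
    vol = rate * dt
    bic = vol * params.secretion_bicarbonate_fraction
    muc = vol * params.secretion_mucus_fraction
    return {"water": max(0.0, vol - bic - muc), "bicarbonate": bic,
            "mucus_protein": muc}


# ---------------------------------------------------------------------------
# transit


def _default_taus() -> Dict[str, float]:
    taus = {"duodenum_pre_oddi": 15.0, "duodenum_post_oddi": 15.0}
    for name in SMALL_INTESTINE:
        if name.startswith(("jejunum", "ileum")):
            taus[name] = 30.0
    taus["colon"] = 1440.0
    return taus


@dataclass
class TransitParams:
    """Residence times and transit modulation.

    Flow out of compartment i is ``V_i / tau_i * g(PYY, GLP-1) * mmc``
    with the ileal-brake factor ``g = 1/(1 + w_pyy*dPYY + w_glp1*dGLP1)``
    decreasing in the brake hormones and the MMC multiplier > 1 during
    fasted phase-III episodes.
    """

    residence_times: Dict[str, float] = field(default_factory=_default_taus)
    brake_weight_pyy: float = 1.2  # per ppm above baseline
    brake_weight_glp1: float = 0.8
    mmc_multiplier: float = 4.0
    max_step_fraction: float = 0.5  # stability cap on per-step outflow


def ileal_brake_factor(
    pyy_excess: float, glp1_excess: float, params: TransitParams
) -> float:
    """Transit slowdown g in (0, 1]; 1 at baseline hormone levels."""
    return 1.0 / (
        1.0
        + params.brake_weight_pyy * max(0.0, pyy_excess)
        + params.brake_weight_glp1 * max(0.0, glp1_excess)
    )


def transit_outflow_fraction(
    tau: float, g: float, mmc_multiplier: float, dt: float,
    params: TransitParams,
) -> float:
    """Fraction of a compartment's content leaving during ``dt``."""
    rate = g * mmc_multiplier / tau
    return min(params.max_step_fraction, 1.0 - math.exp(-rate * dt))


# ---------------------------------------------------------------------------
# unstirred-layer transport


def solve_brush_border_state(
    c_lum: float,
    diffusivity: float,
    area: float,
    thickness: float,
    water_flux: float,
    uptake: Callable[[float], float],
    iters: int = 60,
) -> Tuple[float, float]:
    """Quasi-steady concentration at the epithelial surface.

    Solves the flux balance through the mucus layer

        (D*A/h) * (C_lum - C_bb) + v_w * C_lum = uptake(C_bb)

    for ``C_bb >= 0`` by monotone bisection (``uptake`` must be
    non-decreasing).  Returns ``(C_bb, delivered flux g/min)``.  With no
    uptake and water flux the surface concentration exceeds the luminal
    one (concentration polarization).
    """
    if diffusivity <= 0 or thickness <= 0:
        raise ValueError("diffusivity and thickness must be > 0")
    if c_lum <= 0:
        return 0.0, 0.0
    km = diffusivity * area / thickness  # mL/min
    supply = km * c_lum + water_flux * c_lum

    def g(c_bb: float) -> float:
        return km * (c_lum - c_bb) + water_flux * c_lum - uptake(c_bb)

    hi = c_lum * (1.0 + water_flux / km) + 1.0e-30
    if g(hi) > 0:  # uptake too weak to pull below the polarization ceiling
        c = hi
    else:
        lo = 0.0
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if g(mid) > 0:
                lo = mid
            else:
                hi = mid
        c = 0.5 * (lo + hi)
    flux = km * (c_lum - c) + water_flux * c_lum
    return c, flux


def solve_brush_border_vector(
    c_lum: np.ndarray,
    km: np.ndarray,
    v_w: np.ndarray,
    vmax: np.ndarray,
    k_half: np.ndarray,
    passive: np.ndarray,
    iters: int = 40,
) -> np.ndarray:
    """Vectorized brush-border solve for Michaelis–Menten plus passive uptake.

    All arrays broadcast; uptake(C) = Vmax*C/(K+C) + passive*C.  Returns
    C_bb with the same shape.
    """
    supply = (km + v_w) * c_lum
    hi = np.where(km > 0, c_lum * (1.0 + v_w / np.maximum(km, 1e-30)), c_lum)
    lo = np.zeros_like(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        g = km * (c_lum - mid) + v_w * c_lum - (
            vmax * mid / (k_half + mid) + passive * mid
        )
        pos = g > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)
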