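"""Simulation engine: per-second linearized stepping, per-minute output.

The engine owns the global state (a compartments-by-components mass
ledger plus solid-particle registers), wires the per-step operator
sequence — consumption, oral processing, gastric mechanics, secretions,
transit, brush-border transport, enzymology, absorption, hormones,
glucose homeostasis, sensations — and records a per-minute time series.
The model is deterministic: identical inputs give identical outputs.

Stage order within a step is fixed: sources before sinks, and the
brush-border solve precedes uptake.  Internal stepping defaults to 1 s;
all slow physiological variables are linearized over that interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import absorption as ab
from . import endocrine as endo
from . import enzymology as enz
from . import gastric as ga
from . import meal_io as mio
from . import secretions_transport as st
from .core_state import (
    COMPARTMENTS,
    SMALL_INTESTINE,
    CompartmentState,
    ComponentRegistry,
    default_registry,
    ph_vector,
)

__all__ = [
    "SimulationConfig",
    "Params",
    "SimulationResult",
    "default_params",
    "load_params",
    "simulate",
    "write_timeseries",
    "read_timeseries",
    "builtin_fixture",
    "FIXTURE_NAMES",
]

# compartment indices
PLATE, MOUTH, FUNDUS, CORPUS, ANTRUM = 0, 1, 2, 3, 4
DUO_PRE, DUO_POST = 5, 6
JEJ = (7, 8, 9)
ILE = (10, 11, 12, 13, 14, 15)
COLON = 16
SI = slice(5, 16)  # the eleven small-intestinal compartments
N_SI = 11


@dataclass
class SimulationConfig:
    """Run settings: internal step (s), duration and output cadence (min)."""

    dt_s: float = 1.0
    duration_min: float = 60.0
    output_cadence_min: float = 1.0
    seed: int = 0  # reserved; the core model is deterministic

    def __post_init__(self) -> None:
        if not (0 < self.dt_s <= 60):
            raise ValueError("dt must be positive and at most 60 s")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")


@dataclass
class Params:
    """Aggregate parameter configuration, one section per model aspect."""

    registry: ComponentRegistry = field(default_factory=default_registry)
    oral: mio.OralParams = field(default_factory=mio.OralParams)
    gastric: ga.GastricParams = field(default_factory=ga.GastricParams)
    bile: st.BileParams = field(default_factory=st.BileParams)
    pancreas: st.PancreasParams = field(default_factory=st.PancreasParams)
    mucosa: st.MucosaParams = field(default_factory=st.MucosaParams)
    transit: st.TransitParams = field(default_factory=st.TransitParams)
    reactions: Tuple[enz.EnzymeReaction, ...] = field(
        default_factory=enz.default_reactions
    )
    brush_reactions: Tuple[enz.EnzymeReaction, ...] = field(
        default_factory=enz.brush_reactions
    )
    absorption: ab.AbsorptionParams = field(
        default_factory=ab.default_absorption_params
    )
    hormones: endo.HormoneParams = field(default_factory=endo.HormoneParams)
    glucose: endo.GlucoseParams = field(default_factory=endo.GlucoseParams)
    sensation: endo.SensationParams = field(default_factory=endo.SensationParams)
    mmc: endo.MMCParams = field(default_factory=endo.MMCParams)
    # brush-border enzyme level profile along the small intestine
    brush_levels: Tuple[float, ...] = (
        0.6, 0.8, 1.0, 1.0, 0.9, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2
    )


def default_params() -> Params:
    return Params()


def load_params(path: str | Path) -> Params:
    """Load a YAML parameter file: sections named per model aspect.

    Each section is a flat mapping onto the fields of the corresponding
    parameter dataclass; dict-valued fields are updated key-wise.
    Example::

        gastric:
          p: 0.5
          eis_scale: {osmotic: 0.3}
        hormones:
          degradation: {secretin: 0.5}
        registry:
          glucose: {caloric_density: 3.9}
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = Params()
    for section, payload in raw.items():
        if section == "registry":
            # per-component overrides of the component specs
            params.registry = params.registry.with_overrides(**payload)
            continue
        if not hasattr(params, section):
            raise ValueError(f"unknown parameter section {section!r}")
        target = getattr(params, section)
        if not isinstance(payload, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        for key, value in payload.items():
            if not hasattr(target, key):
                raise ValueError(f"unknown key {key!r} in section {section!r}")
            current = getattr(target, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(target, key, value)
    return params


@dataclass
class SimulationResult:
    """Per-minute time series plus closing ledgers."""

    frame: pd.DataFrame
    absorbed: Dict[str, float]  # cumulative g per component
    excreted: Dict[str, float]
    mass_balance_drift: float  # relative, over the whole run

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()


# ---------------------------------------------------------------------------
# built-in fixtures


FIXTURE_NAMES = (
    "glucose-ogtt",
    "eelderink-bread",
    "eelderink-pasta",
    "fig4-sequence",
    "fig5-sweep",
)

_GLUCOSE_DRINK = mio.CompoundSpec(
    name="glucose-drink", pH=7.0, state="liquid", viscosity=1.0,
    components={"water": 250.0, "glucose": 50.0},
)
# The bread meal totals 132 g of which 67 g water, 9 g fat and 50 g rapidly
# digestible (gelatinized) starch; the unlisted remainder (6 g) is assigned
# to protein (both semi-solid meals owe their CCK/ileal-brake response to
# the presence of fat and protein).
_BREAD = mio.CompoundSpec(
    name="bread", pH=7.0, state="solid", particle_size=8.0,
    oral_breakdown_time=0.5, gastric_breakdown_time=30.0,
    decomposition_time=20.0,
    components={"water": 67.0, "triglyceride": 9.0, "starch_rapid": 50.0,
                "protein": 6.0},
)
# The pasta meal (119 g = 54 g water, 9 g fat, 50 g starch, 6 g protein)
# differs from bread only through a slower mechanical breakdown.
_PASTA = mio.CompoundSpec(
    name="pasta", pH=7.0, state="solid", particle_size=10.0,
    oral_breakdown_time=0.75, gastric_breakdown_time=45.0,
    decomposition_time=30.0,
    components={"water": 54.0, "triglyceride": 9.0, "starch_rapid": 50.0,
                "protein": 6.0},
)
_SIDE_WATER = mio.CompoundSpec(
    name="water-drink", pH=7.0, state="liquid", viscosity=1.0,
    components={"water": 250.0},
)


def _scaled(compound: mio.CompoundSpec, total: float, name: str) -> mio.CompoundSpec:
    f = total / compound.total_mass
    return replace(
        compound, name=name,
        components={k: v * f for k, v in compound.components.items()},
    )


def builtin_fixture(name: str) -> mio.MealPlan:
    """Built-in meal plans reproducing the reference simulation scenarios."""
    if name == "glucose-ogtt":
        return mio.MealPlan(
            (mio.MealEvent("glucose-ogtt", 0.0, 60.0, (_GLUCOSE_DRINK,)),)
        )
    if name == "eelderink-bread":
        return mio.MealPlan(
            (mio.MealEvent("bread-meal", 0.0, 60.0, (_BREAD, _SIDE_WATER)),)
        )
    if name == "eelderink-pasta":
        return mio.MealPlan(
            (mio.MealEvent("pasta-meal", 0.0, 60.0, (_PASTA,)),)
        )
    if name == "fig4-sequence":
        return mio.MealPlan(
            (
                mio.MealEvent("glucose-ogtt", 0.0, 60.0, (_GLUCOSE_DRINK,)),
                mio.MealEvent("bread-meal", 500.0, 60.0, (_BREAD, _SIDE_WATER)),
                mio.MealEvent("pasta-meal", 1000.0, 60.0, (_PASTA,)),
            )
        )
    if name == "fig5-sweep":
        bread300 = _scaled(_BREAD, 300.0, "bread-portion")
        pasta300 = _scaled(_PASTA, 300.0, "pasta-portion")
        meals = []
        for i in range(8):
            meals.append(
                mio.MealEvent(f"bread-{2**i}", 500.0 * i, float(2**i), (bread300,))
            )
        for i in range(8):
            meals.append(
                mio.MealEvent(f"pasta-{2**i}", 5000.0 + 500.0 * i, float(2**i),
                              (pasta300,))
            )
        return mio.MealPlan(tuple(meals))
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# the simulation proper


# species whose epithelial-surface concentration is solved each step
_BB_ABSORBABLE = (
    "glucose", "fructose", "amino_acid", "peptide", "bile_salt_LCFA_complex",
    "monoglyceride", "fatty_acid", "rare_sugar", "citric_acid",
)
_BB_BRUSH_SUBSTRATES = ("maltose", "sucrose", "maltodextrin")
_BB_SPECIES = _BB_ABSORBABLE + _BB_BRUSH_SUBSTRATES


class _Sim:
    """Mutable simulation state and the per-step operator pipeline."""

    def __init__(self, plan: mio.MealPlan, params: Params, config: SimulationConfig):
        self.plan = plan
        self.p = params
        self.cfg = config
        reg = params.registry
        self.reg = reg
        self.idx = reg.index
        self.ns = len(reg)
        self.rho = reg.density
        self.inv_rho = 1.0 / reg.density
        self.kcal = reg.caloric_density
        self.diff = reg.mucus_diffusivity
        # osmotic weights: mol/L per (g/mL) for small solutes (not water)
        self.osmo_w = np.where(
            (reg.molar_mass <= 2000.0) & (np.arange(self.ns) != self.idx["water"]),
            1000.0 / reg.molar_mass,
            0.0,
        )
        self.polymer_idx = [
            self.idx[n]
            for n in ("starch_rapid", "starch_slow", "maltodextrin", "protein",
                      "mucus_protein")
        ]

        self.M = np.zeros((len(COMPARTMENTS), self.ns))
        self.particles: List[Dict[str, List[float]]] = [
            {} for _ in COMPARTMENTS
        ]  # compound -> [mass, size]
        self.plate = CompartmentState(id="plate")
        self.mouth = CompartmentState(id="mouth")
        self.compounds = mio.plan_compound_index(plan)
        self.cmp_density = {
            n: c.density(reg) for n, c in self.compounds.items()
        }
        self.cmp_kcal = {
            n: (sum(m * reg.caloric_density[self.idx[k]]
                    for k, m in c.components.items()) / c.total_mass
                if c.total_mass > 0 else 0.0)
            for n, c in self.compounds.items()
        }
        self.cmp_fracs = {}
        for n, c in self.compounds.items():
            v = np.zeros(self.ns)
            for k, m in c.components.items():
                v[self.idx[k]] = m / c.total_mass
            self.cmp_fracs[n] = v

        self._init_state()
        self._init_brush_arrays()
        self._init_transit_arrays()

        # serum & systemic state
        self.serum = endo.SerumState()
        self.glucose = endo.GlucoseState(
            portal=params.glucose.basal_glucose,
            peripheral=params.glucose.basal_glucose,
            insulin=params.glucose.basal_insulin,
        )
        dt = config.dt_s / 60.0
        n_delay = max(1, int(round(params.glucose.insulin_delay / dt)))
        self.insulin_buffer = np.full(n_delay, params.glucose.basal_insulin)
        self.insulin_ptr = 0
        self.gb = st.GallbladderState()
        self.gstate = ga.GastricState()
        self.mmc = endo.MMCState(fasting_clock=params.mmc.first_episode_delay)
        self.salt_return_rate = 0.0

        # ledgers
        self.inputs_cum = self._system_mass()  # opening stock counts as input
        self.absorbed = np.zeros(self.ns)
        self.excreted = np.zeros(self.ns)
        self.C_bb = np.zeros((N_SI, len(_BB_SPECIES)))
        self.g_factor = np.ones(N_SI)
        self.t_kcal = np.zeros(N_SI)
        self.pH = np.full(len(COMPARTMENTS), 7.0)
        self.pH[CORPUS] = 2.0
        self.pH[ANTRUM] = 2.0
        self.t = 0.0
        self.steps = 0

        # per-cadence accumulators
        self.acc_empty_vol = 0.0
        self.acc_empty_kcal = 0.0
        self.acc_secretion = {"gastric": 0.0, "bile": 0.0, "pancreas": 0.0,
                              "saliva": 0.0, "intestinal": 0.0}
        self.acc_absorbed_kcal = 0.0
        self.mmc_multiplier = 1.0
        self.portal_glucose_rate = 0.0
        self.portal_fructose_rate = 0.0
        self.last_eating_t = -1.0e9  # no meal eaten yet
        self.tone = params.gastric.tone_base
        self.vat = ga.target_antral_volume(self.tone, params.gastric)
        self.F = params.gastric.p
        self.sens = endo.SensationState()

    # -- initialisation -----------------------------------------------------

    def _init_state(self) -> None:
        i = self.idx
        M = self.M
        M[MOUTH, i["water"]] = 1.0
        M[FUNDUS, i["water"]] = 2.0
        M[CORPUS, i["water"]] = 20.0
        M[CORPUS, i["hydrogen_ion"]] = 2.0e-4  # ~pH 2 residual acid
        M[ANTRUM, i["water"]] = 5.0
        M[ANTRUM, i["hydrogen_ion"]] = 5.0e-5
        for c in range(DUO_PRE, COLON):
            M[c, i["water"]] = 8.0
            M[c, i["bicarbonate"]] = 0.02
        M[COLON, i["water"]] = 150.0
        M[COLON, i["mucus_protein"]] = 2.0

    def _init_brush_arrays(self) -> None:
        reg, p = self.reg, self.p
        nb = len(_BB_SPECIES)
        self.bb_idx = np.array([self.idx[s] for s in _BB_SPECIES])
        thick = np.array(
            [p.mucosa.mucus_thickness[c] for c in SMALL_INTESTINE]
        )
        area = np.array([p.mucosa.area[c] for c in SMALL_INTESTINE])
        diff = reg.mucus_diffusivity[self.bb_idx] * p.mucosa.villi_enhancement
        self.bb_km = diff[None, :] * area[:, None] / thick[:, None]  # (11, nb) mL/min
        self.vw = np.array([p.mucosa.water_flux(c) for c in SMALL_INTESTINE])
        vmax = np.zeros(nb)
        khalf = np.full(nb, 1.0)
        passive = np.zeros(nb)
        for j, s in enumerate(_BB_ABSORBABLE):
            spec = p.absorption.pathways.get(s)
            if spec:
                vmax[j], khalf[j], passive[j] = spec.vmax, spec.km, spec.passive
        n_abs = len(_BB_ABSORBABLE)
        self.abs_vmax = vmax[:n_abs]
        self.abs_khalf = khalf[:n_abs]
        self.abs_passive = passive[:n_abs]
        self.levels = np.array(p.brush_levels)
        # aggregate brush-enzyme consumption per substrate for the C_bb solve
        self.bb_uptake_vmax = np.zeros((N_SI, nb))
        self.bb_uptake_k = khalf.copy()
        self.bb_uptake_passive = np.tile(passive, (N_SI, 1))
        self.bb_uptake_vmax[:, : len(_BB_ABSORBABLE)] = vmax[None,
                                                            : len(_BB_ABSORBABLE)]
        for r in p.brush_reactions:
            j = _BB_SPECIES.index(r.substrate)
            self.bb_uptake_vmax[:, j] += self.levels * r.vmax
            self.bb_uptake_k[j] = r.km
        self.bb_kcal = self.kcal[self.bb_idx]
        self.m_max = np.full(N_SI, p.absorption.m_max)

    def _init_transit_arrays(self) -> None:
        taus = self.p.transit.residence_times
        self.transit_tau = np.array(
            [taus[c] for c in COMPARTMENTS[DUO_PRE:COLON + 1]]
        )
        areas = self.p.mucosa.area
        self.si_names = SMALL_INTESTINE

    # -- bookkeeping --------------------------------------------------------

    def _particle_mass(self, c: int) -> float:
        return sum(v[0] for v in self.particles[c].values())

    def _particle_volume(self, c: int) -> float:
        return sum(v[0] / self.cmp_density[k] for k, v in self.particles[c].items())

    def _particle_kcal(self, c: int) -> float:
        return sum(v[0] * self.cmp_kcal[k] for k, v in self.particles[c].items())

    def _system_mass(self) -> float:
        total = float(self.M.sum())
        for c in range(len(COMPARTMENTS)):
            total += self._particle_mass(c)
        total += sum(p.mass for p in self.plate.solid_particles)
        total += sum(self.mouth.masses.values())
        total += sum(p.mass for p in self.mouth.solid_particles)
        total += self.gb.water_mass + self.gb.salt_mass + self.gb.hepatic_salt_pool
        return total

    def mass_drift(self) -> float:
        stock = (
            self._system_mass() + float(self.absorbed.sum())
            + float(self.excreted.sum())
        )
        return abs(stock - self.inputs_cum) / max(1.0, self.inputs_cum)

    def _volumes(self) -> np.ndarray:
        v = self.M @ self.inv_rho
        for c in range(len(COMPARTMENTS)):
            if self.particles[c]:
                v[c] += self._particle_volume(c)
        for p in self.plate.solid_particles:
            v[PLATE] += p.mass / self.cmp_density[p.compound]
        return v

    def _merge_particle(self, c: int, compound: str, mass: float, size: float) -> None:
        if mass <= 0:
            return
        reg = self.particles[c]
        if compound in reg:
            m0, s0 = reg[compound]
            reg[compound] = [m0 + mass, (m0 * s0 + mass * size) / (m0 + mass)]
        else:
            reg[compound] = [mass, size]

    def _move_particles(self, src: int, dst: int, fraction: float,
                        only_below: float | None = None) -> float:
        """Move a mass fraction of (optionally sub-sieve) particles.

        ``dst = -1`` excretes the moved mass (split per the compound's
        composition).  Returns the moved caloric mass (kcal).
        """
        moved_kcal = 0.0
        reg = self.particles[src]
        for name in list(reg):
            mass, size = reg[name]
            if only_below is not None and size >= only_below:
                continue
            dm = mass * fraction
            if dm <= 0:
                continue
            reg[name][0] = mass - dm
            if dst >= 0:
                self._merge_particle(dst, name, dm, size)
            else:
                self.excreted += dm * self.cmp_fracs[name]
            moved_kcal += dm * self.cmp_kcal[name]
            if reg[name][0] < 1.0e-12:
                del reg[name]
        return moved_kcal

    # -- pipeline stages ----------------------------------------------------

    def _stage_consume(self, dt: float) -> None:
        for meal in self.plan.meals:
            if self.t - dt < meal.start_time <= self.t:
                mio.load_plate(
                    mio.MealPlan((meal,)), meal.start_time, dt, self.plate
                )
                self.inputs_cum += meal.total_mass
        mio.consumption_step(self.plan, self.t, dt, self.plate, self.mouth,
                             self.reg)

    def _stage_oral(self, dt: float) -> None:
        if self.plate.solid_particles or self.mouth.solid_particles:
            self.last_eating_t = self.t
        eating = bool(self.mouth.solid_particles)
        saliva = (self.p.oral.saliva_eating if eating
                  else self.p.oral.saliva_basal) * dt
        self.inputs_cum += saliva
        self.acc_secretion["saliva"] += saliva
        bolus_masses, bolus_particles = mio.oral_process_and_swallow(
            self.mouth, dt, self.plan, self.p.oral, self.reg
        )
        row = self.M[CORPUS]
        for name, mass in bolus_masses.items():
            row[self.idx[name]] += mass
        for part in bolus_particles:
            self._merge_particle(CORPUS, part.compound, part.mass, part.size)

    def _stage_gastric(self, dt: float, volumes: np.ndarray) -> None:
        gp = self.p.gastric
        # secretion toward the antral pH target, shut down by duodenal acid
        rate = ga.gastric_secretion_rate(self.pH[ANTRUM], self.pH[DUO_PRE], gp)
        vol = rate * dt
        if vol > 0:
            juice = ga.gastric_juice_masses(vol, gp)
            for name, mass in juice.items():
                self.M[CORPUS, self.idx[name]] += mass
            added = sum(juice.values())
            self.inputs_cum += added
            self.acc_secretion["gastric"] += vol

        v_stomach = volumes[FUNDUS] + volumes[CORPUS] + volumes[ANTRUM]
        self.tone = ga.gastric_tone(v_stomach, self.serum.levels["cck"], gp)
        self.vat = ga.target_antral_volume(self.tone, gp)
        self.gstate.tone = self.tone

        # exact overlap of this step with the pumping (1-2) and emptying
        # (3) parts of the peristaltic cycle, so halving the step leaves
        # the integrated mechanics unchanged
        dt12, dt3 = _phase_overlaps(self.gstate.cycle_time, dt)
        v_corpus = self.M[CORPUS] @ self.inv_rho + self._particle_volume(CORPUS)
        v_antrum = self.M[ANTRUM] @ self.inv_rho + self._particle_volume(ANTRUM)
        v_fundus = self.M[FUNDUS] @ self.inv_rho + self._particle_volume(FUNDUS)

        # fundus as pressure reservoir: corpus overflow in, slow return out
        if v_corpus > gp.corpus_capacity:
            f = (v_corpus - gp.corpus_capacity) / v_corpus
            self.M[FUNDUS] += self.M[CORPUS] * f
            self.M[CORPUS] *= 1.0 - f
            self._move_particles(CORPUS, FUNDUS, f)
            v_fundus += (v_corpus - gp.corpus_capacity)
            v_corpus = gp.corpus_capacity
        elif v_fundus > 0.2:
            back = min(v_fundus - 0.2, gp.fundus_return_rate * dt,
                       gp.corpus_capacity - v_corpus)
            if back > 0:
                f = back / v_fundus
                self.M[CORPUS] += self.M[FUNDUS] * f
                self.M[FUNDUS] *= 1.0 - f
                self._move_particles(FUNDUS, CORPUS, f)
                v_corpus += back

        if dt12 > 0.0:
            # corpus pumps chyme toward the maximum antral volume; the
            # excess over the (tone-dependent) target is what empties
            deficit = max(0.0, gp.Va_max - v_antrum)
            move = min(v_corpus, deficit * dt12 / (2.0 * ga.PHASE_DURATION))
            if move > 0 and v_corpus > 0:
                f = move / v_corpus
                self.M[ANTRUM] += self.M[CORPUS] * f
                self.M[CORPUS] *= 1.0 - f
                self._move_particles(CORPUS, ANTRUM, f)
                v_antrum += move
        if dt3 > 0.0:
            # phase 3: partial backflow grinds antral solids ...
            for name, (mass, size) in list(self.particles[ANTRUM].items()):
                tau = self.compounds[name].gastric_breakdown_time
                self.particles[ANTRUM][name][1] = size * ga.grind_factor(dt3, tau)
            back = v_antrum * gp.backflow_fraction * dt3 / ga.PHASE_DURATION
            if back > 0 and v_antrum > 0:
                f = min(0.9, back / v_antrum)
                self.M[CORPUS] += self.M[ANTRUM] * f
                self.M[ANTRUM] *= 1.0 - f
                self._move_particles(ANTRUM, CORPUS, f)
                v_antrum *= 1.0 - f

            # ... and the antrum empties its excess through the pylorus
            eis_signals = self._eis_signals()
            terms = ga.eis_terms(eis_signals, gp)
            self.F = ga.emptying_restriction_F(terms, gp)
            vat_eff = self.vat
            if self.mmc.phase == 3:
                # fasted phase-III burst sweeps the stomach clean
                vat_eff = gp.VaT_base
            j_cycle = ga.antral_emptying_volume(v_antrum, vat_eff, self.F, 3)
            # background emptying of liquids below the target volume; the
            # same pyloric restriction throttles it (one valve), with a
            # soft square-root coupling so fasted residues still clear
            j_cycle += gp.basal_fraction * v_antrum * math.sqrt(self.F / gp.p)
            # duodenal caloric receptors damp volume outflow by the energy
            # density of the chyme, so plain fluids empty fast while
            # energy-dense chyme is metered out
            if v_antrum > 1.0e-9:
                cal_density = (
                    float(self.M[ANTRUM] @ self.kcal) + self._particle_kcal(ANTRUM)
                ) / v_antrum
            else:
                cal_density = 0.0
            j_cycle /= 1.0 + gp.caloric_damping * cal_density
            # viscous chyme resists antral sieving and pyloric flow
            liq = self.M[ANTRUM] @ self.inv_rho
            poly = float(self.M[ANTRUM, self.polymer_idx].sum())
            visc = ga.mixture_viscosity(poly / liq if liq > 1e-9 else 0.0)
            j_cycle /= 1.0 + gp.viscosity_damping * math.log10(visc)
            # receptive relaxation: while a meal is being eaten the fundus
            # accommodates and pyloric outflow is suppressed; the
            # relaxation wears off smoothly after the last bite
            since = self.t - self.last_eating_t
            if since < 5.0 * gp.accommodation_recovery:
                recovery = 1.0 - math.exp(-since / gp.accommodation_recovery)
                j_cycle *= gp.accommodation_factor + (
                    1.0 - gp.accommodation_factor
                ) * recovery
            empty_vol = j_cycle * dt3 / ga.PHASE_DURATION
            liquid_vol = self.M[ANTRUM] @ self.inv_rho
            passable_pvol = sum(
                m / self.cmp_density[k]
                for k, (m, s) in self.particles[ANTRUM].items()
                if s < gp.sieve_mm
            )
            passable = liquid_vol + passable_pvol
            if empty_vol > 0 and passable > 0:
                f = min(0.9, empty_vol / passable)
                moved = self.M[ANTRUM] * f
                self.M[DUO_PRE] += moved
                self.M[ANTRUM] -= moved
                kcal = float(moved @ self.kcal)
                kcal += self._move_particles(ANTRUM, DUO_PRE, f,
                                             only_below=gp.sieve_mm)
                self.acc_empty_vol += f * passable
                self.acc_empty_kcal += kcal
        self.gstate.advance(dt)

    def _eis_signals(self) -> Dict[str, float]:
        # osmotic load sensed by the duodenum and first jejunal unit (the
        # osmoreceptor-dense proximal small intestine), volume-weighted
        # secreted fluids are isotonic electrolyte solutions, so the
        # deviation from isotonicity equals the nutrient osmolarity on top
        # of that background
        prox = self.M[DUO_PRE:JEJ[0] + 1]
        v_duo = float((prox @ self.inv_rho).sum())
        osm = float(prox.sum(axis=0) @ self.osmo_w) / v_duo if v_duo > 1e-9 else 0.0
        v_ant = self.M[ANTRUM] @ self.inv_rho
        if v_ant > 1.0e-9:
            poly_c = float(self.M[ANTRUM, self.polymer_idx].sum()) / v_ant
        else:
            poly_c = 0.0
        visc = ga.mixture_viscosity(poly_c)
        return {
            "cck": self.serum.levels["cck"],
            "osmotic": osm,
            "ph": max(0.0, 5.0 - self.pH[DUO_PRE]),
            "glp1": self.serum.levels["glp1"],
            "viscosity": math.log10(max(1.0, visc))
            * self.tone
            / self.p.gastric.tone_half,
        }

    def _stage_secretions(self, dt: float) -> None:
        hp = self.p.hormones
        cck = self.serum.levels["cck"]
        secretin_ex = self.serum.excess("secretin", hp)
        cck_ex = self.serum.excess("cck", hp)

        bile, created = st.hepatic_bile_and_gallbladder_step(
            self.gb, cck, secretin_ex, self.salt_return_rate, dt, self.p.bile
        )
        self.inputs_cum += created
        for name, mass in bile.items():
            self.M[DUO_POST, self.idx[name]] += mass
        self.acc_secretion["bile"] += bile.get("water", 0.0)

        panc = st.pancreatic_secretion_step(cck_ex, secretin_ex, dt,
                                            self.p.pancreas)
        for name, mass in panc.items():
            self.M[DUO_POST, self.idx[name]] += mass
        self.inputs_cum += sum(panc.values())
        self.acc_secretion["pancreas"] += panc["water"] + panc["bicarbonate"]

        # intestinal bicarbonate/mucus guess functions, vectorized over the SI
        mp = self.p.mucosa
        rate = mp.secretion_base + mp.secretion_per_secretin * max(
            0.0, secretin_ex
        ) + mp.secretion_per_ph * np.maximum(0.0, 7.0 - self.pH[SI])
        vols = rate * dt
        bic = vols * mp.secretion_bicarbonate_fraction
        muc = vols * mp.secretion_mucus_fraction
        wat = vols - bic - muc
        self.M[SI, self.idx["water"]] += wat
        self.M[SI, self.idx["bicarbonate"]] += bic
        self.M[SI, self.idx["mucus_protein"]] += muc
        total = float(vols.sum())
        self.inputs_cum += total
        self.acc_secretion["intestinal"] += total

        # instant acid-base neutralization (products booked as water)
        h = self.M[:, self.idx["hydrogen_ion"]]
        b = self.M[:, self.idx["bicarbonate"]]
        mol = np.minimum(h, b / 61.0)
        np.maximum(mol, 0.0, out=mol)
        h -= mol
        b -= 61.0 * mol
        self.M[:, self.idx["water"]] += 62.0 * mol

    def _stage_decompose(self, dt: float) -> None:
        for c in range(FUNDUS, COLON + 1):
            reg = self.particles[c]
            if not reg:
                continue
            row = self.M[c]
            for name in list(reg):
                spec = self.compounds[name]
                tau = spec.decomposition_time
                if tau <= 0:
                    frac = 1.0
                else:
                    # surface-limited release: grinding below the pyloric
                    # sieve size exposes more area per mass and release
                    # accelerates accordingly
                    size = reg[name][1]
                    sieve = self.p.gastric.sieve_mm
                    speedup = max(1.0, sieve / max(size, 0.05))
                    frac = 1.0 - math.exp(-dt * speedup / tau)
                released = reg[name][0] * frac
                if released > 0:
                    row += released * self.cmp_fracs[name]
                    reg[name][0] -= released
                if reg[name][0] < 1.0e-12:
                    del reg[name]

    def _stage_transit(self, dt: float, volumes: np.ndarray) -> None:
        tp = self.p.transit
        hp = self.p.hormones
        fed = self._fed_state()
        self.mmc_multiplier = endo.mmc_controller(
            self.mmc, fed, self.serum.levels["motilin"], dt, self.p.mmc,
            tp.mmc_multiplier,
        )
        g = st.ileal_brake_factor(
            self.serum.excess("pyy", hp), self.serum.excess("glp1", hp), tp
        )
        rate = g * self.mmc_multiplier / self.transit_tau
        frac = np.minimum(tp.max_step_fraction, 1.0 - np.exp(-rate * dt))
        # simultaneous update, proximal to distal, with precomputed outflows
        outflows = self.M[DUO_PRE:COLON + 1] * frac[:, None]
        self.M[DUO_PRE:COLON + 1] -= outflows
        self.M[DUO_PRE + 1:COLON + 1] += outflows[:-1]
        self.excreted += outflows[-1]
        for k, c in enumerate(range(DUO_PRE, COLON + 1)):
            if self.particles[c]:
                dst = c + 1 if c < COLON else -1
                self._move_particles(c, dst, float(frac[k]))

    def _fed_state(self) -> bool:
        kcal = 0.0
        for c in (FUNDUS, CORPUS, ANTRUM, DUO_PRE, DUO_POST):
            kcal += float(self.M[c] @ self.kcal) + self._particle_kcal(c)
        return kcal > self.p.mmc.fed_calorie_threshold

    def _stage_brush_and_absorb(self, dt: float, volumes: np.ndarray) -> None:
        v = np.maximum(volumes[SI], 1.0e-9)
        conc = self.M[SI][:, self.bb_idx] / v[:, None]
        # the epithelium actually takes the G-corrected (realized) uptake,
        # so the quasi-steady surface balance uses last step's competition
        # factor; under overload the surface concentration then rises above
        # the luminal one (concentration polarization)
        nb_abs0 = len(_BB_ABSORBABLE)
        vmax_eff = self.bb_uptake_vmax.copy()
        vmax_eff[:, :nb_abs0] *= self.g_factor[:, None]
        passive_eff = self.bb_uptake_passive.copy()
        passive_eff[:, :nb_abs0] *= self.g_factor[:, None]
        self.C_bb = st.solve_brush_border_vector(
            conc, self.bb_km, self.vw[:, None], vmax_eff,
            self.bb_uptake_k[None, :], passive_eff, iters=30,
        )

        # brush-border digestion at the epithelial surface concentration
        rare_idx = _BB_SPECIES.index("rare_sugar")
        rare_c = self.C_bb[:, rare_idx]
        water = self.M[SI, self.idx["water"]]
        for r in self.p.brush_reactions:
            j = _BB_SPECIES.index(r.substrate)
            c_sub = self.C_bb[:, j]
            alpha = np.ones(N_SI)
            alpha_u = np.ones(N_SI)
            for comp, ki, mode in r.inhibitors:
                cc = rare_c if comp == "rare_sugar" else 0.0
                if mode == "competitive":
                    alpha = alpha + cc / ki
                else:
                    alpha_u = alpha_u + cc / ki
            vrate = self.levels * r.vmax * c_sub / (r.km * alpha + c_sub * alpha_u)
            converted = np.minimum(vrate * dt, self.M[SI, self.idx[r.substrate]])
            if r.water_uptake > 0:
                converted = np.minimum(converted, water / r.water_uptake)
            if converted.max() <= 0:
                continue
            self.M[SI, self.idx[r.substrate]] -= converted
            if r.water_uptake > 0:
                self.M[SI, self.idx["water"]] -= converted * r.water_uptake
                water = self.M[SI, self.idx["water"]]
            produced = converted * (1.0 + r.water_uptake)
            for comp, fr in r.products:
                self.M[SI, self.idx[comp]] += produced * fr

        # transporter absorption with the caloric competition factor G
        nb_abs = len(_BB_ABSORBABLE)
        c_abs = self.C_bb[:, :nb_abs]
        rates = (
            self.abs_vmax[None, :] * c_abs / (self.abs_khalf[None, :] + c_abs)
            + self.abs_passive[None, :] * c_abs
        )  # g/min, uncompeted
        t_kcal = rates @ self.bb_kcal[:nb_abs]
        g_fac = self.m_max / (t_kcal + self.m_max)
        realized = rates * g_fac[:, None] * dt
        avail = self.M[SI][:, self.bb_idx[:nb_abs]]
        realized = np.minimum(realized, avail)
        self.M[SI][:, self.bb_idx[:nb_abs]] -= realized
        taken = realized.sum(axis=0)
        self.absorbed[self.bb_idx[:nb_abs]] += taken
        kcal_absorbed = float((realized * self.bb_kcal[None, :nb_abs]).sum())
        self.acc_absorbed_kcal += kcal_absorbed
        self.g_factor = g_fac
        self.t_kcal = t_kcal

        # micellar uptake recycles its bile-salt share to the liver
        j_cx = _BB_ABSORBABLE.index("bile_salt_LCFA_complex")
        salt_back = float(taken[j_cx]) * self.p.absorption.complex_salt_fraction
        # ileal bile-salt resorption (enterohepatic loop)
        ile_rows = list(ILE)
        salt_idx = self.idx["bile_salt"]
        resorb = self.M[ile_rows, salt_idx] * (
            1.0 - math.exp(-self.p.absorption.ileal_salt_resorption * dt)
        )
        self.M[ile_rows, salt_idx] -= resorb
        salt_back += float(resorb.sum())
        self.gb.hepatic_salt_pool += salt_back
        self.salt_return_rate = salt_back / dt
        # the complex's fatty-acid share counts as absorbed; its salt share
        # returned to the pool must leave the absorbed ledger again
        self.absorbed[self.bb_idx[j_cx]] -= float(taken[j_cx]) * \
            self.p.absorption.complex_salt_fraction

        # water absorption: baseline epithelial flux + osmotic co-absorption
        w_idx = self.idx["water"]
        kcal_per_comp = (realized * self.bb_kcal[None, :nb_abs]).sum(axis=1)
        w_take = self.vw * dt + self.p.absorption.water_per_kcal * kcal_per_comp
        # epithelial water uptake stops at a residual film so fasted
        # compartments do not run dry
        w_take = np.minimum(w_take, np.maximum(0.0, self.M[SI, w_idx] - 3.0))
        self.M[SI, w_idx] -= w_take
        self.absorbed[w_idx] += float(w_take.sum())
        colon_w = min(self.p.mucosa.colon_water_flux * dt,
                      max(0.0, self.M[COLON, w_idx] - 30.0))
        self.M[COLON, w_idx] -= colon_w
        self.absorbed[w_idx] += colon_w

        # portal nutrient delivery rates for the glucose model and GIP
        self.portal_glucose_rate = float(
            taken[_BB_ABSORBABLE.index("glucose")]
        ) / dt
        self.portal_fructose_rate = float(
            taken[_BB_ABSORBABLE.index("fructose")]
        ) / dt

    def _stage_luminal_enzymes(self, dt: float, volumes: np.ndarray) -> None:
        v = np.maximum(volumes, 1.0e-9)
        rare_c = self.M[:, self.idx["rare_sugar"]] / v
        bs_c = self.M[:, self.idx["bile_salt"]] / v
        bile_boost = 1.0 + 4.0 * bs_c / (bs_c + 0.002)
        water = self.M[:, self.idx["water"]]
        for r in self.p.reactions:
            s_idx = self.idx[r.substrate]
            e_idx = self.idx[r.enzyme]
            s_mass = self.M[:, s_idx]
            if s_mass.max() <= 1.0e-12:
                continue
            e_mass = self.M[:, e_idx]
            s_conc = s_mass / v
            alpha = np.ones_like(s_conc)
            alpha_u = np.ones_like(s_conc)
            for comp, ki, mode in r.inhibitors:
                cc = rare_c if comp == "rare_sugar" else 0.0
                if mode == "competitive":
                    alpha = alpha + cc / ki
                else:
                    alpha_u = alpha_u + cc / ki
            vrate = e_mass * r.vmax * s_conc / (r.km * alpha + s_conc * alpha_u)
            vrate = vrate * _ph_activity_vec(self.pH, r.ph_window)
            if r.bile_enhanced:
                vrate = vrate * bile_boost
            converted = np.minimum(vrate * dt, s_mass)
            if r.water_uptake > 0:
                converted = np.minimum(converted, water / r.water_uptake)
            if converted.max() <= 0:
                continue
            self.M[:, s_idx] -= converted
            if r.water_uptake > 0:
                self.M[:, self.idx["water"]] -= converted * r.water_uptake
                water = self.M[:, self.idx["water"]]
            produced = converted * (1.0 + r.water_uptake)
            for comp, fr in r.products:
                self.M[:, self.idx[comp]] += produced * fr

        # free long-chain fatty acids pair with bile salts into micelles
        fa = self.M[:, self.idx["fatty_acid"]]
        bs = self.M[:, self.idx["bile_salt"]]
        q = np.minimum(fa, 5.0 * bs)  # complex = 5 parts FA + 1 part salt
        np.maximum(q, 0.0, out=q)
        self.M[:, self.idx["fatty_acid"]] -= q
        self.M[:, self.idx["bile_salt"]] -= q / 5.0
        self.M[:, self.idx["bile_salt_LCFA_complex"]] += q * 1.2

    def _stage_systemic(self, dt: float, volumes: np.ndarray) -> None:
        hp = self.p.hormones
        # receptor stimuli
        duo_jej = [DUO_POST, JEJ[0], JEJ[1]]
        fat_protein = 0.0
        for c in duo_jej:
            k = c - DUO_PRE
            for s in ("peptide", "amino_acid", "monoglyceride", "fatty_acid",
                      "bile_salt_LCFA_complex"):
                fat_protein += self.C_bb[k, _BB_SPECIES.index(s)]
        fat_protein /= len(duo_jej)
        # L-cell receptor field: distal jejunum, ileum and colon sense the
        # luminal caloric concentration (intact fat included)
        ile_nut = 0.0
        lcell = (JEJ[2],) + ILE
        for c in lcell:
            v_c = max(volumes[c], 1.0e-9)
            ile_nut += (float(self.M[c] @ self.kcal)
                        + self._particle_kcal(c)) / v_c
        v_colon = max(volumes[COLON], 1.0e-9)
        ile_nut = ile_nut / len(lcell) + 0.5 * float(
            self.M[COLON] @ self.kcal
        ) / v_colon
        v_stomach = volumes[FUNDUS] + volumes[CORPUS] + volumes[ANTRUM]
        v_ca = max(volumes[CORPUS] + volumes[ANTRUM], 1.0e-9)
        pep_c = (self.M[CORPUS, self.idx["peptide"]]
                 + self.M[ANTRUM, self.idx["peptide"]]) / v_ca
        ramp = 0.0 if self._fed_state() else min(
            1.0, self.mmc.fasting_clock / hp.fasting_ramp
        )
        stimuli = {
            "fat_protein_bb": fat_protein,
            "portal_glucose_rate": self.portal_glucose_rate,
            "ileal_nutrient": ile_nut,
            "duodenal_ph": float(self.pH[DUO_PRE]),
            "gastric_volume": v_stomach,
            "gastric_peptide": pep_c,
            "antral_ph": float(self.pH[ANTRUM]),
            "fasted_ramp": ramp,
        }
        rates = endo.hormone_secretion_rates(stimuli, hp)
        endo.serum_hormone_step(self.serum, rates, dt, hp)

        delayed = float(self.insulin_buffer[self.insulin_ptr])
        endo.glucose_homeostasis_step(
            self.glucose, delayed, self.portal_glucose_rate,
            self.portal_fructose_rate, dt, self.p.glucose,
            gip_excess=self.serum.excess("gip", hp),
        )
        self.insulin_buffer[self.insulin_ptr] = self.glucose.insulin
        self.insulin_ptr = (self.insulin_ptr + 1) % len(self.insulin_buffer)

        self.sens = endo.sensation_scores(
            v_stomach, self.tone, self.serum.levels["ghrelin"], self.p.sensation
        )

    def _stage_ph(self, volumes: np.ndarray) -> None:
        v = volumes.copy()
        mask = v > 1.0e-6
        vv = np.where(mask, v, 1.0)
        conc = self.M / vv[:, None]
        total_h = self.M[:, self.idx["hydrogen_ion"]] / (vv / 1000.0)
        ph = ph_vector(total_h, conc, self.reg, iters=30)
        self.pH = np.where(mask, ph, 7.0)

    # -- main loop ----------------------------------------------------------

    def step(self, dt: float) -> None:
        self.portal_glucose_rate = 0.0
        self.portal_fructose_rate = 0.0
        self._stage_consume(dt)
        self._stage_oral(dt)
        volumes = self._volumes()
        self._stage_gastric(dt, volumes)
        self._stage_secretions(dt)
        self._stage_decompose(dt)
        volumes = self._volumes()
        self._stage_transit(dt, volumes)
        volumes = self._volumes()
        self._stage_brush_and_absorb(dt, volumes)
        self._stage_luminal_enzymes(dt, volumes)
        self._stage_systemic(dt, volumes)
        self._stage_ph(self._volumes())
        m_min = float(self.M.min())
        if m_min < -1.0e-6:
            raise ArithmeticError(
                f"negative mass at t={self.t:.2f} min (min {m_min:.3e} g); "
                "reduce the step size"
            )
        np.maximum(self.M, 0.0, out=self.M)
        # derive time from the step counter so recorded minutes are exact
        self.steps += 1
        self.t = (self.steps * self.cfg.dt_s) / 60.0


# ---------------------------------------------------------------------------
# output schema


def _columns(sim: _Sim) -> List[str]:
    cols = ["t_min"]
    for c in COMPARTMENTS:
        cols.append(f"{c}.volume_mL")
        cols.append(f"{c}.pH")
    for c in COMPARTMENTS:
        for s in sim.reg.names:
            cols.append(f"{c}.{s}_g")
    for c in COMPARTMENTS:
        cols.append(f"{c}.solids_g")
    cols += [
        "gastric.tone_mBar", "gastric.VaT_mL", "gastric.F",
        "gastric.emptying_mL_per_min", "gastric.emptying_kcal_per_min",
        "secretion.gastric_mL_per_min", "secretion.saliva_mL_per_min",
        "secretion.bile_mL_per_min", "secretion.pancreas_mL_per_min",
        "secretion.intestinal_mL_per_min", "gallbladder.volume_mL",
        "absorption.kcal_per_min", "absorbed.glucose_g", "absorbed.fructose_g",
        "absorbed.water_g", "portal.glucose_g_per_min",
    ]
    for h in endo.HORMONES:
        cols.append(f"serum.{h}_ppm")
    cols += [
        "serum.glucose_portal_mM", "serum.glucose_mM", "serum.insulin_mU_L",
        "serum.glucagon_rel",
        "vas.fullness", "vas.hunger", "vas.discomfort", "mmc.phase",
        "brush.glucose_max_g_mL", "ledger.drift_rel",
    ]
    return cols


def _record(sim: _Sim, cadence: float) -> List[float]:
    volumes = sim._volumes()
    row: List[float] = [sim.t]
    for c in range(len(COMPARTMENTS)):
        row.append(float(volumes[c]))
        row.append(float(sim.pH[c]))
    row.extend(sim.M.ravel().tolist())
    for c in range(len(COMPARTMENTS)):
        row.append(sim._particle_mass(c))
    row += [
        sim.tone, sim.vat, sim.F,
        sim.acc_empty_vol / cadence, sim.acc_empty_kcal / cadence,
        sim.acc_secretion["gastric"] / cadence,
        sim.acc_secretion["saliva"] / cadence,
        sim.acc_secretion["bile"] / cadence,
        sim.acc_secretion["pancreas"] / cadence,
        sim.acc_secretion["intestinal"] / cadence,
        sim.gb.volume,
        sim.acc_absorbed_kcal / cadence,
        float(sim.absorbed[sim.idx["glucose"]]),
        float(sim.absorbed[sim.idx["fructose"]]),
        float(sim.absorbed[sim.idx["water"]]),
        sim.portal_glucose_rate,
    ]
    for h in endo.HORMONES:
        row.append(sim.serum.levels[h])
    row += [
        sim.glucose.portal, sim.glucose.peripheral, sim.glucose.insulin,
        sim.glucose.glucagon,
        sim.sens.fullness, sim.sens.hunger, sim.sens.discomfort,
        float(sim.mmc.phase),
        float(sim.C_bb[:, _BB_SPECIES.index("glucose")].max()),
        sim.mass_drift(),
    ]
    sim.acc_empty_vol = 0.0
    sim.acc_empty_kcal = 0.0
    for k in sim.acc_secretion:
        sim.acc_secretion[k] = 0.0
    sim.acc_absorbed_kcal = 0.0
    return row


def simulate(
    meal_plan: mio.MealPlan,
    params: Optional[Params] = None,
    sim_config: Optional[SimulationConfig] = None,
) -> SimulationResult:
    """Run the digestion simulation for a meal plan.

    Returns a :class:`SimulationResult` whose frame holds one row per
    output minute with per-compartment volumes, pH and component masses,
    secretion flows, gastric mechanics, brush-border and serum variables,
    and the visual-analog sensation scores.
    """
    params = params or default_params()
    sim_config = sim_config or SimulationConfig()
    sim = _Sim(meal_plan, params, sim_config)
    dt = sim_config.dt_s / 60.0
    cadence = sim_config.output_cadence_min
    n_steps = int(round(sim_config.duration_min / dt))
    steps_per_record = max(1, int(round(cadence / dt)))

    rows = [_record(sim, cadence)]
    for k in range(1, n_steps + 1):
        sim.step(dt)
        if k % steps_per_record == 0:
            rows.append(_record(sim, cadence))

    frame = pd.DataFrame(rows, columns=_columns(sim))
    absorbed = {
        n: float(sim.absorbed[i]) for n, i in sim.idx.items() if sim.absorbed[i] > 0
    }
    excreted = {
        n: float(sim.excreted[i]) for n, i in sim.idx.items() if sim.excreted[i] > 0
    }
    return SimulationResult(
        frame=frame,
        absorbed=absorbed,
        excreted=excreted,
        mass_balance_drift=sim.mass_drift(),
    )


def _phase_overlaps(cycle_time: float, dt: float) -> Tuple[float, float]:
    """Split a step into its pumping (phases 1-2) and emptying (phase 3)
    shares of the peristaltic cycle, handling wrap-around and steps longer
    than one cycle."""
    full = int(dt // ga.CYCLE_PERIOD)
    dt12 = full * 2.0 * ga.PHASE_DURATION
    dt3 = full * ga.PHASE_DURATION
    remaining = dt - full * ga.CYCLE_PERIOD
    t = cycle_time % ga.CYCLE_PERIOD
    boundary = 2.0 * ga.PHASE_DURATION
    while remaining > 1.0e-15:
        if t < boundary:
            seg = min(remaining, boundary - t)
            dt12 += seg
        else:
            seg = min(remaining, ga.CYCLE_PERIOD - t)
            dt3 += seg
        t = (t + seg) % ga.CYCLE_PERIOD
        remaining -= seg
    return dt12, dt3


def _ph_activity_vec(
    ph: np.ndarray, window: Tuple[float, float, float, float] | None
) -> np.ndarray:
    if window is None:
        return np.ones_like(ph)
    a, b, c, d = window
    up = np.clip((ph - a) / max(b - a, 1e-12), 0.0, 1.0)
    down = np.clip((d - ph) / max(d - c, 1e-12), 0.0, 1.0)
    return np.minimum(up, down)


# ---------------------------------------------------------------------------
# I/O


def write_timeseries(result: SimulationResult, path: str | Path) -> None:
    """Write the per-minute time series as CSV (9 significant digits)."""
    result.frame.to_csv(path, index=False, float_format="%.9g")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
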