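"""Meal plans: file dialect, consumption scheduling, oral processing.

A meal plan is a sequence of timed meals; each meal is a set of compounds
(bread crumb, glucose drink, ...) that carry texture attributes (solid
with a particle size and mechanical breakdown times, or liquid with a
viscosity) plus a component composition in grams.  Consumption moves
compound mass from the plate to the mouth at the meal's consumption rate;
oral processing adds saliva, comminutes solids, releases components from
decomposing compounds and swallows boluses into the gastric corpus (the
esophagus is treated as a zero-delay conduit).

File dialect (UTF-8, line oriented)::

    # comment
    [meal name="breakfast" start_min=0 rate_mL_per_min=60]
    [compound name="drink" pH=7 state=liquid viscosity_mPas=1 \
        oral_break_min=0 gastric_break_min=0 decomp_min=0]
    water<TAB>250
    glucose<TAB>50

``write_meal_file`` emits the canonical form; ``parse`` of the writer's
output round-trips losslessly.
"""

from __future__ import annotations

import math
import re
import shlex
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .core_state import (
    CompartmentState,
    ComponentRegistry,
    SolidParticle,
    default_registry,
    mixed_volume,
)

__all__ = [
    "CompoundSpec",
    "MealEvent",
    "MealPlan",
    "MealFileError",
    "OralParams",
    "parse_meal_file",
    "write_meal_file",
    "consumption_step",
    "oral_process_and_swallow",
]


class MealFileError(ValueError):
    """Syntax or validation error in a meal-plan file (carries the line number)."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass(frozen=True)
class CompoundSpec:
    """A more-or-less separate constituent of a meal.

    ``decomposition_time`` is the first-order time constant (min) with
    which the compound releases its components into the surrounding liquid
    in the mouth and stomach; breakdown times are the comminution time
    constants for mastication and gastric grinding.
    """

    name: str
    pH: float
    state: str  # "solid" | "liquid"
    viscosity: Optional[float] = None  # mPa·s, liquids only
    particle_size: Optional[float] = None  # mm, solids only
    oral_breakdown_time: float = 0.0  # min
    gastric_breakdown_time: float = 0.0  # min
    decomposition_time: float = 0.0  # min
    components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in ("solid", "liquid"):
            raise ValueError(f"{self.name}: state must be solid or liquid")
        if self.state == "liquid" and (
            self.viscosity is None or self.particle_size is not None
        ):
            raise ValueError(f"{self.name}: liquids take viscosity_mPas only")
        if self.state == "solid" and (
            self.particle_size is None or self.viscosity is not None
        ):
            raise ValueError(f"{self.name}: solids take particle_mm only")
        if self.particle_size is not None and self.particle_size <= 0:
            raise ValueError(f"{self.name}: particle size must be > 0")
        for t in (self.oral_breakdown_time, self.gastric_breakdown_time,
                  self.decomposition_time):
            if t < 0:
                raise ValueError(f"{self.name}: times must be >= 0")
        for comp, mass in self.components.items():
            if mass < 0:
                raise ValueError(f"{self.name}: negative mass for {comp}")

    @property
    def total_mass(self) -> float:
        return sum(self.components.values())

    def density(self, registry: ComponentRegistry) -> float:
        """Bulk density (g/mL) from the isochoric volume of the composition."""
        vol = mixed_volume(dict(self.components), registry)
        if vol <= 0:
            return 1.0
        return self.total_mass / vol


@dataclass(frozen=True)
class MealEvent:
    name: str
    start_time: float  # min
    consumption_rate: float  # mL/min
    compounds: Tuple[CompoundSpec, ...]

    def __post_init__(self) -> None:
        if self.consumption_rate <= 0:
            raise ValueError(f"{self.name}: consumption rate must be > 0")
        if self.start_time < 0:
            raise ValueError(f"{self.name}: start time must be >= 0")

    @property
    def total_mass(self) -> float:
        return sum(c.total_mass for c in self.compounds)


@dataclass(frozen=True)
class MealPlan:
    meals: Tuple[MealEvent, ...] = ()

    def __post_init__(self) -> None:
        starts = [m.start_time for m in self.meals]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("meal start times must be non-decreasing")

    @property
    def end_of_intake(self) -> float:
        return max((m.start_time for m in self.meals), default=0.0)


# ---------------------------------------------------------------------------
# parsing / writing

_HEADER_RE = re.compile(r"^\[(meal|compound)\s+(.*)\]$")


def _parse_attrs(body: str, lineno: int) -> Dict[str, str]:
    try:
        tokens = shlex.split(body)
    except ValueError as exc:
        raise MealFileError(str(exc), lineno) from None
    attrs = {}
    for tok in tokens:
        if "=" not in tok:
            raise MealFileError(f"expected key=value, got {tok!r}", lineno)
        k, v = tok.split("=", 1)
        attrs[k] = v
    return attrs


def _fnum(attrs: Dict[str, str], key: str, lineno: int) -> float:
    if key not in attrs:
        raise MealFileError(f"missing attribute {key!r}", lineno)
    try:
        return float(attrs[key])
    except ValueError:
        raise MealFileError(f"bad number for {key!r}: {attrs[key]!r}", lineno) from None


def parse_meal_file(
    text: str, registry: Optional[ComponentRegistry] = None
) -> MealPlan:
    """Parse the meal-plan dialect into a validated :class:`MealPlan`.

    Unknown components are rejected; errors carry the offending line
    number.  Two meals sharing a start time are simply consumed back to
    back (concatenation order = file order).
    """
    registry = registry or default_registry()
    meals: List[MealEvent] = []
    cur_meal: Optional[Dict] = None
    cur_comp: Optional[Dict] = None

    def close_compound() -> None:
        nonlocal cur_comp
        if cur_comp is None:
            return
        try:
            spec = CompoundSpec(**cur_comp["kw"], components=cur_comp["components"])
        except ValueError as exc:
            raise MealFileError(str(exc), cur_comp["line"]) from None
        cur_meal["compounds"].append(spec)  # type: ignore[index]
        cur_comp = None

    def close_meal() -> None:
        nonlocal cur_meal
        if cur_meal is None:
            return
        close_compound()
        try:
            meals.append(
                MealEvent(
                    name=cur_meal["name"],
                    start_time=cur_meal["start"],
                    consumption_rate=cur_meal["rate"],
                    compounds=tuple(cur_meal["compounds"]),
                )
            )
        except ValueError as exc:
            raise MealFileError(str(exc), cur_meal["line"]) from None
        cur_meal = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        m = _HEADER_RE.match(line.strip())
        if m:
            kind, body = m.groups()
            attrs = _parse_attrs(body, lineno)
            if kind == "meal":
                close_meal()
                cur_meal = {
                    "name": attrs.get("name", f"meal-{lineno}"),
                    "start": _fnum(attrs, "start_min", lineno),
                    "rate": _fnum(attrs, "rate_mL_per_min", lineno),
                    "compounds": [],
                    "line": lineno,
                }
            else:
                if cur_meal is None:
                    raise MealFileError("compound outside of a meal block", lineno)
                close_compound()
                state = attrs.get("state")
                if state not in ("solid", "liquid"):
                    raise MealFileError("state must be solid or liquid", lineno)
                kw = {
                    "name": attrs.get("name", f"compound-{lineno}"),
                    "pH": _fnum(attrs, "pH", lineno),
                    "state": state,
                    "oral_breakdown_time": _fnum(attrs, "oral_break_min", lineno),
                    "gastric_breakdown_time": _fnum(attrs, "gastric_break_min", lineno),
                    "decomposition_time": _fnum(attrs, "decomp_min", lineno),
                }
                if state == "liquid":
                    kw["viscosity"] = _fnum(attrs, "viscosity_mPas", lineno)
                else:
                    kw["particle_size"] = _fnum(attrs, "particle_mm", lineno)
                cur_comp = {"kw": kw, "components": {}, "line": lineno}
            continue
        # component line: name <TAB or spaces> mass_g
        if cur_comp is None:
            raise MealFileError("component line outside of a compound block", lineno)
        parts = line.strip().split()
        if len(parts) != 2:
            raise MealFileError(f"expected 'component mass_g', got {line.strip()!r}", lineno)
        comp, mass_s = parts
        if comp not in registry:
            raise MealFileError(f"unknown component {comp!r}", lineno)
        try:
            mass = float(mass_s)
        except ValueError:
            raise MealFileError(f"bad mass {mass_s!r}", lineno) from None
        if mass < 0:
            raise MealFileError(f"negative mass for {comp!r}", lineno)
        cur_comp["components"][comp] = cur_comp["components"].get(comp, 0.0) + mass
    close_meal()
    return MealPlan(tuple(meals))


def _num(x: float) -> str:
    # repr gives the shortest lossless decimal form, so write/parse
    # round-trips bit-exactly
    return repr(float(x))


def write_meal_file(plan: MealPlan) -> str:
    """Emit the canonical dialect text for ``plan``."""
    lines: List[str] = []
    for meal in plan.meals:
        lines.append(
            f'[meal name="{meal.name}" start_min={_num(meal.start_time)} '
            f"rate_mL_per_min={_num(meal.consumption_rate)}]"
        )
        for c in meal.compounds:
            texture = (
                f"viscosity_mPas={_num(c.viscosity)}"
                if c.state == "liquid"
                else f"particle_mm={_num(c.particle_size)}"
            )
            lines.append(
                f'[compound name="{c.name}" pH={_num(c.pH)} state={c.state} '
                f"{texture} oral_break_min={_num(c.oral_breakdown_time)} "
                f"gastric_break_min={_num(c.gastric_breakdown_time)} "
                f"decomp_min={_num(c.decomposition_time)}]"
            )
            for comp in sorted(c.components):
                lines.append(f"{comp}\t{_num(c.components[comp])}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# consumption and oral processing


@dataclass
class OralParams:
    """Salivation and swallowing settings.

    Saliva runs at ``saliva_eating`` mL/min while food is in the mouth and
    at a small basal rate otherwise; 0.5 % of it is salivary amylase.
    Solids are swallowed once comminuted below the swallowable size or
    after three oral-breakdown time constants; liquids go down with the
    next peristaltic tick.
    """

    saliva_eating: float = 4.0  # mL/min
    saliva_basal: float = 0.3  # mL/min
    saliva_amylase_fraction: float = 0.005
    # swallowable bolus particles are larger than the pyloric sieve, so
    # swallowed solids still need gastric grinding before they can empty
    swallow_size_mm: float = 3.0
    swallow_residence_factor: float = 3.0


def load_plate(plan: MealPlan, t: float, dt: float, plate: CompartmentState) -> None:
    """Put compounds of any meal starting within (t, t+dt] onto the plate."""
    for i, meal in enumerate(plan.meals):
        if t - dt < meal.start_time <= t:
            for c in meal.compounds:
                plate.solid_particles.append(
                    SolidParticle(
                        compound=c.name,
                        mass=c.total_mass,
                        size=c.particle_size if c.state == "solid" else 0.0,
                    )
                )


def consumption_step(
    plan: MealPlan,
    t: float,
    dt: float,
    plate: CompartmentState,
    mouth: CompartmentState,
    registry: Optional[ComponentRegistry] = None,
) -> float:
    """Move up to ``rate * dt`` mL of the active meal from plate to mouth.

    The transfer is split proportionally (by volume) across the remaining
    compounds of the meal being eaten.  Returns the volume moved (mL);
    idle (0) when the plate is empty.  The caller serves new meals onto
    the plate with :func:`load_plate`.
    """
    registry = registry or default_registry()
    if not plate.solid_particles:
        return 0.0
    # active rate: latest meal that has started; earlier leftovers are eaten
    # at the same rate (back-to-back concatenation)
    rate = 60.0
    for meal in plan.meals:
        if meal.start_time <= t:
            rate = meal.consumption_rate
    lookup = plan_compound_index(plan)
    vols = []
    for p in plate.solid_particles:
        dens = lookup[p.compound].density(registry)
        vols.append(p.mass / dens)
    total_vol = sum(vols)
    if total_vol <= 0:
        plate.solid_particles.clear()
        return 0.0
    take_vol = min(rate * dt, total_vol)
    frac = take_vol / total_vol
    for p in list(plate.solid_particles):
        moved = p.mass * frac
        p.mass -= moved
        _add_particle(mouth, p.compound, moved, p.size)
    plate.solid_particles = [p for p in plate.solid_particles if p.mass > 1.0e-12]
    return take_vol


def plan_compound_index(plan: MealPlan) -> Dict[str, CompoundSpec]:
    """Name -> spec over all meals; duplicate names must agree."""
    index: Dict[str, CompoundSpec] = {}
    for meal in plan.meals:
        for c in meal.compounds:
            if c.name in index and index[c.name] != c:
                raise ValueError(
                    f"compound name {c.name!r} reused with a different definition"
                )
            index[c.name] = c
    return index


def _add_particle(state: CompartmentState, compound: str, mass: float, size: float) -> None:
    for p in state.solid_particles:
        if p.compound == compound and abs(p.size - size) < 1.0e-9:
            p.mass += mass
            return
    state.solid_particles.append(SolidParticle(compound=compound, mass=mass, size=size))


def release_components(
    particle: SolidParticle,
    spec: CompoundSpec,
    dt: float,
    masses: Dict[str, float],
) -> float:
    """First-order decomposition of a compound into its components.

    Moves ``mass * (1 - exp(-dt/tau))`` from the particle into the liquid
    ledger ``masses`` split per the compound's composition; instantaneous
    when the decomposition time is zero.  Returns the released mass.
    """
    tau = spec.decomposition_time
    if tau <= 0:
        frac = 1.0
    else:
        frac = 1.0 - math.exp(-dt / tau)
    released = particle.mass * frac
    if released <= 0:
        return 0.0
    total = spec.total_mass
    if total > 0:
        for comp, m in spec.components.items():
            masses[comp] = masses.get(comp, 0.0) + released * m / total
    particle.mass -= released
    return released


def oral_process_and_swallow(
    mouth: CompartmentState,
    dt: float,
    plan: MealPlan,
    params: Optional[OralParams] = None,
    registry: Optional[ComponentRegistry] = None,
) -> Tuple[Dict[str, float], List[SolidParticle]]:
    """One oral step: salivate, masticate, decompose, swallow.

    Returns the swallowed bolus as ``(masses, particles)``; the caller
    deposits it into the gastric corpus.  Solid particle sizes decay
    exponentially with the compound's oral breakdown time; particles are
    swallowed once small enough or after a long oral residence, liquids
    within the step.
    """
    params = params or OralParams()
    registry = registry or default_registry()
    lookup = plan_compound_index(plan)

    eating = bool(mouth.solid_particles)
    saliva = (params.saliva_eating if eating else params.saliva_basal) * dt
    amylase = saliva * params.saliva_amylase_fraction
    mouth.masses["water"] = mouth.masses.get("water", 0.0) + saliva - amylase
    mouth.masses["amylase"] = mouth.masses.get("amylase", 0.0) + amylase

    bolus_particles: List[SolidParticle] = []
    keep: List[SolidParticle] = []
    for p in mouth.solid_particles:
        spec = lookup[p.compound]
        p.residence += dt
        if spec.state == "solid" and spec.oral_breakdown_time > 0:
            p.size *= math.exp(-dt / spec.oral_breakdown_time)
        release_components(p, spec, dt, mouth.masses)
        if p.mass <= 1.0e-12:
            continue
        swallow = (
            spec.state == "liquid"
            or p.size < params.swallow_size_mm
            or (
                spec.oral_breakdown_time > 0
                and p.residence > params.swallow_residence_factor * spec.oral_breakdown_time
            )
        )
        (bolus_particles if swallow else keep).append(p)
    mouth.solid_particles = keep

    bolus_masses = dict(mouth.masses)
    mouth.masses = {}
    return bolus_masses, bolus_particles
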