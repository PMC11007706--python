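"""Shared state model: chemical components, compartment mass ledgers, pH.

Every compartment of the alimentary tract is a well-mixed mass ledger
(grams per component).  Volumes follow from isochoric mixing (sum of
component masses over their pure densities), concentrations are mass over
collective volume, and pH is solved from a proton balance that includes
the titration curves of buffering components (proteins, citric acid).

Hydrogen ions are book-kept in grams of H+ (molar mass 1 g/mol) so the
ledger stays uniform; a sentinel density of 1e6 g/mL makes their volume
contribution negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "ComponentSpec",
    "ComponentRegistry",
    "CompartmentState",
    "EpithelialUnitProfile",
    "default_registry",
    "mixed_volume",
    "concentration_at",
    "compute_pH",
    "COMPARTMENTS",
    "SMALL_INTESTINE",
]

# Compartment roster, proximal to distal.  The gallbladder is modeled as a
# dedicated reservoir in secretions_transport, not a luminal ledger.
COMPARTMENTS: Tuple[str, ...] = (
    "plate",
    "mouth",
    "fundus",
    "corpus",
    "antrum",
    "duodenum_pre_oddi",
    "duodenum_post_oddi",
    "jejunum_1",
    "jejunum_2",
    "jejunum_3",
    "ileum_1",
    "ileum_2",
    "ileum_3",
    "ileum_4",
    "ileum_5",
    "ileum_6",
    "colon",
)
#: names of the eleven small-intestinal compartments (lined with epithelium)
SMALL_INTESTINE: Tuple[str, ...] = COMPARTMENTS[5:16]

COMPONENT_CLASSES = frozenset(
    {
        "water", "protein", "peptide", "amino_acid", "triglyceride",
        "diglyceride", "monoglyceride", "fatty_acid", "phospholipid",
        "glucose", "fructose", "rare_sugar", "sucrose", "starch_rapid",
        "starch_slow", "maltose", "maltodextrin", "mucus_protein", "enzyme",
        "bile_salt", "bile_salt_LCFA_complex", "hydrogen_ion", "bicarbonate",
        "citric_acid", "tracer_peptide", "other",
    }
)

#: sentinel density for hydrogen ions (g/mL); their volume is negligible
HYDROGEN_SENTINEL_DENSITY = 1.0e6

KW = 1.0e-14  # water ion product at body temperature, kept at the textbook value


@dataclass(frozen=True)
class ComponentSpec:
    """One food-derived or secreted chemical species.

    ``titration_curve`` is a sequence of ``(pKa, mol acid groups per g)``
    pairs; each group binds protons with Henderson–Hasselbalch occupancy.
    ``molar_mass`` (g/mol) feeds the osmolarity proxy used by the gastric
    emptying feedback; polymers get a large value so they are osmotically
    inert.
    """

    name: str
    component_class: str
    density: float  # g/mL
    caloric_density: float = 0.0  # kcal/g
    mucus_diffusivity: float = 0.0  # cm^2/min
    titration_curve: Tuple[Tuple[float, float], ...] = ()
    is_tracer: bool = False
    molar_mass: float = 1.0e5  # g/mol

    def __post_init__(self) -> None:
        if self.component_class not in COMPONENT_CLASSES:
            raise ValueError(f"unknown component class {self.component_class!r}")
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")
        if self.caloric_density < 0:
            raise ValueError(f"{self.name}: caloric density must be >= 0")
        if self.mucus_diffusivity < 0:
            raise ValueError(f"{self.name}: mucus diffusivity must be >= 0")
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be > 0")


class RegistryError(KeyError):
    """Raised when an unregistered component is referenced."""


class UndefinedConcentrationError(ValueError):
    """Raised when concentrations are requested for a zero-volume ledger."""


class ComponentRegistry:
    """Immutable-ish lookup table of :class:`ComponentSpec` with array views.

    The engine indexes components by integer position; the arrays
    (``density``, ``caloric_density`` ...) are aligned with that order.
    """

    def __init__(self, specs: Iterable[ComponentSpec]):
        self._specs: Dict[str, ComponentSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ValueError(f"duplicate component {spec.name!r}")
            self._specs[spec.name] = spec
        self.names: Tuple[str, ...] = tuple(self._specs)
        self.index: Dict[str, int] = {n: i for i, n in enumerate(self.names)}
        self.density = np.array([s.density for s in self._specs.values()])
        self.caloric_density = np.array(
            [s.caloric_density for s in self._specs.values()]
        )
        self.mucus_diffusivity = np.array(
            [s.mucus_diffusivity for s in self._specs.values()]
        )
        self.molar_mass = np.array([s.molar_mass for s in self._specs.values()])
        # flattened titration groups for the vectorized pH solver
        tit: List[Tuple[int, float, float]] = []
        for i, s in enumerate(self._specs.values()):
            for pka, cap in s.titration_curve:
                tit.append((i, pka, cap))
        self.tit_species = np.array([t[0] for t in tit], dtype=int)
        self.tit_pka = np.array([t[1] for t in tit])
        self.tit_cap = np.array([t[2] for t in tit])

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __getitem__(self, name: str) -> ComponentSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise RegistryError(f"component {name!r} is not registered") from None

    def __len__(self) -> int:
        return len(self._specs)

    def with_overrides(self, **per_component: Mapping[str, float]) -> "ComponentRegistry":
        """Return a copy with selected spec fields replaced per component."""
        specs = []
        for spec in self._specs.values():
            if spec.name in per_component:
                specs.append(replace(spec, **per_component[spec.name]))
            else:
                specs.append(spec)
        return ComponentRegistry(specs)


# Protein-type buffering: carboxylate shoulder near pH 4.5 plus
# histidine/phosphate-like groups near 6.8 (mol acid groups per g protein).
_PROTEIN_CURVE = ((4.5, 5.0e-4), (6.8, 3.0e-4))
_CITRIC_CURVE = ((3.1, 1.0 / 192.0), (4.8, 1.0 / 192.0), (6.4, 1.0 / 192.0))

_SMALL = 6.0e-4   # cm^2/min, small solutes
_MEDIUM = 3.0e-4  # peptides, disaccharides
_LARGE = 6.0e-5   # proteins, polysaccharides, enzymes


def default_registry() -> ComponentRegistry:
    """The built-in component roster with averaged densities.

    Caloric densities are standard Atwater values (4 kcal/g carbohydrate
    and protein, 9 kcal/g fat); both are configurable via
    :meth:`ComponentRegistry.with_overrides`.
    """
    c = ComponentSpec
    return ComponentRegistry(
        [
            c("water", "water", 1.0, 0.0, _SMALL, molar_mass=18.0),
            c("protein", "protein", 1.35, 4.0, _LARGE, _PROTEIN_CURVE),
            c("peptide", "peptide", 1.35, 4.0, _MEDIUM, _PROTEIN_CURVE, molar_mass=2000.0),
            c("amino_acid", "amino_acid", 1.35, 4.0, _SMALL, molar_mass=110.0),
            c("triglyceride", "triglyceride", 0.9, 9.0, _LARGE, molar_mass=885.0),
            c("diglyceride", "diglyceride", 0.9, 9.0, _MEDIUM, molar_mass=621.0),
            c("monoglyceride", "monoglyceride", 0.9, 9.0, _MEDIUM, molar_mass=357.0),
            c("fatty_acid", "fatty_acid", 0.9, 9.0, _MEDIUM, molar_mass=282.0),
            c("phospholipid", "phospholipid", 0.9, 9.0, _LARGE, molar_mass=760.0),
            c("glucose", "glucose", 1.54, 4.0, _SMALL, molar_mass=180.0),
            c("fructose", "fructose", 1.54, 4.0, _SMALL, molar_mass=180.0),
            # pentose sugars (e.g. L-arabinose); poorly metabolized, 0 kcal/g
            c("rare_sugar", "rare_sugar", 1.69, 0.0, _SMALL, molar_mass=150.0),
            c("sucrose", "sucrose", 1.59, 4.0, _SMALL, molar_mass=342.0),
            c("starch_rapid", "starch_rapid", 1.54, 4.0, _LARGE),
            c("starch_slow", "starch_slow", 1.54, 4.0, _LARGE),
            c("maltodextrin", "maltodextrin", 1.54, 4.0, _MEDIUM, molar_mass=5000.0),
            c("maltose", "maltose", 1.54, 4.0, _SMALL, molar_mass=342.0),
            c("mucus_protein", "mucus_protein", 1.35, 0.0, _LARGE, _PROTEIN_CURVE),
            c("bile_salt", "bile_salt", 1.2, 0.0, _MEDIUM, molar_mass=500.0),
            c("bile_salt_LCFA_complex", "bile_salt_LCFA_complex", 1.69, 9.0, _MEDIUM,
              molar_mass=3000.0),
            c("hydrogen_ion", "hydrogen_ion", HYDROGEN_SENTINEL_DENSITY, 0.0, 3.0e-3,
              molar_mass=1.0),
            c("bicarbonate", "bicarbonate", 2.2, 0.0, _SMALL, molar_mass=61.0),
            c("citric_acid", "citric_acid", 1.66, 0.0, _SMALL, _CITRIC_CURVE,
              molar_mass=192.0),
            c("tracer_peptide", "tracer_peptide", 1.35, 0.0, _MEDIUM, is_tracer=True,
              molar_mass=2000.0),
            # digestive enzymes are protein species carried in the ledger
            c("pepsin", "enzyme", 1.35, 0.0, _LARGE),
            c("amylase", "enzyme", 1.35, 0.0, _LARGE),
            c("protease", "enzyme", 1.35, 0.0, _LARGE),
            c("lipase", "enzyme", 1.35, 0.0, _LARGE),
        ]
    )


@dataclass
class SolidParticle:
    """Aggregated solid mass of one compound inside a compartment."""

    compound: str
    mass: float  # g, undecomposed compound
    size: float  # mm, mass-weighted particle diameter
    residence: float = 0.0  # min spent in the current compartment


@dataclass
class CompartmentState:
    """Mass ledger of one luminal compartment.

    ``masses`` covers the dissolved/liquid phase; ``solid_particles`` holds
    still-intact solid compound masses.  Volume is always derived, never
    stored.
    """

    id: str
    masses: Dict[str, float] = field(default_factory=dict)
    solid_particles: List[SolidParticle] = field(default_factory=list)
    viscosity: float = 1.0  # mPa·s of the liquid phase

    def volume(self, registry: ComponentRegistry) -> float:
        return mixed_volume(self.masses, registry)


@dataclass
class EpithelialUnitProfile:
    """Absorptive/secretory properties of one small-intestinal unit.

    ``m_max`` is the maximum caloric absorption rate of the unit (kcal/min,
    about 1 per metre-scale compartment); transporter entries are
    ``(Vmax g/min, Km g/mL)``.
    """

    compartment: str
    mucus_thickness: float  # cm
    area: float  # cm^2
    m_max: float  # kcal/min
    sglt1: Tuple[float, float]
    glut5: Tuple[float, float]
    passive_permeability: float  # mL/min, applied to small absorbable solutes
    brush_enzyme_levels: Dict[str, float] = field(default_factory=dict)
    receptor_densities: Dict[str, float] = field(default_factory=dict)
    water_flux: float = 0.0  # mL/min toward the epithelium


# ---------------------------------------------------------------------------
# volumes and concentrations


def mixed_volume(masses: Mapping[str, float], registry: ComponentRegistry) -> float:
    """Isochoric mixing volume (mL): sum of m_i / rho_i.

    Additive over disjoint mass maps; raises on unknown components or
    negative masses.
    """
    vol = 0.0
    for name, m in masses.items():
        spec = registry[name]
        if m < 0:
            raise ValueError(f"negative mass for {name!r}: {m}")
        vol += m / spec.density
    return vol


def concentration_at(
    state: CompartmentState, component: str, registry: ComponentRegistry
) -> float:
    """Concentration (g/mL) of ``component`` in the liquid phase."""
    vol = state.volume(registry)
    if vol <= 0.0:
        raise UndefinedConcentrationError(
            f"compartment {state.id!r} has zero volume; concentration undefined"
        )
    return state.masses.get(component, 0.0) / vol


# ---------------------------------------------------------------------------
# pH


def _free_h(ph: np.ndarray | float) -> np.ndarray | float:
    """Free proton concentration balance of water, mol/L ([H+] - [OH-])."""
    return 10.0 ** (-np.asarray(ph, dtype=float)) - KW * 10.0 ** np.asarray(ph, dtype=float)


def ph_vector(
    total_h_mol_per_l: np.ndarray,
    conc_g_per_ml: np.ndarray,
    registry: ComponentRegistry,
    iters: int = 50,
) -> np.ndarray:
    """Vectorized proton-balance pH for a batch of compartments.

    Solves ``free(pH) + sum_groups cap * C * (f(pH) - f(7)) = total_H``
    by bisection on [0, 14]; the left side is strictly decreasing in pH so
    bisection is unconditionally convergent.  Group occupancies are
    referenced to their protonation state at neutral pH, so components
    arrive charge-balanced: a buffer added to pure water leaves the pH at
    7, while added acid is shared between the free pool and the buffers.

    Parameters
    ----------
    total_h_mol_per_l : (n,) titratable H+ added per litre (>= 0).
    conc_g_per_ml : (n, n_species) liquid-phase concentrations.
    """
    total = np.asarray(total_h_mol_per_l, dtype=float)
    lo = np.zeros_like(total)
    hi = np.full_like(total, 14.0)
    ts, tp, tc = registry.tit_species, registry.tit_pka, registry.tit_cap
    has_buf = ts.size > 0
    if has_buf:
        # mol groups per L of each buffering species, shape (n, K)
        buf = conc_g_per_ml[:, ts] * 1000.0 * tc[None, :]
        ref = 1.0 / (1.0 + 10.0 ** (7.0 - tp))  # occupancy at neutral pH
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        lhs = _free_h(mid)
        if has_buf:
            frac = 1.0 / (1.0 + 10.0 ** (mid[:, None] - tp[None, :]))
            lhs = lhs + np.sum(buf * (frac - ref[None, :]), axis=1)
        too_acidic = lhs > total  # pH guess too low -> move up
        lo = np.where(too_acidic, mid, lo)
        hi = np.where(too_acidic, hi, mid)
    return 0.5 * (lo + hi)


def compute_pH(
    state: CompartmentState,
    registry: ComponentRegistry,
    tol: float = 1.0e-9,
    max_iter: int = 200,
) -> float:
    """pH of one compartment from its total H+ ledger and buffer curves.

    Bisection on [0, 14] until the proton-balance residual is below ``tol``
    (mol/L).  Raises :class:`UndefinedConcentrationError` on an empty
    compartment and ``ArithmeticError`` on non-convergence.
    """
    vol = state.volume(registry)
    if vol <= 0.0:
        raise UndefinedConcentrationError(
            f"compartment {state.id!r} has zero volume; pH undefined"
        )
    total = state.masses.get("hydrogen_ion", 0.0) / 1.0 / (vol / 1000.0)  # mol/L

    buffers: List[Tuple[float, float, float]] = []  # (g/L, pKa, capacity)
    for name, mass in state.masses.items():
        for pka, cap in registry[name].titration_curve:
            buffers.append((mass / (vol / 1000.0), pka, cap))

    def residual(ph: float) -> float:
        lhs = 10.0 ** (-ph) - KW * 10.0 ** ph
        for g_per_l, pka, cap in buffers:
            occupied = 1.0 / (1.0 + 10.0 ** (ph - pka))
            reference = 1.0 / (1.0 + 10.0 ** (7.0 - pka))
            lhs += g_per_l * cap * (occupied - reference)
        return lhs - total

    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = residual(mid)
        if abs(r) < tol:
            return mid
        if r > 0:
            lo = mid
        else:
            hi = mid
    if hi - lo < 1.0e-12:  # bracket collapsed; residual limited by float precision
        return 0.5 * (lo + hi)
    raise ArithmeticError(
        f"pH solve did not converge for {state.id!r}: bracket [{lo}, {hi}], "
        f"residual {residual(0.5 * (lo + hi)):.3e} mol/L"
    )


def neutralize_bicarbonate(h_mass: float, bicarb_mass: float) -> Tuple[float, float, float]:
    """Instant acid–base reaction H+ + HCO3- -> (water, vented CO2).

    Returns ``(new_h_mass, new_bicarb_mass, water_gained)`` in grams.  The
    full reacted mass is converted to water so the global ledger is exactly
    conserved (CO2 venting is not tracked separately).
    """
    mol = min(h_mass / 1.0, bicarb_mass / 61.0)
    if mol <= 0.0:
        return h_mass, bicarb_mass, 0.0
    return h_mass - mol * 1.0, bicarb_mass - mol * 61.0, mol * 62.0
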