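"""Enzymatic hydrolysis: Michaelis–Menten kinetics with inhibitors.

Luminal enzymes (pepsin, pancreatic amylase/protease/lipase) and
brush-border enzymes (maltase, sucrase, alpha-dextrinase, glucoamylase)
convert food components into absorbable species.  Each reaction is a
single Michaelis–Menten step

    v = E * Vmax * S / (Km * alpha + S * alpha')

with ``alpha = 1 + sum(I/Ki)`` over competitive inhibitors and
``alpha' = 1 + sum(I/Ki)`` over uncompetitive ones, scaled by a
trapezoidal pH-activity factor in [0, 1].  Hydrolysis mass balance
includes the water taken up: digesting S grams of substrate consumes
``S * water_uptake`` grams of water and yields ``S * (1 + water_uptake)``
grams of products, split by the product mass fractions (which sum to 1).

Kinetic constants are not literature truth: they form a documented
default table aligned with typical duodenal activities of static in
vitro digestion protocols, and every entry is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

__all__ = [
    "EnzymeReaction",
    "michaelis_menten_rate",
    "ph_activity",
    "default_reactions",
    "BRUSH_REACTIONS",
]

# hydrolysis stoichiometry (per g substrate): water taken up and product split
_W_DISACCH = 18.0 / 342.0  # sucrose/maltose -> monosaccharides
_W_MALTODEX = 18.0 / 324.0  # per maltose unit cleaved off the glucan
_W_STARCH_GLC = 18.0 / 162.0  # glucan residue -> free glucose
_W_TG = 18.0 / 885.0  # triglyceride -> diglyceride + fatty acid
_W_DG = 18.0 / 621.0  # diglyceride -> monoglyceride + fatty acid


@dataclass(frozen=True)
class EnzymeReaction:
    """One enzyme-catalyzed conversion.

    ``enzyme`` names either a ledger component (luminal enzymes, E in
    grams) or a brush-border enzyme whose level comes from the epithelial
    profile (activity units).  ``vmax`` is g substrate/(min·unit).
    ``products`` are (component, mass fraction of the product mass).
    ``ph_window`` is the (zero, full, full, zero) trapezoid of the
    activity factor; ``None`` means pH-independent.
    """

    name: str
    enzyme: str
    substrate: str
    products: Tuple[Tuple[str, float], ...]
    vmax: float  # g substrate / (min * unit enzyme)
    km: float  # g/mL
    water_uptake: float = 0.0  # g water per g substrate
    ph_window: Tuple[float, float, float, float] | None = None
    inhibitors: Tuple[Tuple[str, float, str], ...] = ()  # (component, Ki, mode)
    bile_enhanced: bool = False
    luminal: bool = True

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError(f"{self.name}: Vmax and Km must be > 0")
        total = sum(f for _, f in self.products)
        if abs(total - 1.0) > 1.0e-9:
            raise ValueError(f"{self.name}: product fractions must sum to 1")
        for comp, ki, mode in self.inhibitors:
            if ki <= 0:
                raise ValueError(f"{self.name}: Ki must be > 0")
            if mode not in ("competitive", "uncompetitive"):
                raise ValueError(f"{self.name}: unknown inhibition mode {mode!r}")


def ph_activity(ph: float, window: Tuple[float, float, float, float] | None) -> float:
    """Trapezoidal pH-activity factor in [0, 1]."""
    if window is None:
        return 1.0
    a, b, c, d = window
    if ph <= a or ph >= d:
        return 0.0
    if ph < b:
        return (ph - a) / (b - a)
    if ph <= c:
        return 1.0
    return (d - ph) / (d - c)


def michaelis_menten_rate(
    substrate_conc: float,
    enzyme_units: float,
    reaction: EnzymeReaction,
    inhibitor_concs: Mapping[str, float] | None = None,
    ph: float | None = None,
) -> float:
    """Hydrolysis rate (g substrate/min) for the given luminal conditions."""
    if substrate_conc <= 0 or enzyme_units <= 0:
        return 0.0
    alpha = 1.0
    alpha_u = 1.0
    if inhibitor_concs:
        for comp, ki, mode in reaction.inhibitors:
            conc = inhibitor_concs.get(comp, 0.0)
            if conc <= 0:
                continue
            if mode == "competitive":
                alpha += conc / ki
            else:
                alpha_u += conc / ki
    v = (
        enzyme_units
        * reaction.vmax
        * substrate_conc
        / (reaction.km * alpha + substrate_conc * alpha_u)
    )
    if ph is not None:
        v *= ph_activity(ph, reaction.ph_window)
    return v


def default_reactions() -> Tuple[EnzymeReaction, ...]:
    """The built-in luminal reaction table."""
    r = EnzymeReaction
    return (
        # gastric protein digestion; pepsin works only in acid
        r("pepsin_proteolysis", "pepsin", "protein", (("peptide", 1.0),),
          vmax=2.0, km=0.02, water_uptake=0.01, ph_window=(0.5, 1.5, 3.5, 5.5)),
        # pancreatic trypsin-like protease
        r("protease_proteolysis", "protease", "protein", (("peptide", 1.0),),
          vmax=3.0, km=0.01, water_uptake=0.01, ph_window=(5.0, 6.5, 8.5, 9.5)),
        r("protease_peptidolysis", "protease", "peptide", (("amino_acid", 1.0),),
          vmax=1.5, km=0.01, water_uptake=0.14, ph_window=(5.0, 6.5, 8.5, 9.5)),
        # alpha-amylase: endo-cleavage of gelatinized starch, then maltose release
        r("amylase_starch_rapid", "amylase", "starch_rapid",
          (("maltodextrin", 1.0),), vmax=6.0, km=0.01, water_uptake=0.0,
          ph_window=(4.0, 5.0, 8.0, 9.0),
          inhibitors=(("rare_sugar", 0.004, "competitive"),)),
        r("amylase_starch_slow", "amylase", "starch_slow",
          (("maltodextrin", 1.0),), vmax=1.2, km=0.01, water_uptake=0.0,
          ph_window=(4.0, 5.0, 8.0, 9.0),
          inhibitors=(("rare_sugar", 0.004, "competitive"),)),
        r("amylase_maltodextrin", "amylase", "maltodextrin",
          (("maltose", 1.0),), vmax=4.0, km=0.01, water_uptake=_W_MALTODEX,
          ph_window=(4.0, 5.0, 8.0, 9.0)),
        # pancreatic lipase (+colipase), enhanced by bile salts; long-chain
        # fatty acids are complexed with bile salts into mixed micelles by
        # the engine after release
        r("lipase_tg", "lipase", "triglyceride",
          (("diglyceride", 621.0 / 903.0), ("fatty_acid", 282.0 / 903.0)),
          vmax=8.0, km=0.01, water_uptake=_W_TG, ph_window=(4.0, 5.5, 8.0, 9.0),
          bile_enhanced=True),
        r("lipase_dg", "lipase", "diglyceride",
          (("monoglyceride", 357.0 / 639.0), ("fatty_acid", 282.0 / 639.0)),
          vmax=8.0, km=0.01, water_uptake=_W_DG, ph_window=(4.0, 5.5, 8.0, 9.0),
          bile_enhanced=True),
    )


def brush_reactions() -> Tuple[EnzymeReaction, ...]:
    """Brush-border disaccharidase/oligosaccharidase table.

    Rates use the substrate concentration at the epithelial surface and
    the compartment's enzyme level; products feed the same-step
    absorption pool.  Sucrase is uncompetitively inhibited by L-arabinose
    (the ``rare_sugar`` component).
    """
    r = EnzymeReaction
    return (
        r("maltase", "maltase", "maltose", (("glucose", 1.0),),
          vmax=1.0, km=0.005, water_uptake=_W_DISACCH, luminal=False,
          inhibitors=(("rare_sugar", 0.003, "uncompetitive"),)),
        r("sucrase", "sucrase", "sucrose",
          (("glucose", 0.5), ("fructose", 0.5)),
          vmax=0.6, km=0.02, water_uptake=_W_DISACCH, luminal=False,
          inhibitors=(("rare_sugar", 0.002, "uncompetitive"),)),
        r("glucoamylase", "glucoamylase", "maltodextrin", (("glucose", 1.0),),
          vmax=0.5, km=0.01, water_uptake=_W_STARCH_GLC, luminal=False),
        r("alpha_dextrinase", "alpha_dextrinase", "maltodextrin",
          (("maltose", 1.0),), vmax=0.3, km=0.01, water_uptake=_W_MALTODEX,
          luminal=False),
    )


BRUSH_REACTIONS = brush_reactions()


def apply_reaction(
    masses: Dict[str, float],
    reaction: EnzymeReaction,
    converted: float,
) -> float:
    """Book the mass balance of converting ``converted`` g of substrate.

    Caps at substrate and water availability; returns the actually
    converted mass.  ``masses`` is mutated in place.
    """
    avail = masses.get(reaction.substrate, 0.0)
    converted = min(converted, avail)
    if reaction.water_uptake > 0:
        converted = min(converted, masses.get("water", 0.0) / reaction.water_uptake)
    if converted <= 0:
        return 0.0
    masses[reaction.substrate] = avail - converted
    if reaction.water_uptake > 0:
        masses["water"] -= converted * reaction.water_uptake
    produced = converted * (1.0 + reaction.water_uptake)
    for comp, frac in reaction.products:
        masses[comp] = masses.get(comp, 0.0) + produced * frac
    return converted
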