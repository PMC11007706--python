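"""Brush-border absorption with saturating caloric competition.

Each absorbable species is taken up from its concentration at the
epithelial surface by a Michaelis–Menten transporter term plus a passive
permeability term: glucose (and galactose) ride the high-capacity
SGLT-1, fructose the lower-capacity GLUT5, amino acids and small
peptides a pooled carrier, and the bile-salt–fatty-acid micellar species
their own pathway.

A compartment cannot absorb calories faster than its maximum M (about
1 kcal/min per metre-scale small-intestinal unit).  With T the summed
uncompeted caloric demand, every rate is scaled by the competition
factor

    G = M / (T + M)

so the realized total G*T = M*T/(T+M) saturates below M, from below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

from .core_state import ComponentRegistry, EpithelialUnitProfile

__all__ = [
    "AbsorptionParams",
    "TransporterSpec",
    "uncompeted_absorption_rate",
    "competition_factor",
    "default_absorption_params",
]


@dataclass(frozen=True)
class TransporterSpec:
    """Michaelis–Menten carrier capacity for one species (per compartment)."""

    vmax: float  # g/min
    km: float  # g/mL
    passive: float = 0.0  # mL/min passive permeability


def _default_pathways() -> Dict[str, TransporterSpec]:
    # Carbohydrate and protein carriers are high-capacity: per-compartment
    # absorption is governed by the caloric ceiling M through the
    # competition factor G, not by carrier saturation.  Fat pathways are
    # interfacially limited (micelle shuttling) and deliberately slow, so
    # lipids persist into the distal small intestine (ileal-brake
    # receptors).
    return {
        # SGLT-1: high capacity, low Km (~2 mM)
        "glucose": TransporterSpec(vmax=5.0, km=0.00036, passive=0.5),
        # GLUT5: lower capacity, higher Km
        "fructose": TransporterSpec(vmax=1.2, km=0.002, passive=0.5),
        "amino_acid": TransporterSpec(vmax=2.0, km=0.005, passive=0.3),
        "peptide": TransporterSpec(vmax=1.5, km=0.005),
        "bile_salt_LCFA_complex": TransporterSpec(vmax=0.1, km=0.002),
        "monoglyceride": TransporterSpec(vmax=0.05, km=0.002),
        "fatty_acid": TransporterSpec(vmax=0.05, km=0.002),
        "rare_sugar": TransporterSpec(vmax=0.0, km=1.0, passive=0.2),
        "citric_acid": TransporterSpec(vmax=0.0, km=1.0, passive=0.2),
    }


@dataclass
class AbsorptionParams:
    """Absorption settings shared by all small-intestinal compartments.

    ``m_max`` is M[i], the caloric absorption ceiling per compartment;
    ``water_per_kcal`` is the osmotically coupled water co-absorption on
    top of the baseline epithelial water flux.  The micellar complex
    returns its bile-salt share (by mass) to the enterohepatic pool on
    uptake.
    """

    m_max: float = 1.0  # kcal/min per compartment
    pathways: Dict[str, TransporterSpec] = field(default_factory=_default_pathways)
    water_per_kcal: float = 0.2  # mL water co-absorbed per kcal
    ileal_salt_resorption: float = 0.05  # /min, bile salt in ileal units
    complex_salt_fraction: float = 500.0 / 3000.0  # bile-salt mass share of micelle


def uncompeted_absorption_rate(
    c_bb: float, component: str, params: AbsorptionParams
) -> float:
    """Absorption rate (g/min) of one species ignoring all competitors."""
    if c_bb <= 0:
        return 0.0
    spec = params.pathways.get(component)
    if spec is None:
        return 0.0
    return spec.vmax * c_bb / (spec.km + c_bb) + spec.passive * c_bb


def competition_factor(m_max: float, t_total: float) -> float:
    """G = M/(T+M); realized total caloric uptake is G*T = M*T/(T+M) < M."""
    if m_max <= 0:
        raise ValueError("M must be > 0")
    if t_total < 0:
        raise ValueError("T must be >= 0")
    return m_max / (t_total + m_max)


def default_absorption_params() -> AbsorptionParams:
    return AbsorptionParams()
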