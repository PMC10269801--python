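"""Steady-state cellular carbon budget of phytoplankton growth.

The model tracks a single currency, carbon, through a cell growing at
steady state.  Photosynthesis supplies carbon at a per-cell rate
``F_Pho`` (mol C cell^-1 d^-1); growth consumes it through three (plus
one optional) sinks, each proportional to the biosynthetic flux
``mu * Q_C``:

* biosynthesis itself (1 mol C incorporated per mol biomass C),
* growth respiration (``e_mu`` mol C respired per mol biomass C),
* silica-frustule deposition (``E_Si`` mol C per mol biomass C,
  the product of the C cost per Si and the cellular Si:C ratio), and
* optionally extracellular excretion (``e_ex``).

Setting the time derivative of the carbon quota to zero yields the
nutrient-replete growth rate

    mu = F_Pho / (Q_C * (1 + e_mu + E_Si + e_ex))

with the carbon quota itself an empirical allometric function of cell
volume, ``Q_C = A_C * V**B_C``.  Diatoms differ from other
photosynthetic protists in two ways only: they pay the silica cost
(E_Si > 0) and they follow a lower quota curve (smaller carbon content
at a given volume).  A third, counterfactual taxon class prices the
frustule as if it were ordinary biomass, which is the comparison that
isolates how cheap silica deposition really is.

All quantities are molar; allometric prefactors are supplied in
pg C cell^-1 (the unit empirical quota compilations report) and
converted internally with the 12.011 g mol^-1 molar mass of carbon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "TaxonGroup",
    "CellParameters",
    "CarbonBudget",
    "carbon_quota",
    "silica_cost_factor",
    "total_cost_factor",
    "silica_fraction_of_cost",
    "growth_rate",
    "carbon_fate",
    "PG_C_TO_MOL_C",
]

#: molar mass of carbon, g mol^-1
C_MOLAR_MASS = 12.011

#: conversion from pg C to mol C
PG_C_TO_MOL_C = 1e-12 / C_MOLAR_MASS


class TaxonGroup(str, Enum):
    """Taxon classes the model distinguishes.

    ``DIATOM`` pays the (cheap) silica deposition cost; ``OTHER``
    deposits no silica; ``DIATOM_NO_SI`` is the counterfactual diatom
    whose frustule is priced like ordinary biomass carbon.
    """

    DIATOM = "diatom"
    OTHER = "other"
    DIATOM_NO_SI = "diatom_no_si"


@dataclass(frozen=True)
class CellParameters:
    """Per-taxon constants of the carbon budget.

    Parameters
    ----------
    group:
        Taxon class (see :class:`TaxonGroup`).
    a_c:
        Allometric quota prefactor: carbon mass per cell at
        V = 1 um^3, in pg C.
    b_c:
        Dimensionless allometric exponent, 0 < b_c < 2.
    e_mu:
        Growth respiration factor, mol C respired per mol biomass C.
    e_si_per_si:
        Direct carbon cost of silica deposition, mol C per mol Si.
    r_sic:
        Cellular Si:C molar ratio (0 for non-diatoms).
    e_ex:
        Optional excreted fraction, mol C excreted per mol biomass C.
    """

    group: TaxonGroup
    a_c: float
    b_c: float
    e_mu: float = 0.691
    e_si_per_si: float = 0.167
    r_sic: float = 0.0
    e_ex: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", TaxonGroup(self.group))
        if not self.a_c > 0:
            raise ValueError(f"a_c must be positive, got {self.a_c}")
        if not 0.0 < self.b_c < 2.0:
            raise ValueError(f"b_c must lie in (0, 2), got {self.b_c}")
        for name in ("e_mu", "e_si_per_si", "r_sic", "e_ex"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.group is TaxonGroup.OTHER and self.r_sic != 0:
            raise ValueError("non-diatom cells deposit no silica: r_sic must be 0")

    def without_silica_discount(self) -> "CellParameters":
        """The counterfactual diatom whose frustule costs as much, per
        mole, as biomass carbon (group ``diatom_no_si``); quota and
        Si:C ratio are unchanged."""
        return replace(self, group=TaxonGroup.DIATOM_NO_SI)


@dataclass(frozen=True)
class CarbonBudget:
    """Steady-state per-cell carbon fluxes, mol C cell^-1 d^-1.

    At steady state the photosynthetic source balances the sinks:
    ``f_pho == flux_biosynthesis + flux_respiration + flux_silica_cost
    + flux_excretion``.
    """

    mu: float
    q_c: float
    f_pho: float
    flux_biosynthesis: float
    flux_respiration: float
    flux_silica_cost: float
    flux_excretion: float


def carbon_quota(v, p: CellParameters):
    """Cellular carbon quota Q_C = A_C * V**B_C, in mol C cell^-1.

    Parameters
    ----------
    v:
        Cell volume in um^3 (scalar or array), strictly positive.
    p:
        Taxon constants; ``p.a_c`` is in pg C and converted to moles.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("cell volume must be positive")
    q = p.a_c * PG_C_TO_MOL_C * v**p.b_c
    return q if q.ndim else float(q)


def silica_cost_factor(p: CellParameters) -> float:
    """Silica deposition cost E_Si, mol C per mol biomass C.

    For diatoms this is the product of the carbon cost per mole of Si
    deposited and the cellular Si:C ratio.  Non-diatoms pay nothing.
    The ``diatom_no_si`` counterfactual charges silica at the full
    biomass production cost (1 + e_mu) per mole of Si instead.
    """
    if p.group is TaxonGroup.OTHER:
        return 0.0
    if p.group is TaxonGroup.DIATOM_NO_SI:
        return (1.0 + p.e_mu) * p.r_sic
    return p.e_si_per_si * p.r_sic


def total_cost_factor(p: CellParameters) -> float:
    """Total carbon spent per mole of biomass carbon produced:
    1 + e_mu + E_Si + e_ex (>= 1)."""
    return 1.0 + p.e_mu + silica_cost_factor(p) + p.e_ex


def silica_fraction_of_cost(p: CellParameters) -> float:
    """Share of the entire carbon cost attributable to silica
    deposition: E_Si / (1 + e_mu + E_Si + e_ex).

    Pure parameter arithmetic — independent of cell volume, growth
    rate, and light.  Defined for diatoms only.
    """
    if p.group is not TaxonGroup.DIATOM:
        raise ValueError(
            "silica cost share is defined for the diatom group only, "
            f"got {p.group.value!r}"
        )
    return silica_cost_factor(p) / total_cost_factor(p)


def growth_rate(f_pho, v, p: CellParameters):
    """Steady-state growth rate, d^-1.

    mu = F_Pho / (Q_C(V) * (1 + e_mu + E_Si + e_ex)); linear in the
    photosynthesis rate ``f_pho`` (mol C cell^-1 d^-1).
    """
    f_pho = np.asarray(f_pho, dtype=float)
    if np.any(f_pho < 0):
        raise ValueError("photosynthesis rate must be non-negative")
    mu = f_pho / (carbon_quota(v, p) * total_cost_factor(p))
    return mu if mu.ndim else float(mu)


def carbon_fate(mu: float, v: float, p: CellParameters) -> CarbonBudget:
    """Partition fixed carbon among its fates at growth rate ``mu``.

    Each flux is exactly linear in ``mu``; their sum is the
    photosynthesis rate that sustains this growth rate at steady
    state, closing the budget against :func:`growth_rate`.
    """
    if mu < 0:
        raise ValueError("growth rate must be non-negative")
    q_c = carbon_quota(v, p)
    biosynthesis = mu * q_c
    respiration = biosynthesis * p.e_mu
    silica = biosynthesis * silica_cost_factor(p)
    excretion = biosynthesis * p.e_ex
    return CarbonBudget(
        mu=float(mu),
        q_c=q_c,
        f_pho=biosynthesis + respiration + silica + excretion,
        flux_biosynthesis=biosynthesis,
        flux_respiration=respiration,
        flux_silica_cost=silica,
        flux_excretion=excretion,
    )
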