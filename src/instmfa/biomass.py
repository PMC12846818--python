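"""Biomass constraints, growth-rate conversions, and derived flux metrics.

These are the quantities read off a fitted flux map when comparing trophic
conditions: branch partitioning (e.g. the glyoxylate-shunt share of
isocitrate consumption), precursor provenance (e.g. the acetate share of
acetyl-CoA production), carbon-weighted respiratory loss relative to
biomass formation, macromolecule turnover, and rescaling of whole flux
maps to a common growth rate for cross-condition comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .network import FluxMap, Network

__all__ = [
    "BiomassComposition",
    "GrowthSpec",
    "growth_rate_from_doubling",
    "doubling_from_growth_rate",
    "biomass_demand_fluxes",
    "rescale_flux_map",
    "branch_partition_fraction",
    "provenance_fraction",
    "respiration_fraction",
    "turnover_fraction",
    "carbon_conversion_loss",
    "DEFAULT_MONOMER_TABLES",
]

#: monomer stoichiometries, umol monomer per gram of macromolecule
#: (editable defaults: average amino acid 110 g/mol; glucosyl unit 162 g/mol;
#: lipid counted as acetyl units, ~43.5 g/mol per 2-carbon unit)
DEFAULT_MONOMER_TABLES: dict[str, dict[str, float]] = {
    "protein": {"amino_acid": 1.0e6 / 110.0},
    "starch": {"glucosyl": 1.0e6 / 162.0},
    "lipid": {"acetyl": 1.0e6 / 43.5},
}


@dataclass
class BiomassComposition:
    """Dry-weight mass fractions of macromolecule classes and their monomer
    stoichiometries (umol monomer per g macromolecule)."""

    fractions: dict[str, float]
    monomer_tables: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MONOMER_TABLES.items()}
    )

    def validate(self) -> None:
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("negative biomass fraction")
        if sum(self.fractions.values()) > 1.0 + 1e-6:
            raise ValueError("biomass fractions sum above 1")
        for macro, frac in self.fractions.items():
            if frac > 0 and macro not in self.monomer_tables and macro != "other":
                raise ValueError(f"missing monomer table for {macro!r}")


@dataclass
class GrowthSpec:
    doubling_time_h: float
    growth_rate_h: float

    def validate(self, slack: float = 0.02) -> None:
        """Flag inconsistency beyond rounding slack (2% relative)."""
        mu = growth_rate_from_doubling(self.doubling_time_h)
        if abs(mu - self.growth_rate_h) > slack * mu:
            raise ValueError(
                f"growth rate {self.growth_rate_h} inconsistent with doubling time "
                f"{self.doubling_time_h} h (ln2/td = {mu:.4f})"
            )


def growth_rate_from_doubling(td_h: float) -> float:
    """Specific growth rate mu = ln 2 / doubling time (h^-1)."""
    if td_h <= 0:
        raise ValueError("doubling time must be positive")
    return math.log(2.0) / td_h


def doubling_from_growth_rate(mu_h: float) -> float:
    if mu_h <= 0:
        raise ValueError("growth rate must be positive")
    return math.log(2.0) / mu_h


def biomass_demand_fluxes(
    comp: BiomassComposition, mu_h: float
) -> dict[str, float]:
    """Precursor demands (umol gDW^-1 h^-1): mu x fraction x monomer stoich.

    The returned map (monomer -> demand) enters the network as fixed sink
    reaction fluxes.
    """
    comp.validate()
    demands: dict[str, float] = {}
    for macro, frac in comp.fractions.items():
        if frac == 0 or macro == "other":
            continue
        table = comp.monomer_tables[macro]
        for monomer, stoich in table.items():
            # stoich umol/g-macro x frac g-macro/gDW x mu 1/h -> umol gDW^-1 h^-1
            demands[monomer] = demands.get(monomer, 0.0) + mu_h * frac * stoich
    return demands


def rescale_flux_map(fm: FluxMap, mu_own: float, mu_ref: float) -> FluxMap:
    """Express a flux map at a reference growth rate (flux per biomass formed).

    Multiplies every net and exchange flux by ``mu_ref / mu_own``, adjusting
    for the difference in doubling time between conditions so that flux
    partitioning can be compared directly.
    """
    if mu_own <= 0 or mu_ref <= 0:
        raise ValueError("growth rates must be positive")
    return fm.scaled(mu_ref / mu_own)


def branch_partition_fraction(
    fm: FluxMap, net: Network, node: str, branch: str
) -> float:
    """Share of a metabolite's total net consumption carried by one branch."""
    rxn = net.reaction(branch)
    if node not in rxn.reactants:
        raise ValueError(f"reaction {branch} does not consume {node}")
    total = 0.0
    for r in net.reactions:
        v = fm.net[r.id]
        n_cons = r.reactants.count(node) if v >= 0 else r.products.count(node)
        total += abs(v) * n_cons
    if total <= 0:
        raise ValueError(f"zero total consumption of {node}")
    v_b = fm.net[branch]
    share = max(v_b, 0.0) * rxn.reactants.count(node) / total
    return min(share, 1.0)


def provenance_fraction(
    fm: FluxMap, net: Network, pool: str, source_reactions: Iterable[str]
) -> float:
    """Share of a pool's total net influx supplied by the named reactions."""
    source_reactions = set(source_reactions)
    total = 0.0
    chosen = 0.0
    for r in net.reactions:
        v = fm.net[r.id]
        n_prod = r.products.count(pool) if v >= 0 else r.reactants.count(pool)
        influx = abs(v) * n_prod
        total += influx
        if r.id in source_reactions:
            chosen += influx
    if total <= 0:
        raise ValueError(f"zero net influx to {pool}")
    return chosen / total


def respiration_fraction(
    fm: FluxMap,
    net: Network,
    co2_pools: Iterable[str] | None = None,
    biomass_reactions: Iterable[str] | None = None,
) -> float:
    """Carbon-weighted respiratory loss over carbon into biomass sinks.

    CO2 release = net carbon flux into CO2 pools from carbon-bearing
    internal reactants (gas dissolution from the medium is excluded because
    its reactant is a source species).  Biomass carbon = carbon flux of
    reactions producing sink metabolites (CO2 outgassing excluded).
    """
    if co2_pools is None:
        co2_pools = {
            m.id for m in net.metabolites.values() if m.id.split(".")[0].upper().startswith("CO2")
        }
    else:
        co2_pools = set(co2_pools)
    release = 0.0
    for r in net.reactions:
        v = fm.net[r.id]
        prods = r.products if v >= 0 else r.reactants
        reacts = r.reactants if v >= 0 else r.products
        n_co2 = sum(1 for m in prods if m in co2_pools)
        if n_co2 == 0:
            continue
        internal = any(
            net.metabolites[m].role != "source"
            and net.metabolites[m].n_carbons > 0
            and m not in co2_pools  # outgassing moves CO2, it does not release it
            for m in reacts
        )
        if internal:
            release += abs(v) * n_co2  # 1 carbon per CO2
    biomass_c = 0.0
    for r in net.reactions:
        if biomass_reactions is not None and r.id not in set(biomass_reactions):
            continue
        v = fm.net[r.id]
        prods = r.products if v >= 0 else r.reactants
        for m in prods:
            met = net.metabolites[m]
            if met.role == "sink" and m not in co2_pools and met.n_carbons > 0:
                if m.split(".")[0].upper().startswith("CO2"):
                    continue
                biomass_c += abs(v) * met.n_carbons
    if biomass_c <= 0:
        raise ValueError("zero biomass carbon flux")
    return release / biomass_c


def turnover_fraction(synthesis_flux: float, degradation_flux: float) -> float:
    """Fraction of synthesized macromolecule that is turned over."""
    if synthesis_flux <= 0:
        raise ValueError("synthesis flux must be positive")
    if degradation_flux < 0:
        raise ValueError("degradation flux must be nonnegative")
    if degradation_flux > synthesis_flux:
        import warnings

        warnings.warn("degradation exceeds synthesis (net loss of the pool)")
    return degradation_flux / synthesis_flux


def carbon_conversion_loss(precursor_carbons: int, product_carbons: int) -> float:
    """Percent of precursor carbon lost in one conversion step."""
    if product_carbons <= 0 or precursor_carbons < product_carbons:
        raise ValueError("need precursor >= product > 0 carbons")
    return 100.0 * (precursor_carbons - product_carbons) / precursor_carbons
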