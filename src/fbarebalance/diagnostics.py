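"""Pre-flight checks: elemental balances, FVA ranges, attainable growth.

Before adjusting anything it pays to know *why* a measured scenario is
infeasible.  The checks here answer the standard questions: do the measured
exchange rates supply enough of every element for the measured products and
biomass (gross elemental imbalance)?  Do the measured values even lie inside
the flux ranges the model admits (FVA)?  And what growth rate can the model
reach at all under a subset of the measurements?
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .biomass import BiomassSpec, GamSpec, extract_biomass_spec
from .model_io import MeasurementSet, MetabolicModel
from .solvers import fba_optimum, solve_lp

__all__ = [
    "ElementalBalanceReport",
    "FvaRange",
    "biomass_elemental_content",
    "elemental_balance",
    "fva_precheck",
    "max_growth",
    "gam_lower_bound",
    "exchange_species",
]


def exchange_species(model: MetabolicModel, rxn_id: str) -> str | None:
    """The single species an exchange reaction imports/exports, else None.

    A reaction with exactly one participating metabolite counts as an
    exchange (boundary) reaction.
    """
    stoich = model.reaction(rxn_id).stoichiometry
    if len(stoich) == 1:
        return next(iter(stoich))
    return None


def biomass_elemental_content(
    model: MetabolicModel,
    spec: BiomassSpec | None = None,
    gam: GamSpec | None = None,
) -> dict[str, float]:
    """Elemental content of 1 gDW of biomass, element -> mmol/gDW.

    content_e = -sum_k c_k,B * count_e(k) over the biomass components.  GAM
    terms are excluded: the hydrolysis stoichiometry is mass balanced and
    nets to zero for every element.
    """
    if spec is None or gam is None:
        spec, gam = extract_biomass_spec(model)
    content: dict[str, float] = {}
    for comp in spec.components:
        c_B = (
            gam.c_B(comp.metabolite_id)
            if comp.metabolite_id in gam.split
            else comp.coefficient
        )
        if c_B == 0.0:
            continue
        formula = model.metabolite(comp.metabolite_id).formula
        if not formula:
            raise ValueError(
                f"biomass component {comp.metabolite_id!r} has no formula"
            )
        for el, count in formula.items():
            content[el] = content.get(el, 0.0) - c_B * count
    return {el: v for el, v in content.items()}


@dataclass
class ElementalBalanceReport:
    """Net element availability over the measured rates.

    ``net[e]`` is the surplus of element e in mmol/(gDW*h): everything the
    measured exchanges import, minus what they export, minus the biomass
    drain mu * content_e.  A positive carbon net means excess carbon that
    unmeasured outflows (e.g. CO2) must carry; a negative net means the
    measured products plus biomass demand more than the measured substrates
    supply — a gross inconsistency no flux distribution can fix.
    """

    net: dict[str, float]
    contributions: dict[str, dict[str, float]]  # rxn -> element -> mmol/gDW/h
    biomass_content: dict[str, float]
    growth_rate: float
    skipped: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["element\tnet [mmol/(gDW*h)]"]
        for el in sorted(self.net):
            lines.append(f"{el}\t{self.net[el]:+.4g}")
        if self.skipped:
            lines.append(f"# skipped non-exchange measurements: "
                         f"{', '.join(self.skipped)}")
        return "\n".join(lines) + "\n"


def elemental_balance(
    model: MetabolicModel,
    measurements: MeasurementSet,
    spec: BiomassSpec | None = None,
    gam: GamSpec | None = None,
) -> ElementalBalanceReport:
    """Element-wise balance over the measured mean fluxes.

    For each measured exchange reaction the net production of its species is
    ``coefficient * f_i`` (an uptake with coefficient -1 and negative flux
    imports the species); the biomass reaction drains ``mu * content_e``.
    Measured internal reactions neither import nor export matter and are
    excluded with a warning.
    """
    if spec is None or gam is None:
        spec, gam = extract_biomass_spec(model)
    content = biomass_elemental_content(model, spec, gam)
    mu = 0.0
    net: dict[str, float] = {el: 0.0 for el in content}
    contributions: dict[str, dict[str, float]] = {}
    skipped: list[str] = []
    for rxn_id, m in measurements:
        if rxn_id == model.biomass_reaction_id:
            mu = m.value
            continue
        species = exchange_species(model, rxn_id)
        if species is None:
            skipped.append(rxn_id)
            warnings.warn(
                f"measured reaction {rxn_id!r} is not an exchange; excluded "
                "from the elemental balance",
                stacklevel=2,
            )
            continue
        formula = model.metabolite(species).formula
        if not formula:
            raise ValueError(f"exchange species {species!r} has no formula")
        coeff = model.reaction(rxn_id).stoichiometry[species]
        contrib = {el: coeff * m.value * n for el, n in formula.items()}
        contributions[rxn_id] = contrib
        for el, v in contrib.items():
            net[el] = net.get(el, 0.0) + v
    for el, c in content.items():
        net[el] = net.get(el, 0.0) - mu * c
    return ElementalBalanceReport(
        net=net,
        contributions=contributions,
        biomass_content=content,
        growth_rate=mu,
        skipped=skipped,
    )


@dataclass
class FvaRange:
    measured: float
    minimum: float
    maximum: float
    in_range: bool


def fva_precheck(
    model: MetabolicModel,
    measurements: MeasurementSet,
    tol: float = 1e-9,
) -> dict[str, FvaRange]:
    """Feasible flux range of each measured reaction, without fixing any.

    Runs flux variability analysis under the model's own constraints only
    (steady state, bounds, general constraints) and flags whether each
    measured value lies inside its closed range.  Unbounded directions are
    reported as +/-inf.
    """
    out: dict[str, FvaRange] = {}
    for rxn_id, m in measurements:
        lo_sol = fba_optimum(model, {rxn_id: 1.0}, sense="min")
        hi_sol = fba_optimum(model, {rxn_id: 1.0}, sense="max")
        lo = (
            lo_sol.objective_value if lo_sol.status == "optimal"
            else (-math.inf if lo_sol.status == "unbounded" else math.nan)
        )
        hi = (
            hi_sol.objective_value if hi_sol.status == "optimal"
            else (math.inf if hi_sol.status == "unbounded" else math.nan)
        )
        in_range = (lo - tol <= m.value <= hi + tol)
        out[rxn_id] = FvaRange(m.value, lo, hi, bool(in_range))
    return out


def max_growth(
    model: MetabolicModel,
    measurements_subset: MeasurementSet | Mapping[str, float] | None = None,
):
    """FBA maximum of the biomass reaction with a measurement subset fixed.

    The subset must not contain the growth reaction itself.  Returns the
    maximal growth rate (1/h), or the solver status string when the fixed
    subset is infeasible.
    """
    fixed: dict[str, float] = {}
    if measurements_subset is not None:
        if isinstance(measurements_subset, MeasurementSet):
            fixed = {k: m.value for k, m in measurements_subset}
        else:
            fixed = dict(measurements_subset)
    if model.biomass_reaction_id in fixed:
        raise ValueError(
            "max_growth subset must exclude the growth reaction itself"
        )
    sol = fba_optimum(
        model, {model.biomass_reaction_id: 1.0}, sense="max", fixed=fixed
    )
    if sol.status != "optimal":
        return sol.status
    return float(sol.objective_value)


def gam_lower_bound(component_estimates: Mapping[str, float]) -> float:
    """Sum of per-process maintenance ATP estimates, mmol/gDW.

    Polymerization costs for the macromolecule classes (protein, RNA, DNA,
    ...) are known from their chemistry; their sum is a lower bound on the
    growth-associated maintenance demand, since GAM additionally covers
    processes that are hard to itemize.
    """
    if any(v < 0 for v in component_estimates.values()):
        raise ValueError("maintenance estimates must be non-negative")
    return float(sum(component_estimates.values()))
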