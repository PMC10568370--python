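"""Seeded toy metabolic models, biomass perturbations and noisy measurements.

Every operation in this package is testable without downloading published
models: :func:`make_toy_model` builds a small, elementally consistent
network — substrate uptake, respiration-style ATP regeneration, one
synthesis route per biomass component, and a biomass reaction with an
embedded GAM hydrolysis — whose biomass weighs exactly 1 g/gDW by
construction (the component coefficients are solved from sampled mass
fractions, not drawn independently).  Formulas use real elements (C, H, O,
N, P) so the elemental diagnostics work unmodified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model_io import (
    Measurement,
    MeasurementSet,
    MetabolicModel,
    Metabolite,
    Reaction,
    molecular_weight,
    parse_formula,
)
from .solvers import fba_optimum

__all__ = [
    "ToyModelParams",
    "make_toy_model",
    "perturb_biomass",
    "simulate_measurements",
    "make_random_network",
]

# BiGG-style (charged species) formulas; the hydrolysis
# atp + h2o -> adp + pi + h balances element-wise with these.
_SPECIES_FORMULAS = {
    "glc__D": "C6H12O6",
    "o2": "O2",
    "co2": "CO2",
    "h2o": "H2O",
    "atp": "C10H12N5O13P3",
    "adp": "C10H12N5O10P2",
    "pi": "HO4P",
    "h": "H",
}


@dataclass(frozen=True)
class ToyModelParams:
    """Generation parameters for the toy model.

    ``component_sizes`` are the CH2O-unit lengths of the biomass components
    (their molecular weight follows as size * MW(CH2O)); when None they are
    sampled in 1..6 from the seed.  ``gam`` is the embedded GAM value g in
    mmol ATP/gDW, ``atp_yield`` the ATP produced per glucose respired, and
    ``synthesis_atp_cost`` the ATP spent per mmol of component synthesized.
    """

    n_components: int = 3
    component_sizes: tuple[int, ...] | None = None
    gam: float = 10.0
    atp_yield: float = 20.0
    synthesis_atp_cost: float = 2.0
    substrate_uptake: float = 10.0
    default_bound: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("need at least one biomass component")
        if self.gam < 0 or self.atp_yield <= 0 or self.substrate_uptake <= 0:
            raise ValueError("gam >= 0, atp_yield > 0, uptake > 0 required")
        if self.component_sizes is not None and (
            len(self.component_sizes) != self.n_components
            or any(s < 1 for s in self.component_sizes)
        ):
            raise ValueError("component_sizes must give a size >= 1 per component")


def make_toy_model(params: ToyModelParams | None = None) -> MetabolicModel:
    """Generate a feasible toy model with an embedded-GAM biomass reaction.

    Same seed, same model (bit-identical); plain FBA on the result has a
    strictly positive growth optimum.
    """
    params = params or ToyModelParams()
    rng = np.random.default_rng(params.seed)
    sizes = params.component_sizes or tuple(
        int(s) for s in rng.integers(1, 7, size=params.n_components)
    )
    # mass fractions summing to 1 g; coefficients follow as c_k = -p_k/MW_k
    fractions = rng.dirichlet(np.full(params.n_components, 2.0))

    mets = [
        Metabolite(mid, formula=parse_formula(f), compartment="c")
        for mid, f in _SPECIES_FORMULAS.items()
    ]
    comp_ids = []
    comp_mws = []
    for i, size in enumerate(sizes):
        mid = f"bm{i + 1}"
        formula = parse_formula(f"C{size}H{2 * size}O{size}")
        mets.append(Metabolite(mid, formula=formula, compartment="c"))
        comp_ids.append(mid)
        comp_mws.append(molecular_weight(formula))

    big = params.default_bound
    e = params.synthesis_atp_cost
    k_atp = params.atp_yield
    g = params.gam
    rxns = [
        Reaction("EX_glc__D", {"glc__D": -1.0}, -params.substrate_uptake, 0.0),
        Reaction("EX_o2", {"o2": -1.0}, -big, 0.0),
        Reaction("EX_co2", {"co2": -1.0}, 0.0, big),
        Reaction("EX_h2o", {"h2o": -1.0}, -big, big),
        Reaction(
            "CAT",
            {"glc__D": -1.0, "o2": -6.0, "adp": -k_atp, "pi": -k_atp,
             "h": -k_atp, "co2": 6.0, "h2o": 6.0 + k_atp, "atp": k_atp},
            0.0, big,
            name="respiration + ATP regeneration",
        ),
    ]
    biomass_stoich: dict[str, float] = {}
    for mid, size, mw, frac in zip(comp_ids, sizes, comp_mws, fractions):
        rxns.append(
            Reaction(
                f"SYN_{mid}",
                {"glc__D": -size / 6.0, "atp": -e, "h2o": -e,
                 mid: 1.0, "adp": e, "pi": e, "h": e},
                0.0, big,
                name=f"synthesis of {mid}",
            )
        )
        biomass_stoich[mid] = -frac / mw
    if g > 0:
        biomass_stoich.update(
            {"atp": -g, "h2o": -g, "adp": g, "pi": g, "h": g}
        )
    rxns.append(
        Reaction("BIOMASS", biomass_stoich, 0.0, big, name="biomass (1 g/gDW)")
    )
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective={"BIOMASS": 1.0},
        biomass_reaction_id="BIOMASS",
        id=f"toy_seed{params.seed}",
    )
    sol = fba_optimum(model)
    if sol.status != "optimal" or sol.objective_value <= 1e-9:
        raise ValueError(
            f"generated toy model has no feasible growth (status "
            f"{sol.status}, mu_max={sol.objective_value})"
        )
    return model


def perturb_biomass(
    model: MetabolicModel,
    deltas: Mapping[str, float],
    preserve_mass: bool = True,
    balance_with: str | None = None,
) -> MetabolicModel:
    """Shift biomass coefficients by Delta_k, optionally mass-neutrally.

    With ``preserve_mass`` the weighted sum ``sum_k Delta_k MW_k`` must be
    zero; pass ``balance_with`` to have that component's Delta solved for
    instead of supplied.  A perturbation may not flip a coefficient's sign
    (components must stay consumed/produced as before).
    """
    from dataclasses import replace

    new = model.copy()
    idx = new.reaction_index[new.biomass_reaction_id]
    biomass = new.reactions[idx]
    stoich = dict(biomass.stoichiometry)
    deltas = dict(deltas)
    for mid in deltas:
        if mid not in stoich:
            raise ValueError(f"{mid!r} is not a biomass component")
    mw = {}
    for mid in set(deltas) | ({balance_with} if balance_with else set()):
        formula = model.metabolite(mid).formula
        if not formula:
            raise ValueError(f"component {mid!r} has no formula (need MW)")
        mw[mid] = molecular_weight(formula)

    if preserve_mass:
        imbalance = sum(d * mw[mid] for mid, d in deltas.items())
        if balance_with is not None:
            if balance_with in deltas:
                raise ValueError(
                    "balance_with component must not also carry an explicit "
                    "delta"
                )
            deltas[balance_with] = -imbalance / mw[balance_with]
        elif abs(imbalance) > 1e-9:
            raise ValueError(
                f"explicit deltas change the biomass weight by "
                f"{imbalance:.3g} g; mass preservation requires "
                "sum(delta * MW) = 0"
            )
    for mid, d in deltas.items():
        old = stoich[mid]
        updated = old + d
        if updated == 0.0 or (updated > 0) != (old > 0):
            raise ValueError(
                f"perturbation flips the sign of {mid!r} "
                f"({old} -> {updated}); components must remain "
                "consumed/produced as before"
            )
        stoich[mid] = updated
    new.reactions[idx] = replace(biomass, stoichiometry=stoich)
    return new


def simulate_measurements(
    model: MetabolicModel,
    objective: str | None = None,
    sd_profile: Mapping[str, float] | None = None,
    noise_seed: int = 0,
) -> MeasurementSet:
    """FBA-derived exchange and growth measurements, optionally noisy.

    Solves FBA maximizing ``objective`` (default: the biomass reaction),
    extracts the exchange fluxes and the growth rate, and adds zero-mean
    Gaussian noise with the standard deviations from ``sd_profile`` (seeded;
    entries without a profile get sd 0 and stay exact).
    """
    sd_profile = dict(sd_profile or {})
    objective = objective or model.biomass_reaction_id
    sol = fba_optimum(model, {objective: 1.0}, sense="max")
    if sol.status == "unbounded":
        raise ValueError(f"FBA objective {objective!r} is unbounded")
    if sol.status != "optimal":
        raise ValueError(f"FBA failed with status {sol.status}")
    rng = np.random.default_rng(noise_seed)
    entries: dict[str, Measurement] = {}
    rxn_ids = [
        r.id for r in model.reactions
        if len(r.stoichiometry) == 1 or r.id == model.biomass_reaction_id
    ]
    rxn_index = model.reaction_index
    for rxn_id in rxn_ids:
        value = float(sol.x[rxn_index[rxn_id]])
        sd = float(sd_profile.get(rxn_id, 0.0))
        if sd > 0:
            value += rng.normal(0.0, sd)
        entries[rxn_id] = Measurement(value, sd=sd)
    return MeasurementSet(entries)


def make_random_network(
    seed: int,
    n_reactions: int = 5,
    n_metabolites: int = 3,
    n_measured: int = 3,
    noise: float = 1.0,
) -> tuple[MetabolicModel, MeasurementSet]:
    """A random small network with a (generally inconsistent) measured set.

    The stoichiometry is drawn sparsely with coefficients in {-2..2}; zero
    flux is always feasible (all lower bounds <= 0).  Measurements are a
    random FBA vertex plus Gaussian noise, so the fixed system is typically
    infeasible and the minimal-correction problem has a nonzero optimum.
    Intended for cross-checking the LP/QP optima against brute-force
    minimization on problems small enough to do so.
    """
    rng = np.random.default_rng(seed)
    while True:
        N = rng.integers(-2, 3, size=(n_metabolites, n_reactions)).astype(float)
        if np.all(np.any(N != 0, axis=0)):
            break
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_metabolites)]
    rxns = []
    for j in range(n_reactions):
        lb = 0.0 if rng.random() < 0.4 else -10.0
        rxns.append(
            Reaction(
                f"r{j}",
                {f"m{i}": N[i, j] for i in range(n_metabolites) if N[i, j]},
                lb, 10.0,
            )
        )
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective={"r0": 1.0},
        biomass_reaction_id=f"r{n_reactions - 1}",
        id=f"random_seed{seed}",
    )
    vertex = fba_optimum(model, {r.id: c for r, c in
                                 zip(rxns, rng.normal(size=n_reactions))})
    r0 = vertex.x if vertex.status == "optimal" else np.zeros(n_reactions)
    measured = rng.choice(n_reactions, size=min(n_measured, n_reactions),
                          replace=False)
    entries = {}
    for j in sorted(measured):
        sd = float(rng.uniform(0.2, 1.0))
        entries[f"r{j}"] = Measurement(
            float(r0[j] + rng.normal(0.0, noise)), sd=sd
        )
    return model, MeasurementSet(entries)
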