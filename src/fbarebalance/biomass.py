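"""Biomass reaction introspection: components, GAM detection, restructuring.

The biomass reaction lists the mmol of each component needed per gram dry
weight of cells; its flux is the growth rate mu (1/h).  Growth-associated
maintenance (GAM) is usually embedded in it as a mass-balanced ATP
hydrolysis, ATP + H2O -> ADP + Pi + H+, scaled by g mmol/gDW.  This module
splits each coefficient c_k into a biomass part c_k,B and a GAM part
c_k,GAM (c_k = c_k,B + c_k,GAM, |c_k,GAM| = g for the five GAM species),
verifies the 1-g mass convention, and offers two restructurings: moving GAM
into a separate reaction and lumping components into macromolecule
pseudo-metabolites.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .model_io import (
    FormulaError,
    MetabolicModel,
    Metabolite,
    Reaction,
    molecular_weight,
)

__all__ = [
    "GAM_ROLES",
    "GAM_SIGNS",
    "BiomassComponent",
    "BiomassSpec",
    "GamSpec",
    "BiomassError",
    "extract_biomass_spec",
    "check_biomass_mass",
    "gam_to_separate_reaction",
    "lump_biomass",
]

GAM_ROLES = ("atp", "adp", "h2o", "pi", "h")

# Hydrolysis direction: ATP and H2O consumed (negative); ADP, Pi, H+ produced.
GAM_SIGNS: Mapping[str, int] = {
    "atp": -1, "adp": +1, "h2o": -1, "pi": +1, "h": +1,
}

MASS_CHECK_TOLERANCE = 5e-3  # grams; published biomass rarely sums exactly to 1


class BiomassError(ValueError):
    """Raised for biomass reactions the introspection cannot handle."""


@dataclass(frozen=True)
class BiomassComponent:
    """One biomass component k: signed coefficient c_k and weight MW_k."""

    metabolite_id: str
    coefficient: float          # c_k, mmol/gDW, signed (consumed < 0)
    molecular_weight: float | None  # MW_k, g/mmol; None if no formula known


@dataclass
class BiomassSpec:
    """The component set C of the biomass reaction."""

    biomass_reaction_id: str
    components: Sequence[BiomassComponent]

    def component(self, met_id: str) -> BiomassComponent:
        for comp in self.components:
            if comp.metabolite_id == met_id:
                return comp
        raise KeyError(met_id)

    def __contains__(self, met_id: str) -> bool:
        return any(c.metabolite_id == met_id for c in self.components)


@dataclass
class GamSpec:
    """GAM bookkeeping: value g, the five GAM species and the c_k split."""

    g: float                                    # mmol ATP/gDW
    gam_metabolites: Mapping[str, tuple[str, int]]  # role -> (met id, sign)
    split: Mapping[str, tuple[float, float]]    # met id -> (c_k,B, c_k,GAM)
    gamma: float                                # max allowed GAM change

    def __post_init__(self) -> None:
        if self.g > 0 and not (0 < self.gamma <= self.g):
            raise BiomassError(
                f"gamma must satisfy 0 < gamma <= g, got gamma={self.gamma} "
                f"with g={self.g}"
            )

    def c_B(self, met_id: str) -> float:
        return self.split.get(met_id, (0.0, 0.0))[0]

    def c_GAM(self, met_id: str) -> float:
        return self.split.get(met_id, (0.0, 0.0))[1]

    @property
    def gam_metabolite_ids(self) -> dict[str, int]:
        """Metabolite id -> sign(c_k,GAM) for the five GAM species."""
        return {mid: sign for mid, sign in self.gam_metabolites.values()}


def _match_gam_metabolite(
    stem: str, candidate_ids: Sequence[str], compartments: Mapping[str, str]
) -> str | None:
    """Find a metabolite whose id is the role stem plus a compartment tag.

    BiGG-style ids (``atp_c``, ``h2o_c``) dominate published models, but the
    match is by stem + suffix rather than a hard-wired id list.  Cytosolic
    compartments are preferred when several compartments carry the species.
    """
    pattern = re.compile(rf"^{re.escape(stem)}(?:_([A-Za-z0-9]+))?$", re.I)
    hits = [mid for mid in candidate_ids if pattern.match(mid)]
    if not hits:
        return None
    if len(hits) > 1:
        cytosolic = [
            mid for mid in hits
            if compartments.get(mid, "").lower().startswith("c")
        ]
        if len(cytosolic) == 1:
            return cytosolic[0]
    return hits[0]


def extract_biomass_spec(
    model: MetabolicModel,
    overrides: Mapping[str, str] | None = None,
    g: float | None = None,
    gamma_max: float | None = None,
    mw_overrides: Mapping[str, float] | None = None,
) -> tuple[BiomassSpec, GamSpec]:
    """Enumerate biomass components and split off the GAM stoichiometry.

    The GAM value g is read off as the ADP coefficient of the biomass
    reaction (ADP is produced only by the embedded ATP hydrolysis), unless
    an explicit ``g`` is supplied.  ``overrides`` maps the roles
    ``atp/adp/h2o/pi/h`` to metabolite ids when the default stem matching
    does not apply.  ``gamma_max`` caps the maximally allowed GAM change;
    the effective gamma is ``min(g, gamma_max)`` (default g).
    """
    overrides = dict(overrides or {})
    mw_overrides = dict(mw_overrides or {})
    biomass = model.biomass_reaction
    if not biomass.stoichiometry:
        raise BiomassError(f"biomass reaction {biomass.id!r} is empty")

    compartments = {m.id: m.compartment for m in model.metabolites}
    met_ids = list(biomass.stoichiometry)
    gam_mets: dict[str, tuple[str, int]] = {}
    for role in GAM_ROLES:
        if role in overrides:
            mid = overrides[role]
            if mid not in biomass.stoichiometry:
                raise BiomassError(
                    f"override for role {role!r}: metabolite {mid!r} is not "
                    f"in the biomass reaction"
                )
        else:
            mid = _match_gam_metabolite(role, met_ids, compartments)
        if mid is not None:
            gam_mets[role] = (mid, GAM_SIGNS[role])

    if g is None:
        if "adp" not in gam_mets:
            if not gam_mets:
                # no GAM species at all in the biomass reaction: GAM is not
                # embedded (e.g. already moved to a separate reaction)
                g = 0.0
            else:
                raise BiomassError(
                    "cannot detect GAM: no ADP in the biomass reaction and "
                    "no explicit GAM value supplied"
                )
        else:
            g = float(biomass.stoichiometry[gam_mets["adp"][0]])
        if g < 0:
            raise BiomassError(
                "cannot detect GAM: biomass ADP coefficient is negative "
                "(expected ADP produced by ATP hydrolysis)"
            )
    if g > 0 and len(gam_mets) < len(GAM_ROLES):
        missing = sorted(set(GAM_ROLES) - set(gam_mets))
        raise BiomassError(
            f"GAM detected (g={g}) but roles {missing} could not be matched "
            "to biomass metabolites; supply overrides"
        )

    split: dict[str, tuple[float, float]] = {}
    for role, (mid, sign) in gam_mets.items():
        c_k = float(biomass.stoichiometry[mid])
        c_gam = sign * g
        split[mid] = (c_k - c_gam, c_gam)

    components = []
    for mid, c_k in biomass.stoichiometry.items():
        met = model.metabolite(mid)
        if mid in mw_overrides:
            mw = float(mw_overrides[mid])
        elif met.formula:
            mw = molecular_weight(met.formula)
        else:
            mw = None
        if mw is not None and mw <= 0:
            raise BiomassError(f"non-positive molecular weight for {mid!r}")
        components.append(BiomassComponent(mid, float(c_k), mw))

    spec = BiomassSpec(biomass_reaction_id=biomass.id, components=components)
    gamma = g if gamma_max is None else min(g, float(gamma_max))
    gam = GamSpec(g=g, gam_metabolites=gam_mets, split=split, gamma=gamma)
    return spec, gam


def check_biomass_mass(
    spec: BiomassSpec, gam: GamSpec, tolerance: float = MASS_CHECK_TOLERANCE
) -> float:
    """Total grams of biomass per gDW: -sum_k c_k,B * MW_k.

    The component coefficients (mmol/gDW) times molecular weights (g/mmol)
    must sum to the nominal 1 g of dry weight.  GAM terms are excluded: ATP
    hydrolysis is mass balanced and contributes zero.  A warning is emitted
    when the result deviates from 1 g by more than ``tolerance``.
    """
    total = 0.0
    for comp in spec.components:
        c_B = (
            gam.c_B(comp.metabolite_id)
            if comp.metabolite_id in gam.split
            else comp.coefficient
        )
        if c_B == 0.0:
            continue
        if comp.molecular_weight is None:
            raise BiomassError(
                f"component {comp.metabolite_id!r} has no formula and no "
                "user-supplied molecular weight"
            )
        total -= c_B * comp.molecular_weight
    if abs(total - 1.0) > tolerance:
        warnings.warn(
            f"biomass weighs {total:.6g} g per gDW (expected 1 g within "
            f"{tolerance:g})",
            stacklevel=2,
        )
    return total


def gam_to_separate_reaction(
    model: MetabolicModel,
    gam: GamSpec,
    reaction_id: str = "GAM",
) -> tuple[MetabolicModel, str]:
    """Move the GAM hydrolysis out of the biomass reaction.

    Returns a model where the five c_k,GAM terms are removed from the
    biomass reaction and an added reaction carries g * sign per GAM species
    (g ATP + g H2O -> g ADP + g Pi + g H+).  The caller is expected to fix
    (measure) the new reaction's rate equal to the growth rate.
    """
    if gam.g == 0 or not gam.gam_metabolites:
        raise BiomassError("GAM already extracted (g = 0 in biomass reaction)")
    if reaction_id in model.reaction_index:
        raise BiomassError(f"reaction id {reaction_id!r} already in model")

    new = model.copy()
    biomass = new.reaction(new.biomass_reaction_id)
    stoich = dict(biomass.stoichiometry)
    gam_stoich: dict[str, float] = {}
    for role, (mid, sign) in gam.gam_metabolites.items():
        c_B, c_gam = gam.split[mid]
        if c_B == 0.0:
            stoich.pop(mid, None)
        else:
            stoich[mid] = c_B
        gam_stoich[mid] = sign * gam.g
    new.reactions[new.reaction_index[new.biomass_reaction_id]] = replace(
        biomass, stoichiometry=stoich
    )
    new.reactions = list(new.reactions) + [
        Reaction(
            id=reaction_id,
            stoichiometry=gam_stoich,
            lower_bound=0.0,
            upper_bound=math.inf,
            name="growth-associated maintenance (extracted)",
        )
    ]
    new.validate()
    return new, reaction_id


def lump_biomass(
    model: MetabolicModel,
    class_map: Mapping[str, str],
    class_maintenance: Mapping[str, float] | None = None,
    gam: GamSpec | None = None,
) -> MetabolicModel:
    """Collect organic biomass components into macromolecule pseudo-metabolites.

    Each class (e.g. protein, RNA, phospholipids) becomes a pseudo-metabolite
    consumed by the biomass reaction with coefficient -1 and produced by one
    synthesis reaction carrying the original component stoichiometry; the
    pseudo-metabolite's molecular weight therefore equals the grams of that
    class per gDW.  Per-class maintenance ATP (mmol/gDW, e.g. polymerization
    cost) is added to the synthesis reaction as hydrolysis and subtracted
    from the biomass reaction's total GAM.

    ``class_map`` maps component metabolite ids to class names and must
    cover every organic (non-GAM-species) biomass component.
    """
    class_maintenance = dict(class_maintenance or {})
    if gam is None:
        _, gam = extract_biomass_spec(model)
    gam_ids = set(gam.gam_metabolite_ids)

    biomass = model.biomass_reaction
    organic = {
        mid: c for mid, c in biomass.stoichiometry.items() if mid not in gam_ids
    }
    uncovered = sorted(set(organic) - set(class_map))
    if uncovered:
        raise BiomassError(f"components in no class: {uncovered}")
    classes: dict[str, dict[str, float]] = {}
    for mid, cls in class_map.items():
        if mid not in organic:
            raise BiomassError(
                f"class_map entry {mid!r} is not an organic biomass component"
            )
        classes.setdefault(cls, {})[mid] = organic[mid]

    total_maint = sum(class_maintenance.values())
    if any(v < 0 for v in class_maintenance.values()):
        raise BiomassError("negative class maintenance")
    if total_maint > gam.g:
        raise BiomassError(
            f"class maintenance ({total_maint}) exceeds total GAM ({gam.g})"
        )
    unknown_cls = sorted(set(class_maintenance) - set(classes))
    if unknown_cls:
        raise BiomassError(f"maintenance for unknown classes: {unknown_cls}")

    new = model.copy()
    compartment = ""
    for mid in biomass.stoichiometry:
        compartment = model.metabolite(mid).compartment
        if compartment:
            break

    new_mets = list(new.metabolites)
    new_rxns = list(new.reactions)
    new_biomass_stoich: dict[str, float] = {
        mid: c for mid, c in biomass.stoichiometry.items() if mid in gam_ids
    }
    for cls, members in classes.items():
        pseudo_id = f"{cls}_pseudo"
        if pseudo_id in model.metabolite_index:
            raise BiomassError(f"metabolite id {pseudo_id!r} already in model")
        # average elemental composition of the class per unit pseudo-metabolite
        composition: dict[str, float] = {}
        have_all_formulas = True
        for mid, c in members.items():
            formula = model.metabolite(mid).formula
            if not formula:
                have_all_formulas = False
                break
            for el, n in formula.items():
                composition[el] = composition.get(el, 0.0) + (-c) * n
        new_mets.append(
            Metabolite(
                id=pseudo_id,
                name=f"{cls} (lumped biomass class)",
                formula=composition if have_all_formulas else None,
                compartment=compartment,
            )
        )
        synth_stoich: dict[str, float] = dict(members)
        synth_stoich[pseudo_id] = 1.0
        maint = class_maintenance.get(cls, 0.0)
        if maint > 0:
            for mid, sign in gam.gam_metabolite_ids.items():
                synth_stoich[mid] = synth_stoich.get(mid, 0.0) + sign * maint
        new_rxns.append(
            Reaction(
                id=f"{cls}_synthesis",
                stoichiometry=synth_stoich,
                lower_bound=0.0,
                upper_bound=math.inf,
                name=f"synthesis of lumped class {cls}",
            )
        )
        new_biomass_stoich[pseudo_id] = -1.0

    # residual GAM after moving per-class maintenance into synthesis reactions
    for mid, sign in gam.gam_metabolite_ids.items():
        c_B, c_gam = gam.split[mid]
        new_c = c_B + c_gam - sign * total_maint
        if new_c == 0.0:
            new_biomass_stoich.pop(mid, None)
        else:
            new_biomass_stoich[mid] = new_c

    idx = new.reaction_index[new.biomass_reaction_id]
    new.metabolites = new_mets
    new.reactions = new_rxns
    new.reactions[idx] = replace(
        new.reaction(new.biomass_reaction_id), stoichiometry=new_biomass_stoich
    )
    new.validate()
    return new
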