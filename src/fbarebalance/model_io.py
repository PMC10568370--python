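"""Metabolic model and measurement containers, SBML I/O and formula handling.

The in-memory model is a light dataclass view of an SBML Level-3 FBC model:
stoichiometry, flux bounds in mmol/(gDW*h), an optional block of general
linear inequality constraints ``A r <= b``, the linear objective and the id
of the biomass (growth) reaction.  Reading and writing go through cobrapy so
that any FBC-compliant file round-trips.

Sign convention: consumed species carry negative stoichiometric
coefficients, produced species positive, everywhere in this package.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ATOMIC_MASSES",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Measurement",
    "MeasurementSet",
    "ModelError",
    "FormulaError",
    "ScenarioError",
    "parse_formula",
    "molecular_weight",
    "read_model",
    "write_model",
    "read_scenario",
]


class ModelError(ValueError):
    """Raised for structurally invalid models or model files."""


class FormulaError(ValueError):
    """Raised for unparseable or unsupported chemical formulas."""


class ScenarioError(ValueError):
    """Raised for invalid measurement/configuration scenario files."""


# IUPAC 2021 standard atomic weights (g/mol), conventional values for the
# elements common in metabolic models.  Kept fixed so elemental balances and
# molecular weights are bit-reproducible across releases.
ATOMIC_MASSES: Mapping[str, float] = {
    "H": 1.008, "He": 4.002602, "Li": 6.94, "Be": 9.0121831, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815384, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.0983,
    "Ca": 40.078, "Cr": 51.9961, "Mn": 54.938043, "Fe": 55.845,
    "Co": 58.933194, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.38,
    "As": 74.921595, "Se": 78.971, "Br": 79.904, "Rb": 85.4678,
    "Sr": 87.62, "Mo": 95.95, "Ag": 107.8682, "Cd": 112.414, "Sn": 118.71,
    "I": 126.90447, "Ba": 137.327, "W": 183.84, "Hg": 200.592,
    "Pb": 207.2,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style sum formula into an element -> count mapping.

    Only flat formulas are supported: element symbols with optional integer
    counts (``C6H12O6``).  Groups, polymer notation (``(C2H4)n``) and
    ``R``-type pseudo-atoms are rejected.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    formula = formula.strip()
    if any(ch in formula for ch in "()[]*."):
        raise FormulaError(f"unsupported grouped/polymer formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"cannot parse formula {formula!r} at position {pos}"
            )
        pos = match.end()
        symbol, digits = match.groups()
        if symbol not in ATOMIC_MASSES:
            raise FormulaError(
                f"unknown element {symbol!r} in formula {formula!r}"
            )
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def molecular_weight(composition: Mapping[str, float]) -> float:
    """Molecular weight of an element->count composition in g/mmol.

    Counts may be fractional (lumped pseudo-metabolites have non-integer
    average compositions).  The result is the g/mol sum divided by 1000,
    matching the mmol/gDW coefficient units of biomass reactions.
    """
    if not composition:
        raise FormulaError("empty composition has no molecular weight")
    total = 0.0
    for element, count in composition.items():
        try:
            total += ATOMIC_MASSES[element] * count
        except KeyError:
            raise FormulaError(
                f"element {element!r} not in the atomic mass table"
            ) from None
    return total / 1000.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: Mapping[str, float] | None = None
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    name: str = ""


@dataclass
class MetabolicModel:
    """Stoichiometric model with bounds, objective and biomass reaction."""

    metabolites: Sequence[Metabolite]
    reactions: Sequence[Reaction]
    objective: Mapping[str, float]
    biomass_reaction_id: str
    general_constraints: tuple[np.ndarray, np.ndarray] | None = None
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- indexing helpers -------------------------------------------------
    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self.metabolite_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self.reaction_index[rxn_id]]

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reaction(self.biomass_reaction_id)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense m x n stoichiometric matrix N (metabolites x reactions)."""
        mi = self.metabolite_index
        N = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                N[mi[met_id], j] = coeff
        return N

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def validate(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = {r.id for r in self.reactions}
        if len(rxn_ids) != len(self.reactions):
            raise ModelError("duplicate reaction ids")
        for rxn in self.reactions:
            if not (
                math.isfinite(rxn.lower_bound) or rxn.lower_bound == -math.inf
            ) or not (
                math.isfinite(rxn.upper_bound) or rxn.upper_bound == math.inf
            ):
                raise ModelError(f"non-finite bound on reaction {rxn.id!r}")
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelError(
                    f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} "
                    f"exceeds upper bound {rxn.upper_bound}"
                )
            for met_id, coeff in rxn.stoichiometry.items():
                if met_id not in met_ids:
                    raise ModelError(
                        f"reaction {rxn.id!r} references unknown "
                        f"metabolite {met_id!r}"
                    )
                if not math.isfinite(coeff):
                    raise ModelError(
                        f"non-finite coefficient in reaction {rxn.id!r}"
                    )
        if self.biomass_reaction_id not in rxn_ids:
            raise ModelError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        for rxn_id in self.objective:
            if rxn_id not in rxn_ids:
                raise ModelError(f"objective references unknown reaction {rxn_id!r}")
        if self.general_constraints is not None:
            A, b = self.general_constraints
            A = np.asarray(A, dtype=float)
            b = np.asarray(b, dtype=float)
            if A.ndim != 2 or A.shape[1] != len(self.reactions):
                raise ModelError("general constraint matrix has wrong shape")
            if b.shape != (A.shape[0],):
                raise ModelError("general constraint vector has wrong shape")
            self.general_constraints = (A, b)

    def copy(self) -> "MetabolicModel":
        gc = None
        if self.general_constraints is not None:
            A, b = self.general_constraints
            gc = (A.copy(), b.copy())
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry))
                       for r in self.reactions],
            objective=dict(self.objective),
            biomass_reaction_id=self.biomass_reaction_id,
            general_constraints=gc,
            id=self.id,
        )


@dataclass(frozen=True)
class Measurement:
    """A measured flux value with an optional standard deviation.

    Units are mmol/(gDW*h) for metabolic fluxes and 1/h for the growth rate.
    ``sd == 0`` marks an exactly known rate (hard-fixed, no correction
    variable); ``sd is None`` marks an unknown accuracy.
    """

    value: float
    sd: float | None = None


class MeasurementSet:
    """The set F of reactions with fixed (measured) rates."""

    def __init__(self, entries: Mapping[str, Measurement | float]):
        self.entries: dict[str, Measurement] = {}
        for rxn_id, entry in entries.items():
            if not isinstance(entry, Measurement):
                entry = Measurement(float(entry))
            if entry.sd is not None and entry.sd < 0:
                raise ScenarioError(
                    f"negative standard deviation for {rxn_id!r}"
                )
            if not math.isfinite(entry.value):
                raise ScenarioError(f"non-finite measurement for {rxn_id!r}")
            self.entries[rxn_id] = entry
        if not self.entries:
            raise ScenarioError("no measurements")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.entries

    def __getitem__(self, rxn_id: str) -> Measurement:
        return self.entries[rxn_id]

    def ids(self) -> list[str]:
        return list(self.entries)

    def validate_against(self, model: MetabolicModel) -> None:
        """Check ids exist and none has fixed model bounds (lb == ub).

        Measured rates are fixed through dedicated equality constraints, so a
        reaction whose bounds already pin its flux cannot additionally carry
        a measurement.
        """
        rxn_index = model.reaction_index
        for rxn_id in self.entries:
            if rxn_id not in rxn_index:
                raise ScenarioError(
                    f"measured reaction {rxn_id!r} not in model {model.id!r}"
                )
            rxn = model.reaction(rxn_id)
            if rxn.lower_bound == rxn.upper_bound:
                raise ScenarioError(
                    f"reaction {rxn_id!r} has fixed bounds "
                    f"(lb == ub == {rxn.lower_bound}); measured rates "
                    "require lb != ub"
                )

    def without(self, rxn_ids: Iterable[str]) -> "MeasurementSet":
        drop = set(rxn_ids)
        kept = {k: v for k, v in self.entries.items() if k not in drop}
        return MeasurementSet(kept)


# ---------------------------------------------------------------------------
# SBML I/O through cobrapy
# ---------------------------------------------------------------------------

def _cobra_to_model(
    cobra_model, biomass_reaction_id: str | None = None
) -> MetabolicModel:
    import cobra.util.solver as cobra_solver

    metabolites = []
    for met in cobra_model.metabolites:
        formula = None
        if met.formula:
            try:
                formula = parse_formula(met.formula)
            except FormulaError:
                formula = None  # tolerate R-group / polymer formulas on read
        metabolites.append(
            Metabolite(
                id=met.id,
                name=met.name or "",
                formula=formula,
                compartment=met.compartment or "",
            )
        )

    reactions = []
    missing_bounds = [
        r.id for r in cobra_model.reactions
        if r.lower_bound is None or r.upper_bound is None
    ]
    if missing_bounds:
        raise ModelError(f"reactions without bounds: {missing_bounds}")
    for rxn in cobra_model.reactions:
        reactions.append(
            Reaction(
                id=rxn.id,
                stoichiometry={m.id: c for m, c in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                name=rxn.name or "",
            )
        )

    objective = {
        rxn.id: coeff
        for rxn, coeff in cobra_solver.linear_reaction_coefficients(
            cobra_model
        ).items()
    }
    if biomass_reaction_id is None:
        if not objective:
            raise ModelError(
                "no biomass reaction: model has no FBC objective and no "
                "override was given"
            )
        biomass_reaction_id = max(objective, key=lambda k: abs(objective[k]))
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective=objective or {biomass_reaction_id: 1.0},
        biomass_reaction_id=biomass_reaction_id,
        id=cobra_model.id or "model",
    )


def _model_to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites:
        m = cobra.Metabolite(
            met.id, name=met.name, compartment=met.compartment or "c"
        )
        if met.formula and all(
            float(v).is_integer() for v in met.formula.values()
        ):
            m.formula = "".join(
                f"{el}{int(n) if int(n) != 1 else ''}"
                for el, n in met.formula.items()
            )
        mets[met.id] = m
    cm.add_metabolites(list(mets.values()))
    for rxn in model.reactions:
        r = cobra.Reaction(
            rxn.id,
            name=rxn.name,
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        cm.add_reactions([r])
        r.add_metabolites({mets[k]: v for k, v in rxn.stoichiometry.items()})
    cm.objective = {
        cm.reactions.get_by_id(k): v for k, v in model.objective.items()
    }
    return cm


def read_model(
    path: str | Path, biomass_reaction_id: str | None = None
) -> MetabolicModel:
    """Read an SBML Level-3 FBC model file into a :class:`MetabolicModel`.

    The biomass reaction is taken from the FBC objective unless
    ``biomass_reaction_id`` overrides it.
    """
    from cobra.io import read_sbml_model

    path = Path(path)
    if not path.exists():
        raise ModelError(f"model file not found: {path}")
    try:
        cobra_model = read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various I/O errors
        raise ModelError(f"cannot parse SBML file {path}: {exc}") from exc
    return _cobra_to_model(cobra_model, biomass_reaction_id)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML Level-3 with FBC (bounds, objective)."""
    from cobra.io import write_sbml_model

    write_sbml_model(_model_to_cobra(model), str(Path(path)))


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {"measurements", "adjust", "mode", "gam", "biomass", "weights"}


def read_scenario(path: str | Path, model: MetabolicModel | None = None):
    """Read a YAML/JSON scenario file into (MeasurementSet, AdjustmentConfig).

    Schema::

        measurements: {<rxn_id>: {value: <num>, sd: <num|null>}}
        adjust: {fluxes: bool, biomass: bool, gam: bool}
        mode: lp|qp
        gam: {max_change: <num>, metabolites: {atp: id, adp: id, ...}}
        biomass: {max_rel_change: <fraction>}
        weights: {flux_scheme: ..., flux_scale: ..., biomass_scheme: ...,
                  gam_weight: ...}

    A bare number is accepted as shorthand for ``{value: <num>}``.  When a
    model is supplied the measurement ids are validated against it.
    """
    from .balancing import AdjustmentConfig

    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise ScenarioError(f"scenario file {path} is not a mapping")
    unknown = set(data) - _SCENARIO_KEYS
    if unknown:
        raise ScenarioError(f"unknown scenario keys: {sorted(unknown)}")

    raw = data.get("measurements") or {}
    entries: dict[str, Measurement] = {}
    for rxn_id, entry in raw.items():
        if isinstance(entry, Mapping):
            extra = set(entry) - {"value", "sd"}
            if extra:
                raise ScenarioError(
                    f"unknown measurement keys for {rxn_id!r}: {sorted(extra)}"
                )
            sd = entry.get("sd")
            entries[rxn_id] = Measurement(
                float(entry["value"]), None if sd is None else float(sd)
            )
        else:
            entries[rxn_id] = Measurement(float(entry))
    measurements = MeasurementSet(entries)  # raises "no measurements" if empty
    if model is not None:
        measurements.validate_against(model)

    config = AdjustmentConfig.from_scenario_dict(data)
    return measurements, config
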