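"""Build and solve the LP/QP adjustment problems.

An infeasible FBA scenario — steady state ``N r = 0``, bounds, optional
general constraints ``A r <= b`` plus measured rates ``r_i = f_i`` — is made
feasible by introducing correction variables and minimizing their weighted
size:

* flux corrections ``delta_i`` with ``r_i = f_i - delta_i``;
* biomass-component corrections ``beta_k`` that shift the stoichiometric
  coefficient ``c_k`` of component k in the biomass reaction, subject to the
  mass-conservation side constraint ``sum_k beta_k MW_k = 0`` so the biomass
  still weighs 1 g/gDW;
* a growth-associated-maintenance correction ``beta_GAM in [-1, 1]`` that
  shifts all five GAM coefficients coherently by ``gamma * sign(c_k,GAM) *
  beta_GAM`` (gamma = maximally allowed GAM change, <= g).

Because the component balances contain ``beta_k * mu`` products, the growth
rate mu must be fixed (measured) whenever biomass or GAM adjustment is
enabled — otherwise the constraints would be bilinear.

The quadratic variant minimizes ``sum w_i delta_i^2 + sum z_k beta_k^2 +
w_GAM beta_GAM^2``; the linear variant splits every correction into
non-negative halves and minimizes the weighted sum of absolute values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .biomass import BiomassSpec, GamSpec, extract_biomass_spec
from .model_io import (
    MeasurementSet,
    Measurement,
    MetabolicModel,
    ScenarioError,
)
from .solvers import LinearSolution, solve_lp, solve_qp

__all__ = [
    "AdjustmentConfig",
    "AdjustmentProblem",
    "BalancingResult",
    "BalancingError",
    "default_flux_weights",
    "default_biomass_weights",
    "build_problem",
    "solve_problem",
    "balance",
    "recover_biomass_perturbation",
    "apply_result",
    "ov_range",
]

FLUX_SCHEMES = ("sd_reciprocal", "sd_reciprocal_squared", "relative")
BIOMASS_SCHEMES = ("relative_molar", "relative_mass")


class BalancingError(ValueError):
    """Raised for ill-posed adjustment problems."""


@dataclass
class AdjustmentConfig:
    """Which corrections are allowed, how they are weighted and bounded.

    ``flux_scale`` divides every flux-correction weight (lowering it makes
    flux corrections more expensive relative to biomass/GAM adjustments).
    ``max_rel_beta`` bounds each component change to that fraction of the
    coefficient being adjusted; ``gam_max_change`` caps the GAM change in
    mmol/gDW (effective gamma = min(g, gam_max_change)).
    """

    mode: str = "qp"                       # "qp" | "lp"
    adjust_fluxes: bool = True
    adjust_biomass: bool = False
    adjust_gam: bool = False
    flux_weight_scheme: str | Mapping[str, float] = "sd_reciprocal"
    flux_scale: float = 1.0
    biomass_weight_scheme: str | Mapping[str, float] = "relative_molar"
    gam_weight: float = 1.0
    max_rel_beta: float = 0.3
    gam_max_change: float | None = None
    gam_metabolite_overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("qp", "lp"):
            raise BalancingError(f"unknown mode {self.mode!r}")
        if self.flux_scale <= 0:
            raise BalancingError("flux_scale must be positive")
        if not (0 < self.max_rel_beta <= 1):
            raise BalancingError("max_rel_beta must be in (0, 1]")
        if self.gam_weight < 0:
            raise BalancingError("gam_weight must be non-negative")
        if isinstance(self.flux_weight_scheme, str):
            if self.flux_weight_scheme not in FLUX_SCHEMES:
                raise BalancingError(
                    f"unknown flux weight scheme {self.flux_weight_scheme!r}"
                )
        if isinstance(self.biomass_weight_scheme, str):
            if self.biomass_weight_scheme not in BIOMASS_SCHEMES:
                raise BalancingError(
                    f"unknown biomass weight scheme "
                    f"{self.biomass_weight_scheme!r}"
                )
        if not (self.adjust_fluxes or self.adjust_biomass or self.adjust_gam):
            raise BalancingError("no adjustment class enabled")

    @classmethod
    def from_scenario_dict(cls, data: Mapping) -> "AdjustmentConfig":
        adjust = dict(data.get("adjust") or {})
        weights = dict(data.get("weights") or {})
        gam_cfg = dict(data.get("gam") or {})
        biomass_cfg = dict(data.get("biomass") or {})
        for section, allowed in (
            (adjust, {"fluxes", "biomass", "gam"}),
            (weights, {"flux_scheme", "flux_scale", "biomass_scheme",
                       "gam_weight"}),
            (gam_cfg, {"max_change", "metabolites"}),
            (biomass_cfg, {"max_rel_change"}),
        ):
            unknown = set(section) - allowed
            if unknown:
                raise ScenarioError(
                    f"unknown scenario config keys: {sorted(unknown)}"
                )
        kwargs = dict(
            mode=str(data.get("mode", "qp")).lower(),
            adjust_fluxes=bool(adjust.get("fluxes", True)),
            adjust_biomass=bool(adjust.get("biomass", False)),
            adjust_gam=bool(adjust.get("gam", False)),
        )
        if "flux_scheme" in weights:
            kwargs["flux_weight_scheme"] = weights["flux_scheme"]
        if "flux_scale" in weights:
            kwargs["flux_scale"] = float(weights["flux_scale"])
        if "biomass_scheme" in weights:
            kwargs["biomass_weight_scheme"] = weights["biomass_scheme"]
        if "gam_weight" in weights:
            kwargs["gam_weight"] = float(weights["gam_weight"])
        if "max_change" in gam_cfg:
            kwargs["gam_max_change"] = float(gam_cfg["max_change"])
        if "metabolites" in gam_cfg:
            kwargs["gam_metabolite_overrides"] = dict(gam_cfg["metabolites"])
        if "max_rel_change" in biomass_cfg:
            kwargs["max_rel_beta"] = float(biomass_cfg["max_rel_change"])
        try:
            return cls(**kwargs)
        except BalancingError as exc:
            raise ScenarioError(str(exc)) from exc


def default_flux_weights(
    measurements: MeasurementSet,
    scheme: str | Mapping[str, float] = "sd_reciprocal",
    flux_scale: float = 1.0,
) -> tuple[dict[str, float], set[str]]:
    """Correction weights w_i per measured reaction, and the hard-fixed set.

    ``sd_reciprocal``: w_i = (1/sd_i)/flux_scale (the default; an entry with
    sd = 0 is exactly known, gets no correction variable and is hard-fixed).
    ``sd_reciprocal_squared``: w_i = (1/sd_i^2)/flux_scale.
    ``relative``: w_i = (1/|f_i|)/flux_scale, minimizing relative changes;
    f_i = 0 is hard-fixed.  A mapping gives custom weights directly.

    Entries without an sd under an sd-based scheme fall back to the relative
    scheme for that entry, with a warning.
    """
    if isinstance(scheme, Mapping):
        missing = [i for i, _ in measurements if i not in scheme]
        if missing:
            raise BalancingError(f"no custom weight for measurements {missing}")
        weights = {}
        hard = set()
        for rxn_id, _ in measurements:
            w = float(scheme[rxn_id])
            if w < 0:
                raise BalancingError(f"negative weight for {rxn_id!r}")
            if math.isinf(w):
                hard.add(rxn_id)
            else:
                weights[rxn_id] = w / flux_scale
        return weights, hard

    weights: dict[str, float] = {}
    hard: set[str] = set()
    for rxn_id, m in measurements:
        sd, f = m.sd, m.value
        entry_scheme = scheme
        if scheme in ("sd_reciprocal", "sd_reciprocal_squared"):
            if sd is None:
                warnings.warn(
                    f"measurement {rxn_id!r} has no standard deviation; "
                    "falling back to the relative weight 1/|f| for it",
                    stacklevel=2,
                )
                entry_scheme = "relative"
            elif sd == 0:
                hard.add(rxn_id)
                continue
        if entry_scheme == "relative" and f == 0:
            hard.add(rxn_id)
            continue
        if entry_scheme == "sd_reciprocal":
            weights[rxn_id] = (1.0 / sd) / flux_scale
        elif entry_scheme == "sd_reciprocal_squared":
            weights[rxn_id] = (1.0 / sd**2) / flux_scale
        else:
            weights[rxn_id] = (1.0 / abs(f)) / flux_scale
    return weights, hard


def default_biomass_weights(
    components: Mapping[str, float],
    mws: Mapping[str, float],
    scheme: str | Mapping[str, float],
    mode: str,
) -> dict[str, float]:
    """Component weights z_k.

    ``relative_molar`` minimizes relative molar changes: z_k = 1/c_k^2 in
    the QP (so z_k beta_k^2 = (beta_k/c_k)^2) and 1/|c_k| in the LP.
    ``relative_mass`` minimizes gram changes relative to the 1-g total:
    z_k = MW_k^2 (QP) / MW_k (LP).
    """
    if isinstance(scheme, Mapping):
        out = {}
        for k in components:
            if k not in scheme:
                raise BalancingError(f"no custom weight for component {k!r}")
            out[k] = float(scheme[k])
        return out
    z = {}
    for k, c in components.items():
        if scheme == "relative_molar":
            z[k] = 1.0 / c**2 if mode == "qp" else 1.0 / abs(c)
        else:  # relative_mass
            mw = mws[k]
            z[k] = mw**2 if mode == "qp" else mw
    return z


# ---------------------------------------------------------------------------
# Problem construction
# ---------------------------------------------------------------------------

@dataclass
class AdjustmentProblem:
    """Assembled LP/QP in dense form, plus variable bookkeeping.

    Variable order: all reaction rates first, then correction variables.
    In LP mode corrections are split into non-negative (plus, minus) pairs;
    ``delta_vars``/``beta_vars`` map each correction to its column index
    (QP) or (plus, minus) column pair (LP).
    """

    mode: str
    n_reactions: int
    var_names: list[str]
    lb: np.ndarray
    ub: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    A_ub: np.ndarray | None
    b_ub: np.ndarray | None
    cost: np.ndarray                      # diagonal q (QP) or linear c (LP)
    delta_vars: dict[str, tuple[int, ...]]
    beta_vars: dict[str, tuple[int, ...]]
    bgam_var: tuple[int, ...] | None
    hard_fixed: set[str]
    flux_weights: dict[str, float]
    beta_weights: dict[str, float]
    c_ref: dict[str, float]               # coefficient each beta_k adjusts
    mu: float | None
    model: MetabolicModel
    measurements: MeasurementSet
    spec: BiomassSpec | None
    gam: GamSpec | None
    config: AdjustmentConfig

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def correction_value(self, x: np.ndarray, cols: tuple[int, ...]) -> float:
        if len(cols) == 1:
            return float(x[cols[0]])
        return float(x[cols[0]] - x[cols[1]])


def build_problem(
    model: MetabolicModel,
    measurements: MeasurementSet,
    spec: BiomassSpec | None = None,
    gam: GamSpec | None = None,
    config: AdjustmentConfig | None = None,
) -> AdjustmentProblem:
    """Assemble the adjustment LP/QP for the given model and measurements."""
    config = config or AdjustmentConfig()
    measurements.validate_against(model)
    need_biomass = config.adjust_biomass or config.adjust_gam
    if need_biomass and (spec is None or gam is None):
        spec, gam = extract_biomass_spec(
            model,
            overrides=config.gam_metabolite_overrides or None,
            gamma_max=config.gam_max_change,
        )
    mu = None
    if need_biomass:
        if model.biomass_reaction_id not in measurements:
            raise BalancingError(
                "biomass/GAM adjustment requires a fixed growth rate: the "
                "component balances contain beta*mu products, so a free mu "
                "would make them bilinear; add the growth rate to the "
                "measurements"
            )
        mu = measurements[model.biomass_reaction_id].value
    if config.adjust_gam and gam is not None and gam.g <= 0:
        raise BalancingError("GAM adjustment requested but model GAM is 0")

    flux_weights: dict[str, float] = {}
    hard: set[str] = set()
    if config.adjust_fluxes:
        flux_weights, hard = default_flux_weights(
            measurements, config.flux_weight_scheme, config.flux_scale
        )
    else:
        hard = set(measurements.ids())
    if need_biomass:
        # growth is always hard-fixed when the biomass reaction is adjusted
        hard.add(model.biomass_reaction_id)
        flux_weights.pop(model.biomass_reaction_id, None)

    # adjustable component set C: biomass metabolites with nonzero reference
    # coefficient (c_k, or c_k,B when GAM is handled separately) and known MW
    beta_weights: dict[str, float] = {}
    c_ref: dict[str, float] = {}
    if config.adjust_biomass:
        assert spec is not None and gam is not None
        mws: dict[str, float] = {}
        for comp in spec.components:
            # GAM species are referenced by their biomass part c_k,B; a pure
            # GAM carrier (c_k,B = 0) is not an adjustable component — its
            # coefficient moves only through beta_GAM
            cref = (
                gam.c_B(comp.metabolite_id)
                if comp.metabolite_id in gam.split
                else comp.coefficient
            )
            if cref == 0.0:
                continue
            if comp.molecular_weight is None:
                raise BalancingError(
                    f"biomass component {comp.metabolite_id!r} has no "
                    "molecular weight; mass conservation needs MW_k for "
                    "every adjustable component"
                )
            c_ref[comp.metabolite_id] = cref
            mws[comp.metabolite_id] = comp.molecular_weight
        beta_weights = default_biomass_weights(
            c_ref, mws, config.biomass_weight_scheme, config.mode
        )

    # ---- variable layout ----
    lp = config.mode == "lp"
    var_names = [r.id for r in model.reactions]
    lb_list, ub_list = ([*model.bounds_arrays()[0]], [*model.bounds_arrays()[1]])
    cost = [0.0] * len(var_names)

    def add_var(name: str, lo: float, hi: float, w: float) -> int:
        var_names.append(name)
        lb_list.append(lo)
        ub_list.append(hi)
        cost.append(w)
        return len(var_names) - 1

    def add_correction(name: str, bound: float, w: float) -> tuple[int, ...]:
        if lp:
            ip = add_var(f"{name}+", 0.0, bound, w)
            im = add_var(f"{name}-", 0.0, bound, w)
            return (ip, im)
        return (add_var(name, -bound, bound, w),)

    delta_vars: dict[str, tuple[int, ...]] = {}
    for rxn_id, w in flux_weights.items():
        delta_vars[rxn_id] = add_correction(f"delta_{rxn_id}", math.inf, w)

    beta_vars: dict[str, tuple[int, ...]] = {}
    for met_id, w in beta_weights.items():
        bound = config.max_rel_beta * abs(c_ref[met_id])
        beta_vars[met_id] = add_correction(f"beta_{met_id}", bound, w)

    bgam_var = None
    if config.adjust_gam:
        bgam_var = add_correction("beta_GAM", 1.0, config.gam_weight)

    n = len(var_names)
    rxn_index = model.reaction_index
    gam_signs = gam.gam_metabolite_ids if (gam is not None) else {}

    # ---- equality rows ----
    rows: list[np.ndarray] = []
    rhs: list[float] = []

    def new_row() -> np.ndarray:
        row = np.zeros(n)
        rows.append(row)
        return row

    for met in model.metabolites:
        row = new_row()
        rhs.append(0.0)
        if met.id in beta_vars:
            cols = beta_vars[met.id]
            row[cols[0]] += mu
            if len(cols) == 2:
                row[cols[1]] -= mu
        if config.adjust_gam and met.id in gam_signs:
            coeff = gam.gamma * gam_signs[met.id] * mu
            row[bgam_var[0]] += coeff
            if len(bgam_var) == 2:
                row[bgam_var[1]] -= coeff
    N = model.stoichiometric_matrix()
    for i, row in enumerate(rows):
        row[: N.shape[1]] += N[i]

    # mass conservation: sum_k beta_k MW_k = 0
    if beta_vars:
        row = new_row()
        rhs.append(0.0)
        for comp in spec.components:
            if comp.metabolite_id not in beta_vars:
                continue
            cols = beta_vars[comp.metabolite_id]
            mw = comp.molecular_weight
            row[cols[0]] += mw
            if len(cols) == 2:
                row[cols[1]] -= mw

    # measurement links
    for rxn_id, m in measurements:
        row = new_row()
        rhs.append(m.value)
        row[rxn_index[rxn_id]] = 1.0
        if rxn_id in delta_vars and rxn_id not in hard:
            cols = delta_vars[rxn_id]
            row[cols[0]] += 1.0
            if len(cols) == 2:
                row[cols[1]] -= 1.0

    A_eq = np.vstack(rows)
    b_eq = np.array(rhs)

    A_ub = b_ub = None
    if model.general_constraints is not None:
        A_g, b_g = model.general_constraints
        A_ub = np.hstack([A_g, np.zeros((A_g.shape[0], n - A_g.shape[1]))])
        b_ub = np.asarray(b_g, dtype=float)

    return AdjustmentProblem(
        mode=config.mode,
        n_reactions=len(model.reactions),
        var_names=var_names,
        lb=np.array(lb_list),
        ub=np.array(ub_list),
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        cost=np.array(cost),
        delta_vars=delta_vars,
        beta_vars=beta_vars,
        bgam_var=bgam_var,
        hard_fixed=hard,
        flux_weights=flux_weights,
        beta_weights=beta_weights,
        c_ref=c_ref,
        mu=mu,
        model=model,
        measurements=measurements,
        spec=spec,
        gam=gam,
        config=config,
    )


# ---------------------------------------------------------------------------
# Solving and results
# ---------------------------------------------------------------------------

@dataclass
class MeasurementAdjustment:
    measured: float
    adjusted: float
    delta: float
    sd: float | None
    hard: bool


@dataclass
class ComponentAdjustment:
    coefficient: float   # the (reference) coefficient that was adjusted
    beta: float
    adjusted: float


@dataclass
class BalancingResult:
    """Solution of an adjustment problem.

    ``gam_adjusted`` reports g' = g + gamma * beta_GAM: a positive beta_GAM
    increases the magnitude of every GAM coefficient.  At an optimum the
    steady state, the measurement links and the mass-conservation constraint
    all hold within solver tolerance.
    """

    status: str
    objective_value: float | None
    fluxes: dict[str, float]
    measurements: dict[str, MeasurementAdjustment]
    components: dict[str, ComponentAdjustment]
    beta_gam: float | None
    gamma: float | None
    gam_original: float | None
    gam_adjusted: float | None
    gam_signs: dict[str, int]
    mode: str
    message: str = ""
    x: np.ndarray | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def mass_conservation_residual(self, spec: BiomassSpec) -> float:
        """|sum_k beta_k MW_k| over the adjusted components (0 at optimum)."""
        total = 0.0
        for comp in spec.components:
            adj = self.components.get(comp.metabolite_id)
            if adj is not None:
                total += adj.beta * comp.molecular_weight
        return abs(total)

    def to_json_dict(self) -> dict:
        return {
            "status": self.status,
            "mode": self.mode,
            "objective_value": self.objective_value,
            "beta_gam": self.beta_gam,
            "gam_original": self.gam_original,
            "gam_adjusted": self.gam_adjusted,
            "measurements": {
                k: {"measured": v.measured, "adjusted": v.adjusted,
                    "delta": v.delta, "sd": v.sd, "hard": v.hard}
                for k, v in self.measurements.items()
            },
            "components": {
                k: {"coefficient": v.coefficient, "beta": v.beta,
                    "adjusted": v.adjusted}
                for k, v in self.components.items()
            },
        }

    def to_tsv(self) -> str:
        lines = ["kind\tid\treference\tadjusted\tchange"]
        for k, v in self.measurements.items():
            lines.append(
                f"measurement\t{k}\t{v.measured:.6g}\t{v.adjusted:.6g}"
                f"\t{-v.delta:.6g}"
            )
        for k, v in self.components.items():
            lines.append(
                f"component\t{k}\t{v.coefficient:.6g}\t{v.adjusted:.6g}"
                f"\t{v.beta:.6g}"
            )
        if self.gam_adjusted is not None:
            lines.append(
                f"gam\tGAM\t{self.gam_original:.6g}\t{self.gam_adjusted:.6g}"
                f"\t{self.gam_adjusted - self.gam_original:.6g}"
            )
        return "\n".join(lines) + "\n"


def _failed_result(problem: AdjustmentProblem, sol: LinearSolution):
    return BalancingResult(
        status=sol.status,
        objective_value=None,
        fluxes={},
        measurements={},
        components={},
        beta_gam=None,
        gamma=problem.gam.gamma if problem.gam else None,
        gam_original=problem.gam.g if problem.gam else None,
        gam_adjusted=None,
        gam_signs=dict(problem.gam.gam_metabolite_ids) if problem.gam else {},
        mode=problem.mode,
        message=sol.message,
    )


def solve_problem(problem: AdjustmentProblem) -> BalancingResult:
    """Solve an assembled adjustment problem with the mode's backend."""
    if problem.mode == "lp":
        sol = solve_lp(
            problem.cost, problem.A_eq, problem.b_eq, problem.lb, problem.ub,
            problem.A_ub, problem.b_ub,
        )
    else:
        sol = solve_qp(
            problem.cost, problem.A_eq, problem.b_eq, problem.lb, problem.ub,
            problem.A_ub, problem.b_ub,
        )
    if sol.status != "optimal":
        return _failed_result(problem, sol)

    x = sol.x
    fluxes = {
        r.id: float(x[j]) for j, r in enumerate(problem.model.reactions)
    }
    meas: dict[str, MeasurementAdjustment] = {}
    for rxn_id, m in problem.measurements:
        if rxn_id in problem.delta_vars:
            delta = problem.correction_value(x, problem.delta_vars[rxn_id])
            hard = False
        else:
            delta = 0.0
            hard = True
        meas[rxn_id] = MeasurementAdjustment(
            measured=m.value,
            adjusted=m.value - delta,
            delta=delta,
            sd=m.sd,
            hard=hard,
        )
    comps: dict[str, ComponentAdjustment] = {}
    for met_id, cols in problem.beta_vars.items():
        beta = problem.correction_value(x, cols)
        cref = problem.c_ref[met_id]
        comps[met_id] = ComponentAdjustment(
            coefficient=cref, beta=beta, adjusted=cref + beta
        )
    beta_gam = gam_adjusted = None
    gamma = g = None
    if problem.gam is not None:
        gamma, g = problem.gam.gamma, problem.gam.g
    if problem.bgam_var is not None:
        beta_gam = problem.correction_value(x, problem.bgam_var)
        gam_adjusted = g + gamma * beta_gam
    return BalancingResult(
        status="optimal",
        objective_value=float(sol.objective_value),
        fluxes=fluxes,
        measurements=meas,
        components=comps,
        beta_gam=beta_gam,
        gamma=gamma,
        gam_original=g,
        gam_adjusted=gam_adjusted,
        gam_signs=dict(problem.gam.gam_metabolite_ids) if problem.gam else {},
        mode=problem.mode,
        message=sol.message,
        x=x,
    )


def balance(
    model: MetabolicModel,
    measurements: MeasurementSet,
    config: AdjustmentConfig | None = None,
    spec: BiomassSpec | None = None,
    gam: GamSpec | None = None,
) -> BalancingResult:
    """Build and solve the adjustment problem in one step."""
    return solve_problem(build_problem(model, measurements, spec, gam, config))


def recover_biomass_perturbation(
    model: MetabolicModel,
    fixed_fluxes: Mapping[str, float],
    spec: BiomassSpec | None = None,
    gam: GamSpec | None = None,
    config: AdjustmentConfig | None = None,
) -> BalancingResult:
    """Biomass adjustment with every reaction rate fixed.

    With the full flux vector pinned, each component balance determines its
    beta_k pointwise, so a model whose biomass was perturbed mass-neutrally
    by Delta returns beta_k = -Delta_k exactly (to solver tolerance).
    """
    if config is None:
        config = AdjustmentConfig(
            mode="qp", adjust_fluxes=False, adjust_biomass=True,
            max_rel_beta=1.0,
        )
    missing = [r.id for r in model.reactions if r.id not in fixed_fluxes]
    if missing:
        raise BalancingError(
            f"fixed flux vector must cover every reaction; missing {missing}"
        )
    measurements = MeasurementSet(
        {rxn_id: Measurement(float(v), sd=0.0)
         for rxn_id, v in fixed_fluxes.items()}
    )
    return balance(model, measurements, config, spec, gam)


def apply_result(
    model: MetabolicModel, result: BalancingResult
) -> MetabolicModel:
    """Write the biomass adjustments of an optimal result into the model.

    Component coefficients become c_k + beta_k and the five GAM coefficients
    move by gamma * sign(c_k,GAM) * beta_GAM.  Measured-flux corrections are
    data, not model content, and are not written.
    """
    if not result.optimal:
        raise BalancingError(
            f"cannot apply a result with status {result.status!r}"
        )
    new = model.copy()
    idx = new.reaction_index[new.biomass_reaction_id]
    biomass = new.reactions[idx]
    stoich = dict(biomass.stoichiometry)
    for met_id, adj in result.components.items():
        stoich[met_id] = stoich.get(met_id, 0.0) + adj.beta
    if result.beta_gam is not None:
        for met_id, sign in result.gam_signs.items():
            stoich[met_id] = (
                stoich.get(met_id, 0.0)
                + result.gamma * sign * result.beta_gam
            )
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    new.reactions[idx] = replace(biomass, stoichiometry=stoich)
    new.validate()
    return new


def ov_range(
    problem: AdjustmentProblem,
    result: BalancingResult,
    quantity: str | Mapping[str, float],
    rel_tol: float = 1e-6,
) -> tuple[float, float]:
    """Min/max of a named quantity over the optimal face of an LP.

    LP optima can be non-unique; the objective value is canonical but a
    reported quantity (e.g. the adjusted GAM) may vary across alternate
    optima.  This fixes the objective at OV*(1+rel_tol) and minimizes /
    maximizes the quantity: ``"gam"`` for the adjusted GAM g', or a mapping
    reaction-id -> coefficient for a linear function of the fluxes.
    """
    if problem.mode != "lp":
        raise BalancingError(
            "the fixed-OV post-pass applies to LP problems (QP optima of "
            "strictly weighted corrections are unique)"
        )
    if not result.optimal:
        raise BalancingError("ov_range needs an optimal result")
    n = problem.n_vars
    target = np.zeros(n)
    if quantity == "gam":
        if problem.bgam_var is None:
            raise BalancingError("problem has no GAM adjustment variable")
        cols = problem.bgam_var
        target[cols[0]] = problem.gam.gamma
        if len(cols) == 2:
            target[cols[1]] = -problem.gam.gamma
        offset = problem.gam.g
    elif isinstance(quantity, Mapping):
        rxn_index = problem.model.reaction_index
        for rxn_id, coeff in quantity.items():
            target[rxn_index[rxn_id]] = coeff
        offset = 0.0
    else:
        raise BalancingError(f"unknown quantity {quantity!r}")

    ov = result.objective_value
    A_ub = problem.cost.reshape(1, -1)
    b_ub = np.array([ov * (1 + rel_tol) + 1e-12])
    if problem.A_ub is not None:
        A_ub = np.vstack([problem.A_ub, A_ub])
        b_ub = np.concatenate([problem.b_ub, b_ub])
    out = []
    for sign in (1.0, -1.0):
        sol = solve_lp(
            sign * target, problem.A_eq, problem.b_eq, problem.lb,
            problem.ub, A_ub, b_ub,
        )
        if sol.status != "optimal":
            raise BalancingError(f"post-pass solve failed: {sol.status}")
        out.append(sign * sol.objective_value + offset)
    return min(out), max(out)
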