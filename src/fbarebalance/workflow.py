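"""The step 0–3 application guideline and scenario-comparison reports.

The recommended way to use the adjustment machinery is to run the whole
ladder and compare, rather than trusting any single setting:

* step 0 — diagnostics: is the bare model feasible, do the measured values
  lie inside the FVA ranges, do the elemental balances reveal gross
  imbalances, is an NGAM-like fixed demand present?
* step 1 — flux corrections only (LP and QP);
* step 2 — biomass reaction adjustments only: (a) GAM alone, (b) components
  alone, (c) both — any of these may legitimately be infeasible;
* step 3 — everything merged.

Each scenario keeps its own configuration and result; the comparison
renders as a table with one row per measured rate and reported biomass
quantity and one column per scenario, with "Unchanged" printed for
corrections below the display threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping

from .balancing import (
    AdjustmentConfig,
    BalancingError,
    BalancingResult,
    balance,
)
from .biomass import BiomassSpec, GamSpec, extract_biomass_spec
from .diagnostics import (
    ElementalBalanceReport,
    FvaRange,
    elemental_balance,
    fva_precheck,
)
from .model_io import MeasurementSet, MetabolicModel
from .solvers import fba_optimum

__all__ = [
    "ScenarioComparison",
    "GuidelineStep0",
    "run_guideline",
    "render_comparison",
    "detect_ngam_reaction",
]

UNCHANGED_THRESHOLD = 5e-4  # display only; raw values are always retained
BOUND_HIT_TOL = 1e-6


def detect_ngam_reaction(model: MetabolicModel) -> str | None:
    """Find an ATP-hydrolysis-like reaction with a positive lower bound.

    Non-growth-associated maintenance is conventionally a forced flux
    through plain ATP + H2O -> ADP + Pi + H+; its fixed lower bound is not
    adjustable by the balancing problems, so the guideline flags it (the
    bound can be turned into a measurement instead).
    """
    for rxn in model.reactions:
        if rxn.id == model.biomass_reaction_id or rxn.lower_bound <= 0:
            continue
        consumed = {m for m, c in rxn.stoichiometry.items() if c < 0}
        produced = {m for m, c in rxn.stoichiometry.items() if c > 0}
        if len(rxn.stoichiometry) == 5 and any(
            "atp" in m.lower() for m in consumed
        ) and any("adp" in m.lower() for m in produced):
            return rxn.id
    return None


@dataclass
class GuidelineStep0:
    model_feasible: bool
    fixed_system_feasible: bool
    fva: dict[str, FvaRange]
    elemental: ElementalBalanceReport | None
    ngam_reaction: str | None
    notes: list[str] = field(default_factory=list)


@dataclass
class ScenarioComparison:
    """Results of the guideline scenarios over one model + measurement set."""

    model_id: str
    step0: GuidelineStep0
    scenarios: dict[str, tuple[AdjustmentConfig, BalancingResult]]
    flags: dict[str, list[str]] = field(default_factory=dict)

    def result(self, label: str) -> BalancingResult:
        return self.scenarios[label][1]


def _bound_flags(
    model: MetabolicModel, config: AdjustmentConfig, result: BalancingResult
) -> list[str]:
    flags = []
    if not result.optimal:
        return flags
    for rxn_id, adj in result.measurements.items():
        rxn = model.reaction(rxn_id)
        if (
            abs(adj.adjusted - rxn.lower_bound) < BOUND_HIT_TOL
            or abs(adj.adjusted - rxn.upper_bound) < BOUND_HIT_TOL
        ):
            flags.append(f"corrected flux of {rxn_id} lies on a reaction bound")
    for met_id, adj in result.components.items():
        limit = config.max_rel_beta * abs(adj.coefficient)
        if limit - abs(adj.beta) < BOUND_HIT_TOL:
            flags.append(f"component change of {met_id} is at its bound")
    if result.beta_gam is not None and 1.0 - abs(result.beta_gam) < BOUND_HIT_TOL:
        flags.append("GAM change is at the maximal allowed change gamma")
    return flags


def run_guideline(
    model: MetabolicModel,
    measurements: MeasurementSet,
    base_config: AdjustmentConfig | None = None,
    spec: BiomassSpec | None = None,
    gam: GamSpec | None = None,
) -> ScenarioComparison:
    """Run diagnostics plus the step 1/2/3 scenario ladder.

    Solver failures and infeasibilities in one scenario are recorded and do
    not abort the remaining scenarios.
    """
    base_config = base_config or AdjustmentConfig()
    if spec is None or gam is None:
        spec, gam = extract_biomass_spec(
            model,
            overrides=base_config.gam_metabolite_overrides or None,
            gamma_max=base_config.gam_max_change,
        )

    # ---- step 0 ----
    notes: list[str] = []
    model_feasible = fba_optimum(model).status == "optimal"
    fixed = {rxn_id: m.value for rxn_id, m in measurements}
    fixed_feasible = (
        fba_optimum(model, {model.biomass_reaction_id: 0.0}, fixed=fixed).status
        == "optimal"
    )
    fva = fva_precheck(model, measurements)
    out_of_range = [k for k, v in fva.items() if not v.in_range]
    if out_of_range:
        notes.append(
            "measured values outside the model's FVA range: "
            + ", ".join(out_of_range)
            + "; consider relaxing the corresponding reaction bounds"
        )
    try:
        elemental = elemental_balance(model, measurements, spec, gam)
    except ValueError as exc:
        elemental = None
        notes.append(f"elemental balance unavailable: {exc}")
    ngam = detect_ngam_reaction(model)
    if ngam is not None:
        notes.append(
            f"reaction {ngam!r} looks like an NGAM demand with a fixed lower "
            "bound; consider setting the bound to zero and supplying the old "
            "bound as a measurement to make it adjustable"
        )
    step0 = GuidelineStep0(
        model_feasible=model_feasible,
        fixed_system_feasible=fixed_feasible,
        fva=fva,
        elemental=elemental,
        ngam_reaction=ngam,
        notes=notes,
    )

    # ---- scenario ladder ----
    growth_measured = model.biomass_reaction_id in measurements
    plans: list[tuple[str, AdjustmentConfig]] = [
        ("step1_lp", dc_replace(base_config, mode="lp", adjust_fluxes=True,
                                adjust_biomass=False, adjust_gam=False)),
        ("step1_qp", dc_replace(base_config, mode="qp", adjust_fluxes=True,
                                adjust_biomass=False, adjust_gam=False)),
    ]
    if growth_measured and gam.g > 0:
        plans.append(
            ("step2a_gam", dc_replace(base_config, adjust_fluxes=False,
                                      adjust_biomass=False, adjust_gam=True))
        )
    if growth_measured:
        plans.append(
            ("step2b_biomass", dc_replace(base_config, adjust_fluxes=False,
                                          adjust_biomass=True,
                                          adjust_gam=False))
        )
        plans.append(
            ("step2c_both", dc_replace(base_config, adjust_fluxes=False,
                                       adjust_biomass=True,
                                       adjust_gam=gam.g > 0))
        )
        plans.append(
            ("step3_merged", dc_replace(base_config, adjust_fluxes=True,
                                        adjust_biomass=True,
                                        adjust_gam=gam.g > 0))
        )

    scenarios: dict[str, tuple[AdjustmentConfig, BalancingResult]] = {}
    flags: dict[str, list[str]] = {}
    for label, config in plans:
        try:
            result = balance(model, measurements, config, spec, gam)
        except BalancingError as exc:
            result = BalancingResult(
                status="solver_error", objective_value=None, fluxes={},
                measurements={}, components={}, beta_gam=None,
                gamma=gam.gamma if gam else None,
                gam_original=gam.g if gam else None, gam_adjusted=None,
                gam_signs={}, mode=config.mode, message=str(exc),
            )
        scenarios[label] = (config, result)
        flags[label] = _bound_flags(model, config, result)

    return ScenarioComparison(
        model_id=model.id, step0=step0, scenarios=scenarios, flags=flags
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _format_value(adj, hard: bool) -> str:
    if hard:
        return "Fixed"
    if abs(adj.delta) < UNCHANGED_THRESHOLD:
        return "Unchanged"
    return f"{adj.adjusted:.4g}"


def _comparison_rows(comparison: ScenarioComparison):
    labels = list(comparison.scenarios)
    all_measured: list[str] = []
    for _, result in comparison.scenarios.values():
        for rxn_id in result.measurements:
            if rxn_id not in all_measured:
                all_measured.append(rxn_id)
    rows = []
    for rxn_id in all_measured:
        row = {"quantity": rxn_id}
        for label in labels:
            result = comparison.result(label)
            adj = result.measurements.get(rxn_id)
            if not result.optimal:
                row[label] = result.status
            elif adj is None:
                row[label] = ""
            else:
                row[label] = _format_value(adj, adj.hard)
        ref = next(
            r.measurements[rxn_id]
            for _, r in comparison.scenarios.values()
            if rxn_id in r.measurements
        )
        row["measured"] = (
            f"{ref.measured:.4g}"
            + (f" ({ref.sd:.4g})" if ref.sd is not None else "")
        )
        rows.append(row)

    components: list[str] = []
    for _, result in comparison.scenarios.values():
        for met_id in result.components:
            if met_id not in components:
                components.append(met_id)
    for met_id in components:
        row = {"quantity": f"biomass {met_id}"}
        ref_val = None
        for label in labels:
            result = comparison.result(label)
            adj = result.components.get(met_id)
            if not result.optimal:
                row[label] = result.status
            elif adj is None:
                row[label] = "Fixed"
            else:
                ref_val = adj.coefficient
                if abs(adj.beta) < UNCHANGED_THRESHOLD * abs(adj.coefficient):
                    row[label] = "Unchanged"
                else:
                    row[label] = (
                        f"{adj.adjusted:.4g} "
                        f"({100 * adj.beta / adj.coefficient:+.3g}%)"
                    )
        row["measured"] = f"{ref_val:.4g}" if ref_val is not None else ""
        rows.append(row)

    if any(r.gam_original is not None for _, r in comparison.scenarios.values()):
        row = {"quantity": "GAM"}
        g0 = None
        for label in labels:
            result = comparison.result(label)
            if not result.optimal:
                row[label] = result.status
            elif result.gam_adjusted is None:
                row[label] = "Fixed"
            else:
                row[label] = f"{result.gam_adjusted:.4g}"
            if result.gam_original is not None:
                g0 = result.gam_original
        row["measured"] = f"{g0:.4g}" if g0 is not None else ""
        rows.append(row)

    row = {"quantity": "OV"}
    for label in labels:
        result = comparison.result(label)
        row[label] = (
            f"{result.objective_value:.4g}" if result.optimal else result.status
        )
    row["measured"] = ""
    rows.append(row)
    return labels, rows


def render_comparison(comparison: ScenarioComparison, format: str = "tsv") -> str:
    """Render the scenario table as ``tsv``, ``markdown`` or ``json``.

    The JSON form carries the raw numbers (no "Unchanged" thresholding) and
    round-trips: rendering the parsed JSON reproduces the same table.
    """
    if format == "json":
        payload = {
            "model": comparison.model_id,
            "step0": {
                "model_feasible": comparison.step0.model_feasible,
                "fixed_system_feasible": comparison.step0.fixed_system_feasible,
                "fva": {
                    k: {"measured": v.measured, "min": v.minimum,
                        "max": v.maximum, "in_range": v.in_range}
                    for k, v in comparison.step0.fva.items()
                },
                "elemental_net": (
                    comparison.step0.elemental.net
                    if comparison.step0.elemental else None
                ),
                "ngam_reaction": comparison.step0.ngam_reaction,
                "notes": comparison.step0.notes,
            },
            "scenarios": {
                label: result.to_json_dict()
                for label, (_, result) in comparison.scenarios.items()
            },
            "flags": comparison.flags,
        }
        return json.dumps(payload, indent=2, default=float)

    labels, rows = _comparison_rows(comparison)
    header = ["quantity", "measured", *labels]
    if format == "tsv":
        lines = ["\t".join(header)]
        for row in rows:
            lines.append("\t".join(str(row.get(col, "")) for col in header))
        return "\n".join(lines) + "\n"
    if format == "markdown":
        lines = [
            "| " + " | ".join(header) + " |",
            "|" + "|".join("---" for _ in header) + "|",
        ]
        for row in rows:
            lines.append(
                "| " + " | ".join(str(row.get(col, "")) for col in header) + " |"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")
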