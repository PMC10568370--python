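"""Recover a known mass-neutral biomass perturbation.

The biomass reaction of a toy model is deliberately modified: one
component's coefficient is raised and another is lowered so the biomass
still weighs 1 g/gDW.  Fixing the *unperturbed* model's FBA flux vector in
the perturbed model is infeasible; minimal biomass adjustment under the
mass-conservation constraint then returns exactly the corrections
beta_k = -Delta_k, restoring the original coefficients.
"""

from fbarebalance import (
    ToyModelParams,
    make_toy_model,
    perturb_biomass,
    recover_biomass_perturbation,
)
from fbarebalance.solvers import fba_optimum

model = make_toy_model(ToyModelParams(seed=11))
solution = fba_optimum(model)
r_star = {r.id: float(solution.x[j]) for j, r in enumerate(model.reactions)}

c1 = model.biomass_reaction.stoichiometry["bm1"]
perturbed = perturb_biomass(
    model, {"bm1": 0.2 * abs(c1)}, preserve_mass=True, balance_with="bm2"
)
print("introduced perturbation (Delta_k, mmol/gDW):")
for met_id in ("bm1", "bm2", "bm3"):
    delta = (perturbed.biomass_reaction.stoichiometry[met_id]
             - model.biomass_reaction.stoichiometry[met_id])
    print(f"  {met_id}: {delta:+.6f}")

result = recover_biomass_perturbation(perturbed, r_star)
print(f"\nrecovery status: {result.status}, OV = "
      f"{result.objective_value:.4g}")
print("computed corrections (beta_k):")
for met_id in ("bm1", "bm2", "bm3"):
    adj = result.components[met_id]
    print(f"  {met_id}: beta {adj.beta:+.6f} -> adjusted coefficient "
          f"{adj.adjusted:.6f} (original {model.biomass_reaction.stoichiometry[met_id]:.6f})")

print(
    "\nEach beta equals minus the introduced Delta: with every flux "
    "fixed, the component balances pin the corrections pointwise."
)
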