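"""Shared test utilities: independent optimization oracles.

The oracles deliberately avoid the code paths of the package's own solvers:
LPs are re-solved with GLPK through optlang, QPs with SLSQP (multi-start
from random LP vertices, keeping the best feasible value).
"""

from __future__ import annotations

import numpy as np
import scipy.optimize as sopt

from fbarebalance.balancing import AdjustmentProblem


def glpk_lp_oracle(problem: AdjustmentProblem) -> float:
    """Solve the assembled LP independently with GLPK via optlang."""
    from optlang.glpk_interface import Constraint, Model, Objective, Variable

    p = problem
    variables = [
        Variable(
            f"x{i}",
            lb=None if np.isneginf(p.lb[i]) else float(p.lb[i]),
            ub=None if np.isposinf(p.ub[i]) else float(p.ub[i]),
        )
        for i in range(p.n_vars)
    ]
    model = Model()
    constraints = []
    for row, b in zip(p.A_eq, p.b_eq):
        expr = sum(float(c) * variables[i] for i, c in enumerate(row) if c)
        constraints.append(Constraint(expr, lb=float(b), ub=float(b)))
    if p.A_ub is not None:
        for row, b in zip(p.A_ub, p.b_ub):
            expr = sum(float(c) * variables[i] for i, c in enumerate(row) if c)
            constraints.append(Constraint(expr, ub=float(b)))
    model.add(constraints)
    model.objective = Objective(
        sum(float(c) * variables[i] for i, c in enumerate(p.cost) if c),
        direction="min",
    )
    status = model.optimize()
    assert status == "optimal", f"GLPK oracle status {status}"
    return float(model.objective.value)


def slsqp_qp_oracle(
    problem: AdjustmentProblem, n_starts: int = 6, seed: int = 0
) -> float:
    """Best feasible SLSQP value over multiple LP-vertex starts."""
    from fbarebalance.solvers import solve_lp

    p = problem
    rng = np.random.default_rng(seed)
    q = p.cost
    constraints = [
        {
            "type": "eq",
            "fun": lambda x, A=p.A_eq, b=p.b_eq: A @ x - b,
            "jac": lambda x, A=p.A_eq: A,
        }
    ]
    if p.A_ub is not None:
        constraints.append(
            {
                "type": "ineq",
                "fun": lambda x, A=p.A_ub, b=p.b_ub: b - A @ x,
                "jac": lambda x, A=p.A_ub: -A,
            }
        )
    bounds = [
        (None if np.isneginf(l) else l, None if np.isposinf(u) else u)
        for l, u in zip(p.lb, p.ub)
    ]
    best = np.inf
    for s in range(n_starts):
        c = rng.normal(size=p.n_vars) if s else np.zeros(p.n_vars)
        start = solve_lp(c, p.A_eq, p.b_eq, p.lb, p.ub, p.A_ub, p.b_ub)
        if start.status != "optimal":
            continue
        res = sopt.minimize(
            lambda x: float(x @ (q * x)),
            start.x,
            jac=lambda x: 2.0 * q * x,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        if res.x is None:
            continue
        x = np.asarray(res.x)
        feasible = (
            np.max(np.abs(p.A_eq @ x - p.b_eq), initial=0.0) < 1e-7
            and np.all(x >= p.lb - 1e-8)
            and np.all(x <= p.ub + 1e-8)
        )
        if p.A_ub is not None:
            feasible &= np.max(p.A_ub @ x - p.b_ub, initial=0.0) < 1e-7
        if feasible:
            best = min(best, float(x @ (q * x)))
    assert np.isfinite(best), "QP oracle found no feasible point"
    return best


def relative_perturbation(model, rho: float):
    """Mass-neutral biomass perturbation: shrink the lightest component by
    the relative amount rho, compensate with the heaviest.

    Returns (perturbed model, expected beta per component id).
    """
    from fbarebalance import extract_biomass_spec, perturb_biomass

    spec, _ = extract_biomass_spec(model)
    organic = {
        c.metabolite_id: c
        for c in spec.components
        if c.metabolite_id.startswith("bm")
    }
    mass = {
        k: -c.coefficient * c.molecular_weight for k, c in organic.items()
    }
    small = min(mass, key=mass.get)
    big = max(mass, key=mass.get)
    delta = rho * abs(organic[small].coefficient)
    perturbed = perturb_biomass(
        model, {small: delta}, preserve_mass=True, balance_with=big
    )
    original = model.biomass_reaction.stoichiometry
    shifted = perturbed.biomass_reaction.stoichiometry
    expected_beta = {
        k: original[k] - shifted[k] for k in organic
    }
    return perturbed, expected_beta
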