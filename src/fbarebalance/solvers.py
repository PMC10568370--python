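"""LP and convex-QP backends on top of scipy.optimize.

Two solver routes, one interface:

* linear programs run through :func:`scipy.optimize.linprog` (HiGHS, dual
  simplex, deterministic default settings);
* convex quadratic programs (diagonal positive-semidefinite Hessians, as
  produced by weighted sum-of-squares correction objectives) run through
  ``trust-constr`` from a feasible interior start, followed by an
  active-set KKT polish that solves the equality-constrained optimum to
  near machine precision and is accepted only when it is feasible and not
  worse.

Both routes report a common status vocabulary: ``optimal``, ``infeasible``,
``unbounded``, ``solver_error``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.linalg
import scipy.optimize as sopt
from scipy.optimize import Bounds, LinearConstraint

__all__ = ["LinearSolution", "solve_lp", "solve_qp", "fba_optimum"]

# Constraint feasibility tolerances (absolute): LP solutions come from a
# simplex basis and are tight; QP solutions are iterative.
LP_FEAS_TOL = 1e-9
QP_FEAS_TOL = 1e-6

_LP_STATUS = {0: "optimal", 1: "solver_error", 2: "infeasible",
              3: "unbounded", 4: "solver_error"}


@dataclass
class LinearSolution:
    status: str
    x: np.ndarray | None
    objective_value: float | None
    message: str = ""


def _as_bounds_list(lb: np.ndarray, ub: np.ndarray) -> list[tuple]:
    return [
        (None if np.isneginf(l) else l, None if np.isposinf(u) else u)
        for l, u in zip(lb, ub)
    ]


def solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray | None,
    b_eq: np.ndarray | None,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
) -> LinearSolution:
    """Minimize ``c @ x`` subject to equalities, inequalities and bounds."""
    res = sopt.linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=_as_bounds_list(lb, ub),
        method="highs",
    )
    status = _LP_STATUS.get(res.status, "solver_error")
    if status != "optimal":
        return LinearSolution(status, None, None, res.message)
    return LinearSolution("optimal", res.x, float(res.fun), res.message)


def _feasible_point(
    A_eq: np.ndarray | None,
    b_eq: np.ndarray | None,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None,
    b_ub: np.ndarray | None,
) -> LinearSolution:
    n = len(lb)
    return solve_lp(np.zeros(n), A_eq, b_eq, lb, ub, A_ub, b_ub)


def _kkt_polish(
    q: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None,
    b_ub: np.ndarray | None,
    x: np.ndarray,
    active_tol: float = 1e-7,
) -> np.ndarray | None:
    """Re-solve the QP with the active set at ``x`` as equalities.

    Minimizing ``sum q_i x_i^2`` subject to ``A x = b`` has the KKT system
    ``[[2 diag(q), A^T], [A, 0]] [x; lam] = [0; b]``; a least-squares solve
    handles the rank-deficient case (directions with zero cost and no
    constraint are left at their minimum-norm value, which does not affect
    the objective).  Returns None when the polished point is not feasible.
    """
    rows = [A_eq]
    rhs = [b_eq]
    n = len(x)
    at_lower = np.flatnonzero(np.isfinite(lb) & (x - lb < active_tol))
    at_upper = np.flatnonzero(np.isfinite(ub) & (ub - x < active_tol))
    for idx, vals in ((at_lower, lb), (at_upper, ub)):
        if idx.size:
            E = np.zeros((idx.size, n))
            E[np.arange(idx.size), idx] = 1.0
            rows.append(E)
            rhs.append(vals[idx])
    if A_ub is not None and len(A_ub):
        slack = b_ub - A_ub @ x
        tight = np.flatnonzero(slack < active_tol)
        if tight.size:
            rows.append(A_ub[tight])
            rhs.append(b_ub[tight])
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    m = A.shape[0]
    kkt = np.zeros((n + m, n + m))
    kkt[:n, :n] = np.diag(2.0 * q)
    kkt[:n, n:] = A.T
    kkt[n:, :n] = A
    sol, *_ = scipy.linalg.lstsq(kkt, np.concatenate([np.zeros(n), b]),
                                 lapack_driver="gelsd")
    x_new = sol[:n]
    # accept only a genuinely feasible polish
    if np.any(x_new < lb - QP_FEAS_TOL) or np.any(x_new > ub + QP_FEAS_TOL):
        return None
    if np.max(np.abs(A_eq @ x_new - b_eq), initial=0.0) > QP_FEAS_TOL:
        return None
    if A_ub is not None and len(A_ub):
        if np.max(A_ub @ x_new - b_ub, initial=0.0) > QP_FEAS_TOL:
            return None
    return np.clip(x_new, lb, ub)


def _reduce_equalities(
    A_eq: np.ndarray, b_eq: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Replace ``A x = b`` by an equivalent full-row-rank system.

    Steady-state matrices routinely contain redundant rows (conserved
    moieties) and fixing every flux makes the system overdetermined, which
    the trust-region solver rejects.  For a consistent system the SVD rows
    ``S V^T x = U^T b`` restricted to the nonzero singular values span the
    same constraint set and are perfectly conditioned.
    """
    U, s, Vt = scipy.linalg.svd(A_eq, full_matrices=False)
    rank = int(np.sum(s > max(A_eq.shape) * np.finfo(float).eps * s[0])) if len(s) else 0
    A_red = s[:rank, None] * Vt[:rank]
    b_red = U[:, :rank].T @ b_eq
    return A_red, b_red


def solve_qp(
    q: np.ndarray,
    A_eq: np.ndarray | None,
    b_eq: np.ndarray | None,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
) -> LinearSolution:
    """Minimize ``sum_i q_i x_i^2`` (q >= 0) subject to linear constraints.

    The objective is reported on that scale (no 1/2 factor), matching the
    weighted sum-of-squared-corrections convention.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("QP requires non-negative diagonal costs")
    feas = _feasible_point(A_eq, b_eq, lb, ub, A_ub, b_ub)
    if feas.status != "optimal":
        return LinearSolution(feas.status, None, None, feas.message)
    x0 = feas.x
    if not np.any(q > 0):  # pure feasibility problem
        return LinearSolution("optimal", x0, 0.0)
    if A_eq is not None and len(A_eq):
        A_eq, b_eq = _reduce_equalities(np.asarray(A_eq, float),
                                        np.asarray(b_eq, float))

    def fun(x):
        return float(x @ (q * x))

    def jac(x):
        return 2.0 * q * x

    hess = 2.0 * np.diag(q)

    constraints = []
    if A_eq is not None and len(A_eq):
        constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
    if A_ub is not None and len(A_ub):
        constraints.append(
            LinearConstraint(A_ub, -np.inf * np.ones(len(b_ub)), b_ub)
        )
    import warnings

    with warnings.catch_warnings():
        # trust-constr warns about singular constraint Jacobians; redundant
        # steady-state rows are expected and handled by its SVD fallback
        warnings.filterwarnings(
            "ignore", message=".*[Ss]ingular Jacobian.*", category=UserWarning
        )
        warnings.filterwarnings(
            "ignore", message=".*delta_grad == 0.*", category=UserWarning
        )
        res = sopt.minimize(
            fun,
            np.clip(x0, lb, ub),
            jac=jac,
            hess=lambda x: hess,
            method="trust-constr",
            bounds=Bounds(lb, ub),
            constraints=constraints,
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000},
        )
    if not res.success and res.status not in (1, 2):  # 1/2: tolerance reached
        return LinearSolution("solver_error", None, None, res.message)
    x = np.asarray(res.x)
    if A_eq is not None and len(A_eq):
        # polish with increasingly generous active-set guesses; a polish is
        # only accepted when feasible and at least as good, so over-guessing
        # the active set is safe
        for active_tol in (1e-7, 1e-5, 1e-3):
            polished = _kkt_polish(
                q, A_eq, b_eq, lb, ub, A_ub, b_ub, x, active_tol=active_tol
            )
            if polished is not None and fun(polished) <= fun(x) + 1e-12 * (
                1.0 + abs(fun(x))
            ):
                x = polished
    return LinearSolution("optimal", x, fun(x), res.message)


# ---------------------------------------------------------------------------
# Plain FBA on a MetabolicModel (used by diagnostics, workflow and synthetic)
# ---------------------------------------------------------------------------

def fba_optimum(
    model,
    objective: Mapping[str, float] | None = None,
    sense: str = "max",
    fixed: Mapping[str, float] | None = None,
) -> LinearSolution:
    """Solve the FBA LP max/min c^T r subject to N r = 0, bounds, A r <= b.

    ``fixed`` pins reaction rates through equality constraints (the set F).
    Returns the solution with the objective value on the max/min scale
    requested (not the internal minimization sign).
    """
    objective = dict(objective if objective is not None else model.objective)
    rxn_index = model.reaction_index
    n = len(model.reactions)
    c = np.zeros(n)
    for rxn_id, coeff in objective.items():
        c[rxn_index[rxn_id]] = coeff
    sign = -1.0 if sense == "max" else 1.0

    N = model.stoichiometric_matrix()
    b_eq = [np.zeros(N.shape[0])]
    A_eq = [N]
    if fixed:
        rows = np.zeros((len(fixed), n))
        vals = np.zeros(len(fixed))
        for i, (rxn_id, value) in enumerate(fixed.items()):
            rows[i, rxn_index[rxn_id]] = 1.0
            vals[i] = value
        A_eq.append(rows)
        b_eq.append(vals)
    A_ub = b_ub = None
    if model.general_constraints is not None:
        A_ub, b_ub = model.general_constraints
    lb, ub = model.bounds_arrays()
    sol = solve_lp(
        sign * c, np.vstack(A_eq), np.concatenate(b_eq), lb, ub, A_ub, b_ub
    )
    if sol.status == "optimal":
        sol.objective_value = sign * sol.objective_value
    return sol
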