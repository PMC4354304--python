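"""Thin optimization backends: LP/MILP via scipy (HiGHS) and a box+equality QP.

Everything downstream (gapfilling, reduction, flux fitting, FVA) goes
through these wrappers so solver settings and failure handling live in
one place.  HiGHS is deterministic, so identical inputs give identical
solutions without any seeding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp, minimize

from .model_core.types import Media, MetabolicModel, ROLE_BIOMASS
from .model_core.transform import apply_media

__all__ = [
    "SolverError",
    "solve_milp_problem",
    "solve_lp",
    "solve_qp",
    "net_flux_bounds",
    "max_biomass",
    "fva",
]

FEASIBILITY_TOL = 1e-9
INTEGRALITY_TOL = 1e-6


class SolverError(RuntimeError):
    """Solver did not return an optimal solution."""

    def __init__(self, message: str, status: Optional[int] = None):
        super().__init__(message)
        self.status = status


def solve_milp_problem(
    c: np.ndarray,
    constraints: List[LinearConstraint],
    lb: np.ndarray,
    ub: np.ndarray,
    integrality: np.ndarray,
) -> Tuple[np.ndarray, float]:
    """Globally solve min c.x subject to linear constraints and bounds."""
    res = milp(
        c=c,
        constraints=constraints,
        bounds=Bounds(lb, ub),
        integrality=integrality,
        options={"mip_rel_gap": 0.0, "presolve": True},
    )
    if res.status != 0 or res.x is None:
        raise SolverError(f"MILP failed: {res.message}", status=res.status)
    return np.asarray(res.x), float(res.fun)


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[sp.spmatrix],
    b_eq: Optional[np.ndarray],
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: Optional[sp.spmatrix] = None,
    b_ub: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float]:
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status != 0 or res.x is None:
        raise SolverError(f"LP failed: {res.message}", status=res.status)
    return np.asarray(res.x), float(res.fun)


# ---------------------------------------------------------------------------
# QP: min sum w_i (v_i - t_i)^2 + ridge * ||v||^2  s.t.  A v = b, lb <= v <= ub
# ---------------------------------------------------------------------------


def _qp_objective(w, t, ridge):
    def f(v):
        return float(np.sum(w * (v - t) ** 2) + ridge * np.sum(v**2))

    def grad(v):
        return 2.0 * w * (v - t) + 2.0 * ridge * v

    H = np.diag(2.0 * w + 2.0 * ridge)

    def hess(_v):
        return H

    return f, grad, hess


def _eqp_solve(w, t, ridge, Ad, b, lb, ub, fixed_lb, fixed_ub):
    """Equality-constrained QP with a working set of fixed bounds.

    Nullspace method; the reduced Hessian is positive definite because
    ridge > 0.  Returns the unconstrained-in-the-box minimizer for the
    current working set (may violate inactive bounds).
    """
    from scipy.linalg import null_space

    n = lb.size
    fixed = fixed_lb | fixed_ub
    vfix = np.where(fixed_ub, ub, lb)
    free = ~fixed
    x = np.where(fixed, vfix, 0.0)
    if not free.any():
        return x
    Af = Ad[:, free]
    rhs = b - Ad[:, fixed] @ vfix[fixed]
    h = 2.0 * w[free] + 2.0 * ridge
    x_p, *_ = np.linalg.lstsq(Af, rhs, rcond=None)
    Z = null_space(Af) if Af.size else np.eye(int(free.sum()))
    if Z.size:
        Hred = Z.T @ (h[:, None] * Z)
        grad0 = h * x_p - 2.0 * w[free] * t[free]
        y = np.linalg.solve(Hred, -Z.T @ grad0)
        x[free] = x_p + Z @ y
    else:
        x[free] = x_p
    return x


def _active_set_qp(w, t, ridge, A, b, lb, ub, x0, max_iter=None):
    """Primal active-set refinement of an approximate QP solution."""
    Ad = A.toarray() if sp.issparse(A) else np.asarray(A)
    n = x0.size
    max_iter = max_iter or (3 * n + 20)
    x = np.clip(np.asarray(x0, dtype=float), lb, ub)
    at_lb = x <= lb + 1e-7
    at_ub = (x >= ub - 1e-7) & ~at_lb
    mu_tol = 1e-9
    for _it in range(max_iter):
        xs = _eqp_solve(w, t, ridge, Ad, b, lb, ub, at_lb, at_ub)
        viol_lo = lb - xs
        viol_hi = xs - ub
        if max(viol_lo.max(initial=0.0), viol_hi.max(initial=0.0)) > 1e-9:
            # step toward xs until the first blocking bound
            d = xs - x
            alpha = 1.0
            block = None
            block_ub = False
            for i in np.nonzero(np.abs(d) > 1e-14)[0]:
                if d[i] < 0 and x[i] + alpha * d[i] < lb[i]:
                    a_i = (lb[i] - x[i]) / d[i]
                    if a_i < alpha:
                        alpha, block, block_ub = a_i, i, False
                elif d[i] > 0 and x[i] + alpha * d[i] > ub[i]:
                    a_i = (ub[i] - x[i]) / d[i]
                    if a_i < alpha:
                        alpha, block, block_ub = a_i, i, True
            x = np.clip(x + max(alpha, 0.0) * d, lb, ub)
            if block is None:
                break
            if block_ub:
                at_ub[block] = True
                at_lb[block] = False
            else:
                at_lb[block] = True
                at_ub[block] = False
            continue
        x = np.clip(xs, lb, ub)
        # check multipliers of the working set; release the worst violator
        g = 2.0 * w * (x - t) + 2.0 * ridge * x
        free = ~(at_lb | at_ub)
        if free.any() and Ad.size:
            lam, *_ = np.linalg.lstsq(Ad[:, free].T, -g[free], rcond=None)
        else:
            lam = np.zeros(Ad.shape[0])
        red = g + Ad.T @ lam
        worst, worst_i, worst_ub = -mu_tol, None, False
        for i in np.nonzero(at_lb)[0]:
            if -red[i] > worst:
                worst, worst_i, worst_ub = -red[i], i, False
        for i in np.nonzero(at_ub)[0]:
            if red[i] > worst:
                worst, worst_i, worst_ub = red[i], i, True
        if worst_i is None:
            break
        if worst_ub:
            at_ub[worst_i] = False
        else:
            at_lb[worst_i] = False
    return x


def solve_qp(
    w: np.ndarray,
    t: np.ndarray,
    A_eq: sp.spmatrix,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    ridge: float = 1e-8,
) -> Tuple[np.ndarray, float]:
    """Convex QP: weighted squared distance to ``t`` over a flux polytope.

    The tiny ridge term canonicalizes coordinates the distance term does
    not pin down (approximate minimum-norm completion).  Returns
    ``(v, kkt_residual)``.
    """
    w = np.asarray(w, dtype=float)
    t = np.asarray(t, dtype=float)
    n = w.size
    f, grad, hess = _qp_objective(w, t, ridge)
    x0 = np.clip(t, lb, ub)  # trust-constr handles infeasible starts
    res = minimize(
        f,
        x0,
        jac=grad,
        hess=hess,
        method="trust-constr",
        constraints=[LinearConstraint(A_eq, b_eq, b_eq)],
        bounds=Bounds(lb, ub),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000, "verbose": 0},
    )
    if res.x is None:
        raise SolverError("QP failed: no solution returned")
    b_arr = np.asarray(b_eq, float)
    cand = _active_set_qp(w, t, ridge, A_eq, b_arr, lb, ub, res.x)
    Ad = A_eq.toarray() if sp.issparse(A_eq) else np.asarray(A_eq)
    feasible = (
        np.max(np.abs(Ad @ cand - b_arr)) <= 1e-7 if Ad.size else True
    )
    v = cand if (feasible and f(cand) <= f(res.x) + 1e-10) else res.x
    kkt = _kkt_residual(v, grad(v), A_eq, lb, ub)
    return np.asarray(v), kkt


def _kkt_residual(v, g, A, lb, ub, tol=1e-7) -> float:
    """Stationarity residual: norm of the gradient projected onto the
    feasible directions (nullspace of A restricted to inactive bounds)."""
    Ad = A.toarray() if sp.issparse(A) else np.asarray(A)
    free = ~((v <= lb + tol) | (v >= ub - tol))
    if not free.any():
        return 0.0
    Af = Ad[:, free]
    gf = g[free]
    # project gf onto nullspace of Af
    if Af.size:
        lam, *_ = np.linalg.lstsq(Af.T, gf, rcond=None)
        resid = gf - Af.T @ lam
    else:
        resid = gf
    return float(np.max(np.abs(resid))) if resid.size else 0.0


# ---------------------------------------------------------------------------
# undecomposed (net-flux) LP helpers shared by growth checks and FVA
# ---------------------------------------------------------------------------


def net_flux_bounds(
    model: MetabolicModel,
    media: Optional[Media] = None,
    flux_bound: float = 1000.0,
    exchange_cap: Optional[float] = None,
) -> Tuple[sp.csr_matrix, np.ndarray, np.ndarray, List[str]]:
    """Mass-balance matrix and signed net-flux bounds for a model.

    Internal bounds derive from reversibility (``[0, flux_bound]`` or
    ``[-flux_bound, flux_bound]``); exchange bounds come from the media.
    Returns ``(A_eq, lb, ub, reaction ids)``.
    """
    work = model if media is None else apply_media(
        model, media, exchange_cap if exchange_cap is not None else media.default_cap
    )
    met_index = {m: i for i, m in enumerate(work.metabolites)}
    rxn_ids = list(work.reactions)
    rows, cols, vals = [], [], []
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        rxn = work.reactions[rid]
        for mid, coef in rxn.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(coef)
        if rxn.is_exchange:
            lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        elif rxn.role == ROLE_BIOMASS:
            lb[j], ub[j] = 0.0, flux_bound
        else:
            lb[j] = -flux_bound if rxn.reversible else 0.0
            ub[j] = flux_bound
    A = sp.csr_matrix((vals, (rows, cols)), shape=(len(met_index), len(rxn_ids)))
    return A, lb, ub, rxn_ids


def max_biomass(
    model: MetabolicModel,
    media: Media,
    flux_bound: float = 1000.0,
    exchange_cap: Optional[float] = None,
) -> float:
    """Maximum biomass flux on the media (0.0 when no biomass reaction)."""
    if model.biomass_id is None:
        return 0.0
    A, lb, ub, rxn_ids = net_flux_bounds(model, media, flux_bound, exchange_cap)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.biomass_id)] = -1.0
    try:
        _x, fun = solve_lp(c, A, np.zeros(A.shape[0]), lb, ub)
    except SolverError:
        return 0.0
    return -fun


def fva(
    model: MetabolicModel,
    media: Media,
    reactions: Optional[Iterable[str]] = None,
    flux_bound: float = 1000.0,
    exchange_cap: Optional[float] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction min/max net flux (flux-variability analysis)."""
    A, lb, ub, rxn_ids = net_flux_bounds(model, media, flux_bound, exchange_cap)
    b = np.zeros(A.shape[0])
    targets = list(reactions) if reactions is not None else rxn_ids
    idx = {rid: j for j, rid in enumerate(rxn_ids)}
    out: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        j = idx[rid]
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        _x, vmin = solve_lp(c, A, b, lb, ub)
        _x, vmax_neg = solve_lp(-c, A, b, lb, ub)
        out[rid] = (vmin, -vmax_neg)
    return out
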