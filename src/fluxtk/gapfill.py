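"""Slack-flux pathway gapfilling.

Given a draft model, a candidate-reaction database and a growth media,
find the minimum-cost set of candidate additions / direction reversals
that lets as many gene-associated reactions as possible carry flux.

The MILP minimizes

    a * sum(gamma_activate_i * delta_i)  +  sum(gamma_gapfill_i * v_i)

where ``delta_i`` is the slack flux of activation-set reaction ``i``
(forced to 0.01 exactly when the reaction carries no flux) and the
second sum ranges over candidate-reaction component fluxes.  Binary
variables appear only to forbid simultaneous forward+reverse flux
through the two components of a reversible reaction; the objective
itself is continuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint

from ._opt import SolverError, max_biomass, solve_milp_problem
from .model_core.transform import (
    SLACK_ACTIVITY,
    DecomposedProblem,
    apply_media,
    decompose,
    merge_database,
)
from .model_core.types import (
    BiochemDatabase,
    Media,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    ROLE_INTERNAL,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltyConfig",
    "GapfillProblem",
    "GapfillSolution",
    "default_penalties",
    "build_problem",
    "solve",
    "integrate",
    "gapfill",
]

#: slack upper bound; values above the activity threshold are never useful.
SLACK_UB = SLACK_ACTIVITY
FLUX_TOL = 1e-6


@dataclass(frozen=True)
class PenaltyConfig:
    """Additive gapfill-penalty surcharges on a base cost of 1."""

    base: float = 1.0
    reverse_surcharge: float = 2.0
    transport_surcharge: float = 1.0
    no_gene_surcharge: float = 1.0
    uniform: bool = False


def penalty_for(
    reaction: Reaction,
    *,
    reverse: bool = False,
    transport: bool = False,
    config: PenaltyConfig = PenaltyConfig(),
) -> float:
    if config.uniform:
        return config.base
    pen = config.base
    if reverse:
        pen += config.reverse_surcharge
    if transport:
        pen += config.transport_surcharge
    if reaction.gpr is None:
        pen += config.no_gene_surcharge
    return pen


def _is_transport(rxn: Reaction, compartments: Dict[str, str]) -> bool:
    comps = {compartments.get(m) for m in rxn.stoichiometry}
    comps.discard(None)
    return len(comps) > 1


def default_penalties(
    database: BiochemDatabase, config: PenaltyConfig = PenaltyConfig()
) -> Dict[str, float]:
    """Penalty per candidate: 1 + configurable surcharges (transport, no
    associated gene); reverse-direction use is priced separately when
    reversal candidates are built."""
    comps = getattr(database, "metabolite_compartments", {}) or {}
    return {
        rid: penalty_for(rxn, transport=_is_transport(rxn, comps), config=config)
        for rid, rxn in database.reactions.items()
    }


@dataclass
class GapfillProblem:
    dec: DecomposedProblem
    media: Media
    a: float
    flux_penalty: np.ndarray  # per decomposed column
    gamma_activate: Dict[str, float]
    database_ids: List[str]
    reversal_cols: Dict[str, int]  # model rxn id -> reverse-candidate column
    require_growth: bool
    cap: float

    @property
    def activation_ids(self) -> List[str]:
        return self.dec.activation_ids


@dataclass
class GapfillSolution:
    added: Set[str]
    reversed: Set[str]
    active: Set[str]
    inactive: Set[str]
    objective: float
    fluxes: Dict[str, float]
    slacks: Dict[str, float]
    component_fluxes: Dict[str, float] = field(default_factory=dict)
    problem: Optional[GapfillProblem] = None


def build_problem(
    model: MetabolicModel,
    database: BiochemDatabase,
    media: Media,
    a: float = 0.1,
    activation_set: Optional[Iterable[str]] = None,
    gamma_activate: Optional[Dict[str, float]] = None,
    cap: float = 100.0,
    require_growth: bool = False,
    reversal_candidates: bool = True,
    penalty_config: Optional[PenaltyConfig] = None,
) -> GapfillProblem:
    """Assemble the gapfilling MILP over the model plus the database.

    The default activation set is every gene-associated model reaction
    plus the biomass reaction.  Candidates referencing unconnectable
    metabolites are dropped with a warning.
    """
    if not (0.0 < a <= 1.0):
        raise ModelValidationError(f"scaling factor a={a} outside (0, 1]")
    database.validate_against(model)
    penalties = dict(database.penalties)
    if penalty_config is not None:
        penalties = default_penalties(database, penalty_config)

    merged, kept = merge_database(model, database)
    merged = apply_media(merged, media, cap)

    if activation_set is None:
        activation = [
            r.id for r in model.reactions.values() if r.gpr is not None
        ]
        if model.biomass_id is not None and model.biomass_id not in activation:
            activation.append(model.biomass_id)
    else:
        activation = list(activation_set)

    reversal_ids = []
    if reversal_candidates:
        reversal_ids = [
            r.id
            for r in model.reactions.values()
            if r.role == ROLE_INTERNAL and not r.reversible and r.source == "model"
        ]

    dec = decompose(merged, activation, cap=cap, extra_reverse=reversal_ids)

    flux_penalty = np.zeros(dec.n_vars)
    comps = {m.id: m.compartment for m in merged.metabolites.values()}
    for rid in kept:
        for col in dec.columns_for(rid):
            flux_penalty[col] = penalties[rid]
    reversal_cols: Dict[str, int] = {}
    pcfg = penalty_config or PenaltyConfig()
    for rid in reversal_ids:
        col = dec.col_index.get((rid, "rev"))
        if col is None:
            continue
        reversal_cols[rid] = col
        rxn = model.reactions[rid]
        flux_penalty[col] = penalty_for(
            rxn, reverse=True, transport=_is_transport(rxn, comps), config=pcfg
        )

    gact = {rid: 1.0 for rid in activation}
    if gamma_activate:
        gact.update(gamma_activate)

    return GapfillProblem(
        dec=dec,
        media=media,
        a=a,
        flux_penalty=flux_penalty,
        gamma_activate=gact,
        database_ids=kept,
        reversal_cols=reversal_cols,
        require_growth=require_growth,
        cap=cap,
    )


def _assemble(problem: GapfillProblem):
    """Variable layout: [component fluxes | binaries | slacks]."""
    dec = problem.dec
    n_x = dec.n_vars
    n_z = 2 * len(dec.pairs)
    n_d = len(dec.activation_ids)
    n = n_x + n_z + n_d

    lb = np.zeros(n)
    ub = np.concatenate(
        [dec.upper, np.ones(n_z), np.full(n_d, SLACK_UB)]
    )
    integrality = np.zeros(n)
    integrality[n_x : n_x + n_z] = 1

    constraints: List[LinearConstraint] = []
    # mass balance
    A_eq = sp.hstack(
        [dec.matrix, sp.csr_matrix((dec.matrix.shape[0], n_z + n_d))]
    ).tocsr()
    zero = np.zeros(dec.matrix.shape[0])
    constraints.append(LinearConstraint(A_eq, zero, zero))

    # direction exclusivity: v <= ub*z per component, z_for + z_rev <= 1
    rows, cols, vals, lo, hi = [], [], [], [], []
    r = 0
    for k, (fc, rc) in enumerate(dec.pairs):
        zf, zr = n_x + 2 * k, n_x + 2 * k + 1
        for vcol, zcol in ((fc, zf), (rc, zr)):
            rows += [r, r]
            cols += [vcol, zcol]
            cap_v = dec.upper[vcol] if dec.upper[vcol] > 0 else 1.0
            vals += [1.0, -cap_v]
            lo.append(-np.inf)
            hi.append(0.0)
            r += 1
        rows += [r, r]
        cols += [zf, zr]
        vals += [1.0, 1.0]
        lo.append(-np.inf)
        hi.append(1.0)
        r += 1
    if r:
        A_excl = sp.csr_matrix((vals, (rows, cols)), shape=(r, n))
        constraints.append(LinearConstraint(A_excl, lo, hi))

    # slack: v_for + v_rev + delta >= activity threshold
    rows, cols, vals = [], [], []
    for k, rid in enumerate(dec.activation_ids):
        for col in dec.columns_for(rid):
            rows.append(k)
            cols.append(col)
            vals.append(1.0)
        rows.append(k)
        cols.append(n_x + n_z + k)
        vals.append(1.0)
    if dec.activation_ids:
        A_slack = sp.csr_matrix((vals, (rows, cols)), shape=(n_d, n))
        constraints.append(
            LinearConstraint(A_slack, np.full(n_d, SLACK_ACTIVITY), np.inf)
        )

    if problem.require_growth:
        bid = problem.dec.model.biomass_id
        if bid is None:
            raise ModelValidationError("require_growth set but model has no biomass")
        col = problem.dec.col_index[(bid, "for")]
        lb[col] = SLACK_ACTIVITY

    c = np.zeros(n)
    c[:n_x] = problem.flux_penalty
    for k, rid in enumerate(dec.activation_ids):
        c[n_x + n_z + k] = problem.a * problem.gamma_activate.get(rid, 1.0)
    return c, constraints, lb, ub, integrality, (n_x, n_z, n_d)


def solve(problem: GapfillProblem) -> GapfillSolution:
    """Solve to global optimality, then canonicalize among alternate optima
    by a secondary minimum-total-flux LP with the binaries fixed."""
    c, constraints, lb, ub, integrality, (n_x, n_z, n_d) = _assemble(problem)
    x, fun = solve_milp_problem(c, constraints, lb, ub, integrality)

    # lexicographic tie-break: fix binaries, pin objective, minimize total flux
    z = np.round(x[n_x : n_x + n_z])
    lb2, ub2 = lb.copy(), ub.copy()
    lb2[n_x : n_x + n_z] = z
    ub2[n_x : n_x + n_z] = z
    cons2 = list(constraints)
    cons2.append(
        LinearConstraint(sp.csr_matrix([c]), fun - 1e-11, fun + 1e-11)
    )
    c2 = np.zeros_like(c)
    c2[:n_x] = 1.0
    c2[n_x + n_z :] = 1.0  # keep slacks tight as well
    try:
        x2, _ = solve_milp_problem(c2, cons2, lb2, ub2, np.zeros_like(c))
        x = x2
    except SolverError:  # keep the primary solution
        logger.warning("secondary flux-minimization failed; using primary optimum")

    dec = problem.dec
    slacks = {
        rid: float(x[n_x + n_z + k]) for k, rid in enumerate(dec.activation_ids)
    }
    added = {
        rid
        for rid in problem.database_ids
        if dec.component_sum(x, rid) >= FLUX_TOL
    }
    rev = {
        rid for rid, col in problem.reversal_cols.items() if x[col] >= FLUX_TOL
    }
    active = {
        rid
        for rid in dec.activation_ids
        if dec.component_sum(x, rid) >= SLACK_ACTIVITY - FLUX_TOL
    }
    inactive = set(dec.activation_ids) - active
    comp = {
        f"{rid}:{d}": float(x[col])
        for (rid, d), col in dec.col_index.items()
    }
    return GapfillSolution(
        added=added,
        reversed=rev,
        active=active,
        inactive=inactive,
        objective=float(c @ x),
        fluxes=dec.recompose(x[:n_x]),
        slacks=slacks,
        component_fluxes=comp,
        problem=problem,
    )


def integrate(
    model: MetabolicModel,
    solution: GapfillSolution,
    database: Optional[BiochemDatabase] = None,
) -> MetabolicModel:
    """Apply a gapfill solution: append added candidates (source
    ``gapfilled``, no GPR) and widen the bounds of reversed reactions.

    When the solution achieved growth, the integrated model is verified
    to still produce biomass on the gapfilling media.
    """
    if solution.problem is None and database is None and solution.added:
        raise ValueError("cannot integrate: no database available on the solution")
    out = model.copy()
    for rid in sorted(solution.added):
        if database is not None and rid in database.reactions:
            src = database.reactions[rid]
        else:
            src = solution.problem.dec.model.reactions[rid]
        rxn = src.copy()
        rxn.source = "gapfilled"
        rxn.gpr = None
        out.add_reaction(rxn)
    for rid in sorted(solution.reversed):
        rxn = out.reactions[rid]
        rxn.reversible = True
        rxn.lower_bound = -abs(rxn.upper_bound)
    if solution.problem is not None:
        prob = solution.problem
        grew = (
            out.biomass_id is not None
            and (prob.require_growth or out.biomass_id in solution.active)
        )
        if grew:
            growth = max_biomass(out, prob.media, exchange_cap=prob.cap)
            if growth < SLACK_ACTIVITY - 1e-9:
                raise AssertionError(
                    f"integrated model fails to grow (biomass {growth:.3g}); "
                    "internal inconsistency"
                )
    return out


def gapfill(
    model: MetabolicModel,
    database: BiochemDatabase,
    media: Media,
    a: float = 0.1,
    require_growth: bool = False,
    **kwargs,
) -> GapfillSolution:
    """Convenience one-shot: build and solve."""
    problem = build_problem(
        model, database, media, a=a, require_growth=require_growth, **kwargs
    )
    return solve(problem)
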