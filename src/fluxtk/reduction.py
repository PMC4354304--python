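"""Transcriptome-based model reduction.

Starting from a (gapfilled) growth-capable model and a reaction score
set, solve

    min  sum a * E_high_i * delta_i  +  sum a * E_low_i * v_i

over the model's own stoichiometry: activate as many high-expression
reactions as the network allows while zeroing flux through
low-expression reactions, with slack variables letting a high reaction
stay off when turning it on would force too much low-expression flux.
Pruning then drops exactly the low-expression reactions with zero
optimal flux; inactive high-expression reactions, unscored reactions,
exchanges and biomass are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set

import numpy as np

from ._opt import max_biomass
from .expression import CLASS_HIGH, CLASS_LOW, ReactionScoreSet
from .gapfill import FLUX_TOL, GapfillProblem, GapfillSolution
from .gapfill import solve as _solve_milp
from .model_core.transform import SLACK_ACTIVITY, apply_media, decompose
from .model_core.types import Media, MetabolicModel, ModelValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ReductionError",
    "ReductionProblem",
    "ReductionSolution",
    "build_reduction",
    "solve_reduction",
    "prune",
    "reduce_model",
]


class ReductionError(RuntimeError):
    pass


@dataclass
class ReductionProblem:
    inner: GapfillProblem
    score_set: ReactionScoreSet
    high_ids: Set[str]
    low_ids: Set[str]
    a: float
    media: Media
    cap: float
    require_growth: bool


@dataclass
class ReductionSolution:
    active_high: Set[str]
    inactive_high: Set[str]
    active_low: Set[str]
    inactive_low: Set[str]
    objective: float
    fluxes: Dict[str, float]
    slacks: Dict[str, float]
    problem: Optional[ReductionProblem] = None
    reduced_model: Optional[MetabolicModel] = None


def build_reduction(
    model: MetabolicModel,
    score_set: ReactionScoreSet,
    media: Media,
    a: float = 0.1,
    cap: float = 100.0,
    require_growth: bool = True,
    biomass_weight: float = 1.0,
) -> ReductionProblem:
    """Assemble the reduction MILP (model stoichiometry only).

    The biomass reaction joins the activation set with weight
    ``biomass_weight``; by default growth is also enforced as a hard
    constraint so the pruned model always grows on the media.
    """
    if not (0.0 < a <= 1.0):
        raise ModelValidationError(f"scaling factor a={a} outside (0, 1]")
    high = set(score_set.high_ids) & set(model.reactions)
    low = set(score_set.low_ids) & set(model.reactions)
    if not high:
        raise ModelValidationError("empty high-expression set: nothing to activate")

    activation = sorted(high)
    weights = {rid: score_set.scores[rid] for rid in activation}
    if model.biomass_id is not None and model.biomass_id not in activation:
        activation.append(model.biomass_id)
        weights[model.biomass_id] = biomass_weight

    bounded = apply_media(model, media, cap)
    dec = decompose(bounded, activation, cap=cap)

    flux_penalty = np.zeros(dec.n_vars)
    for rid in low:
        for col in dec.columns_for(rid):
            flux_penalty[col] = a * score_set.scores[rid]

    inner = GapfillProblem(
        dec=dec,
        media=media,
        a=a,
        flux_penalty=flux_penalty,
        gamma_activate=weights,
        database_ids=[],
        reversal_cols={},
        require_growth=require_growth,
        cap=cap,
    )
    return ReductionProblem(
        inner=inner,
        score_set=score_set,
        high_ids=high,
        low_ids=low,
        a=a,
        media=media,
        cap=cap,
        require_growth=require_growth,
    )


def solve_reduction(problem: ReductionProblem) -> ReductionSolution:
    """Global MILP optimum, classified by the 0.01 activity rule for
    high-expression reactions and a nonzero-flux rule for low ones."""
    sol: GapfillSolution = _solve_milp(problem.inner)
    high, low = problem.high_ids, problem.low_ids
    active_high = {r for r in high if r in sol.active}
    inactive_high = high - active_high
    active_low = {r for r in low if abs(sol.fluxes[r]) >= FLUX_TOL}
    inactive_low = low - active_low
    return ReductionSolution(
        active_high=active_high,
        inactive_high=inactive_high,
        active_low=active_low,
        inactive_low=inactive_low,
        objective=sol.objective,
        fluxes=sol.fluxes,
        slacks=sol.slacks,
        problem=problem,
    )


def prune(
    model: MetabolicModel,
    solution: ReductionSolution,
    media: Media,
    cap: Optional[float] = None,
) -> MetabolicModel:
    """Drop the zero-flux low-expression reactions; keep everything else.

    High-expression reactions are retained whether or not they carried
    flux in the single optimal state.  The reduced model is re-verified
    to grow on the media.
    """
    drop = {
        rid for rid in solution.inactive_low if rid in model.reactions
    }
    reduced = model.copy()
    reduced.id = model.id + "_reduced"
    for rid in sorted(drop):
        reduced.remove_reaction(rid)
    cap = cap if cap is not None else (
        solution.problem.cap if solution.problem else media.default_cap
    )
    if reduced.biomass_id is not None:
        growth = max_biomass(reduced, media, exchange_cap=cap)
        if growth < SLACK_ACTIVITY - 1e-9:
            raise ReductionError(
                f"pruned model fails to grow (biomass {growth:.3g}); "
                "re-solve with require_growth=True"
            )
    solution.reduced_model = reduced
    return reduced


def reduce_model(
    model: MetabolicModel,
    score_set: ReactionScoreSet,
    media: Media,
    a: float = 0.1,
    cap: float = 100.0,
    biomass_swap: Optional[Dict[str, float]] = None,
) -> ReductionSolution:
    """One-shot build/solve/prune.

    ``biomass_swap`` replaces the biomass coefficient table before
    solving (tissue-specific biomass compositions are input data).
    """
    work = model
    if biomass_swap is not None:
        if model.biomass_id is None:
            raise ModelValidationError("biomass swap on a model without biomass")
        work = model.copy()
        missing = [m for m in biomass_swap if m not in work.metabolites]
        if missing:
            raise ModelValidationError(
                f"biomass table names unknown metabolites: {missing}"
            )
        work.reactions[work.biomass_id].stoichiometry = dict(biomass_swap)
    problem = build_reduction(work, score_set, media, a=a, cap=cap)
    solution = solve_reduction(problem)
    prune(work, solution, media, cap=cap)
    return solution
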