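"""Media application, reversible-reaction decomposition, stoichiometric matrices.

All optimizers in the toolkit work on a :class:`DecomposedProblem`, in which
every reversible reaction is split into non-negative forward and reverse
component fluxes so that all fluxes are positive.  Exchange bounds follow the
uptake-positive convention documented in :mod:`fluxtk.model_core.types`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .types import (
    Media,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    ROLE_BIOMASS,
    ROLE_EXCHANGE,
)

logger = logging.getLogger(__name__)

__all__ = [
    "apply_media",
    "decompose",
    "stoich_matrix",
    "DecomposedProblem",
    "merge_database",
    "SLACK_ACTIVITY",
]

#: activity threshold shared by the slack constraint and post-solve
#: classification: a reaction is "active" when its component fluxes sum
#: to at least this value.
SLACK_ACTIVITY = 0.01


def apply_media(
    model: MetabolicModel, media: Media, cap: Optional[float] = None
) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set from ``media``.

    For each exchange reaction the uptake direction is bounded by
    ``min(limit, cap)`` when the metabolite is in the media and by 0
    otherwise; the secretion direction is bounded by ``cap``.
    """
    cap = media.default_cap if cap is None else cap
    exchangeable = {
        r.exchange_metabolite for r in model.reactions.values() if r.is_exchange
    }
    missing = sorted(set(media.uptake_limits) - exchangeable)
    if missing:
        raise ModelValidationError(
            "media names metabolites with no exchange reaction: " + ", ".join(missing)
        )
    bounded = model.copy()
    for rxn in bounded.reactions.values():
        if not rxn.is_exchange:
            continue
        met = rxn.exchange_metabolite
        coef = rxn.stoichiometry[met]
        uptake = media.uptake_bound(met, cap)
        if coef > 0:  # positive flux produces the metabolite => uptake
            rxn.lower_bound, rxn.upper_bound = -cap, uptake
        else:
            rxn.lower_bound, rxn.upper_bound = -uptake, cap
        rxn.reversible = rxn.lower_bound < 0
    return bounded


def merge_database(
    model: MetabolicModel, database
) -> Tuple[MetabolicModel, List[str]]:
    """Append database candidate reactions to a copy of ``model``.

    Candidates referencing a foreign metabolite that no other reaction in
    the combined network touches can never carry steady-state flux; they
    are dropped with a warning.  Returns (merged model, kept candidate ids).
    """
    merged = model.copy()
    refcount: Dict[str, int] = {}
    for rxn in list(model.reactions.values()) + list(database.reactions.values()):
        for mid in rxn.stoichiometry:
            refcount[mid] = refcount.get(mid, 0) + 1
    kept: List[str] = []
    for rid, rxn in database.reactions.items():
        foreign = [m for m in rxn.stoichiometry if m not in model.metabolites]
        dead = [m for m in foreign if refcount.get(m, 0) < 2]
        if dead:
            logger.warning(
                "dropping candidate %s: dead-end metabolites %s", rid, dead
            )
            continue
        for mid in foreign:
            if mid not in merged.metabolites:
                from .types import Metabolite

                merged.add_metabolite(Metabolite(id=mid, compartment="c"))
        merged.add_reaction(rxn.copy())
        kept.append(rid)
    return merged, kept


def _component_bounds(rxn: Reaction, cap: float) -> Tuple[float, Optional[float]]:
    """(forward ub, reverse ub or None) for the decomposed components."""
    if rxn.is_exchange:
        fwd = max(0.0, min(rxn.upper_bound, cap))
        rev = max(0.0, min(-rxn.lower_bound, cap))
        return fwd, (rev if (rxn.reversible or rxn.lower_bound < 0) else None)
    if rxn.role == ROLE_BIOMASS:
        return cap, None
    if rxn.reversible:
        return cap, cap
    return cap, None


@dataclass
class DecomposedProblem:
    """Forward/reverse split of a model, ready for MILP/LP assembly.

    Variables are indexed by ``(reaction id, direction)`` with direction
    in ``{"for", "rev"}``; the stoichiometric column of a reverse
    component is the negation of the forward column.
    """

    model: MetabolicModel
    variables: List[Tuple[str, str]]
    upper: np.ndarray
    matrix: sp.csr_matrix
    met_index: Dict[str, int]
    col_index: Dict[Tuple[str, str], int]
    pairs: List[Tuple[int, int]]  # (forward col, reverse col) per 2-component rxn
    activation_ids: List[str]
    cap: float = 100.0

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def columns_for(self, rxn_id: str) -> List[int]:
        out = []
        for d in ("for", "rev"):
            c = self.col_index.get((rxn_id, d))
            if c is not None:
                out.append(c)
        return out

    def recompose(self, x: Sequence[float]) -> Dict[str, float]:
        """Map a component-flux vector back to signed net fluxes."""
        net: Dict[str, float] = {}
        for rid in self.model.reactions:
            v = 0.0
            c = self.col_index.get((rid, "for"))
            if c is not None:
                v += x[c]
            c = self.col_index.get((rid, "rev"))
            if c is not None:
                v -= x[c]
            net[rid] = v
        return net

    def component_sum(self, x: Sequence[float], rxn_id: str) -> float:
        return sum(x[c] for c in self.columns_for(rxn_id))


def decompose(
    model: MetabolicModel,
    activation_set: Iterable[str] = (),
    cap: float = 100.0,
    extra_reverse: Iterable[str] = (),
) -> DecomposedProblem:
    """Split reversible reactions into forward/reverse components.

    ``activation_set`` members (must be model reactions) are the reactions
    that will receive slack variables in the optimizers built on top.
    ``extra_reverse`` forces a reverse component for reactions that are
    irreversible in the model (used to price direction-reversal
    candidates during gapfilling).
    """
    activation = list(dict.fromkeys(activation_set))
    extra_rev = set(extra_reverse)
    unknown = [rid for rid in activation if rid not in model.reactions]
    if unknown:
        raise ModelValidationError(f"activation set not in model: {unknown}")

    met_ids = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    variables: List[Tuple[str, str]] = []
    upper: List[float] = []
    col_index: Dict[Tuple[str, str], int] = {}
    pairs: List[Tuple[int, int]] = []
    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []

    for rid, rxn in model.reactions.items():
        fwd_ub, rev_ub = _component_bounds(rxn, cap)
        if rev_ub is None and rid in extra_rev:
            rev_ub = cap
        fcol = len(variables)
        variables.append((rid, "for"))
        upper.append(fwd_ub)
        col_index[(rid, "for")] = fcol
        for mid, coef in rxn.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(fcol)
            vals.append(coef)
        if rev_ub is not None:
            rcol = len(variables)
            variables.append((rid, "rev"))
            upper.append(rev_ub)
            col_index[(rid, "rev")] = rcol
            for mid, coef in rxn.stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(rcol)
                vals.append(-coef)
            pairs.append((fcol, rcol))

    matrix = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(variables))
    )
    return DecomposedProblem(
        model=model,
        variables=variables,
        upper=np.asarray(upper, dtype=float),
        matrix=matrix,
        met_index=met_index,
        col_index=col_index,
        pairs=pairs,
        activation_ids=activation,
        cap=cap,
    )


def stoich_matrix(
    model: MetabolicModel,
    database=None,
    decomposed: bool = False,
    cap: float = 100.0,
):
    """Stoichiometric matrix (rows = metabolites, columns = reactions).

    With ``database`` the candidate reactions are appended (the N_super of
    gapfilling); with ``decomposed`` reversible reactions contribute a
    negated second column.  Returns ``(matrix, metabolite ids, column labels)``.
    """
    if database is not None:
        model, _ = merge_database(model, database)
    if decomposed:
        prob = decompose(model, cap=cap)
        return prob.matrix, list(model.metabolites), list(prob.variables)
    met_ids = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions.values()):
        for mid, coef in rxn.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(coef)
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(model.reactions))
    )
    return mat, met_ids, list(model.reactions)
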