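"""Independent reference implementations used to cross-check the package.

Everything here deliberately avoids the package's own assembly/solver
paths: GPR rules are evaluated by Python operator overloading on the raw
boolean string, and gapfill subsets are scored with LPs built directly
in optlang/GLPK from the constraint definitions.
"""

from __future__ import annotations

import re
from itertools import combinations
from typing import Dict, Iterable, Mapping, Optional

import numpy as np


# ---------------------------------------------------------------------------
# GPR oracle: evaluate the raw string via operator overloading
# ---------------------------------------------------------------------------


class _Score:
    """max/min semiring element with None = unscorable poisoning for AND."""

    def __init__(self, value):
        self.value = value  # float or None (unscorable)

    def __and__(self, other):
        if self.value is None or other.value is None:
            return _Score(None)
        return _Score(min(self.value, other.value))

    def __or__(self, other):
        if self.value is None:
            return other
        if other.value is None:
            return self
        return _Score(max(self.value, other.value))


def _pyexpr(rule: str) -> str:
    out = re.sub(r"\band\b", "&", rule, flags=re.IGNORECASE)
    return re.sub(r"\bor\b", "|", out, flags=re.IGNORECASE)


def brute_force_score(rule: str, gene_scores: Mapping[str, float]) -> Optional[float]:
    """Score a GPR string without parsing it ourselves."""
    genes = set(re.findall(r"[A-Za-z_][\w.]*", re.sub(r"\b(and|or)\b", " ", rule, flags=re.IGNORECASE)))
    env = {g: _Score(gene_scores.get(g)) for g in genes}
    result = eval(_pyexpr(rule), {"__builtins__": {}}, env)  # noqa: S307
    return result.value


def brute_force_eval(rule: str, present: Mapping[str, bool]) -> bool:
    genes = set(re.findall(r"[A-Za-z_][\w.]*", re.sub(r"\b(and|or)\b", " ", rule, flags=re.IGNORECASE)))
    env = {g: bool(present.get(g, False)) for g in genes}
    return bool(eval(_pyexpr(rule), {"__builtins__": {}}, env))  # noqa: S307


def random_rule(rng: np.random.Generator, genes, depth: int = 0) -> str:
    """Random nested boolean rule over the given gene ids."""
    if depth >= 3 or rng.random() < 0.35:
        return str(rng.choice(genes))
    op = " and " if rng.random() < 0.5 else " or "
    k = int(rng.integers(2, 4))
    parts = [random_rule(rng, genes, depth + 1) for _ in range(k)]
    return "(" + op.join(parts) + ")"


# ---------------------------------------------------------------------------
# gapfill oracle: exhaustive database-subset enumeration, GLPK LP per subset
# ---------------------------------------------------------------------------


def _subset_lp(model, extra_reactions, penalties, media, activation, cap, a,
               require_growth):
    """Objective of the gapfill LP restricted to one candidate subset,
    assembled directly in optlang (GLPK).  Returns None when infeasible."""
    from optlang.glpk_interface import Constraint, Model, Objective, Variable

    om = Model()
    balance: Dict[str, list] = {}
    obj_terms = []
    delta_vars = {}
    flux_vars = {}

    def add_rxn(rxn, penalty=0.0):
        # forward / reverse component bounds straight from the definitions
        if rxn.is_exchange:
            met = rxn.exchange_metabolite
            coef = rxn.stoichiometry[met]
            uptake = min(media.uptake_limits.get(met, 0.0), cap)
            if coef > 0:
                fwd_ub, rev_ub = uptake, cap
            else:
                fwd_ub, rev_ub = cap, uptake
        elif rxn.role == "biomass":
            fwd_ub, rev_ub = cap, 0.0
        else:
            fwd_ub = cap
            rev_ub = cap if rxn.reversible else 0.0
        vf = Variable(f"vf_{rxn.id}", lb=0, ub=fwd_ub)
        vr = Variable(f"vr_{rxn.id}", lb=0, ub=rev_ub)
        om.add([vf, vr])
        flux_vars[rxn.id] = (vf, vr)
        for mid, c in rxn.stoichiometry.items():
            balance.setdefault(mid, []).append((vf, c))
            balance.setdefault(mid, []).append((vr, -c))
        if penalty:
            obj_terms.append(penalty * (vf + vr))

    for rxn in model.reactions.values():
        add_rxn(rxn)
    for rxn in extra_reactions:
        add_rxn(rxn, penalty=penalties[rxn.id])

    for rid in activation:
        vf, vr = flux_vars[rid]
        d = Variable(f"d_{rid}", lb=0, ub=0.01)
        om.add([d])
        delta_vars[rid] = d
        om.add(Constraint(vf + vr + d, lb=0.01))
        obj_terms.append(a * d)

    for mid, terms in balance.items():
        expr = sum(v * c for v, c in terms)
        om.add(Constraint(expr, lb=0, ub=0))

    if require_growth and model.biomass_id is not None:
        vf, _vr = flux_vars[model.biomass_id]
        om.add(Constraint(vf, lb=0.01))

    om.objective = Objective(sum(obj_terms), direction="min")
    status = om.optimize()
    if status != "optimal":
        return None
    return om.objective.value


def exhaustive_gapfill_objective(
    model, database, media, a=0.1, cap=100.0, require_growth=True
) -> float:
    """Best objective over all candidate subsets (reactions outside the
    subset carry zero flux).  Valid oracle for instances whose model
    reactions are all irreversible (no direction binaries needed).

    The LP is assembled once in optlang/GLPK; each subset is scored by
    zeroing the bounds of the excluded candidates and re-optimizing.
    """
    from optlang.glpk_interface import Constraint, Model, Objective, Variable

    activation = [r.id for r in model.reactions.values() if r.gpr is not None]
    if model.biomass_id is not None and model.biomass_id not in activation:
        activation.append(model.biomass_id)

    om = Model()
    balance: Dict[str, list] = {}
    obj_terms = []
    flux_vars = {}
    orig_ub = {}

    def add_rxn(rxn, penalty=0.0):
        if rxn.is_exchange:
            met = rxn.exchange_metabolite
            coef = rxn.stoichiometry[met]
            uptake = min(media.uptake_limits.get(met, 0.0), cap)
            fwd_ub, rev_ub = (uptake, cap) if coef > 0 else (cap, uptake)
        elif rxn.role == "biomass":
            fwd_ub, rev_ub = cap, 0.0
        else:
            fwd_ub = cap
            rev_ub = cap if rxn.reversible else 0.0
        vf = Variable(f"vf_{rxn.id}", lb=0, ub=fwd_ub)
        vr = Variable(f"vr_{rxn.id}", lb=0, ub=rev_ub)
        om.add([vf, vr])
        flux_vars[rxn.id] = (vf, vr)
        orig_ub[rxn.id] = (fwd_ub, rev_ub)
        for mid, c in rxn.stoichiometry.items():
            balance.setdefault(mid, []).append((vf, c))
            balance.setdefault(mid, []).append((vr, -c))
        if penalty:
            obj_terms.append(penalty * (vf + vr))

    for rxn in model.reactions.values():
        add_rxn(rxn)
    for rid, rxn in database.reactions.items():
        add_rxn(rxn, penalty=database.penalties[rid])
    for rid in activation:
        vf, vr = flux_vars[rid]
        d = Variable(f"d_{rid}", lb=0, ub=0.01)
        om.add([d])
        om.add(Constraint(vf + vr + d, lb=0.01))
        obj_terms.append(a * d)
    for mid, terms in balance.items():
        om.add(Constraint(sum(v * c for v, c in terms), lb=0, ub=0))
    if require_growth and model.biomass_id is not None:
        om.add(Constraint(flux_vars[model.biomass_id][0], lb=0.01))
    om.objective = Objective(sum(obj_terms), direction="min")

    ids = list(database.reactions)
    best = None
    for size in range(len(ids) + 1):
        for subset in combinations(ids, size):
            chosen = set(subset)
            for rid in ids:
                fub, rub = orig_ub[rid] if rid in chosen else (0.0, 0.0)
                vf, vr = flux_vars[rid]
                vf.ub = fub
                vr.ub = rub
            status = om.optimize()
            if status != "optimal":
                continue
            val = om.objective.value
            if best is None or val < best:
                best = val
    assert best is not None, "no feasible subset found"
    return best


# ---------------------------------------------------------------------------
# FVA oracle via cobrapy + GLPK
# ---------------------------------------------------------------------------


def to_cobra(model, media, cap=50.0, flux_bound=1000.0):
    """Independent conversion to a cobra model with fitting-style bounds."""
    import cobra

    cm = cobra.Model(model.id)
    cm.solver = "glpk"
    cm.add_metabolites(
        [
            cobra.Metabolite(m.id, compartment=m.compartment)
            for m in model.metabolites.values()
        ]
    )
    crs = []
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            met = rxn.exchange_metabolite
            coef = rxn.stoichiometry[met]
            uptake = min(media.uptake_limits.get(met, 0.0), cap)
            lo, hi = (-cap, uptake) if coef > 0 else (-uptake, cap)
        elif rxn.role == "biomass":
            lo, hi = 0.0, flux_bound
        else:
            lo = -flux_bound if rxn.reversible else 0.0
            hi = flux_bound
        cr = cobra.Reaction(rxn.id, lower_bound=lo, upper_bound=hi)
        crs.append((cr, rxn))
    cm.add_reactions([cr for cr, _ in crs])
    for cr, rxn in crs:
        cr.add_metabolites(
            {cm.metabolites.get_by_id(m): c for m, c in rxn.stoichiometry.items()}
        )
    return cm


def brute_force_blocked(model, media, cap=50.0, flux_bound=1000.0):
    """Blocked reactions found by naive per-reaction max/min FBA in cobra."""
    cm = to_cobra(model, media, cap, flux_bound)
    blocked = []
    for rxn in cm.reactions:
        cm.objective = rxn.id
        cm.objective_direction = "max"
        hi = cm.optimize().objective_value or 0.0
        cm.objective_direction = "min"
        lo = cm.optimize().objective_value or 0.0
        if abs(hi) < 1e-6 and abs(lo) < 1e-6:
            blocked.append(rxn.id)
    return blocked


def reduction_lp_objective(model, score_set, media, a=0.1, cap=100.0,
                           require_growth=True):
    """Reduction objective via an independently assembled GLPK LP.

    Valid for models whose internal reactions are irreversible (no
    direction-exclusivity binaries are then needed).
    """
    from optlang.glpk_interface import Constraint, Model, Objective, Variable

    om = Model()
    balance = {}
    obj_terms = []
    flux_vars = {}
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            met = rxn.exchange_metabolite
            coef = rxn.stoichiometry[met]
            uptake = min(media.uptake_limits.get(met, 0.0), cap)
            fwd_ub, rev_ub = (uptake, cap) if coef > 0 else (cap, uptake)
        elif rxn.role == "biomass":
            fwd_ub, rev_ub = cap, 0.0
        else:
            fwd_ub = cap
            rev_ub = cap if rxn.reversible else 0.0
        vf = Variable(f"vf_{rxn.id}", lb=0, ub=fwd_ub)
        vr = Variable(f"vr_{rxn.id}", lb=0, ub=rev_ub)
        om.add([vf, vr])
        flux_vars[rxn.id] = (vf, vr)
        for mid, c in rxn.stoichiometry.items():
            balance.setdefault(mid, []).append((vf, c))
            balance.setdefault(mid, []).append((vr, -c))
        cls = score_set.classes.get(rxn.id)
        if cls == "low":
            obj_terms.append(a * score_set.scores[rxn.id] * (vf + vr))
    activation = list(score_set.high_ids)
    weights = {rid: score_set.scores[rid] for rid in activation}
    if model.biomass_id is not None and model.biomass_id not in activation:
        activation.append(model.biomass_id)
        weights[model.biomass_id] = 1.0
    for rid in activation:
        vf, vr = flux_vars[rid]
        d = Variable(f"d_{rid}", lb=0, ub=0.01)
        om.add([d])
        om.add(Constraint(vf + vr + d, lb=0.01))
        obj_terms.append(a * weights[rid] * d)
    for mid, terms in balance.items():
        om.add(Constraint(sum(v * c for v, c in terms), lb=0, ub=0))
    if require_growth and model.biomass_id is not None:
        om.add(Constraint(flux_vars[model.biomass_id][0], lb=0.01))
    om.objective = Objective(sum(obj_terms), direction="min")
    status = om.optimize()
    assert status == "optimal", status
    return om.objective.value
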