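"""Seeded synthetic fixtures for every input the toolkit consumes.

Models are built from linear/branched pathways running from exchangeable
source metabolites to a biomass reaction; "core" pathways feed biomass
(so their chain reactions are growth-essential), the rest end in a
secretable product.  Gapfill cases delete essential reactions into a
decoy-padded candidate database and verify the minimal completion by
exhaustive search; expression fixtures plant high/low pathways; flux
cases sample feasible flux vectors.  Every generator is a pure function
of its spec (bit-reproducible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._opt import SolverError, max_biomass, net_flux_bounds, solve_lp
from .fluxfit import MeasuredFluxSet
from .expression import ExpressionMatrix
from .model_core.gpr import parse_gpr
from .model_core.transform import SLACK_ACTIVITY
from .model_core.types import (
    BiochemDatabase,
    Media,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    ROLE_BIOMASS,
    ROLE_EXCHANGE,
    ROLE_INTERNAL,
)

__all__ = [
    "FixtureSpec",
    "GapfillCase",
    "make_model",
    "default_media",
    "make_gapfill_case",
    "make_bypass_case",
    "make_expression",
    "make_flux_case",
    "essential_reactions",
]

import pandas as pd


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic description of one synthetic fixture family."""

    seed: int = 0
    n_reactions: int = 12
    n_pathways: int = 3
    n_core: Optional[int] = None  # pathways feeding biomass; default ceil(P/2)
    reversible_fraction: float = 0.0
    gpr_complexity: str = "mixed"  # single | complex | mixed
    planted_removals: int = 1
    n_decoys: int = 4
    noise_sigma: float = 0.0
    cap: float = 100.0

    def __post_init__(self) -> None:
        if self.n_reactions < 2 * self.n_pathways:
            raise ModelValidationError(
                "need at least two reactions per pathway"
            )
        if self.n_pathways < 1 or self.n_reactions < 1:
            raise ModelValidationError("counts must be positive")
        if not (0.0 <= self.reversible_fraction <= 1.0):
            raise ModelValidationError("reversible_fraction outside [0,1]")
        if self.gpr_complexity not in ("single", "complex", "mixed"):
            raise ModelValidationError(
                f"unknown gpr_complexity {self.gpr_complexity!r}"
            )

    @property
    def core_count(self) -> int:
        return self.n_core if self.n_core is not None else math.ceil(
            self.n_pathways / 2
        )


def _gpr_string(rng: np.random.Generator, rid: str, complexity: str) -> str:
    g = lambda k: f"g_{rid}_{k}"
    if complexity == "mixed":
        complexity = "single" if rng.random() < 0.5 else "complex"
    if complexity == "single":
        return g(1)
    pattern = rng.integers(0, 3)
    if pattern == 0:
        return f"({g(1)} and {g(2)}) or {g(3)}"
    if pattern == 1:
        return f"{g(1)} and ({g(2)} or {g(3)})"
    return f"({g(1)} or {g(2)}) and ({g(3)} or {g(4)})"


def make_model(spec: FixtureSpec) -> MetabolicModel:
    """Pathway-structured model with exactly ``n_reactions`` internal
    reactions, growth-feasible on :func:`default_media` by construction."""
    rng = np.random.default_rng(spec.seed)
    P = spec.n_pathways
    model = MetabolicModel(f"synth_{spec.seed}", compartments=["c"])

    lengths = [spec.n_reactions // P] * P
    for i in range(spec.n_reactions % P):
        lengths[i] += 1

    products: List[str] = []
    for p in range(P):
        k = lengths[p]
        branch = k >= 5 and rng.random() < 0.4
        m = k - 2 if branch else k  # main-chain reaction count
        nodes = [f"S{p}"] + [f"M{p}_{j}" for j in range(1, m)] + [f"Q{p}"]
        for node in nodes:
            if node not in model.metabolites:
                model.add_metabolite(Metabolite(id=node, compartment="c"))
        subsystem = f"P{p}"
        for j in range(m):
            rid = f"P{p}_R{j + 1}"
            # non-unit product coefficients keep fluxes distinct along a
            # chain (useful for rank-based fixtures); 3 decimals so the
            # TSV round-trip is exact.
            coef = round(float(rng.uniform(0.6, 1.8)), 3)
            rxn = Reaction(
                id=rid,
                stoichiometry={nodes[j]: -1.0, nodes[j + 1]: coef},
                reversible=bool(rng.random() < spec.reversible_fraction),
                gpr=parse_gpr(_gpr_string(rng, rid, spec.gpr_complexity)),
                role=ROLE_INTERNAL,
                subsystem=subsystem,
            )
            model.add_reaction(rxn)
        if branch:
            b = int(rng.integers(0, m - 1))  # bypass nodes[b] -> nodes[b+1]
            bm = f"B{p}"
            model.add_metabolite(Metabolite(id=bm, compartment="c"))
            for tag, sto in (
                ("B1", {nodes[b]: -1.0, bm: 1.0}),
                ("B2", {bm: -1.0, nodes[b + 1]: 1.0}),
            ):
                rid = f"P{p}_{tag}"
                model.add_reaction(
                    Reaction(
                        id=rid,
                        stoichiometry=sto,
                        gpr=parse_gpr(_gpr_string(rng, rid, spec.gpr_complexity)),
                        role=ROLE_INTERNAL,
                        subsystem=subsystem,
                    )
                )
        products.append(nodes[-1])

    for p in range(P):
        model.add_reaction(
            Reaction(
                id=f"EX_S{p}",
                stoichiometry={f"S{p}": 1.0},
                reversible=True,
                role=ROLE_EXCHANGE,
            )
        )
        model.add_reaction(
            Reaction(
                id=f"EX_Q{p}",
                stoichiometry={products[p]: 1.0},
                reversible=True,
                role=ROLE_EXCHANGE,
            )
        )
    model.add_reaction(
        Reaction(
            id="BIOMASS",
            stoichiometry={products[p]: -1.0 for p in range(spec.core_count)},
            role=ROLE_BIOMASS,
        )
    )
    model.validate()
    growth = max_biomass(model, default_media(model, spec.cap), exchange_cap=spec.cap)
    assert growth >= SLACK_ACTIVITY, "generated model must grow by construction"
    return model


def default_media(model: MetabolicModel, cap: float = 100.0) -> Media:
    """Media feeding every exchangeable metabolite that some internal
    reaction consumes (the pathway sources)."""
    consumed = set()
    for rxn in model.reactions.values():
        if rxn.role == ROLE_INTERNAL:
            consumed |= {m for m, c in rxn.stoichiometry.items() if c < 0}
    limits = {}
    for rxn in model.reactions.values():
        if rxn.is_exchange and rxn.exchange_metabolite in consumed:
            limits[rxn.exchange_metabolite] = cap
    return Media(uptake_limits=limits, default_cap=cap)


def essential_reactions(
    model: MetabolicModel, media: Media, cap: float = 100.0
) -> List[str]:
    """Internal reactions whose single removal abolishes growth."""
    out = []
    for rid, rxn in model.reactions.items():
        if rxn.role != ROLE_INTERNAL:
            continue
        trial = model.copy()
        trial.remove_reaction(rid)
        if max_biomass(trial, media, exchange_cap=cap) < SLACK_ACTIVITY:
            out.append(rid)
    return out


@dataclass
class GapfillCase:
    model: MetabolicModel  # truncated model
    database: BiochemDatabase
    media: Media
    known_minimum: int
    removed: List[str]
    full_model: MetabolicModel


def _grows_with(
    model: MetabolicModel,
    database: BiochemDatabase,
    subset: Iterable[str],
    media: Media,
    cap: float,
) -> bool:
    trial = model.copy()
    for rid in subset:
        rxn = database.reactions[rid].copy()
        for mid in rxn.stoichiometry:
            if mid not in trial.metabolites:
                trial.add_metabolite(Metabolite(id=mid, compartment="c"))
        trial.add_reaction(rxn)
    return max_biomass(trial, media, exchange_cap=cap) >= SLACK_ACTIVITY


def _verify_minimum(
    model: MetabolicModel, database: BiochemDatabase, media: Media, cap: float
) -> Optional[int]:
    """Smallest candidate-subset size restoring growth (exhaustive)."""
    ids = list(database.reactions)
    for size in range(len(ids) + 1):
        for subset in combinations(ids, size):
            if _grows_with(model, database, subset, media, cap):
                return size
    return None


def make_gapfill_case(spec: FixtureSpec) -> GapfillCase:
    """Delete ``planted_removals`` essential reactions into a database
    padded with ``n_decoys`` decoys; the minimal completion size is
    verified exhaustively at generation time."""
    if spec.planted_removals < 1:
        raise ModelValidationError("planted_removals must be >= 1")
    rng = np.random.default_rng(spec.seed + 7_919)
    full = make_model(spec)
    media = default_media(full, spec.cap)
    ess = essential_reactions(full, media, spec.cap)
    if len(ess) < spec.planted_removals:
        raise ModelValidationError(
            f"requested {spec.planted_removals} removals but only "
            f"{len(ess)} essential reactions exist"
        )
    removed = sorted(
        rng.choice(np.array(ess, dtype=object), spec.planted_removals, replace=False)
    )
    truncated = full.copy()
    truncated.id = full.id + "_gap"
    db = BiochemDatabase()
    for rid in removed:
        rxn = truncated.remove_reaction(rid).copy()
        rxn.gpr = None
        db.add(rxn, penalty=1.0)

    # decoys: links between non-core metabolites (never producing a
    # core-pathway metabolite, so they cannot shortcut the completion)
    core_subs = {f"P{p}" for p in range(spec.core_count)}
    core_mets: Set[str] = set()
    for rxn in full.reactions.values():
        if rxn.subsystem in core_subs:
            core_mets |= set(rxn.stoichiometry)
    noncore = sorted(set(full.metabolites) - core_mets)
    n_decoys = spec.n_decoys
    existing = {
        frozenset(r.stoichiometry) for r in full.reactions.values()
    }
    attempts = 0
    made = 0
    while made < n_decoys and attempts < 200:
        attempts += 1
        if len(noncore) >= 2:
            a, b = rng.choice(np.array(noncore, dtype=object), 2, replace=False)
        else:  # single-pathway models: decoys into fresh dead metabolites
            a = str(rng.choice(np.array(sorted(core_mets), dtype=object)))
            b = f"X{made}"
        key = frozenset((a, b))
        if key in existing:
            continue
        existing.add(key)
        db.add(
            Reaction(
                id=f"DECOY{made}",
                stoichiometry={a: -1.0, b: 1.0},
                source="database",
            ),
            penalty=1.0,
        )
        made += 1

    known = _verify_minimum(truncated, db, media, spec.cap)
    assert known is not None, "removed set must restore growth"
    return GapfillCase(
        model=truncated,
        database=db,
        media=media,
        known_minimum=known,
        removed=list(removed),
        full_model=full,
    )


def make_bypass_case(seed: int = 0) -> GapfillCase:
    """Hand-shaped case: three consecutive essential reactions removed,
    database holds only a two-reaction bypass, so the verified minimal
    completion (2) is smaller than the deletion (3)."""
    spec = FixtureSpec(seed=seed, n_reactions=6, n_pathways=1, n_core=1)
    full = make_model(spec)
    media = default_media(full, spec.cap)
    chain = [r for r in full.reactions.values() if r.role == ROLE_INTERNAL]
    assert len(chain) >= 3
    removed = [r.id for r in chain[1:4]]
    first = full.reactions[removed[0]]
    last = full.reactions[removed[-1]]
    start = next(m for m, c in first.stoichiometry.items() if c < 0)
    end = next(m for m, c in last.stoichiometry.items() if c > 0)
    truncated = full.copy()
    for rid in removed:
        truncated.remove_reaction(rid)
    db = BiochemDatabase()
    db.add(Reaction(id="BYP1", stoichiometry={start: -1.0, "BYP_m": 1.0}), 1.0)
    db.add(Reaction(id="BYP2", stoichiometry={"BYP_m": -1.0, end: 1.0}), 1.0)
    known = _verify_minimum(truncated, db, media, spec.cap)
    assert known == 2
    return GapfillCase(
        model=truncated,
        database=db,
        media=media,
        known_minimum=known,
        removed=removed,
        full_model=full,
    )


N_BACKGROUND_CONDITIONS = 4
FOCAL_CONDITION = "target"
_HI, _MID, _LO = 50.0, 5.0, 0.5  # raw levels: normalized 10 / 1 / 0.1


def make_expression(
    model: MetabolicModel,
    spec: FixtureSpec,
    active_pathway_ids: Sequence[str],
) -> ExpressionMatrix:
    """Expression matrix planting ``active_pathway_ids`` high.

    In the focal condition (``"target"``) genes of active pathways
    normalize to ~10 and all other genes to ~0.1; background conditions
    sit at the median.  Lognormal multiplicative noise with
    ``noise_sigma``.
    """
    pathways = {
        r.subsystem for r in model.reactions.values() if r.subsystem is not None
    }
    unknown = set(active_pathway_ids) - pathways
    if unknown:
        raise ModelValidationError(f"unknown pathway ids: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed + 104_729)
    active = set(active_pathway_ids)
    genes: List[str] = []
    is_active: List[bool] = []
    for rxn in model.reactions.values():
        for g in sorted(rxn.genes):
            genes.append(g)
            is_active.append(rxn.subsystem in active)
    conditions = [
        f"cond{i + 1}" for i in range(N_BACKGROUND_CONDITIONS)
    ] + [FOCAL_CONDITION]
    base = np.full((len(genes), len(conditions)), _MID)
    base[:, -1] = np.where(is_active, _HI, _LO)
    noise = np.exp(
        spec.noise_sigma * rng.standard_normal(base.shape)
    )
    df = pd.DataFrame(base * noise, index=genes, columns=conditions)
    return ExpressionMatrix(df)


def make_flux_case(
    model: MetabolicModel,
    spec: FixtureSpec,
    media: Optional[Media] = None,
    cap: float = 50.0,
    flux_bound: float = 1000.0,
    measured_fraction: float = 0.5,
) -> MeasuredFluxSet:
    """Sample a feasible flux vector (random-objective LP with growth
    forced), pick a measured subset, add Gaussian noise ``noise_sigma``.
    The noiseless source vector rides along as ``.truth``."""
    media = media if media is not None else default_media(model, cap)
    A, lb, ub, rxn_ids = net_flux_bounds(
        model, media, flux_bound=flux_bound, exchange_cap=cap
    )
    rng = np.random.default_rng(spec.seed + 15_485_863)
    if model.biomass_id is not None:
        # force a substantial growth rate so sampled fluxes have a real
        # scale (otherwise measurement noise swamps the signal)
        gmax = max_biomass(model, media, flux_bound=flux_bound,
                           exchange_cap=cap)
        lb = lb.copy()
        lb[rxn_ids.index(model.biomass_id)] = max(
            SLACK_ACTIVITY, 0.3 * gmax
        )
    internal = [
        rid
        for rid in rxn_ids
        if model.reactions[rid].role == ROLE_INTERNAL
    ]
    for _try in range(20):
        c = rng.standard_normal(len(rxn_ids))
        try:
            x, _ = solve_lp(c, A, np.zeros(A.shape[0]), lb, ub)
        except SolverError:
            continue
        truth = dict(zip(rxn_ids, (float(v) for v in x)))
        n_meas = max(2, int(round(measured_fraction * len(internal))))
        # keep measured values pairwise distinct: chained reactions share
        # identical fluxes, and exact ties would make the noiseless
        # rank-correlation target ambiguous.
        pool = list(internal)
        if model.biomass_id is not None:
            pool.append(model.biomass_id)
        rng.shuffle(pool)
        chosen: List[str] = []
        taken: List[float] = []
        for rid in pool:
            v = truth[rid]
            if all(abs(v - u) > 1e-3 for u in taken):
                chosen.append(rid)
                taken.append(v)
            if len(chosen) >= n_meas:
                break
        chosen = sorted(chosen)
        vals = np.array([truth[r] for r in chosen])
        if len(chosen) < 2 or np.ptp(vals) < 1e-6:
            continue  # degenerate sample; re-draw objective
        noisy = vals + spec.noise_sigma * rng.standard_normal(vals.size)
        return MeasuredFluxSet(
            fluxes=dict(zip(chosen, (float(v) for v in noisy))),
            label=f"synthetic_seed{spec.seed}",
            truth=truth,
        )
    raise SolverError("could not sample a non-degenerate feasible flux vector")
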