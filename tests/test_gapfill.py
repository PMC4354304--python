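import numpy as np
import pytest

from fluxtk._opt import max_biomass
from fluxtk.gapfill import (
    PenaltyConfig,
    build_problem,
    default_penalties,
    gapfill,
    integrate,
    penalty_for,
    solve,
)
from fluxtk.model_core.types import (
    BiochemDatabase,
    Media,
    ModelValidationError,
    Reaction,
)
from fluxtk.synthgen import FixtureSpec, make_gapfill_case

from _oracles import exhaustive_gapfill_objective
from conftest import build_model


def _db(*reactions, penalty=1.0):
    db = BiochemDatabase()
    for rid, stoich in reactions:
        db.add(Reaction(id=rid, stoichiometry=dict(stoich)), penalty)
    return db


@pytest.fixture
def broken_chain():
    """EX->A, [A->B deleted], B->C gene-assoc, C->biomass; database holds
    the missing link plus a 2-reaction bypass."""
    model = build_model(
        [
            ("EX_A", {"A": 1.0}, dict(role="exchange", reversible=True)),
            ("R_BC", {"B": -1.0, "C": 1.0}, dict(gpr="gBC")),
            ("BIO", {"C": -1.0}, dict(role="biomass")),
        ]
    )
    db = _db(
        ("D_AB", {"A": -1.0, "B": 1.0}),
        ("D_AX", {"A": -1.0, "X": 1.0}),
        ("D_XB", {"X": -1.0, "B": 1.0}),
    )
    media = Media(uptake_limits={"A": 100.0})
    return model, db, media


def test_build_problem_counts():
    model = build_model(
        [
            ("EX_A", {"A": 1.0}, dict(role="exchange", reversible=True)),
            ("R1", {"A": -1.0, "B": 1.0}, dict(gpr="g1")),
            ("R2", {"B": -1.0, "C": 1.0}, dict(gpr="g2")),
            ("R3", {"C": -1.0, "D": 1.0}, dict(gpr="g3")),
            ("BIO", {"D": -1.0}, dict(role="biomass")),
        ]
    )
    db = _db(*[(f"D{i}", {"A": -1.0, "B": 1.0 + i}) for i in range(10)])
    prob = build_problem(
        model, db, Media(uptake_limits={"A": 100.0}), reversal_candidates=False
    )
    # columns: EX_A decomposed (2) + 4 irreversible model + 10 database
    assert prob.dec.n_vars == 2 + 4 + 10
    # slacks: 3 gene-associated + biomass
    assert len(prob.activation_ids) == 4
    assert set(prob.activation_ids) == {"R1", "R2", "R3", "BIO"}


def test_build_problem_drops_unconnectable_candidate(caplog):
    model = build_model(
        [
            ("EX_A", {"A": 1.0}, dict(role="exchange", reversible=True)),
            ("R1", {"A": -1.0, "B": 1.0}, dict(gpr="g1")),
            ("BIO", {"B": -1.0}, dict(role="biomass")),
        ]
    )
    db = _db(("D_dead", {"A": -1.0, "GHOST": 1.0}))
    prob = build_problem(model, db, Media(uptake_limits={"A": 100.0}))
    assert prob.database_ids == []


def test_invalid_scaling_factor():
    model = build_model([("R1", {"A": -1.0, "B": 1.0}, dict())])
    with pytest.raises(ModelValidationError):
        build_problem(model, BiochemDatabase(), Media(), a=0.0)


def test_database_id_collision_rejected(chain_model):
    db = _db(("R_AB", {"A": -1.0, "B": 1.0}))
    with pytest.raises(ModelValidationError):
        build_problem(chain_model, db, Media(uptake_limits={"A": 100.0}))


def test_solve_adds_single_missing_link(broken_chain):
    model, db, media = broken_chain
    sol = gapfill(model, db, media, require_growth=True,
                  reversal_candidates=False)
    assert sol.added == {"D_AB"}
    assert "BIO" in sol.active and "R_BC" in sol.active
    oracle = exhaustive_gapfill_objective(model, db, media)
    assert sol.objective == pytest.approx(oracle, abs=1e-6)


def test_solve_already_active_model(chain_model, chain_media):
    sol = gapfill(chain_model, BiochemDatabase(), chain_media,
                  reversal_candidates=False)
    assert sol.added == set()
    assert sol.inactive == set()
    assert all(abs(s) < 1e-9 for s in sol.slacks.values())
    assert sol.objective == pytest.approx(0.0, abs=1e-9)


def test_unproducible_substrate_stays_inactive():
    model = build_model(
        [
            ("EX_A", {"A": 1.0}, dict(role="exchange", reversible=True)),
            ("R_AB", {"A": -1.0, "B": 1.0}, dict(gpr="g1")),
            # ORPHAN is produced by nothing in model or database
            ("R_orphan", {"ORPHAN": -1.0, "B": 1.0}, dict(gpr="g2")),
            ("BIO", {"B": -1.0}, dict(role="biomass")),
        ]
    )
    db = _db(("D1", {"A": -1.0, "C": 1.0}), ("D2", {"C": -1.0, "B": 1.0}))
    sol = gapfill(model, db, Media(uptake_limits={"A": 100.0}),
                  reversal_candidates=False)
    assert "R_orphan" in sol.inactive
    assert sol.slacks["R_orphan"] == pytest.approx(0.01, abs=1e-9)


def test_empty_database_reduces_to_activation(chain_model, chain_media):
    sol = gapfill(chain_model, BiochemDatabase(), chain_media)
    assert sol.active == {"R_AB", "R_BC", "BIO"}


def test_mass_balance_holds_on_solution(broken_chain):
    model, db, media = broken_chain
    prob = build_problem(model, db, media, require_growth=True)
    sol = solve(prob)
    x = np.array(
        [sol.component_fluxes[f"{rid}:{d}"] for rid, d in prob.dec.variables]
    )
    assert np.max(np.abs(prob.dec.matrix @ x)) < 1e-8


def test_direction_exclusivity_blocks_futile_self_activation():
    # reversible dead-end reaction: only a forward+reverse futile cycle
    # could satisfy its slack constraint, and Eq-3 binaries forbid that
    model = build_model(
        [
            ("EX_A", {"A": 1.0}, dict(role="exchange", reversible=True)),
            ("R_AB", {"A": -1.0, "B": 1.0}, dict(gpr="g1", reversible=True)),
            ("R_dead", {"D": -1.0, "E": 1.0}, dict(gpr="g2", reversible=True)),
            ("BIO", {"B": -1.0}, dict(role="biomass")),
        ]
    )
    sol = gapfill(model, BiochemDatabase(), Media(uptake_limits={"A": 100.0}),
                  reversal_candidates=False)
    assert "R_dead" in sol.inactive
    vf = sol.component_fluxes["R_dead:for"]
    vr = sol.component_fluxes["R_dead:rev"]
    assert min(vf, vr) < 1e-9  # no simultaneous forward+reverse flux


def test_reversal_candidate_rescues_wrong_direction():
    # B -> A is written backwards; reversing it is the only way to grow
    model = build_model(
        [
            ("EX_A", {"A": 1.0}, dict(role="exchange", reversible=True)),
            ("R_BA", {"B": -1.0, "A": 1.0}, dict(gpr="g1")),
            ("BIO", {"B": -1.0}, dict(role="biomass")),
        ]
    )
    sol = gapfill(model, BiochemDatabase(), Media(uptake_limits={"A": 100.0}),
                  require_growth=True, reversal_candidates=True)
    assert sol.reversed == {"R_BA"}
    assert "BIO" in sol.active


# --- penalties -------------------------------------------------------------


def test_penalty_plain_candidate():
    rxn = Reaction(id="r", stoichiometry={"A": -1.0, "B": 1.0},
                   gpr=None)
    rxn2 = Reaction(id="r2", stoichiometry={"A": -1.0, "B": 1.0})
    from fluxtk.model_core.gpr import parse_gpr

    rxn_with_gene = Reaction(
        id="rg", stoichiometry={"A": -1.0, "B": 1.0}, gpr=parse_gpr("g1")
    )
    assert penalty_for(rxn_with_gene) == 1.0
    assert penalty_for(rxn) == 2.0  # +1 no-gene surcharge


def test_penalty_transport_reverse():
    from fluxtk.model_core.gpr import parse_gpr

    rxn = Reaction(
        id="t", stoichiometry={"A_c": -1.0, "A_p": 1.0}, gpr=parse_gpr("g1")
    )
    assert penalty_for(rxn, reverse=True, transport=True) == 4.0


def test_penalty_uniform_mode():
    db = _db(("D1", {"A": -1.0, "B": 1.0}), ("D2", {"B": -1.0, "C": 1.0}))
    pens = default_penalties(db, PenaltyConfig(uniform=True))
    assert all(p == 1.0 for p in pens.values())


def test_default_penalties_detect_transport():
    db = BiochemDatabase()
    db.add(Reaction(id="T1", stoichiometry={"Ac": -1.0, "Ap": 1.0}), 1.0)
    db.metabolite_compartments = {"Ac": "c", "Ap": "p"}
    pens = default_penalties(db)
    assert pens["T1"] == 1.0 + 1.0 + 1.0  # base + transport + no gene


# --- integration -----------------------------------------------------------


def test_integrate_chain_grows(broken_chain):
    model, db, media = broken_chain
    sol = gapfill(model, db, media, require_growth=True)
    integrated = integrate(model, sol)
    assert "D_AB" in integrated.reactions
    assert integrated.reactions["D_AB"].source == "gapfilled"
    assert integrated.reactions["D_AB"].gpr is None
    assert max_biomass(integrated, media) >= 0.01


def test_integrate_empty_solution_is_identity(chain_model, chain_media):
    sol = gapfill(chain_model, BiochemDatabase(), chain_media)
    integrated = integrate(chain_model, sol)
    assert set(integrated.reactions) == set(chain_model.reactions)


def test_integrate_random_cases_always_grow():
    for seed in range(8):
        spec = FixtureSpec(seed=seed, n_reactions=12, n_pathways=3,
                           planted_removals=1, n_decoys=3)
        case = make_gapfill_case(spec)
        sol = gapfill(case.model, case.database, case.media,
                      require_growth=True)
        integrated = integrate(case.model, sol)
        assert max_biomass(integrated, case.media) >= 0.01, seed


def test_solution_minimality(broken_chain):
    # dropping any added reaction and re-solving without it must cost more
    model, db, media = broken_chain
    sol = gapfill(model, db, media, require_growth=True,
                  reversal_candidates=False)
    for rid in sol.added:
        db2 = BiochemDatabase()
        for other, rxn in db.reactions.items():
            if other != rid:
                db2.add(rxn.copy(), db.penalties[other])
        try:
            sol2 = gapfill(model, db2, media, require_growth=True,
                           reversal_candidates=False)
            assert sol2.objective > sol.objective + 1e-9
        except Exception:
            pass  # infeasible without it: trivially worse


def test_feasibility_without_growth_requirement():
    # unconnectable model: optimum is full slack, never infeasible
    model = build_model(
        [
            ("R_dead", {"D": -1.0, "E": 1.0}, dict(gpr="g1")),
            ("BIO", {"E": -1.0}, dict(role="biomass")),
        ]
    )
    sol = gapfill(model, BiochemDatabase(), Media(), reversal_candidates=False)
    assert sol.inactive == {"R_dead", "BIO"}
    assert sol.objective == pytest.approx(0.1 * 0.01 * 2, abs=1e-9)
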