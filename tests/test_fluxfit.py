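import math

import numpy as np
import pytest
from scipy import stats as st

from fluxtk._opt import net_flux_bounds, solve_lp
from fluxtk.fluxfit import (
    MeasuredFluxSet,
    blocked_fraction,
    find_blocked,
    fit,
    spearman,
)
from fluxtk.model_core.types import Media, ModelValidationError
from fluxtk.synthgen import (
    FixtureSpec,
    default_media,
    make_flux_case,
    make_model,
)

from _oracles import brute_force_blocked
from conftest import build_model


def _open_chain():
    return build_model(
        [
            ("EX_A", {"A": 1.0}, dict(role="exchange", reversible=True)),
            ("R_AB", {"A": -1.0, "B": 1.0}, dict()),
            ("R_BC", {"B": -1.0, "C": 1.0}, dict()),
            ("EX_C", {"C": 1.0}, dict(role="exchange", reversible=True)),
        ]
    )


CHAIN_MEDIA = Media(uptake_limits={"A": 50.0}, default_cap=50.0)


# --- fit -------------------------------------------------------------------


def test_feasible_measurement_gives_zero_distance():
    m = _open_chain()
    measured = MeasuredFluxSet({"R_AB": 5.0, "R_BC": 5.0})
    res = fit(m, measured, CHAIN_MEDIA)
    assert res.distance == pytest.approx(0.0, abs=1e-8)
    assert res.fluxes["R_AB"] == pytest.approx(5.0, abs=1e-6)
    assert res.fluxes["R_BC"] == pytest.approx(5.0, abs=1e-6)


def test_infeasible_sign_projected_to_zero():
    # R_AB is irreversible; a measured -5 projects onto v = 0
    m = _open_chain()
    measured = MeasuredFluxSet({"R_AB": -5.0, "R_BC": 0.0})
    res = fit(m, measured, CHAIN_MEDIA)
    assert res.fluxes["R_AB"] == pytest.approx(0.0, abs=1e-6)
    assert res.distance == pytest.approx(25.0, abs=1e-6)


def test_fit_needs_two_matched_reactions():
    m = _open_chain()
    with pytest.raises(ModelValidationError):
        fit(m, MeasuredFluxSet({"R_AB": 1.0}), CHAIN_MEDIA)


def test_fit_unmatched_id_errors_without_mapping():
    m = _open_chain()
    with pytest.raises(ModelValidationError, match="mapping"):
        fit(m, MeasuredFluxSet({"nope": 1.0, "R_AB": 1.0}), CHAIN_MEDIA)


def test_fit_with_id_mapping():
    m = _open_chain()
    measured = MeasuredFluxSet({"exp_rxn_1": 5.0, "exp_rxn_2": 5.0})
    res = fit(
        m,
        measured,
        CHAIN_MEDIA,
        mapping={"exp_rxn_1": "R_AB", "exp_rxn_2": "R_BC"},
    )
    assert res.distance == pytest.approx(0.0, abs=1e-8)


def test_fit_respects_mass_balance():
    spec = FixtureSpec(seed=2, n_reactions=12, n_pathways=3)
    m = make_model(spec)
    media = default_media(m, cap=50.0)
    measured = make_flux_case(m, spec, media=media)
    res = fit(m, measured, media)
    A, lb, ub, rxn_ids = net_flux_bounds(m, media, exchange_cap=50.0)
    v = np.array([res.fluxes[r] for r in rxn_ids])
    assert np.max(np.abs(A @ v)) < 1e-6
    assert (v >= lb - 1e-7).all() and (v <= ub + 1e-7).all()


def test_qp_beats_random_feasible_points():
    # Monte-Carlo certificate of convex optimality
    spec = FixtureSpec(seed=6, n_reactions=12, n_pathways=3)
    m = make_model(spec)
    media = default_media(m, cap=50.0)
    measured = make_flux_case(m, spec, media=media)
    res = fit(m, measured, media)
    A, lb, ub, rxn_ids = net_flux_bounds(m, media, exchange_cap=50.0)
    rng = np.random.default_rng(0)
    # vertices from random-objective LPs, then random convex combinations
    verts = []
    for _ in range(12):
        c = rng.standard_normal(len(rxn_ids))
        x, _ = solve_lp(c, A, np.zeros(A.shape[0]), lb, ub)
        verts.append(x)
    verts = np.array(verts)
    idx = {r: j for j, r in enumerate(rxn_ids)}
    for _ in range(1000):
        wts = rng.dirichlet(np.ones(len(verts)))
        point = wts @ verts
        d = sum(
            (measured.fluxes[r] - point[idx[r]]) ** 2 for r in res.matched_ids
        )
        assert res.distance <= d + 1e-9


def test_kkt_residual_small():
    spec = FixtureSpec(seed=8, n_reactions=12, n_pathways=3)
    m = make_model(spec)
    media = default_media(m, cap=50.0)
    res = fit(m, make_flux_case(m, spec, media=media), media)
    assert res.kkt_residual < 1e-6


# --- spearman --------------------------------------------------------------


def test_spearman_identity():
    rho, p = spearman([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(2.0 / math.factorial(4))  # only 2 of 4! perms


def test_spearman_reversal():
    rho, _p = spearman([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
    assert rho == pytest.approx(-1.0)


def test_spearman_zero_variance_flagged():
    with pytest.raises(ModelValidationError, match="variance"):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_spearman_needs_two_points():
    with pytest.raises(ModelValidationError):
        spearman([1.0], [1.0])


def test_spearman_matches_scipy_with_ties():
    rng = np.random.default_rng(31)
    for _ in range(20):
        n = int(rng.integers(10, 40))
        x = rng.integers(0, 10, n).astype(float)  # ties guaranteed
        y = x + rng.normal(0, 3, n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, p = spearman(x, y)
        ref = st.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_spearman_exact_p_is_permutation_fraction():
    rng = np.random.default_rng(5)
    x = rng.normal(size=6)
    y = rng.normal(size=6)
    rho, p = spearman(x, y)
    # recompute the permutation fraction naively
    from itertools import permutations

    ry = st.rankdata(y)
    rx = st.rankdata(x)
    count = 0
    total = 0
    for perm in permutations(ry):
        r = st.pearsonr(rx, perm).statistic
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    assert p == pytest.approx(count / total)


# --- blocked reactions -----------------------------------------------------


def test_open_chain_has_no_blocked_reactions():
    assert blocked_fraction(_open_chain(), CHAIN_MEDIA) == 0.0


def test_dead_end_consumer_is_blocked():
    m = build_model(
        [
            ("EX_A", {"A": 1.0}, dict(role="exchange", reversible=True)),
            ("R_AB", {"A": -1.0, "B": 1.0}, dict()),
            ("EX_B", {"B": 1.0}, dict(role="exchange", reversible=True)),
            ("R_dead", {"A": -1.0, "DEAD": 1.0}, dict()),
        ]
    )
    blocked = find_blocked(m, CHAIN_MEDIA)
    assert blocked == ["R_dead"]
    assert blocked_fraction(m, CHAIN_MEDIA) == pytest.approx(25.0)


def test_blocked_matches_bruteforce_fva():
    for seed in (1, 4, 7):
        spec = FixtureSpec(seed=seed, n_reactions=10, n_pathways=2,
                           reversible_fraction=0.3)
        m = make_model(spec)
        media = default_media(m, cap=50.0)
        assert set(find_blocked(m, media)) == set(
            brute_force_blocked(m, media)
        ), seed


def test_blocked_set_monotone_under_removal():
    spec = FixtureSpec(seed=3, n_reactions=12, n_pathways=3)
    m = make_model(spec)
    media = default_media(m, cap=50.0)
    before = set(find_blocked(m, media))
    smaller = m.copy()
    victim = next(
        rid for rid, r in m.reactions.items() if r.role == "internal"
    )
    smaller.remove_reaction(victim)
    after = set(find_blocked(smaller, media))
    assert (before & set(smaller.reactions)) <= after


# --- parameter recovery ----------------------------------------------------


def test_noise_free_recovery():
    spec = FixtureSpec(seed=12, n_reactions=12, n_pathways=3, noise_sigma=0.0)
    m = make_model(spec)
    media = default_media(m, cap=50.0)
    measured = make_flux_case(m, spec, media=media)
    res = fit(m, measured, media)
    assert res.distance == pytest.approx(0.0, abs=1e-6)
    assert res.spearman_rho == pytest.approx(1.0)
    for rid in res.matched_ids:
        assert res.fluxes[rid] == pytest.approx(
            measured.truth[rid], abs=1e-5
        )


def test_rho_improves_as_noise_shrinks():
    rhos = []
    for sigma in (2.0, 0.5, 0.0):
        vals = []
        for seed in range(6):
            spec = FixtureSpec(seed=seed, n_reactions=12, n_pathways=3,
                               noise_sigma=sigma)
            m = make_model(spec)
            media = default_media(m, cap=50.0)
            res = fit(m, make_flux_case(m, spec, media=media), media)
            vals.append(res.spearman_rho)
        rhos.append(np.mean(vals))
    assert rhos[0] <= rhos[1] + 0.05 <= rhos[2] + 0.1
    assert rhos[-1] == pytest.approx(1.0)


# --- hypothesis property tests ---------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st_h

from fluxtk.fluxfit import _rankdata


@settings(max_examples=100, deadline=None)
@given(
    st_h.lists(
        st_h.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        min_size=1,
        max_size=30,
    )
)
def test_hypothesis_midranks_match_scipy(xs):
    assert np.allclose(_rankdata(np.array(xs)), st.rankdata(xs))


@settings(max_examples=40, deadline=None)
@given(
    st_h.lists(
        st_h.tuples(
            st_h.floats(min_value=-100, max_value=100, allow_nan=False),
            st_h.floats(min_value=-100, max_value=100, allow_nan=False),
        ),
        min_size=10,
        max_size=30,
    )
)
def test_hypothesis_spearman_matches_scipy(pairs):
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(_rankdata(x)) == 0 or np.ptp(_rankdata(y)) == 0:
        return
    rho, p = spearman(x, y)
    ref = st.spearmanr(x, y)
    assert rho == pytest.approx(ref.statistic, abs=1e-12)
    assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)
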