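"""Quadratic-programming fit of model fluxes to measured fluxomics.

Minimize ``sum_measured (v_exp_i - v_i)^2`` over the standard FBA
polytope (mass balance, reversibility-derived bounds, media-gated
exchange bounds at a 50 cap by default).  Reversible reactions are NOT
decomposed here; measured values are compared against signed net
fluxes.  Fit quality is reported as the squared distance plus a
Spearman rank correlation with its p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import stats as _st

from ._opt import fva, net_flux_bounds, solve_qp
from .model_core.types import Media, MetabolicModel, ModelValidationError

__all__ = [
    "MeasuredFluxSet",
    "FluxFitResult",
    "fit",
    "spearman",
    "blocked_fraction",
    "find_blocked",
]

BLOCKED_TOL = 1e-6


@dataclass
class MeasuredFluxSet:
    """Measured net fluxes keyed by reaction id."""

    fluxes: Dict[str, float]
    label: str = "measured"
    truth: Optional[Dict[str, float]] = None  # fixture ground truth, if any

    def __post_init__(self) -> None:
        bad = [r for r, v in self.fluxes.items() if not math.isfinite(v)]
        if bad:
            raise ModelValidationError(f"non-finite measured fluxes: {bad}")

    def mapped(self, mapping: Mapping[str, str]) -> "MeasuredFluxSet":
        """Rename measured ids onto model ids via an explicit mapping."""
        return MeasuredFluxSet(
            fluxes={mapping.get(r, r): v for r, v in self.fluxes.items()},
            label=self.label,
        )

    def __len__(self) -> int:
        return len(self.fluxes)


@dataclass
class FluxFitResult:
    fluxes: Dict[str, float]
    distance: float
    spearman_rho: float
    spearman_p: float
    n_matched: int
    matched_ids: list = field(default_factory=list)
    kkt_residual: float = 0.0

    def residuals(self, measured: MeasuredFluxSet) -> Dict[str, float]:
        return {
            rid: measured.fluxes[rid] - self.fluxes[rid]
            for rid in self.matched_ids
        }


def _rankdata(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties); independent of scipy's rankdata."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(
    fitted: np.ndarray, measured: np.ndarray, exact_below: int = 10
) -> Tuple[float, float]:
    """Spearman rank correlation with midrank ties, two-sided p-value.

    For n below ``exact_below`` the p-value is an exact permutation
    enumeration; otherwise the usual t-distribution approximation with
    n-2 degrees of freedom.
    """
    x = np.asarray(fitted, dtype=float)
    y = np.asarray(measured, dtype=float)
    n = x.size
    if n < 2:
        raise ModelValidationError("Spearman needs at least two observations")
    rx, ry = _rankdata(x), _rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ModelValidationError("zero variance: Spearman rho undefined")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if n < exact_below:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        rhos = (pc @ rxc) / (
            np.sqrt((pc**2).sum(axis=1)) * np.sqrt((rxc**2).sum())
        )
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * _st.t.sf(abs(tstat), n - 2))
    return rho, p


def fit(
    model: MetabolicModel,
    measured: MeasuredFluxSet,
    media: Media,
    cap: float = 50.0,
    flux_bound: float = 1000.0,
    mapping: Optional[Mapping[str, str]] = None,
) -> FluxFitResult:
    """Fit model fluxes to the measured values by convex QP.

    The projection onto the measured coordinates is unique; the rest of
    the vector is canonicalized by a small minimum-norm (ridge) term.
    """
    if mapping is not None:
        measured = measured.mapped(mapping)
    A, lb, ub, rxn_ids = net_flux_bounds(
        model, media, flux_bound=flux_bound, exchange_cap=cap
    )
    idx = {rid: j for j, rid in enumerate(rxn_ids)}
    matched = [rid for rid in measured.fluxes if rid in idx]
    unmatched = sorted(set(measured.fluxes) - set(matched))
    if unmatched:
        raise ModelValidationError(
            f"measured reactions not in model (supply an id mapping): {unmatched}"
        )
    if len(matched) < 2:
        raise ModelValidationError(
            "need at least two matched reactions for a correlation"
        )
    n = len(rxn_ids)
    w = np.zeros(n)
    t = np.zeros(n)
    for rid in matched:
        w[idx[rid]] = 1.0
        t[idx[rid]] = measured.fluxes[rid]
    v, kkt = solve_qp(w, t, A, np.zeros(A.shape[0]), lb, ub)
    fitted = {rid: float(v[j]) for rid, j in idx.items()}
    dist = float(
        sum((measured.fluxes[rid] - fitted[rid]) ** 2 for rid in matched)
    )
    mv = np.array([measured.fluxes[r] for r in matched])
    fv = np.array([fitted[r] for r in matched])
    try:
        rho, p = spearman(fv, mv)
    except ModelValidationError:  # zero variance: rho undefined, flagged
        rho, p = float("nan"), float("nan")
    return FluxFitResult(
        fluxes=fitted,
        distance=dist,
        spearman_rho=rho,
        spearman_p=p,
        n_matched=len(matched),
        matched_ids=matched,
        kkt_residual=kkt,
    )


def find_blocked(
    model: MetabolicModel,
    media: Media,
    cap: float = 50.0,
    flux_bound: float = 1000.0,
) -> list:
    """Reactions whose flux-variability range is [0, 0] under the
    fitting constraints."""
    ranges = fva(model, media, flux_bound=flux_bound, exchange_cap=cap)
    return [
        rid
        for rid, (lo, hi) in ranges.items()
        if abs(lo) < BLOCKED_TOL and abs(hi) < BLOCKED_TOL
    ]


def blocked_fraction(
    model: MetabolicModel,
    media: Media,
    cap: float = 50.0,
    flux_bound: float = 1000.0,
) -> float:
    """Percentage of model reactions unable to carry any flux, to one
    decimal place."""
    if not model.reactions:
        return 0.0
    blocked = find_blocked(model, media, cap=cap, flux_bound=flux_bound)
    return round(100.0 * len(blocked) / len(model.reactions), 1)
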