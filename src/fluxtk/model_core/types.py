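"""Core stoichiometric data model.

Conventions used throughout the toolkit:

* Stoichiometric coefficients are signed; negative = consumed.
* An exchange reaction touches exactly one metabolite.  Its *uptake*
  direction is the direction in which that metabolite is produced into
  the network, so an exchange written ``-> A`` has uptake as positive
  flux.  Media membership gates the uptake bound only; secretion is
  always allowed up to the cap.
* Internal flux bounds used by the optimizers are derived from the
  ``reversible`` flag and a configurable cap; the stored bounds of
  exchange reactions are set by :func:`fluxtk.model_core.transform.apply_media`.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set

from .gpr import GeneAssociation

__all__ = [
    "ModelValidationError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "BiochemDatabase",
    "Media",
    "ROLE_INTERNAL",
    "ROLE_EXCHANGE",
    "ROLE_BIOMASS",
]

ROLE_INTERNAL = "internal"
ROLE_EXCHANGE = "exchange"
ROLE_BIOMASS = "biomass"
_ROLES = (ROLE_INTERNAL, ROLE_EXCHANGE, ROLE_BIOMASS)
_SOURCES = ("model", "database", "gapfilled")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    is_exchangeable: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Optional[GeneAssociation] = None
    role: str = ROLE_INTERNAL
    source: str = "model"
    subsystem: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.role not in _ROLES:
            raise ModelValidationError(f"reaction {self.id!r}: bad role {self.role!r}")
        if self.source not in _SOURCES:
            raise ModelValidationError(
                f"reaction {self.id!r}: bad source {self.source!r}"
            )
        if self.role == ROLE_EXCHANGE and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )
        if self.reversible and self.lower_bound == 0.0:
            self.lower_bound = -1000.0

    @property
    def is_exchange(self) -> bool:
        return self.role == ROLE_EXCHANGE

    @property
    def exchange_metabolite(self) -> str:
        if not self.is_exchange:
            raise ValueError(f"{self.id} is not an exchange reaction")
        return next(iter(self.stoichiometry))

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes if self.gpr is not None else frozenset()

    def copy(self) -> "Reaction":
        r = _copy.copy(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


class MetabolicModel:
    """A compartmentalized stoichiometric model with GPR rules."""

    def __init__(
        self,
        model_id: str = "model",
        compartments: Optional[Iterable[str]] = None,
    ):
        self.id = model_id
        self.compartments: List[str] = list(compartments or [])
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.biomass_id: Optional[str] = None

    # -- construction ---------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            self.compartments.append(met.compartment)
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        if rxn.role == ROLE_BIOMASS:
            if self.biomass_id is not None and self.biomass_id != rxn.id:
                raise ModelValidationError("model already has a biomass reaction")
            self.biomass_id = rxn.id
        if rxn.is_exchange:
            self.metabolites[rxn.exchange_metabolite].is_exchangeable = True
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        rxn = self.reactions.pop(rxn_id)
        if rxn_id == self.biomass_id:
            self.biomass_id = None
        return rxn

    # -- queries --------------------------------------------------------

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    @property
    def gene_associated_ids(self) -> List[str]:
        return [r.id for r in self.reactions.values() if r.gpr is not None]

    @property
    def exchange_ids(self) -> List[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def exchange_for(self, met_id: str) -> Optional[Reaction]:
        for rxn in self.reactions.values():
            if rxn.is_exchange and rxn.exchange_metabolite == met_id:
                return rxn
        return None

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id!r}: unknown compartment {met.compartment!r}"
                )
        n_biomass = sum(1 for r in self.reactions.values() if r.role == ROLE_BIOMASS)
        if n_biomass > 1:
            raise ModelValidationError("more than one biomass reaction")
        if self.biomass_id is not None and self.biomass_id not in self.reactions:
            raise ModelValidationError(f"biomass id {self.biomass_id!r} not a reaction")

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(self.id, list(self.compartments))
        for met in self.metabolites.values():
            m.metabolites[met.id] = _copy.copy(met)
        for rxn in self.reactions.values():
            m.reactions[rxn.id] = rxn.copy()
        m.biomass_id = self.biomass_id
        return m

    def subset(self, reaction_ids: Iterable[str]) -> "MetabolicModel":
        """Model restricted to ``reaction_ids`` (metabolites pruned to those used)."""
        keep = set(reaction_ids)
        m = MetabolicModel(self.id + "_sub", list(self.compartments))
        used: Set[str] = set()
        for rid in self.reactions:
            if rid in keep:
                used |= set(self.reactions[rid].stoichiometry)
        for mid, met in self.metabolites.items():
            if mid in used:
                m.metabolites[mid] = _copy.copy(met)
                m.metabolites[mid].is_exchangeable = False
        for rid, rxn in self.reactions.items():
            if rid in keep:
                m.add_reaction(rxn.copy())
        return m

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


@dataclass
class BiochemDatabase:
    """Candidate reactions for gapfilling, with strictly positive penalties."""

    reactions: Dict[str, Reaction] = field(default_factory=dict)
    penalties: Dict[str, float] = field(default_factory=dict)

    def add(self, rxn: Reaction, penalty: float = 1.0) -> None:
        if penalty <= 0:
            raise ModelValidationError(
                f"database reaction {rxn.id!r}: penalty must be positive"
            )
        rxn.source = "database"
        self.reactions[rxn.id] = rxn
        self.penalties[rxn.id] = float(penalty)

    def validate_against(self, model: MetabolicModel) -> None:
        overlap = set(self.reactions) & set(model.reactions)
        if overlap:
            raise ModelValidationError(
                f"database ids collide with model ids: {sorted(overlap)}"
            )
        for rid, pen in self.penalties.items():
            if pen <= 0:
                raise ModelValidationError(f"penalty for {rid!r} must be positive")

    def __len__(self) -> int:
        return len(self.reactions)


@dataclass
class Media:
    """Growth media: per-metabolite maximum uptake rates.

    A metabolite absent from ``uptake_limits`` gets an uptake bound of
    zero (its gamma coefficient is 0); secretion is always capped at
    ``default_cap``.
    """

    uptake_limits: Dict[str, float] = field(default_factory=dict)
    default_cap: float = 100.0

    def __post_init__(self) -> None:
        for mid, lim in self.uptake_limits.items():
            if lim < 0:
                raise ModelValidationError(f"media limit for {mid!r} is negative")

    def gamma(self, met_id: str) -> int:
        return 1 if met_id in self.uptake_limits else 0

    def uptake_bound(self, met_id: str, cap: Optional[float] = None) -> float:
        cap = self.default_cap if cap is None else cap
        if met_id not in self.uptake_limits:
            return 0.0
        return min(self.uptake_limits[met_id], cap)
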