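import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fluxtk.model_core.gpr import parse_gpr
from fluxtk.model_core.types import (
    Media,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from fluxtk.synthgen import FixtureSpec, default_media, make_model


def build_model(reactions, biomass=None, model_id="toy"):
    """Helper: build a model from (id, stoich, kwargs) tuples."""
    m = MetabolicModel(model_id)
    for rid, stoich, kwargs in reactions:
        for mid in stoich:
            if mid not in m.metabolites:
                m.add_metabolite(Metabolite(id=mid, compartment="c"))
        gpr = kwargs.pop("gpr", None)
        if isinstance(gpr, str):
            gpr = parse_gpr(gpr)
        m.add_reaction(Reaction(id=rid, stoichiometry=dict(stoich), gpr=gpr, **kwargs))
    return m


@pytest.fixture
def chain_model():
    """EX -> A -> B -> C -> biomass, all gene-associated internals."""
    return build_model(
        [
            ("EX_A", {"A": 1.0}, dict(role="exchange", reversible=True)),
            ("R_AB", {"A": -1.0, "B": 1.0}, dict(gpr="gAB")),
            ("R_BC", {"B": -1.0, "C": 1.0}, dict(gpr="gBC")),
            ("BIO", {"C": -1.0}, dict(role="biomass")),
        ]
    )


@pytest.fixture
def chain_media():
    return Media(uptake_limits={"A": 100.0}, default_cap=100.0)


@pytest.fixture
def small_spec():
    return FixtureSpec(seed=11, n_reactions=12, n_pathways=3)


@pytest.fixture
def small_model(small_spec):
    return make_model(small_spec)


@pytest.fixture
def small_media(small_model):
    return default_media(small_model)
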