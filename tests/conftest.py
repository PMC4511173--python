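import numpy as np
import pytest

from bteval.fixtures import FixtureProfile, generate_bb_document, generate_ontology
from bteval.ontology import Ontology, OntologyConcept


@pytest.fixture
def chain_ontology():
    """A is_a B is_a C (C is the root)."""
    return Ontology([
        OntologyConcept("C", name="root"),
        OntologyConcept("B", name="mid", parents=(("is_a", "C"),)),
        OntologyConcept("A", name="leaf", parents=(("is_a", "B"),)),
    ])


@pytest.fixture
def tree_ontology():
    return generate_ontology(depth=4, branching=3, seed=7)


@pytest.fixture
def dag_ontology():
    return generate_ontology(depth=4, branching=3, seed=11, cross_link_rate=0.4)


@pytest.fixture
def bb_doc(tree_ontology):
    profile = FixtureProfile(discontinuity_rate=0.0, equivalence_rate=0.3,
                             events_per_doc=5, entities_per_doc=10)
    return generate_bb_document(profile, tree_ontology, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20130913)
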