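"""Shared fixtures: the reference synthetic bundle and a hand-built toy graph."""

import numpy as np
import pytest

from medkg.corpus import corpus_index
from medkg.kg import (
    CAUSE,
    CORRESPONDED_TO,
    LOCATED_IN,
    ConceptClass,
    Entity,
    KnowledgeGraph,
    Relation,
)
from medkg.synth import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_bundle():
    """The reference study bundle (200 balanced chains, 0.95/0.05 signal)."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_corpus(default_bundle):
    return corpus_index(default_bundle.documents)


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fast bundle for pipeline tests (10+10 chains)."""
    return generate(
        GeneratorConfig(
            n_symptoms=12,
            n_diseases=8,
            n_treatments=6,
            causes_per_symptom=3,
            n_meaningful_chains=10,
            n_meaningless_chains=10,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free limit: every signal planted, no spurious co-mentions."""
    return generate(GeneratorConfig(seed=2, p_signal=1.0, p_noise=0.0))


def build_toy_graph():
    """The classic junction motif: inflammation in lung/skin/mouth, but only
    lung inflammation leads to pneumonia (treated by antibiotics)."""
    g = KnowledgeGraph()
    ents = {}
    for name, concept in [
        ("lung", ConceptClass.BODILY_PART),
        ("skin", ConceptClass.BODILY_PART),
        ("mouth", ConceptClass.BODILY_PART),
        ("inflammation", ConceptClass.SYMPTOM),
        ("pneumonia", ConceptClass.DISEASE),
        ("antibiotics", ConceptClass.TREATMENT),
    ]:
        ents[name] = g.add_entity(Entity.from_name(name, concept))
    for part in ("lung", "skin", "mouth"):
        g.add_relation(Relation(LOCATED_IN, ents["inflammation"], ents[part]))
    g.add_relation(Relation(CAUSE, ents["inflammation"], ents["pneumonia"]))
    g.add_relation(Relation(CORRESPONDED_TO, ents["pneumonia"], ents["antibiotics"]))
    return g


@pytest.fixture()
def toy_graph():
    return build_toy_graph()


def random_typed_graph(rng: np.random.Generator, n_entities: int = 20) -> KnowledgeGraph:
    """A random schema-valid graph over the four core concept classes."""
    g = KnowledgeGraph()
    classes = [
        ConceptClass.BODILY_PART,
        ConceptClass.SYMPTOM,
        ConceptClass.DISEASE,
        ConceptClass.TREATMENT,
    ]
    by_class = {c: [] for c in classes}
    for i in range(n_entities):
        concept = classes[int(rng.integers(len(classes)))]
        e = g.add_entity(Entity.from_name(f"e{i:02d}", concept))
        by_class[concept].append(e)
    for schema in (LOCATED_IN, CAUSE, CORRESPONDED_TO):
        subjects = by_class[schema.domain]
        objects = by_class[schema.range]
        if not subjects or not objects:
            continue
        n_edges = int(rng.integers(0, 2 * n_entities))
        for _ in range(n_edges):
            s = subjects[int(rng.integers(len(subjects)))]
            o = objects[int(rng.integers(len(objects)))]
            g.add_relation(Relation(schema, s, o))
    return g
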