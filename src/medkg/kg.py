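"""Typed medical knowledge graph.

Entities are glossary-resolved medical terms carrying exactly one concept
class (bodily part, symptom, disease, treatment, ...).  Directed binary
relations between entities are constrained by a closed set of relation
schemas (domain and range concept classes):

    LOCATED_IN       : SYMPTOM  -> BODILY_PART
    CAUSE            : SYMPTOM  -> DISEASE
    CORRESPONDED_TO  : DISEASE  -> TREATMENT

The graph deduplicates triples: re-adding an existing (schema, subject,
object) triple merges provenance and keeps the maximum confidence, because
the same fact is legitimately harvested from many sentences.  Graphs
serialize to sorted N-Triples via rdflib.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import rdflib
from rdflib.namespace import RDF

from .errors import RelationTypeError, SchemaViolationError

#: fixed project base IRI for RDF export (deterministic IRIs across runs)
BASE_IRI = "http://purl.example.net/medkg/"
NS = rdflib.Namespace(BASE_IRI)


class ConceptClass(enum.Enum):
    """Closed enumeration of medical concept classes."""

    BODILY_PART = "BODILY_PART"
    SYMPTOM = "SYMPTOM"
    DISEASE = "DISEASE"
    TREATMENT = "TREATMENT"
    CLINICAL_HISTORY = "CLINICAL_HISTORY"
    LABORATORY_TEST = "LABORATORY_TEST"
    DRUG = "DRUG"
    DEPARTMENT = "DEPARTMENT"


def slugify(name: str) -> str:
    """Deterministic entity id from a canonical name.

    Lowercased, unicode-normalized, whitespace collapsed to underscores.
    """
    norm = unicodedata.normalize("NFKC", name).strip().lower()
    norm = re.sub(r"\s+", "_", norm)
    if not norm:
        raise ValueError("entity name must be non-empty")
    return norm


@dataclass(frozen=True)
class RelationSchema:
    """A typed directed relation: name plus domain/range concept classes."""

    name: str
    domain: ConceptClass
    range: ConceptClass


LOCATED_IN = RelationSchema("LOCATED_IN", ConceptClass.SYMPTOM, ConceptClass.BODILY_PART)
CAUSE = RelationSchema("CAUSE", ConceptClass.SYMPTOM, ConceptClass.DISEASE)
CORRESPONDED_TO = RelationSchema("CORRESPONDED_TO", ConceptClass.DISEASE, ConceptClass.TREATMENT)

#: the closed relation-schema registry
SCHEMAS: dict[str, RelationSchema] = {
    s.name: s for s in (LOCATED_IN, CAUSE, CORRESPONDED_TO)
}


def get_schema(name: str) -> RelationSchema:
    try:
        return SCHEMAS[name]
    except KeyError:
        raise SchemaViolationError(f"unknown relation schema {name!r}") from None


@dataclass
class Entity:
    """A graph vertex: a glossary-resolved term with one concept class."""

    id: str
    canonical_name: str
    concept: ConceptClass
    synonyms: set[str] = field(default_factory=set)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise ValueError("canonical_name must be non-empty")
        self.synonyms = set(self.synonyms)
        self.synonyms.add(self.canonical_name)

    @classmethod
    def from_name(cls, name: str, concept: ConceptClass, **kw) -> "Entity":
        return cls(id=slugify(name), canonical_name=name, concept=concept, **kw)

    def __hash__(self) -> int:  # identity by id within a graph
        return hash(self.id)

    def __eq__(self, other) -> bool:
        return isinstance(other, Entity) and self.id == other.id


#: provenance pointer: (document_id, sentence_index)
Provenance = tuple[str, int]


@dataclass
class Relation:
    """A typed directed edge with sentence-level provenance."""

    schema: RelationSchema
    subject: Entity
    object: Entity
    provenance: list[Provenance] = field(default_factory=list)
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.subject.concept is not self.schema.domain:
            raise RelationTypeError(
                f"{self.schema.name} domain is {self.schema.domain.value}, "
                f"got subject {self.subject.id!r} of class {self.subject.concept.value}"
            )
        if self.object.concept is not self.schema.range:
            raise RelationTypeError(
                f"{self.schema.name} range is {self.schema.range.value}, "
                f"got object {self.object.id!r} of class {self.object.concept.value}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.schema.name, self.subject.id, self.object.id)


class KnowledgeGraph:
    """Entities plus a deduplicated set of typed relations (the set S)."""

    def __init__(self) -> None:
        self.entities: dict[str, Entity] = {}
        self._relations: dict[tuple[str, str, str], Relation] = {}
        # adjacency: (schema, entity_id) -> set of neighbor ids
        self._fwd: dict[tuple[str, str], set[str]] = {}
        self._inv: dict[tuple[str, str], set[str]] = {}

    # -- entities ---------------------------------------------------------
    def add_entity(self, entity: Entity) -> Entity:
        existing = self.entities.get(entity.id)
        if existing is not None:
            if existing.concept is not entity.concept:
                raise SchemaViolationError(
                    f"entity {entity.id!r} already present with class "
                    f"{existing.concept.value}, cannot re-add as {entity.concept.value}"
                )
            existing.synonyms |= entity.synonyms
            return existing
        self.entities[entity.id] = entity
        return entity

    def __contains__(self, entity) -> bool:
        eid = entity.id if isinstance(entity, Entity) else entity
        return eid in self.entities

    # -- relations --------------------------------------------------------
    @property
    def relations(self) -> list[Relation]:
        return list(self._relations.values())

    def __len__(self) -> int:
        """|S|, the number of distinct triples."""
        return len(self._relations)

    def get_relation(self, schema: RelationSchema | str, subject_id: str, object_id: str) -> Relation:
        name = schema if isinstance(schema, str) else schema.name
        return self._relations[(name, subject_id, object_id)]

    def add_relation(self, relation: Relation) -> "KnowledgeGraph":
        """Insert a relation; duplicates merge provenance and keep max confidence."""
        for endpoint in (relation.subject, relation.object):
            if endpoint.id not in self.entities:
                raise SchemaViolationError(
                    f"relation endpoint {endpoint.id!r} is not an entity of this graph"
                )
            if self.entities[endpoint.id].concept is not endpoint.concept:
                raise RelationTypeError(
                    f"endpoint {endpoint.id!r} class mismatch with graph entity"
                )
        existing = self._relations.get(relation.key)
        if existing is not None:
            for prov in relation.provenance:
                if prov not in existing.provenance:
                    existing.provenance.append(prov)
            existing.confidence = max(existing.confidence, relation.confidence)
            return self
        # re-point endpoints at the graph's own Entity objects
        relation.subject = self.entities[relation.subject.id]
        relation.object = self.entities[relation.object.id]
        self._relations[relation.key] = relation
        name = relation.schema.name
        self._fwd.setdefault((name, relation.subject.id), set()).add(relation.object.id)
        self._inv.setdefault((name, relation.object.id), set()).add(relation.subject.id)
        return self

    def neighbors(
        self,
        entity: Entity | str,
        schema: RelationSchema | str,
        direction: str = "forward",
    ) -> set[Entity]:
        """Adjacent entities through one relation schema.

        ``forward`` returns objects of relations whose subject is ``entity``;
        ``inverse`` returns subjects of relations whose object is ``entity``.
        """
        eid = entity.id if isinstance(entity, Entity) else entity
        name = schema if isinstance(schema, str) else schema.name
        if direction == "forward":
            ids = self._fwd.get((name, eid), set())
        elif direction == "inverse":
            ids = self._inv.get((name, eid), set())
        else:
            raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
        return {self.entities[i] for i in ids}


# -- RDF export / import --------------------------------------------------

def _entity_iri(eid: str) -> rdflib.URIRef:
    return NS[f"entity/{eid}"]


def _class_iri(concept: ConceptClass) -> rdflib.URIRef:
    return NS[f"class/{concept.value}"]


def _schema_iri(schema: RelationSchema) -> rdflib.URIRef:
    return NS[f"relation/{schema.name.lower()}"]


def export_ntriples(graph: KnowledgeGraph, path: str | Path) -> None:
    """Write the graph as sorted N-Triples (UTF-8, one triple per line).

    One rdf:type triple per entity plus one triple per relation; ordering is
    lexicographic so equal graphs serialize byte-identically.
    """
    g = rdflib.Graph()
    for entity in graph.entities.values():
        g.add((_entity_iri(entity.id), RDF.type, _class_iri(entity.concept)))
    for rel in graph.relations:
        g.add((_entity_iri(rel.subject.id), _schema_iri(rel.schema), _entity_iri(rel.object.id)))
    lines = sorted(
        line for line in g.serialize(format="nt").splitlines() if line.strip()
    )
    Path(path).write_text("".join(f"{line}\n" for line in lines), encoding="utf-8")


def import_ntriples(path: str | Path) -> KnowledgeGraph:
    """Rebuild a graph from an N-Triples file written by :func:`export_ntriples`."""
    g = rdflib.Graph()
    g.parse(str(path), format="nt")
    kg = KnowledgeGraph()
    class_by_iri = {str(_class_iri(c)): c for c in ConceptClass}
    schema_by_iri = {str(_schema_iri(s)): s for s in SCHEMAS.values()}
    prefix = str(NS["entity/"])

    def eid_of(iri: rdflib.URIRef) -> str:
        s = str(iri)
        if not s.startswith(prefix):
            raise SchemaViolationError(f"unexpected entity IRI {s!r}")
        return s[len(prefix):]

    relation_triples = []
    for s, p, o in g:
        if p == RDF.type:
            concept = class_by_iri.get(str(o))
            if concept is None:
                raise SchemaViolationError(f"unknown concept class IRI {o}")
            eid = eid_of(s)
            kg.add_entity(Entity(id=eid, canonical_name=eid.replace("_", " "), concept=concept))
        else:
            relation_triples.append((s, p, o))
    for s, p, o in relation_triples:
        schema = schema_by_iri.get(str(p))
        if schema is None:
            raise SchemaViolationError(f"unknown relation IRI {p}")
        kg.add_relation(
            Relation(schema=schema, subject=kg.entities[eid_of(s)], object=kg.entities[eid_of(o)])
        )
    return kg


# -- terminology glossary -------------------------------------------------

def _normalize_term(term: str) -> str:
    return re.sub(r"\s+", " ", unicodedata.normalize("NFKC", term).strip().lower())


class TerminologyGlossary:
    """Metathesaurus mapping surface terms (incl. synonyms) to entity ids.

    Lookup is case-insensitive after unicode/whitespace normalization.  A term
    may map to several entities; callers disambiguate (the entity recognizer
    prefers the lexicographically smallest id for determinism).
    """

    def __init__(self) -> None:
        self._term_to_ids: dict[str, set[str]] = {}
        self._id_to_concept: dict[str, ConceptClass] = {}
        self._id_to_name: dict[str, str] = {}

    def add(self, term: str, entity_id: str, concept: ConceptClass) -> None:
        norm = _normalize_term(term)
        if not norm:
            raise ValueError("glossary term must be non-empty")
        self._term_to_ids.setdefault(norm, set()).add(entity_id)
        known = self._id_to_concept.get(entity_id)
        if known is not None and known is not concept:
            raise SchemaViolationError(
                f"entity {entity_id!r} registered with two concept classes"
            )
        self._id_to_concept[entity_id] = concept
        self._id_to_name.setdefault(entity_id, term)

    def add_entity(self, entity: Entity) -> None:
        for term in sorted(entity.synonyms):
            self.add(term, entity.id, entity.concept)
        self._id_to_name[entity.id] = entity.canonical_name

    @classmethod
    def from_graph(cls, graph: KnowledgeGraph) -> "TerminologyGlossary":
        glossary = cls()
        for entity in graph.entities.values():
            glossary.add_entity(entity)
        return glossary

    @classmethod
    def from_entities(cls, entities: Iterable[Entity]) -> "TerminologyGlossary":
        glossary = cls()
        for entity in entities:
            glossary.add_entity(entity)
        return glossary

    def lookup(self, term: str) -> list[str]:
        """Entity ids for a surface term, sorted; empty list when unknown."""
        return sorted(self._term_to_ids.get(_normalize_term(term), ()))

    def concept_of(self, entity_id: str) -> ConceptClass:
        return self._id_to_concept[entity_id]

    def name_of(self, entity_id: str) -> str:
        return self._id_to_name[entity_id]

    @property
    def entity_ids(self) -> list[str]:
        return sorted(self._id_to_concept)

    def terms_by_concept(self, concept: ConceptClass) -> list[str]:
        return sorted(
            term
            for term, ids in self._term_to_ids.items()
            if any(self._id_to_concept[i] is concept for i in ids)
        )

    @property
    def max_term_tokens(self) -> int:
        if not self._term_to_ids:
            return 0
        return max(len(t.split()) for t in self._term_to_ids)

    def __len__(self) -> int:
        return len(self._term_to_ids)

    def entity_stub(self, entity_id: str) -> Entity:
        """Minimal Entity reconstructed from glossary information."""
        return Entity(
            id=entity_id,
            canonical_name=self._id_to_name.get(entity_id, entity_id.replace("_", " ")),
            concept=self._id_to_concept[entity_id],
        )

    # -- TSV io -----------------------------------------------------------
    def save_tsv(self, path: str | Path) -> None:
        rows = ["term\tentity_id\tconcept_class"]
        for term in sorted(self._term_to_ids):
            for eid in sorted(self._term_to_ids[term]):
                rows.append(f"{term}\t{eid}\t{self._id_to_concept[eid].value}")
        Path(path).write_text("".join(r + "\n" for r in rows), encoding="utf-8")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "TerminologyGlossary":
        glossary = cls()
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        for lineno, line in enumerate(lines):
            if not line.strip() or (lineno == 0 and line.startswith("term\t")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno + 1}: expected 3 tab-separated columns")
            term, eid, concept = parts
            glossary.add(term, eid, ConceptClass(concept))
        return glossary


# -- seed facts TSV -------------------------------------------------------

def save_seed_facts(relations: Iterable[Relation], path: str | Path) -> None:
    rows = ["relation\tsubject_id\tobject_id"]
    for rel in sorted(relations, key=lambda r: r.key):
        rows.append(f"{rel.schema.name}\t{rel.subject.id}\t{rel.object.id}")
    Path(path).write_text("".join(r + "\n" for r in rows), encoding="utf-8")


def load_seed_facts(path: str | Path) -> list[tuple[str, str, str]]:
    """Seed facts as (schema_name, subject_id, object_id) triples."""
    seeds = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines):
        if not line.strip() or (lineno == 0 and line.startswith("relation\t")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno + 1}: expected 3 tab-separated columns")
        get_schema(parts[0])  # validates the schema name
        seeds.append((parts[0], parts[1], parts[2]))
    return seeds
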