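"""Forward/backward chain inference over the knowledge graph.

An inference chain composes binary relations over shared endpoint entities,
e.g. bodily part -> symptom -> disease -> treatment.  A schema path fixes,
per step, the relation schema and the traversal direction (``forward``
walks subject->object, ``inverse`` object->subject); concept classes must
chain correctly.  Chains are simple (no repeated entity) and enumerated
depth-first in lexicographic entity-id order, so output is deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

from .errors import SchemaViolationError
from .kg import ConceptClass, Entity, KnowledgeGraph, Relation, RelationSchema, get_schema

MEANINGFUL = "meaningful"
MEANINGLESS = "meaningless"
UNLABELED = "unlabeled"

FORWARD = "forward"
INVERSE = "inverse"


def _entry_class(schema: RelationSchema, traversal: str) -> ConceptClass:
    return schema.domain if traversal == FORWARD else schema.range


def _exit_class(schema: RelationSchema, traversal: str) -> ConceptClass:
    return schema.range if traversal == FORWARD else schema.domain


@dataclass(frozen=True)
class SchemaPath:
    """An ordered list of (schema, traversal) steps with chaining classes."""

    steps: tuple[tuple[RelationSchema, str], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise SchemaViolationError("schema path must have at least one step")
        for schema, traversal in self.steps:
            if traversal not in (FORWARD, INVERSE):
                raise SchemaViolationError(f"unknown traversal {traversal!r}")
        for (s1, t1), (s2, t2) in zip(self.steps, self.steps[1:]):
            if _exit_class(s1, t1) is not _entry_class(s2, t2):
                raise SchemaViolationError(
                    f"schema path broken: {s1.name}/{t1} exits "
                    f"{_exit_class(s1, t1).value} but {s2.name}/{t2} enters "
                    f"{_entry_class(s2, t2).value}"
                )

    @classmethod
    def of(cls, *steps: tuple[RelationSchema | str, str]) -> "SchemaPath":
        resolved = tuple(
            (get_schema(s) if isinstance(s, str) else s, t) for s, t in steps
        )
        return cls(steps=resolved)

    @property
    def entry_class(self) -> ConceptClass:
        return _entry_class(*self.steps[0])

    @property
    def exit_class(self) -> ConceptClass:
        return _exit_class(*self.steps[-1])

    def reversed(self) -> "SchemaPath":
        flipped = tuple(
            (schema, INVERSE if traversal == FORWARD else FORWARD)
            for schema, traversal in reversed(self.steps)
        )
        return SchemaPath(steps=flipped)

    def __len__(self) -> int:
        return len(self.steps)


#: default study-set schema path: bodily part => symptoms => diseases => treatments
DEFAULT_SCHEMA_PATH = SchemaPath.of(
    ("LOCATED_IN", INVERSE), ("CAUSE", FORWARD), ("CORRESPONDED_TO", FORWARD)
)


@dataclass
class ChainStep:
    """One traversed relation inside a chain."""

    relation: Relation
    traversal: str

    @property
    def source(self) -> Entity:
        return self.relation.subject if self.traversal == FORWARD else self.relation.object

    @property
    def target(self) -> Entity:
        return self.relation.object if self.traversal == FORWARD else self.relation.subject


@dataclass
class InferenceChain:
    """An endpoint-joined sequence of traversed relations with a label."""

    steps: list[ChainStep]
    entity_path: list[Entity]
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if len(self.entity_path) != len(self.steps) + 1:
            raise ValueError("entity_path length must be number of steps + 1")
        for i, step in enumerate(self.steps):
            if step.source != self.entity_path[i] or step.target != self.entity_path[i + 1]:
                raise ValueError(f"step {i} endpoints inconsistent with entity_path")

    @property
    def entity_ids(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.entity_path)

    def reversed(self) -> "InferenceChain":
        steps = [
            ChainStep(
                relation=s.relation,
                traversal=INVERSE if s.traversal == FORWARD else FORWARD,
            )
            for s in reversed(self.steps)
        ]
        return InferenceChain(
            steps=steps, entity_path=list(reversed(self.entity_path)), label=self.label
        )


def enumerate_chains(
    graph: KnowledgeGraph,
    start: Entity,
    schema_path: SchemaPath,
    max_chains: int = 10_000,
) -> list[InferenceChain]:
    """All simple chains from ``start`` along ``schema_path`` (forward chaining).

    Depth-first, neighbors visited in lexicographic id order; chains never
    repeat an entity.  Results beyond ``max_chains`` are dropped with a
    truncation warning.
    """
    if start.id not in graph.entities:
        raise SchemaViolationError(f"start entity {start.id!r} not in graph")
    start = graph.entities[start.id]
    if start.concept is not schema_path.entry_class:
        raise SchemaViolationError(
            f"start entity class {start.concept.value} does not match schema path "
            f"entry class {schema_path.entry_class.value}"
        )
    chains: list[InferenceChain] = []
    truncated = False

    def walk(position: Entity, depth: int, path: list[Entity], steps: list[ChainStep]) -> None:
        nonlocal truncated
        if truncated:
            return
        if depth == len(schema_path):
            if len(chains) >= max_chains:
                truncated = True
                return
            chains.append(
                InferenceChain(steps=list(steps), entity_path=list(path))
            )
            return
        schema, traversal = schema_path.steps[depth]
        direction = FORWARD if traversal == FORWARD else INVERSE
        for nxt in sorted(graph.neighbors(position, schema, direction), key=lambda e: e.id):
            if nxt in path:
                continue  # chains are simple
            if traversal == FORWARD:
                relation = graph.get_relation(schema, position.id, nxt.id)
            else:
                relation = graph.get_relation(schema, nxt.id, position.id)
            steps.append(ChainStep(relation=relation, traversal=traversal))
            path.append(nxt)
            walk(nxt, depth + 1, path, steps)
            path.pop()
            steps.pop()

    walk(start, 0, [start], [])
    if truncated:
        warnings.warn(
            f"chain enumeration truncated at {max_chains} chains", stacklevel=2
        )
    return chains


def backward_chains(
    graph: KnowledgeGraph,
    goal: Entity,
    schema_path: SchemaPath,
    max_chains: int = 10_000,
) -> list[InferenceChain]:
    """Backward chaining: chains ending at ``goal``, as forward-oriented chains.

    Exactly the reversal duality: enumerate on the reversed schema path from
    the goal, then re-reverse each chain.
    """
    if goal.id in graph.entities:
        goal = graph.entities[goal.id]
    if goal.concept is not schema_path.exit_class:
        raise SchemaViolationError(
            f"goal entity class {goal.concept.value} does not match schema path "
            f"exit class {schema_path.exit_class.value}"
        )
    reverse = enumerate_chains(graph, goal, schema_path.reversed(), max_chains=max_chains)
    return [chain.reversed() for chain in reverse]


def junction_fanout(
    graph: KnowledgeGraph,
    entity: Entity,
    schema: RelationSchema,
    traversal: str = FORWARD,
) -> int:
    """Number of chain continuations through a junction entity.

    Fan-out > 1 marks an n-to-1 / 1-to-n junction where meaningless chains
    can arise.  Always equals |neighbors(entity, schema, direction)|.
    """
    direction = FORWARD if traversal == FORWARD else INVERSE
    return len(graph.neighbors(entity, schema, direction))


# -- chains JSONL io ------------------------------------------------------

def save_chains(chains: list[InferenceChain], path: str | Path) -> None:
    lines = []
    for chain in chains:
        lines.append(
            json.dumps(
                {
                    "entity_path": list(chain.entity_ids),
                    "steps": [
                        {
                            "relation": s.relation.schema.name,
                            "subject": s.relation.subject.id,
                            "object": s.relation.object.id,
                            "traversal": s.traversal,
                            "provenance": [[d, i] for d, i in s.relation.provenance],
                        }
                        for s in chain.steps
                    ],
                    "label": chain.label,
                },
                sort_keys=True,
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def load_chains(path: str | Path, graph: KnowledgeGraph) -> list[InferenceChain]:
    """Load chains, resolving relations (and their provenance) from ``graph``."""
    chains = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        steps = [
            ChainStep(
                relation=graph.get_relation(s["relation"], s["subject"], s["object"]),
                traversal=s["traversal"],
            )
            for s in obj["steps"]
        ]
        entity_path = [graph.entities[eid] for eid in obj["entity_path"]]
        chains.append(
            InferenceChain(steps=steps, entity_path=entity_path, label=obj.get("label", UNLABELED))
        )
    return chains
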