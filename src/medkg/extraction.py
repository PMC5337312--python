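"""Seed-bootstrapped pattern mining and fact harvesting.

Patterns are lifted shortest dependency paths between two typed entity
slots: the tokens along the path with the mention head positions replaced
by ``<DOMAIN>`` and ``<RANGE>`` placeholders.  A pattern's confidence is the
fraction of its distinct entity pairs that are known seed facts
(``seed_hits / pair_count``) — a precision-style estimator of how reliably
the pattern expresses the target relation.  Harvesting bootstraps: accepted
patterns emit their entity pairs as fact candidates, which are promoted to
seeds for the next iteration; the loop stops early once an iteration yields
no new facts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import Document, mention_head, shortest_dep_path
from .errors import ConfigurationError
from .kg import Provenance, Relation, RelationSchema, TerminologyGlossary

#: entity pair (subject_id, object_id)
Pair = tuple[str, str]


class PatternConfidence(float):
    """A pattern confidence score, validated to [0, 1]."""

    def __new__(cls, value: float) -> "PatternConfidence":
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"confidence {value} outside [0, 1]")
        return super().__new__(cls, value)


@dataclass
class Pattern:
    """A lifted dependency-path pattern with its occurrence statistics."""

    schema: RelationSchema
    path_signature: tuple[str, ...]
    support: int = 0
    seed_hits: int = 0
    pairs: dict[Pair, list[Provenance]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.path_signature.count("<DOMAIN>") != 1 or self.path_signature.count("<RANGE>") != 1:
            raise ValueError("path_signature must contain <DOMAIN> and <RANGE> exactly once")

    @property
    def pair_count(self) -> int:
        return len(self.pairs)


def gather_patterns(
    documents: list[Document],
    schema: RelationSchema,
    glossary: TerminologyGlossary,
) -> list[Pattern]:
    """Extract patterns for one relation schema from a mention-annotated corpus.

    Every sentence containing a (domain-typed, range-typed) mention pair
    contributes one occurrence, keyed by the lifted shortest-path signature.
    Patterns are returned sorted by signature for determinism.
    """
    patterns: dict[tuple[str, ...], Pattern] = {}
    for doc in documents:
        for sent in doc.sentences:
            typed = [
                (m, glossary.concept_of(m[0])) for m in sent.entity_mentions
            ]
            domain_mentions = [m for m, c in typed if c is schema.domain]
            range_mentions = [m for m, c in typed if c is schema.range]
            for dm in domain_mentions:
                for rm in range_mentions:
                    if dm[1] == rm[1]:  # same span (an entity in both classes cannot occur)
                        continue
                    path = shortest_dep_path(sent, dm, rm)
                    surfaces = [sent.tokens[i].surface for i in path]
                    sig = []
                    for idx, surface in zip(path, surfaces):
                        if idx == mention_head(dm):
                            sig.append("<DOMAIN>")
                        elif idx == mention_head(rm):
                            sig.append("<RANGE>")
                        else:
                            sig.append(surface)
                    signature = tuple(sig)
                    pattern = patterns.get(signature)
                    if pattern is None:
                        pattern = Pattern(schema=schema, path_signature=signature)
                        patterns[signature] = pattern
                    pattern.support += 1
                    pattern.pairs.setdefault((dm[0], rm[0]), []).append(
                        (doc.document_id, sent.index)
                    )
    return [patterns[sig] for sig in sorted(patterns)]


def score_pattern(pattern: Pattern, seeds: set[Pair] | set) -> PatternConfidence:
    """Confidence = seed_hits / pair_count (0 when the pattern matched no pairs).

    ``seeds`` may contain (subject_id, object_id) pairs or Relation objects.
    Also stamps ``pattern.seed_hits``.
    """
    seed_pairs = {
        (s.subject.id, s.object.id) if isinstance(s, Relation) else s for s in seeds
    }
    pattern.seed_hits = sum(1 for pair in pattern.pairs if pair in seed_pairs)
    if pattern.pair_count == 0:
        return PatternConfidence(0.0)
    return PatternConfidence(pattern.seed_hits / pattern.pair_count)


@dataclass
class FactCandidate:
    """A harvested relation instance with its best supporting pattern confidence."""

    relation: Relation
    best_pattern_confidence: float
    iteration: int

    @property
    def key(self) -> tuple[str, str, str]:
        return self.relation.key


def harvest(
    documents: list[Document],
    schema: RelationSchema,
    glossary: TerminologyGlossary,
    seeds,
    confidence_threshold: float = 0.5,
    max_iterations: int = 3,
) -> list[FactCandidate]:
    """Bootstrapped fact harvesting for one relation schema.

    Per iteration: score every pattern against the current seed set, accept
    patterns with confidence >= threshold, emit every entity pair matched by
    an accepted pattern as a FactCandidate (stamped with the iteration
    number), then promote the newly harvested facts to seeds.  Stops early
    when an iteration yields no new facts.  The harvested set is monotone
    non-decreasing across iterations.
    """
    if not 0.0 < confidence_threshold <= 1.0:
        raise ConfigurationError("confidence_threshold must be in (0, 1]")
    if max_iterations < 1:
        raise ConfigurationError("max_iterations must be >= 1")
    seed_pairs = {
        (s.subject.id, s.object.id) if isinstance(s, Relation) else (s[1], s[2]) if len(s) == 3 else s
        for s in seeds
    }
    if not seed_pairs:
        raise ConfigurationError("harvest requires a non-empty seed set")

    patterns = gather_patterns(documents, schema, glossary)
    known: set[Pair] = set(seed_pairs)
    emitted: dict[Pair, FactCandidate] = {}
    for iteration in range(1, max_iterations + 1):
        accepted = []
        for pattern in patterns:
            conf = score_pattern(pattern, known)
            if conf >= confidence_threshold:
                accepted.append((pattern, float(conf)))
        new_pairs: set[Pair] = set()
        for pattern, conf in accepted:
            for pair in sorted(pattern.pairs):
                prov = pattern.pairs[pair]
                cand = emitted.get(pair)
                if cand is None:
                    subject = glossary.entity_stub(pair[0])
                    obj = glossary.entity_stub(pair[1])
                    relation = Relation(
                        schema=schema,
                        subject=subject,
                        object=obj,
                        provenance=list(prov),
                        confidence=conf,
                    )
                    emitted[pair] = FactCandidate(
                        relation=relation, best_pattern_confidence=conf, iteration=iteration
                    )
                    if pair not in known:
                        new_pairs.add(pair)
                else:
                    for p in prov:
                        if p not in cand.relation.provenance:
                            cand.relation.provenance.append(p)
                    if conf > cand.best_pattern_confidence:
                        cand.best_pattern_confidence = conf
                        cand.relation.confidence = conf
        if not new_pairs:
            break
        known |= new_pairs
    return [emitted[pair] for pair in sorted(emitted)]


@dataclass(frozen=True)
class ConsistencyConstraints:
    """Hard constraints for consistency filtering.

    ``functional_subject`` names schemas allowing at most one object per
    subject; ``functional_object`` at most one subject per object.  Exact
    duplicate triples are always deduplicated.
    """

    functional_subject: frozenset[str] = frozenset()
    functional_object: frozenset[str] = frozenset()


def consistency_filter(
    candidates: list[FactCandidate],
    constraints: ConsistencyConstraints | None = None,
) -> list[FactCandidate]:
    """Greedy weighted consistency filtering of harvested fact candidates.

    Each candidate is a soft clause weighted by its best pattern confidence;
    typing and the declared functional constraints are hard.  Candidates are
    taken in descending weight order (ties broken by triple key) and kept
    when feasible — a greedy approximation that is exact when the only
    constraints are per-key deduplication.
    """
    constraints = constraints or ConsistencyConstraints()
    order = sorted(
        candidates, key=lambda c: (-c.best_pattern_confidence, c.key)
    )
    kept: list[FactCandidate] = []
    seen_triples: set[tuple[str, str, str]] = set()
    used_subjects: set[tuple[str, str]] = set()
    used_objects: set[tuple[str, str]] = set()
    for cand in order:
        name, sid, oid = cand.key
        if cand.key in seen_triples:
            continue
        if name in constraints.functional_subject and (name, sid) in used_subjects:
            continue
        if name in constraints.functional_object and (name, oid) in used_objects:
            continue
        kept.append(cand)
        seen_triples.add(cand.key)
        used_subjects.add((name, sid))
        used_objects.add((name, oid))
    kept.sort(key=lambda c: c.key)
    return kept


def sample_for_verification(
    candidates: list[FactCandidate], k: int, seed: int
) -> list[FactCandidate]:
    """Uniform sample without replacement, reproducible under ``seed``.

    Asking for more candidates than exist returns them all with a warning.
    """
    if k > len(candidates):
        warnings.warn(
            f"requested {k} candidates but only {len(candidates)} available; returning all",
            stacklevel=2,
        )
        return list(candidates)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(idx)]


# -- facts TSV io ---------------------------------------------------------

def save_facts_tsv(candidates: list[FactCandidate], path) -> None:
    from pathlib import Path

    rows = ["relation\tsubject_id\tobject_id\tconfidence\titeration\tprovenance"]
    for cand in sorted(candidates, key=lambda c: c.key):
        prov = ";".join(f"{d}:{s}" for d, s in cand.relation.provenance)
        rows.append(
            f"{cand.key[0]}\t{cand.key[1]}\t{cand.key[2]}\t"
            f"{cand.best_pattern_confidence:.6f}\t{cand.iteration}\t{prov}"
        )
    Path(path).write_text("".join(r + "\n" for r in rows), encoding="utf-8")
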