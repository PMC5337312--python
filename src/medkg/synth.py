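"""Synthetic study-data generator.

Emits mutually consistent bundles — terminology glossary, ground-truth
knowledge graph, relation-bearing corpus, seed facts, and a labeled chain
study set — that emulate the structure the pruning problem lives on:

* four concept classes (bodily part, symptom, disease, treatment) wired by
  the three relation schemas, with n-to-1 junctions: every symptom is
  located in several bodily parts but, per symptom, only one site takes
  part in valid disease chains;
* each relation is supported by at least one template sentence with a
  head-final dependency parse, flanked by filler sentences;
* the contextual signal: for every labeled study chain, each constituent
  relation's context window co-mentions the chain's precedent/antecedent
  entity with probability ``p_signal`` (meaningful chains) or ``p_noise``
  (meaningless chains).  Meaningless chains are compositions of
  individually valid relations that cross a junction through a wrong site —
  never corrupted single relations.

A fixed demo subgraph (lung / skin / mouth / inflammation / pneumonia /
antibiotics) reproduces the classic motif — inflammation occurs in lung,
skin, or mouth, but only lung inflammation leads to pneumonia — and is
embedded in the default study set (one meaningful, two meaningless chains).

Entity names are pronounceable nonsense words, so no real medical claim is
encoded beyond the demo motif.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Document, Sentence, save_corpus
from .errors import AuditError, ConfigurationError
from .inference import (
    FORWARD,
    INVERSE,
    MEANINGFUL,
    MEANINGLESS,
    ChainStep,
    InferenceChain,
    save_chains,
)
from .kg import (
    CAUSE,
    CORRESPONDED_TO,
    LOCATED_IN,
    ConceptClass,
    Entity,
    KnowledgeGraph,
    Relation,
    TerminologyGlossary,
    export_ntriples,
    save_seed_facts,
)

# cue-token templates per schema; shortest dependency paths lift to
# (<DOMAIN>, *cue, <RANGE>) signatures under the head-final chain parse
TEMPLATES: dict[str, list[tuple[str, ...]]] = {
    "LOCATED_IN": [
        ("appears", "within"),
        ("is", "seen", "in"),
        ("arises", "at"),
        ("occurs", "inside"),
        ("localizes", "to"),
    ],
    "CAUSE": [
        ("may", "cause"),
        ("often", "causes"),
        ("leads", "to"),
        ("can", "produce"),
        ("results", "in"),
    ],
    "CORRESPONDED_TO": [
        ("is", "treated", "by"),
        ("responds", "to"),
        ("managed", "with"),
        ("is", "addressed", "by"),
        ("calls", "for"),
    ],
}

#: context/filler sentences share one carrier template; only the trailing
#: noun slot differs (a neutral filler noun, or co-mentioned entity names),
#: so no function word separates signal sentences from filler sentences
CARRIER = ("the", "record", "also", "mentions")
FILLER_NOUNS = (
    "rest", "fluids", "diet", "sleep", "exercise", "hygiene", "checkup",
    "dosage", "history", "routine", "followup", "monitoring", "recovery",
)

DEMO_PARTS = ("lung", "skin", "mouth")
DEMO_SYMPTOM = "inflammation"
DEMO_DISEASE = "pneumonia"
DEMO_TREATMENT = "antibiotics"

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"

#: seed-fact counts per schema in the reference setting
DEFAULT_SEED_COUNTS = {"LOCATED_IN": 22, "CAUSE": 22, "CORRESPONDED_TO": 20}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic bundle.

    The defaults define the reference study set: a 200-chain balanced
    labeled set (100 meaningful / 100 meaningless 3-relation chains) with
    co-mention probabilities 0.95 (signal) and 0.05 (noise), context
    windows compatible with a pruning context range of 3.
    """

    n_bodily_parts: int = 10
    n_symptoms: int = 42
    n_diseases: int = 20
    n_treatments: int = 20
    fanout_located_in: int = 3
    causes_per_symptom: int = 5
    templates_per_schema: int = 3
    p_signal: float = 0.95
    p_noise: float = 0.05
    n_meaningful_chains: int = 100
    n_meaningless_chains: int = 100
    context_pad_sentences: int = 4
    signal_window: int = 3
    support_sentences_per_relation: int = 1
    seed_counts: dict = field(default_factory=lambda: dict(DEFAULT_SEED_COUNTS))
    include_demo: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_noise <= self.p_signal <= 1.0):
            raise ConfigurationError("need 0 <= p_noise <= p_signal <= 1")
        if self.fanout_located_in < 1:
            raise ConfigurationError("fanout_located_in must be >= 1")
        if self.fanout_located_in > self.n_bodily_parts:
            raise ConfigurationError("fanout_located_in exceeds n_bodily_parts")
        if self.n_meaningless_chains > 0 and self.fanout_located_in < 2:
            raise ConfigurationError(
                "meaningless chains need junctions: fanout_located_in >= 2"
            )
        if self.causes_per_symptom > self.n_diseases:
            raise ConfigurationError("causes_per_symptom exceeds n_diseases")
        max_templates = min(len(t) for t in TEMPLATES.values())
        if not 1 <= self.templates_per_schema <= max_templates:
            raise ConfigurationError(f"templates_per_schema must be in [1, {max_templates}]")
        if self.signal_window < 1 or self.signal_window > self.context_pad_sentences:
            raise ConfigurationError("need 1 <= signal_window <= context_pad_sentences")
        if self.support_sentences_per_relation < 1:
            raise ConfigurationError("support_sentences_per_relation must be >= 1")
        if self.include_demo and (
            self.n_bodily_parts < 3
            or self.n_symptoms < 1
            or self.n_diseases < 1
            or self.n_treatments < 1
        ):
            raise ConfigurationError("demo subgraph needs >= 3 parts and >= 1 of each other class")
        pairs_needed = (
            self.n_meaningful_chains
            + self.n_meaningless_chains
            + (1 if self.include_demo else 0)
        )
        if self.n_symptoms * self.causes_per_symptom < pairs_needed:
            raise ConfigurationError(
                f"need {pairs_needed} distinct (symptom, disease) pairs but only "
                f"{self.n_symptoms * self.causes_per_symptom} are available; "
                "increase n_symptoms or causes_per_symptom"
            )


@dataclass
class Bundle:
    """A generated study bundle; every piece is mutually consistent.

    ``chains`` is the labeled study set; ``demo_chains`` holds the fixed
    lung/skin/mouth motif chains as a held-out illustration set (labeled by
    ground truth, not part of the study counts).
    """

    config: GeneratorConfig
    glossary: TerminologyGlossary
    graph: KnowledgeGraph
    documents: list[Document]
    seed_facts: list[tuple[str, str, str]]
    chains: list[InferenceChain]
    demo_chains: list[InferenceChain] = field(default_factory=list)


def _make_names(rng: np.random.Generator, count: int, reserved: set[str]) -> list[str]:
    names = []
    while len(names) < count:
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(3)
        )
        if word not in reserved:
            reserved.add(word)
            names.append(word)
    return names


def generate(config: GeneratorConfig | None = None) -> Bundle:
    """Generate a bundle under ``config`` (defaults define the reference set)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    reserved: set[str] = set(FILLER_NOUNS) | set(CARRIER)
    for templates in TEMPLATES.values():
        for t in templates:
            reserved.update(t)
    reserved.update(DEMO_PARTS)
    reserved.update((DEMO_SYMPTOM, DEMO_DISEASE, DEMO_TREATMENT))

    if config.include_demo:
        parts = list(DEMO_PARTS) + _make_names(rng, config.n_bodily_parts - 3, reserved)
        symptoms = [DEMO_SYMPTOM] + _make_names(rng, config.n_symptoms - 1, reserved)
        diseases = [DEMO_DISEASE] + _make_names(rng, config.n_diseases - 1, reserved)
        treatments = [DEMO_TREATMENT] + _make_names(rng, config.n_treatments - 1, reserved)
    else:
        parts = _make_names(rng, config.n_bodily_parts, reserved)
        symptoms = _make_names(rng, config.n_symptoms, reserved)
        diseases = _make_names(rng, config.n_diseases, reserved)
        treatments = _make_names(rng, config.n_treatments, reserved)

    graph = KnowledgeGraph()
    for name, concept in (
        *((p, ConceptClass.BODILY_PART) for p in parts),
        *((s, ConceptClass.SYMPTOM) for s in symptoms),
        *((d, ConceptClass.DISEASE) for d in diseases),
        *((t, ConceptClass.TREATMENT) for t in treatments),
    ):
        graph.add_entity(Entity.from_name(name, concept))
    glossary = TerminologyGlossary.from_graph(graph)
    ent = graph.entities  # ids equal names (single-token lowercase)

    # -- ground-truth wiring ---------------------------------------------
    sites: dict[str, list[str]] = {}
    true_site: dict[str, str] = {}
    for s in symptoms:
        if config.include_demo and s == DEMO_SYMPTOM:
            chosen = list(DEMO_PARTS)  # the 3-way junction motif
            if config.fanout_located_in > 3:
                extra = [p for p in parts if p not in DEMO_PARTS]
                chosen += list(rng.choice(extra, config.fanout_located_in - 3, replace=False))
            sites[s] = chosen
            true_site[s] = DEMO_PARTS[0]  # lung
        else:
            chosen = list(rng.choice(parts, config.fanout_located_in, replace=False))
            sites[s] = chosen
            true_site[s] = chosen[int(rng.integers(len(chosen)))]

    cause_pairs: list[tuple[str, str]] = []
    for s in symptoms:
        chosen = list(rng.choice(diseases, config.causes_per_symptom, replace=False))
        if config.include_demo and s == DEMO_SYMPTOM and DEMO_DISEASE not in chosen:
            chosen[0] = DEMO_DISEASE
        cause_pairs.extend((s, d) for d in sorted(chosen))

    treatment_of = {d: treatments[i % len(treatments)] for i, d in enumerate(diseases)}

    for s in symptoms:
        for b in sorted(sites[s]):
            graph.add_relation(Relation(LOCATED_IN, ent[s], ent[b]))
    for s, d in cause_pairs:
        graph.add_relation(Relation(CAUSE, ent[s], ent[d]))
    for d in diseases:
        graph.add_relation(Relation(CORRESPONDED_TO, ent[d], ent[treatment_of[d]]))

    # -- study-chain selection -------------------------------------------
    # the study set uses disjoint (symptom, disease) pairs so each middle
    # relation's context planting is determined by exactly one study chain;
    # the demo motif chains are kept out of the study counts (held-out set).
    # pairs are assigned to the two classes alternately *within* each
    # symptom junction, so entity identity carries no label information —
    # each junction contributes both valid and invalid compositions, as in
    # the motivating motif
    demo_pair = (DEMO_SYMPTOM, DEMO_DISEASE)
    pos_stream: list[tuple[str, str]] = []
    neg_stream: list[tuple[str, str]] = []
    for s in symptoms:
        pairs_s = [p for p in cause_pairs if p[0] == s and not (config.include_demo and p == demo_pair)]
        order = rng.permutation(len(pairs_s))
        start_pos = len(pos_stream) <= len(neg_stream)
        for j, idx in enumerate(order):
            (pos_stream if (j % 2 == 0) == start_pos else neg_stream).append(pairs_s[idx])
    if len(pos_stream) < config.n_meaningful_chains or len(neg_stream) < config.n_meaningless_chains:
        raise ConfigurationError(
            "not enough (symptom, disease) pairs per class; increase n_symptoms "
            "or causes_per_symptom"
        )
    pos_pairs = pos_stream[: config.n_meaningful_chains]
    neg_pairs = neg_stream[: config.n_meaningless_chains]

    chain_specs: list[tuple[str, str, str, str, str]] = []  # (b, s, d, t, label)
    for s, d in pos_pairs:
        chain_specs.append((true_site[s], s, d, treatment_of[d], MEANINGFUL))
    for s, d in neg_pairs:
        decoys = sorted(b for b in sites[s] if b != true_site[s])
        decoy = decoys[int(rng.integers(len(decoys)))]
        chain_specs.append((decoy, s, d, treatment_of[d], MEANINGLESS))

    demo_specs: list[tuple[str, str, str, str, str]] = []
    if config.include_demo:
        demo_specs.append(
            (DEMO_PARTS[0], DEMO_SYMPTOM, DEMO_DISEASE, DEMO_TREATMENT, MEANINGFUL)
        )
        for decoy in DEMO_PARTS[1:]:
            demo_specs.append(
                (decoy, DEMO_SYMPTOM, DEMO_DISEASE, DEMO_TREATMENT, MEANINGLESS)
            )

    # -- contextual co-mention coins -------------------------------------
    # plants[(relation key)][(side, distance)] -> entity names to co-mention
    plants: dict[tuple[str, str, str], dict[tuple[str, int], set[str]]] = {}

    def plant(rel_key, side: str, name: str) -> None:
        dist = int(rng.integers(1, config.signal_window + 1))
        plants.setdefault(rel_key, {}).setdefault((side, dist), set()).add(name)

    for b, s, d, t, label in chain_specs + demo_specs:
        p = config.p_signal if label == MEANINGFUL else config.p_noise
        path = (b, s, d, t)
        rel_keys = (
            ("LOCATED_IN", s, b),
            ("CAUSE", s, d),
            ("CORRESPONDED_TO", d, t),
        )
        for i, rel_key in enumerate(rel_keys):
            if i > 0 and rng.random() < p:  # precedent entity, preceding context
                plant(rel_key, "before", path[i - 1])
            if i + 2 < len(path) and rng.random() < p:  # antecedent entity, following context
                plant(rel_key, "after", path[i + 2])

    # -- corpus -----------------------------------------------------------
    pad = config.context_pad_sentences
    documents: list[Document] = []
    template_counter: dict[str, int] = {name: 0 for name in TEMPLATES}

    def filler_tokens(pos: int) -> list[str]:
        # deterministic by sentence position: filler columns are constant
        # across chains, so contextual variance comes only from co-mentions
        return list(CARRIER) + [FILLER_NOUNS[pos % len(FILLER_NOUNS)]]

    for rel in sorted(graph.relations, key=lambda r: r.key):
        schema_name = rel.schema.name
        for copy in range(config.support_sentences_per_relation):
            doc_id = f"d{len(documents):05d}"
            t_idx = template_counter[schema_name] % config.templates_per_schema
            template_counter[schema_name] += 1
            rel_plants = plants.get(rel.key, {}) if copy == 0 else {}
            sentences = []
            for pos in range(2 * pad + 1):
                if pos == pad:
                    cue = TEMPLATES[schema_name][t_idx]
                    surfaces = [rel.subject.id, *cue, rel.object.id]
                    sent = Sentence.from_surfaces(pos, surfaces)
                    sent.tokens[0].pos = "NN"
                    sent.tokens[-1].pos = "NN"
                    sent.entity_mentions = [
                        (rel.subject.id, 0, 1),
                        (rel.object.id, len(surfaces) - 1, len(surfaces)),
                    ]
                else:
                    side = "before" if pos < pad else "after"
                    dist = pad - pos if pos < pad else pos - pad
                    names = sorted(rel_plants.get((side, dist), ()))
                    if names:
                        surfaces = list(CARRIER) + names
                        sent = Sentence.from_surfaces(pos, surfaces)
                        base = len(CARRIER)
                        for j, name in enumerate(names):
                            sent.tokens[base + j].pos = "NN"
                        sent.entity_mentions = [
                            (name, base + j, base + j + 1) for j, name in enumerate(names)
                        ]
                    else:
                        sent = Sentence.from_surfaces(pos, filler_tokens(pos))
                sentences.append(sent)
            rel.provenance.append((doc_id, pad))
            documents.append(Document(document_id=doc_id, sentences=sentences))

    # -- seed facts --------------------------------------------------------
    seed_facts: list[tuple[str, str, str]] = []
    for schema_name in sorted(TEMPLATES):
        rels = sorted(
            (r for r in graph.relations if r.schema.name == schema_name), key=lambda r: r.key
        )
        want = min(config.seed_counts.get(schema_name, 0), len(rels))
        idx = rng.choice(len(rels), size=want, replace=False)
        seed_facts.extend(rels[i].key for i in sorted(idx))

    # -- labeled chains ----------------------------------------------------
    def build_chain(spec: tuple[str, str, str, str, str]) -> InferenceChain:
        b, s, d, t, label = spec
        steps = [
            ChainStep(graph.get_relation("LOCATED_IN", s, b), INVERSE),
            ChainStep(graph.get_relation("CAUSE", s, d), FORWARD),
            ChainStep(graph.get_relation("CORRESPONDED_TO", d, t), FORWARD),
        ]
        return InferenceChain(
            steps=steps, entity_path=[ent[b], ent[s], ent[d], ent[t]], label=label
        )

    return Bundle(
        config=config,
        glossary=glossary,
        graph=graph,
        documents=documents,
        seed_facts=seed_facts,
        chains=[build_chain(spec) for spec in chain_specs],
        demo_chains=[build_chain(spec) for spec in demo_specs],
    )


def write_bundle(bundle: Bundle, out_dir: str | Path) -> None:
    """Write every bundle artifact in the documented text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.glossary.save_tsv(out / "glossary.tsv")
    export_ntriples(bundle.graph, out / "graph.nt")
    save_corpus(bundle.documents, out / "corpus.json")
    seeds = [
        bundle.graph.get_relation(*key) for key in bundle.seed_facts
    ]
    save_seed_facts(seeds, out / "seeds.tsv")
    save_chains(bundle.chains, out / "chains.jsonl")
    if bundle.demo_chains:
        save_chains(bundle.demo_chains, out / "demo_chains.jsonl")
    cfg = dataclasses.asdict(bundle.config)
    (out / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True), encoding="utf-8")


def _window_tokens(
    bundle: Bundle, rel: Relation, side: str, doc_by_id: dict[str, Document] | None = None
) -> set[str]:
    if doc_by_id is None:
        doc_by_id = {d.document_id: d for d in bundle.documents}
    w = bundle.config.signal_window
    tokens: set[str] = set()
    for doc_id, s_idx in rel.provenance:
        doc = doc_by_id[doc_id]
        lo, hi = (s_idx - w, s_idx - 1) if side == "before" else (s_idx + 1, s_idx + w)
        for i in range(max(0, lo), min(len(doc.sentences), hi + 1)):
            tokens.update(t.surface for t in doc.sentences[i].tokens)
    return tokens


def audit(bundle: Bundle) -> dict:
    """Verify the bundle's invariants; raises AuditError naming a violation.

    Checks glossary coverage, the junction motif, provenance, class counts,
    chain/graph consistency, and the empirical co-mention rates at the two
    coin sites that identify their chain uniquely (the middle relation's
    preceding window and the first relation's following window), which must
    lie within 3 sigma of p_signal / p_noise (exact for probabilities 0/1).
    """
    config = bundle.config
    for eid in bundle.graph.entities:
        if not bundle.glossary.lookup(eid.replace("_", " ")):
            raise AuditError(f"glossary does not cover entity {eid!r}")
    n_pos = sum(1 for c in bundle.chains if c.label == MEANINGFUL)
    n_neg = sum(1 for c in bundle.chains if c.label == MEANINGLESS)
    if n_pos != config.n_meaningful_chains or n_neg != config.n_meaningless_chains:
        raise AuditError(
            f"class counts {n_pos}/{n_neg} differ from configured "
            f"{config.n_meaningful_chains}/{config.n_meaningless_chains}"
        )
    has_junction = any(
        len(bundle.graph.neighbors(e, LOCATED_IN, "forward")) >= 3
        for e in bundle.graph.entities.values()
        if e.concept is ConceptClass.SYMPTOM
    )
    if not has_junction:
        raise AuditError("no LOCATED_IN junction with fan-out >= 3")
    for rel in bundle.graph.relations:
        if not rel.provenance:
            raise AuditError(f"relation {rel.key} has no supporting sentence")
    for chain in bundle.chains:
        for step in chain.steps:
            try:
                bundle.graph.get_relation(*step.relation.key)
            except KeyError:
                raise AuditError(f"chain uses relation {step.relation.key} missing from graph")

    doc_by_id = {d.document_id: d for d in bundle.documents}
    rates = {}
    for label, p in ((MEANINGFUL, config.p_signal), (MEANINGLESS, config.p_noise)):
        hits = trials = 0
        for chain in bundle.chains:
            if chain.label != label:
                continue
            b, s, d = (e.id for e in chain.entity_path[:3])
            # middle relation, preceding window: the precedent entity b
            if b in _window_tokens(bundle, chain.steps[1].relation, "before", doc_by_id):
                hits += 1
            # first relation, following window: the antecedent entity d
            if d in _window_tokens(bundle, chain.steps[0].relation, "after", doc_by_id):
                hits += 1
            trials += 2
        if trials == 0:
            continue
        rate = hits / trials
        rates[label] = rate
        if p in (0.0, 1.0):
            if rate != p:
                raise AuditError(f"{label} co-mention rate {rate:.3f} != exact {p}")
        else:
            tol = 3.0 * float(np.sqrt(p * (1 - p) / trials))
            if abs(rate - p) > tol:
                raise AuditError(
                    f"{label} co-mention rate {rate:.3f} outside {p} +/- {tol:.3f}"
                )
    return {
        "n_entities": len(bundle.graph.entities),
        "n_relations": len(bundle.graph),
        "n_documents": len(bundle.documents),
        "n_meaningful": n_pos,
        "n_meaningless": n_neg,
        "co_mention_rates": rates,
    }
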