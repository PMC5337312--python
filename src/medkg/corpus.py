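"""Corpus data model and dictionary-based entity recognition.

Documents are ordered lists of sentences; each sentence carries tokens
(surface + part-of-speech), a single-rooted dependency tree over token
indices, and entity mentions as half-open token spans resolved against a
terminology glossary.  Tokenization and parsing are performed upstream (by
the synthetic generator or an external preprocessor); this module consumes
pre-tokenized text, which keeps the pipeline language-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import CorpusFormatError, ParseError
from .kg import TerminologyGlossary


@dataclass
class Token:
    index: int
    surface: str
    pos: str = "XX"


#: dependency edge: (head_index, dependent_index, label)
DepEdge = tuple[int, int, str]
#: entity mention: (entity_id, start_token, end_token) half-open
Mention = tuple[str, int, int]


@dataclass
class Sentence:
    index: int
    tokens: list[Token]
    dep_edges: set[DepEdge] = field(default_factory=set)
    entity_mentions: list[Mention] = field(default_factory=list)

    @classmethod
    def from_surfaces(
        cls,
        index: int,
        surfaces: list[str],
        pos: list[str] | None = None,
        dep_edges: set[DepEdge] | None = None,
    ) -> "Sentence":
        """Build a sentence; defaults to a head-final chain parse."""
        tokens = [
            Token(i, s, pos[i] if pos else "XX") for i, s in enumerate(surfaces)
        ]
        if dep_edges is None:
            dep_edges = {(i + 1, i, "dep") for i in range(len(surfaces) - 1)}
        return cls(index=index, tokens=tokens, dep_edges=set(dep_edges))

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def validate(self, where: str = "") -> None:
        n = len(self.tokens)
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise CorpusFormatError(f"{where}: token indices not contiguous from 0")
        if n == 0:
            if self.dep_edges:
                raise CorpusFormatError(f"{where}: dependency edges on empty sentence")
        else:
            heads: dict[int, int] = {}
            for head, dep, _ in self.dep_edges:
                if not (0 <= head < n and 0 <= dep < n):
                    raise CorpusFormatError(f"{where}: dependency edge out of bounds")
                if dep in heads:
                    raise CorpusFormatError(f"{where}: token {dep} has two heads")
                heads[dep] = head
            roots = [i for i in range(n) if i not in heads]
            if len(roots) != 1:
                raise CorpusFormatError(
                    f"{where}: dependency graph must have exactly one root, found {len(roots)}"
                )
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from((h, d) for h, d, _ in self.dep_edges)
            if len(self.dep_edges) != n - 1 or not nx.is_connected(g):
                raise CorpusFormatError(f"{where}: dependency edges do not form a tree")
        last_end = 0
        for eid, start, end in sorted(self.entity_mentions, key=lambda m: m[1]):
            if not (0 <= start < end <= n):
                raise CorpusFormatError(f"{where}: mention span [{start},{end}) out of bounds")
            if start < last_end:
                raise CorpusFormatError(f"{where}: overlapping entity mentions")
            last_end = end


@dataclass
class Document:
    document_id: str
    sentences: list[Sentence]

    def validate(self) -> None:
        for i, sent in enumerate(self.sentences):
            if sent.index != i:
                raise CorpusFormatError(
                    f"document {self.document_id!r}: sentence indices not contiguous from 0"
                )
            sent.validate(where=f"document {self.document_id!r}, sentence {i}")


def recognize_entities(sentence: Sentence, glossary: TerminologyGlossary) -> Sentence:
    """Populate entity mentions by greedy longest-match dictionary matching.

    Scans left to right over token n-grams (longest first); spans never
    overlap.  Equal-length candidates at the same start position are broken
    by the lexicographically smallest entity id.  Returns a new Sentence.
    """
    surfaces = [t.surface for t in sentence.tokens]
    max_len = min(glossary.max_term_tokens, len(surfaces))
    mentions: list[Mention] = []
    i = 0
    while i < len(surfaces):
        matched = False
        for length in range(max_len, 0, -1):
            if i + length > len(surfaces):
                continue
            ids = glossary.lookup(" ".join(surfaces[i : i + length]))
            if ids:
                mentions.append((ids[0], i, i + length))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return Sentence(
        index=sentence.index,
        tokens=list(sentence.tokens),
        dep_edges=set(sentence.dep_edges),
        entity_mentions=mentions,
    )


def mention_head(mention: Mention) -> int:
    """Head token of a mention span: the last token (head-final convention)."""
    return mention[2] - 1


def shortest_dep_path(sentence: Sentence, mention_a: Mention, mention_b: Mention) -> list[int]:
    """Unique undirected shortest path between two mention heads in the parse tree.

    Endpoints included; in a tree the shortest path is unique, so
    ``shortest_dep_path(a, b) == list(reversed(shortest_dep_path(b, a)))``.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(sentence.tokens)))
    g.add_edges_from((h, d) for h, d, _ in sentence.dep_edges)
    try:
        return nx.shortest_path(g, mention_head(mention_a), mention_head(mention_b))
    except nx.NetworkXNoPath as exc:
        raise ParseError(
            f"sentence {sentence.index}: mentions lie in disconnected parse components"
        ) from exc


# -- JSON corpus io -------------------------------------------------------

def _sentence_to_json(sent: Sentence) -> dict:
    return {
        "tokens": [{"surface": t.surface, "pos": t.pos} for t in sent.tokens],
        "dep_edges": sorted([h, d, lab] for h, d, lab in sent.dep_edges),
        "entity_mentions": [[eid, s, e] for eid, s, e in sent.entity_mentions],
    }


def save_corpus(documents: list[Document], path: str | Path) -> None:
    payload = {
        "documents": [
            {
                "document_id": doc.document_id,
                "sentences": [_sentence_to_json(s) for s in doc.sentences],
            }
            for doc in documents
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def load_corpus(path: str | Path) -> list[Document]:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(payload, dict) or "documents" not in payload:
        raise CorpusFormatError(f"{path}: missing top-level 'documents' key")
    documents = []
    for d in payload["documents"]:
        sentences = []
        for i, s in enumerate(d.get("sentences", [])):
            sentences.append(
                Sentence(
                    index=i,
                    tokens=[
                        Token(j, t["surface"], t.get("pos", "XX"))
                        for j, t in enumerate(s.get("tokens", []))
                    ],
                    dep_edges={(h, dep, lab) for h, dep, lab in s.get("dep_edges", [])},
                    entity_mentions=[
                        (eid, start, end) for eid, start, end in s.get("entity_mentions", [])
                    ],
                )
            )
        doc = Document(document_id=d["document_id"], sentences=sentences)
        doc.validate()
        documents.append(doc)
    return documents


def corpus_index(documents: list[Document]) -> dict[str, Document]:
    """document_id -> Document map."""
    return {d.document_id: d for d in documents}
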