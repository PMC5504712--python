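"""Typed directed graph over term codes: synonymy, generalization, classing.

The network supplies the context the matcher leans on: ``synonym-of`` edges
collapse codes that mean the same thing; the hierarchical edge types
(``is-a``, ``is-part-of``, ``is-class-of``, ``is-element-of``) support
broadening a query term to coarser concepts (finger -> hand). The
hierarchical subgraph must be acyclic so generalization terminates.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

import networkx as nx

from .knowledge_model import normalize_label

if TYPE_CHECKING:  # pragma: no cover
    from .knowledge_model import KnowledgeBase

__all__ = [
    "EDGE_TYPES",
    "HIERARCHICAL_TYPES",
    "GENERALIZE_TYPES",
    "SemanticEdge",
    "SemanticNet",
    "resolve_term",
    "generalize",
    "check_acyclic",
    "read_edges_tsv",
    "write_edges_tsv",
]

EDGE_TYPES = (
    "is-a",
    "is-part-of",
    "has-attribute-of",
    "is-class-of",
    "synonym-of",
    "is-element-of",
    "has-element",
    "has-variant",
)

#: Edge types whose subgraph must stay acyclic.
HIERARCHICAL_TYPES = frozenset({"is-a", "is-part-of", "is-class-of", "is-element-of"})

#: Edge types followed when broadening a query term. ``has-attribute-of`` is
#: deliberately excluded: it changes meaning, not granularity.
GENERALIZE_TYPES = frozenset({"is-a", "is-part-of", "is-class-of"})


@dataclass(frozen=True)
class SemanticEdge:
    source: str
    edge_type: str
    target: str


class UnknownNodeError(KeyError):
    pass


@dataclass
class SemanticNet:
    """Node set + typed edge list, with cached views for queries.

    ``synonym-of`` is stored once per pair but treated as symmetric.
    """

    nodes: set[str] = field(default_factory=set)
    edges: list[SemanticEdge] = field(default_factory=list)

    def __eq__(self, other):
        if not isinstance(other, SemanticNet):
            return NotImplemented
        return self.nodes == other.nodes and set(self.edges) == set(other.edges)

    def add_edge(self, source: str, edge_type: str, target: str) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {edge_type!r}")
        self.nodes.update((source, target))
        self.edges.append(SemanticEdge(source, edge_type, target))

    def graph(self, types: Optional[Iterable[str]] = None) -> nx.DiGraph:
        """Directed graph restricted to ``types`` (all types by default)."""
        wanted = set(types) if types is not None else set(EDGE_TYPES)
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if e.edge_type in wanted:
                g.add_edge(e.source, e.target, edge_type=e.edge_type)
        return g

    def synonym_class(self, code: str) -> frozenset[str]:
        """All codes synonymous with ``code`` (including itself)."""
        comp = self._synonym_components().get(code)
        return comp if comp is not None else frozenset({code})

    def same_meaning(self, a: str, b: str) -> bool:
        return a == b or b in self.synonym_class(a)

    def _synonym_components(self) -> dict[str, frozenset[str]]:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if e.edge_type == "synonym-of":
                g.add_edge(e.source, e.target)
        out: dict[str, frozenset[str]] = {}
        for comp in nx.connected_components(g):
            fs = frozenset(comp)
            for node in comp:
                out[node] = fs
        return out


def check_acyclic(net: SemanticNet) -> list[list[str]]:
    """Directed cycles in the hierarchical subgraph; empty iff valid.

    Synonym and tree-mirror edges (``has-element``, ``has-variant``) are
    exempt: only the four generalizing/classing types must form a DAG.
    """
    g = net.graph(HIERARCHICAL_TYPES)
    return [list(c) for c in nx.simple_cycles(g)]


def generalize(term: str, net: SemanticNet, max_steps: int) -> list[str]:
    """Broader concepts reachable from ``term`` within ``max_steps`` hops.

    Breadth-first over outgoing is-a / is-part-of / is-class-of edges; the
    start term itself is excluded. Order: increasing distance, ties by
    term code.
    """
    if term not in net.nodes:
        raise UnknownNodeError(term)
    if max_steps < 1:
        raise ValueError("max_steps must be positive")
    g = net.graph(GENERALIZE_TYPES)
    out: list[str] = []
    seen = {term}
    frontier = [term]
    for _ in range(max_steps):
        nxt = sorted({s for f in frontier for s in g.successors(f)} - seen)
        if not nxt:
            break
        out.extend(nxt)
        seen.update(nxt)
        frontier = nxt
    return out


def _label_index(kb: "KnowledgeBase", language: Optional[str]) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for code, term in kb.lexicon.items():
        for lang, surface in term.labels:
            if language is not None and lang != language:
                continue
            index.setdefault(normalize_label(surface), set()).add(code)
    return index


def resolve_term(
    surface: str,
    kb: "KnowledgeBase",
    language: Optional[str] = None,
    fuzzy_threshold: float = 0.8,
    max_fuzzy: int = 5,
) -> list[tuple[str, str]]:
    """Map a surface string to term codes.

    Returns ``(term_code, match_kind)`` pairs, ``match_kind`` one of
    ``exact-label`` (the string is a label of that term, up to case and
    diacritics), ``synonym`` (a synonym-linked term carries the label), or
    ``fuzzy-suggestion``. Fuzzy suggestions (normalized similarity >=
    ``fuzzy_threshold``, at most ``max_fuzzy``) are produced only when no
    exact or synonym match exists. Total: any input yields a (possibly
    empty) list.
    """
    if not surface:
        return []
    key = normalize_label(surface)
    index = _label_index(kb, language)
    exact = sorted(index.get(key, ()))
    results: list[tuple[str, str]] = [(c, "exact-label") for c in exact]
    seen = set(exact)
    for code in exact:
        for syn in sorted(kb.net.synonym_class(code) - {code}):
            if syn not in seen and syn in kb.lexicon:
                results.append((syn, "synonym"))
                seen.add(syn)
    if results:
        return results
    # fuzzy fallback over all languages
    scored: dict[str, float] = {}
    for code, term in kb.lexicon.items():
        for _, lab in term.labels:
            ratio = difflib.SequenceMatcher(None, key, normalize_label(lab)).ratio()
            if ratio >= fuzzy_threshold and ratio > scored.get(code, 0.0):
                scored[code] = ratio
    ranked = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))[:max_fuzzy]
    return [(code, "fuzzy-suggestion") for code, _ in ranked]


def read_edges_tsv(text: str) -> list[SemanticEdge]:
    """Parse an edge list in ``source<TAB>edge_type<TAB>target`` form."""
    edges = []
    rows = list(csv.reader(text.splitlines(), delimiter="\t"))
    start = 1 if rows and rows[0][:2] == ["source", "edge_type"] else 0
    for src, etype, tgt in rows[start:]:
        if etype not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {etype!r}")
        edges.append(SemanticEdge(src, etype, tgt))
    return edges


def write_edges_tsv(edges: Iterable[SemanticEdge]) -> str:
    lines = ["source\tedge_type\ttarget"]
    for e in sorted(edges, key=lambda e: (e.source, e.edge_type, e.target)):
        lines.append(f"{e.source}\t{e.edge_type}\t{e.target}")
    return "\n".join(lines) + "\n"
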