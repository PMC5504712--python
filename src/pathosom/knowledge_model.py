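"""Core domain model for prototypic-disease knowledge bases.

A *pathosom* is a prototypic disease: a vector of *pathophems*, each an
atomistic (stem-word) medical term carrying up to three attributes and an
occurrence grade. Grades are ordinal frequency symbols mapped onto
probability intervals; the special grade ``NOT`` marks a finding that
excludes the disease. Pathosoms sit in a subset tree (is-element-of /
has-element / has-variant) and cross-reference external thesauri such as
ICD-10-GM or OMIM.

This module defines the data types, the grade -> probability-interval
mapping, and whole-KB validation. Validation deliberately happens *after*
construction (``validate_kb`` returns issue records rather than raising),
so that malformed knowledge bases can be loaded, inspected and repaired.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING, Iterable, Optional, Union

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .semantic_network import SemanticNet

__all__ = [
    "THESAURI",
    "GRADE_SYMBOLS",
    "EXCLUDED",
    "ThesaurusRef",
    "ClassCode",
    "AtomisticTerm",
    "Attribute",
    "OccurrenceGrade",
    "Pathophem",
    "Pathosom",
    "KnowledgeBase",
    "ValidationIssue",
    "class_table",
    "lookup_class",
    "grade_interval",
    "grade_weight",
    "grade_for_probability",
    "validate_kb",
    "normalize_label",
]

#: Thesaurus acronyms accepted in cross-references.
THESAURI = (
    "ICD-10-GM",
    "ICD-O",
    "ORPHANET",
    "OPS",
    "LOINC",
    "OMIM",
    "TA",
    "CAS",
    "EC",
    "HGNC",
    "ATC",
)

#: Internal term-code shape: optional uppercase letter, digits, optional
#: single-letter flag (with or without a separating space). Covers codes
#: like M3094, O812, 10209, "10221 T" and 10787Z.
TERM_CODE_RE = re.compile(r"^[A-Z]?[0-9]+(?: ?[A-Z])?$")

LANGUAGES = ("de", "en", "la")

#: Marker returned by :func:`grade_interval` for the excluding grade.
EXCLUDED = "EXCLUDED"

# (lower, upper, upper_closed). Bounds reproduce the published mapping
# verbatim, gaps included (e.g. nothing between 0.09 and 0.1): Lead = always
# present (probability 1), "+++" 0.5-0.99, "++" 0.1-0.49, "+" 0.01-0.09,
# "(+)" below 0.01 (0 included).
_GRADE_INTERVALS = {
    "Lead": (1.0, 1.0, True),
    "+++": (0.5, 0.99, True),
    "++": (0.1, 0.49, True),
    "+": (0.01, 0.09, True),
    "(+)": (0.0, 0.01, False),
}

GRADE_SYMBOLS = ("Lead", "+++", "++", "+", "(+)", "NOT")


class InvalidGradeError(ValueError):
    """Raised for a grade symbol outside the six-symbol vocabulary."""


def grade_interval(symbol: str) -> Union[tuple[float, float, bool], str]:
    """Probability interval for a grade symbol.

    Returns ``(lower, upper, upper_closed)``; ``NOT`` returns the
    :data:`EXCLUDED` marker instead of an interval.
    """
    if symbol == "NOT":
        return EXCLUDED
    try:
        return _GRADE_INTERVALS[symbol]
    except KeyError:
        raise InvalidGradeError(f"unknown occurrence grade {symbol!r}") from None


def grade_weight(symbol: str) -> float:
    """Scalar weight of a non-excluding grade: the interval midpoint."""
    if symbol == "NOT":
        raise InvalidGradeError(
            "grade 'NOT' carries no weight; exclusion is handled separately"
        )
    lo, hi, _ = grade_interval(symbol)
    return (lo + hi) / 2.0


def grade_for_probability(p: float) -> Optional[str]:
    """Grade symbol whose interval contains ``p``, or None if ``p`` falls in
    one of the printed gaps between intervals (e.g. 0.095) or outside [0, 1].
    """
    for sym, (lo, hi, closed) in _GRADE_INTERVALS.items():
        if lo <= p and (p <= hi if closed else p < hi):
            return sym
    return None


@dataclass(frozen=True)
class ThesaurusRef:
    """Cross-reference into an external coding system, e.g. ICD-10-GM D46.2."""

    thesaurus: str
    code: str


@dataclass(frozen=True)
class ClassCode:
    """Semantic class of a term/pathophem, keyed by the packaged taxonomy."""

    code: int
    class_path: tuple[str, str, str] = ("", "", "")


@dataclass(frozen=True)
class Attribute:
    """One attribute of a term: cardinal (category), ordinal or numeric.

    ``value`` by kind:

    * cardinal -- a category string (``"firm"``)
    * ordinal  -- ``{"level": str, "scale": [lowest, ..., highest]}``
    * numeric  -- ``{"value": x, "unit": u}`` or a half-open interval
      ``{"lo": a, "hi": b, "unit": u}``
    """

    kind: str
    name: str
    value: object

    def canonical_value(self) -> object:
        v = self.value
        if isinstance(v, dict):
            return tuple(sorted((k, tuple(x) if isinstance(x, list) else x) for k, x in v.items()))
        return v


@dataclass(frozen=True)
class AtomisticTerm:
    """A stem-word concept: internal code, multilingual labels, class, xrefs."""

    term_code: str
    labels: tuple[tuple[str, str], ...]  # (language, surface)
    class_code: ClassCode
    xrefs: tuple[ThesaurusRef, ...] = ()


@dataclass(frozen=True)
class OccurrenceGrade:
    """A grade symbol together with its interval (or the exclusion marker)."""

    symbol: str

    @property
    def interval(self):
        return grade_interval(self.symbol)

    @property
    def excludes(self) -> bool:
        return self.symbol == "NOT"


@dataclass(frozen=True)
class Pathophem:
    """One attributed finding inside a disease prototype.

    ``probability`` optionally stores an explicit occurrence probability; when
    present it takes precedence over the grade midpoint for weighting.
    """

    subject: str
    attributes: tuple[Attribute, ...]
    grade: str
    class_code: ClassCode
    probability: Optional[float] = None

    def weight(self) -> float:
        if self.probability is not None:
            return self.probability
        return grade_weight(self.grade)


@dataclass
class Pathosom:
    """A prototypic disease: a pathophem vector plus tree links and a rule."""

    pathosom_id: str
    name: str
    pathophems: list[Pathophem] = field(default_factory=list)
    rule: Optional[str] = None
    parent: Optional[str] = None
    children: list[str] = field(default_factory=list)
    variants: list[str] = field(default_factory=list)
    xrefs: list[ThesaurusRef] = field(default_factory=list)


@dataclass
class KnowledgeBase:
    """Lexicon + pathosom pool + semantic network, with referential integrity."""

    lexicon: dict[str, AtomisticTerm]
    pathosoms: dict[str, Pathosom]
    net: "SemanticNet"


@dataclass(frozen=True)
class ValidationIssue:
    entity: str  # e.g. "pathosom:M3501" or "term:10209"
    invariant: str  # short machine-readable tag, e.g. "attribute-arity"
    severity: str  # "error" | "warning"
    message: str


def class_table() -> dict[int, tuple[str, str, str]]:
    """The packaged class taxonomy: code -> (class, subclass, subclass2)."""
    table: dict[int, tuple[str, str, str]] = {}
    text = resources.files("pathosom.data").joinpath("class_table.tsv").read_text("utf-8")
    for row in csv.reader(text.splitlines()[1:], delimiter="\t"):
        row = row + [""] * (4 - len(row))
        table[int(row[0])] = (row[1], row[2], row[3])
    return table


_CLASS_TABLE_CACHE: Optional[dict[int, tuple[str, str, str]]] = None


def lookup_class(code: int) -> ClassCode:
    """ClassCode for ``code``; unknown codes get an empty class path."""
    global _CLASS_TABLE_CACHE
    if _CLASS_TABLE_CACHE is None:
        _CLASS_TABLE_CACHE = class_table()
    return ClassCode(code, _CLASS_TABLE_CACHE.get(code, ("", "", "")))


def normalize_label(surface: str) -> str:
    """Case- and diacritic-insensitive canonical form of a label."""
    decomposed = unicodedata.normalize("NFKD", surface)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return " ".join(stripped.casefold().split())


def _iter_issues(kb: KnowledgeBase) -> Iterable[ValidationIssue]:
    known_classes = class_table()

    for code, term in kb.lexicon.items():
        ent = f"term:{code}"
        if code != term.term_code:
            yield ValidationIssue(ent, "lexicon-key", "error",
                                  f"lexicon key {code!r} != term_code {term.term_code!r}")
        if not TERM_CODE_RE.match(term.term_code):
            yield ValidationIssue(ent, "term-code-pattern", "error",
                                  f"term code {term.term_code!r} is not letter?+digits+flag?")
        if not term.labels:
            yield ValidationIssue(ent, "labels-nonempty", "error", "term has no labels")
        for lang, surface in term.labels:
            if lang not in LANGUAGES:
                yield ValidationIssue(ent, "label-language", "warning",
                                      f"unknown language tag {lang!r}")
            if not surface:
                yield ValidationIssue(ent, "label-empty", "error", "empty label surface")
        if term.class_code.code not in known_classes:
            yield ValidationIssue(ent, "class-code-unknown", "warning",
                                  f"class code {term.class_code.code} not in packaged taxonomy")
        for ref in term.xrefs:
            if ref.thesaurus not in THESAURI:
                yield ValidationIssue(ent, "thesaurus-unknown", "error",
                                      f"unknown thesaurus {ref.thesaurus!r}")
            if not ref.code:
                yield ValidationIssue(ent, "xref-code-empty", "error", "empty xref code")

    for pid, p in kb.pathosoms.items():
        ent = f"pathosom:{pid}"
        if pid != p.pathosom_id:
            yield ValidationIssue(ent, "pathosom-key", "error",
                                  f"pool key {pid!r} != pathosom_id {p.pathosom_id!r}")
        for i, pp in enumerate(p.pathophems):
            pent = f"{ent}/pathophem[{i}]"
            if len(pp.attributes) > 3:
                yield ValidationIssue(pent, "attribute-arity", "error",
                                      f"{len(pp.attributes)} attributes (max 3)")
            if pp.subject not in kb.lexicon:
                yield ValidationIssue(pent, "subject-unresolved", "error",
                                      f"subject {pp.subject!r} not in lexicon")
            if pp.grade not in GRADE_SYMBOLS:
                yield ValidationIssue(pent, "grade-symbol", "error",
                                      f"unknown grade {pp.grade!r}")
            if pp.probability is not None:
                if pp.grade == "NOT":
                    yield ValidationIssue(pent, "probability-on-not", "error",
                                          "excluding pathophem cannot carry a probability")
                elif grade_for_probability(pp.probability) is None:
                    yield ValidationIssue(pent, "probability-gap", "error",
                                          f"probability {pp.probability} falls in a gap "
                                          "between grade intervals")
            for a in pp.attributes:
                if a.kind == "numeric" and isinstance(a.value, dict) and "lo" in a.value:
                    if not a.value["lo"] < a.value["hi"]:
                        yield ValidationIssue(pent, "interval-order", "error",
                                              f"numeric interval lo >= hi in {a.name!r}")
                if a.kind == "ordinal" and isinstance(a.value, dict):
                    scale = a.value.get("scale", [])
                    if a.value.get("level") not in scale:
                        yield ValidationIssue(pent, "ordinal-scale", "error",
                                              f"level {a.value.get('level')!r} not on scale")
        for ref in p.xrefs:
            if ref.thesaurus not in THESAURI:
                yield ValidationIssue(ent, "thesaurus-unknown", "error",
                                      f"unknown thesaurus {ref.thesaurus!r}")
        if p.parent is not None:
            parent = kb.pathosoms.get(p.parent)
            if parent is None:
                yield ValidationIssue(ent, "tree-consistency", "error",
                                      f"parent {p.parent!r} not in pool")
            elif pid not in parent.children:
                yield ValidationIssue(ent, "tree-consistency", "error",
                                      f"parent {p.parent!r} does not list {pid!r} as child")
        for cid in p.children:
            child = kb.pathosoms.get(cid)
            if child is None:
                yield ValidationIssue(ent, "tree-consistency", "error",
                                      f"child {cid!r} not in pool")
            elif child.parent != pid:
                yield ValidationIssue(ent, "tree-consistency", "error",
                                      f"child {cid!r} does not point back to {pid!r}")
        for vid in p.variants:
            if vid not in kb.pathosoms:
                yield ValidationIssue(ent, "variant-unresolved", "error",
                                      f"variant {vid!r} not in pool")

    # ancestor cycles in the pathosom tree
    for pid in kb.pathosoms:
        seen = {pid}
        cur = kb.pathosoms[pid].parent
        while cur is not None and cur in kb.pathosoms:
            if cur in seen:
                yield ValidationIssue(f"pathosom:{pid}", "tree-cycle", "error",
                                      f"{pid!r} is its own ancestor via {cur!r}")
                break
            seen.add(cur)
            cur = kb.pathosoms[cur].parent

    from .semantic_network import check_acyclic  # local import: cycle guard

    for node in kb.net.nodes:
        if node not in kb.lexicon:
            yield ValidationIssue(f"net:{node}", "node-unresolved", "warning",
                                  f"network node {node!r} not in lexicon")
    for e in kb.net.edges:
        for endpoint in (e.source, e.target):
            if endpoint not in kb.net.nodes:
                yield ValidationIssue(f"net:{endpoint}", "edge-endpoint", "error",
                                      f"edge endpoint {endpoint!r} is not a network node")
    for cycle in check_acyclic(kb.net):
        yield ValidationIssue("net", "hierarchy-cycle", "error",
                              "cycle in hierarchical subgraph: " + " -> ".join(cycle))


def validate_kb(kb: KnowledgeBase) -> list[ValidationIssue]:
    """Check every type invariant and referential-integrity rule.

    Returns an empty list iff the KB is fully consistent. Unknown class codes
    and unknown network nodes are warnings (user KBs may extend the taxonomy);
    everything else is an error.
    """
    return list(_iter_issues(kb))
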