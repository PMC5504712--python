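"""Matching a patient vector against the pathosom pool.

The diagnostic loop is a *linguistic game* rather than a metric
classification: verify the query terms against the lexicon, intersect them
with the disease prototypes, rank the survivors, roll equal-evidence tree
branches up to their most general representative, then either *narrow* (ask
the most discriminating missing finding) when the candidate set is too
large or *broaden* (drop attributes, then generalize terms over the
semantic network) when it is too small or empty.

Match levels and their ranking factors:

* ``exact``             (1.0) -- same subject after synonym closure, every
  query attribute satisfied by the pathophem;
* ``attribute-relaxed`` (0.8) -- same subject, at least one query attribute
  unsatisfied (admitted only in relaxed mode or after an attribute drop);
* ``generalized``       (0.6) -- the pathophem's subject is a broader
  concept of the query term (finger -> hand).

A pathosom carrying a ``NOT``-graded pathophem whose subject matches any
query element is excluded outright, whatever else matches.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

from .knowledge_model import (
    Attribute,
    KnowledgeBase,
    Pathophem,
    normalize_label,
)
from .semantic_network import generalize, resolve_term

__all__ = [
    "QueryElement",
    "PatientVector",
    "QueryConfig",
    "MatchResult",
    "VerificationIssue",
    "EmptyQueryError",
    "NothingToAskError",
    "verify_vector",
    "match_strict",
    "rank",
    "roll_up",
    "broaden",
    "narrow_suggest",
    "dialogue",
    "run_query",
    "evaluate_cases",
]

LEVEL_EXACT = "exact"
LEVEL_ATTR = "attribute-relaxed"
LEVEL_GEN = "generalized"
_LEVEL_ORDER = {LEVEL_EXACT: 0, LEVEL_ATTR: 1, LEVEL_GEN: 2}


@dataclass(frozen=True)
class QueryElement:
    """One entry of the patient vector: a term (code once resolved, surface
    string before verification) with up to three attributes."""

    term: str
    attributes: tuple[Attribute, ...] = ()
    resolved: bool = False


@dataclass(frozen=True)
class PatientVector:
    elements: tuple[QueryElement, ...]

    def __post_init__(self):
        if not 1 <= len(self.elements) <= 5:
            raise ValueError("patient vector must hold 1-5 elements")
        for e in self.elements:
            if len(e.attributes) > 3:
                raise ValueError("query element carries more than 3 attributes")


@dataclass(frozen=True)
class QueryConfig:
    mode: str = "strict"  # "strict" | "relaxed"
    roll_up: bool = True
    min_results: int = 1
    max_results: int = 10
    max_broaden_steps: int = 2
    factor_exact: float = 1.0
    factor_attr: float = 0.8
    factor_gen: float = 0.6

    def __post_init__(self):
        if self.min_results > self.max_results:
            raise ValueError("min_results must not exceed max_results")

    def factor(self, level: str) -> float:
        return {LEVEL_EXACT: self.factor_exact,
                LEVEL_ATTR: self.factor_attr,
                LEVEL_GEN: self.factor_gen}[level]


@dataclass(frozen=True)
class VerificationIssue:
    element_index: int
    surface: str
    kind: str  # "unresolvable" | "ambiguous"
    suggestions: tuple[tuple[str, str], ...] = ()


@dataclass
class MatchResult:
    pathosom_id: str
    score: float
    matched: list[tuple[int, Pathophem, str]]  # (element index, pathophem, level)
    missing: list[int]
    excluded_by: Optional[Pathophem] = None
    trace: list[str] = field(default_factory=list)
    name: Optional[str] = None  # filled in by presentation layers

    @property
    def lead_matches(self) -> int:
        return sum(1 for _, pp, _ in self.matched if pp.grade == "Lead")


class EmptyQueryError(ValueError):
    pass


class NothingToAskError(ValueError):
    pass


# ---------------------------------------------------------------------------
# verification

def verify_vector(pv: PatientVector, kb: KnowledgeBase, language: Optional[str] = None):
    """Resolve surface strings to term codes (the syntactic analysis step).

    Returns a fully resolved :class:`PatientVector`, or a list of
    :class:`VerificationIssue` carrying fuzzy/ambiguity suggestions. A
    vector whose every element is unresolvable raises
    :class:`EmptyQueryError`.
    """
    resolved: list[QueryElement] = []
    issues: list[VerificationIssue] = []
    n_unresolvable = 0
    for i, el in enumerate(pv.elements):
        if el.resolved or el.term in kb.lexicon:
            resolved.append(replace(el, resolved=True))
            continue
        hits = resolve_term(el.term, kb, language=language)
        firm = [(c, k) for c, k in hits if k in ("exact-label", "synonym")]
        if len(firm) >= 1 and sum(1 for _, k in firm if k == "exact-label") <= 1:
            resolved.append(QueryElement(firm[0][0], el.attributes, resolved=True))
        elif firm:
            issues.append(VerificationIssue(i, el.term, "ambiguous", tuple(firm)))
        else:
            n_unresolvable += 1
            issues.append(VerificationIssue(i, el.term, "unresolvable", tuple(hits)))
    if n_unresolvable == len(pv.elements):
        raise EmptyQueryError("no query element could be resolved")
    if issues:
        return issues
    return PatientVector(tuple(resolved))


# ---------------------------------------------------------------------------
# the match predicate

def _attr_compatible(q: Attribute, p: Attribute) -> bool:
    if q.kind != p.kind:
        return False
    if q.kind == "cardinal":
        return normalize_label(str(q.value)) == normalize_label(str(p.value))
    if q.kind == "ordinal":
        scale = p.value.get("scale", []) if isinstance(p.value, dict) else []
        q_level = q.value.get("level") if isinstance(q.value, dict) else q.value
        p_level = p.value.get("level") if isinstance(p.value, dict) else p.value
        if q_level not in scale or p_level not in scale:
            return False
        return scale.index(q_level) >= scale.index(p_level)
    if q.kind == "numeric":
        q_lo, q_hi, q_unit = _num_bounds(q.value)
        p_lo, p_hi, p_unit = _num_bounds(p.value)
        if q_unit is not None and p_unit is not None and q_unit != p_unit:
            return False
        return p_lo <= q_lo and q_hi <= p_hi
    return False


def _num_bounds(v) -> tuple[float, float, Optional[str]]:
    if isinstance(v, dict):
        unit = v.get("unit")
        if "lo" in v:
            return float(v["lo"]), float(v["hi"]), unit
        x = float(v["value"])
        return x, x, unit
    x = float(v)
    return x, x, None


def _attrs_satisfied(q_attrs: Sequence[Attribute], pp: Pathophem) -> bool:
    """Every query attribute must find a same-named compatible counterpart;
    extra pathophem attributes are fine (the prototype may be more specific)."""
    by_name = {a.name: a for a in pp.attributes}
    for qa in q_attrs:
        pa = by_name.get(qa.name)
        if pa is None or not _attr_compatible(qa, pa):
            return False
    return True


def _element_level(el: QueryElement, pp: Pathophem, kb: KnowledgeBase,
                   broader: Sequence[str] = ()) -> Optional[str]:
    """Best match level of one query element against one pathophem."""
    if pp.grade == "NOT":
        return None
    if kb.net.same_meaning(el.term, pp.subject):
        return LEVEL_EXACT if _attrs_satisfied(el.attributes, pp) else LEVEL_ATTR
    for b in broader:
        if kb.net.same_meaning(b, pp.subject):
            return LEVEL_GEN
    return None


def _excluding_pathophem(p, pv: PatientVector, kb: KnowledgeBase) -> Optional[Pathophem]:
    for pp in p.pathophems:
        if pp.grade != "NOT":
            continue
        for el in pv.elements:
            if kb.net.same_meaning(el.term, pp.subject):
                return pp
    return None


def _match_evidence(p, pv: PatientVector, kb: KnowledgeBase,
                    allow_attr_relax: bool,
                    broader_map: Optional[dict[int, Sequence[str]]] = None):
    """Per-element best (pathophem, level); None for unmatched elements."""
    evidence = []
    for i, el in enumerate(pv.elements):
        best = None
        broader = broader_map.get(i, ()) if broader_map else ()
        for pp in p.pathophems:
            level = _element_level(el, pp, kb, broader)
            if level is None:
                continue
            if level == LEVEL_ATTR and not allow_attr_relax:
                continue
            key = (_LEVEL_ORDER[level], -pp.weight())
            if best is None or key < best[0]:
                best = (key, pp, level)
        evidence.append(None if best is None else (best[1], best[2]))
    return evidence


def match_strict(pv: PatientVector, kb: KnowledgeBase) -> set[str]:
    """Pathosoms matching every query element exactly (synonym closure on the
    subject, all query attributes satisfied), minus NOT-excluded ones."""
    return _match(pv, kb, allow_attr_relax=False)


def _match(pv: PatientVector, kb: KnowledgeBase, allow_attr_relax: bool,
           broader_map=None) -> set[str]:
    out = set()
    for pid, p in kb.pathosoms.items():
        if _excluding_pathophem(p, pv, kb) is not None:
            continue
        ev = _match_evidence(p, pv, kb, allow_attr_relax, broader_map)
        if all(e is not None for e in ev):
            out.add(pid)
    return out


# ---------------------------------------------------------------------------
# ranking and roll-up

def rank(candidates: set[str], pv: PatientVector, kb: KnowledgeBase,
         config: QueryConfig = QueryConfig()) -> list[MatchResult]:
    """Score and order candidates.

    score = sum over matched elements of pathophem weight x level factor,
    normalized by vector length. Ties: more Lead-grade matches first, then
    lexicographic pathosom id.
    """
    broader_map = {
        i: _safe_generalize(el.term, kb, config.max_broaden_steps)
        for i, el in enumerate(pv.elements)
    }
    results = []
    for pid in candidates:
        p = kb.pathosoms[pid]
        excl = _excluding_pathophem(p, pv, kb)
        if excl is not None:
            continue  # an excluded pathosom never reaches a candidate list
        ev = _match_evidence(p, pv, kb, allow_attr_relax=True, broader_map=broader_map)
        matched = [(i, pp, level) for i, e in enumerate(ev) if e is not None
                   for pp, level in [e]]
        missing = [i for i, e in enumerate(ev) if e is None]
        score = sum(pp.weight() * config.factor(level) for _, pp, level in matched)
        score /= len(pv.elements)
        results.append(MatchResult(pid, score, matched, missing))
    results.sort(key=lambda r: (-r.score, -r.lead_matches, r.pathosom_id))
    return results


def _safe_generalize(term: str, kb: KnowledgeBase, max_steps: int) -> list[str]:
    if term not in kb.net.nodes or max_steps < 1:
        return []
    return generalize(term, kb.net, max_steps)


def _ancestors(pid: str, kb: KnowledgeBase) -> set[str]:
    out: set[str] = set()
    cur = kb.pathosoms[pid].parent
    while cur is not None and cur in kb.pathosoms and cur not in out:
        out.add(cur)
        cur = kb.pathosoms[cur].parent
    return out


def roll_up(results: list[MatchResult], kb: KnowledgeBase) -> list[MatchResult]:
    """Collapse tree branches with identical evidence to their most general
    member: a result is dropped when an ancestor pathosom is also present
    with the same matched query-element set."""
    evidence = {r.pathosom_id: frozenset(i for i, _, _ in r.matched) for r in results}
    kept = []
    for r in results:
        anc = _ancestors(r.pathosom_id, kb)
        shadowed = any(
            a in evidence and evidence[a] == evidence[r.pathosom_id] for a in anc
        )
        if not shadowed:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# broadening (query relaxation)

def _attr_drop_order(pv: PatientVector) -> list[tuple[int, Attribute]]:
    # most specific first: categorical qualities before ordinal levels before
    # numeric values; ties in declaration order
    kind_rank = {"cardinal": 0, "ordinal": 1, "numeric": 2}
    out = [(i, a) for i, el in enumerate(pv.elements) for a in el.attributes]
    out.sort(key=lambda ia: (kind_rank.get(ia[1].kind, 3), ia[0]))
    return out


def drop_attribute(pv: PatientVector, name_or_value: str) -> PatientVector:
    """Remove every query attribute whose name *or* cardinal value equals
    ``name_or_value`` (case-insensitive). Convenience for scripted
    relaxation, e.g. dropping "firm"."""
    key = normalize_label(name_or_value)
    elements = []
    for el in pv.elements:
        attrs = tuple(
            a for a in el.attributes
            if normalize_label(a.name) != key
            and not (a.kind == "cardinal" and normalize_label(str(a.value)) == key)
        )
        elements.append(replace(el, attributes=attrs))
    return PatientVector(tuple(elements))


def _drop_one(pv: PatientVector, idx: int, attr: Attribute) -> PatientVector:
    elements = list(pv.elements)
    el = elements[idx]
    elements[idx] = replace(el, attributes=tuple(a for a in el.attributes if a != attr))
    return PatientVector(tuple(elements))


def broaden(pv: PatientVector, kb: KnowledgeBase, config: QueryConfig = QueryConfig(),
            force: bool = False) -> tuple[set[str], list[str]]:
    """Staged query relaxation.

    Stage 1 drops query attributes one at a time (most specific first),
    re-matching after each single drop and accumulating newly admitted
    candidates. Stage 2 lets each term additionally match broader concepts
    reached by up to ``config.max_broaden_steps`` generalization hops.
    Stops as soon as the accumulated count reaches ``config.min_results``
    unless ``force`` is set, in which case each started stage runs to
    exhaustion. The trace records every relaxation applied.
    """
    current = match_strict(pv, kb)
    trace: list[str] = []
    if len(current) >= config.min_results and not force:
        return current, trace

    for idx, attr in _attr_drop_order(pv):
        pv2 = _drop_one(pv, idx, attr)
        admitted = _match(pv2, kb, allow_attr_relax=False) - current
        trace.append(
            f"drop-attribute element={idx} {attr.name}={attr.value!r} "
            f"(+{len(admitted)})"
        )
        current |= admitted
        if len(current) >= config.min_results and not force:
            return current, trace
    if len(current) >= config.min_results and force:
        return current, trace

    broader_map = {
        i: _safe_generalize(el.term, kb, config.max_broaden_steps)
        for i, el in enumerate(pv.elements)
    }
    if any(broader_map.values()):
        admitted = _match(pv, kb, allow_attr_relax=True, broader_map=broader_map) - current
        for i, bs in broader_map.items():
            if bs:
                trace.append(
                    f"generalize element={i} {pv.elements[i].term} -> {','.join(bs)}"
                )
        trace.append(f"generalized-match (+{len(admitted)})")
        current |= admitted
    return current, trace


# ---------------------------------------------------------------------------
# narrowing (question selection)

def narrow_suggest(candidates: set[str], pv: PatientVector, kb: KnowledgeBase,
                   skip: frozenset[str] = frozenset()):
    """The next finding to ask about: the pathophem subject (not already in
    the query) whose presence count across candidates is closest to half —
    the most discriminating split. Ties go to the higher grade weight, then
    to term-code order. Returns ``(term_code, attributes)``."""
    if len(candidates) <= 1:
        raise NothingToAskError("narrowing needs more than one candidate")
    in_query = set()
    for el in pv.elements:
        in_query |= kb.net.synonym_class(el.term)
    counts: dict[str, int] = {}
    best_pp: dict[str, Pathophem] = {}
    for pid in candidates:
        seen_here = set()
        for pp in kb.pathosoms[pid].pathophems:
            if pp.grade == "NOT" or pp.subject in in_query or pp.subject in skip:
                continue
            if pp.subject not in seen_here:
                counts[pp.subject] = counts.get(pp.subject, 0) + 1
                seen_here.add(pp.subject)
            prev = best_pp.get(pp.subject)
            if prev is None or pp.weight() > prev.weight():
                best_pp[pp.subject] = pp
    if not counts:
        raise NothingToAskError("no askable pathophem remains")
    half = len(candidates) / 2.0
    subject = min(
        counts,
        key=lambda s: (abs(counts[s] - half), -best_pp[s].weight(), s),
    )
    return subject, best_pp[subject].attributes


# ---------------------------------------------------------------------------
# the dialogue loop

def dialogue(pv: PatientVector, kb: KnowledgeBase, config: QueryConfig = QueryConfig(),
             answer_provider: Optional[Callable] = None):
    """Run the interactive loop until the candidate set fits the window.

    ``answer_provider(term_code, attributes) -> "TRUE"|"FALSE"|"NA"``. A
    TRUE answer appends the finding to the patient vector (while room
    remains in the 5-tuple); FALSE excludes candidates for which that
    finding is Lead-graded (always present); NA retires the question.
    Deterministic given the answer sequence. Returns
    ``(ranked results, transcript)``.
    """
    verified = verify_vector(pv, kb)
    if isinstance(verified, list):
        raise EmptyQueryError(f"unverifiable query elements: {verified}")
    pv = verified
    transcript: list[str] = []
    asked: set[str] = set()
    excluded: set[str] = set()
    broadened: Optional[set[str]] = None

    while True:
        cands = (match_strict(pv, kb) if broadened is None else set(broadened)) - excluded
        n = len(cands)
        if n > config.max_results and answer_provider is not None:
            try:
                subject, attrs = narrow_suggest(cands, pv, kb, skip=frozenset(asked))
            except NothingToAskError:
                transcript.append("narrow: exhausted")
                break
            answer = answer_provider(subject, attrs)
            transcript.append(f"ask {subject} -> {answer}")
            asked.add(subject)
            if answer == "TRUE":
                if len(pv.elements) < 5:
                    pv = PatientVector(pv.elements + (QueryElement(subject, (), True),))
                    broadened = None
                else:
                    transcript.append("vector full; stopping questions")
                    break
            elif answer == "FALSE":
                newly = {
                    pid for pid in cands
                    if any(pp.grade == "Lead" and kb.net.same_meaning(pp.subject, subject)
                           for pp in kb.pathosoms[pid].pathophems)
                }
                excluded |= newly
                transcript.append(f"excluded {len(newly)} Lead-bound candidates")
            continue
        if n < config.min_results and broadened is None:
            relaxed, trace = broaden(pv, kb, config)
            transcript.extend("broaden: " + t for t in trace)
            broadened = relaxed
            continue
        break

    cands = (match_strict(pv, kb) if broadened is None else set(broadened)) - excluded
    results = rank(cands, pv, kb, config)
    if config.roll_up:
        results = roll_up(results, kb)
    return results, transcript


def run_query(pv: PatientVector, kb: KnowledgeBase,
              config: QueryConfig = QueryConfig()) -> list[MatchResult]:
    """One-shot pipeline: verify, match, broaden if short, rank, roll up."""
    results, _ = dialogue(pv, kb, config, answer_provider=None)
    return results


# ---------------------------------------------------------------------------
# evaluation harness

def evaluate_cases(cases: Sequence[tuple[PatientVector, str]], kb: KnowledgeBase,
                   config: QueryConfig = QueryConfig()) -> dict:
    """Identification rate and median proposal count over labelled cases.

    A case counts as identified when the expected pathosom — or, with
    roll-up, one of its tree ancestors — appears in the final results.
    The median uses the lower middle value for even counts.
    """
    if not cases:
        raise ValueError("no cases supplied")
    rows = []
    identified = 0
    counts = []
    for pv, expected in cases:
        results = run_query(pv, kb, config)
        ids = {r.pathosom_id for r in results}
        ok = expected in ids
        if not ok and config.roll_up:
            ok = bool(_ancestors(expected, kb) & ids)
        identified += ok
        counts.append(len(results))
        rows.append({
            "expected": expected,
            "identified": bool(ok),
            "n_proposals": len(results),
            "top": results[0].pathosom_id if results else None,
        })
    return {
        "identification_rate": identified / len(cases),
        "median_proposal_count": statistics.median_low(counts),
        "cases": rows,
    }
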