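"""Shared test utilities: seeded random expression trees, an independent
Kleene fold, fact realization, and a brute-force match predicate."""

from __future__ import annotations

import numpy as np

from pathosom.pathophem_dsl import (
    NA,
    TRUE,
    FALSE,
    And,
    Atom,
    Or,
    Range,
    Seq,
    ValueConstraint,
)


def random_ast(rng: np.random.Generator, max_atoms: int = 6, top: bool = True):
    """A grammar-conformant random expression with 1..max_atoms atoms.

    Atom keys are unique within one expression; roughly a third of atoms
    carry a range constraint and some carry the opaque T flag.
    """
    n = int(rng.integers(1, max_atoms + 1))
    atoms = []
    for i in range(n):
        flag = "T" if rng.random() < 0.2 else None
        r = rng.random()
        if r < 0.3:
            lo = float(rng.integers(0, 50))
            constraint = Range(lo, lo + float(rng.integers(1, 50)), "%")
        elif r < 0.4:
            constraint = ValueConstraint("firm")
        else:
            constraint = None
        atoms.append(Atom(f"{100 + i}", flag, constraint))
    return _build(rng, atoms, top)


def _build(rng, atoms, top):
    if len(atoms) == 1:
        return atoms[0]
    ops = [And, Or] + ([Seq] if top else [])
    op = ops[int(rng.integers(0, len(ops)))]
    k = int(rng.integers(2, min(len(atoms), 4) + 1))
    cuts = sorted(rng.choice(np.arange(1, len(atoms)), size=k - 1, replace=False)) \
        if len(atoms) > k - 1 else list(range(1, k))
    groups, prev = [], 0
    for c in list(cuts) + [len(atoms)]:
        groups.append(atoms[prev:int(c)])
        prev = int(c)
    groups = [g for g in groups if g]
    if len(groups) < 2:
        return atoms[0] if len(atoms) == 1 else And(tuple(atoms))
    return op(tuple(_build(rng, g, top=False) for g in groups))


def iter_atoms(node):
    if isinstance(node, Atom):
        yield node
    else:
        for c in node.children:
            yield from iter_atoms(c)


def realize_facts(node, assignment: dict) -> dict:
    """Build a fact set under which each atom evaluates to its assigned
    tri-state (TRUE/FALSE/NA)."""
    facts = {}
    for atom in iter_atoms(node):
        tri = assignment[atom.key]
        if tri == NA:
            continue
        c = atom.constraint
        if isinstance(c, Range):
            value = (c.lo + c.hi) / 2 if tri == TRUE else c.hi + 1.0
            facts[atom.key] = {"value": value, "unit": c.unit}
        elif isinstance(c, ValueConstraint):
            facts[atom.key] = c.value if tri == TRUE else c.value + "-other"
        else:
            facts[atom.key] = tri == TRUE
    return facts


_ENC = {FALSE: 0.0, NA: 0.5, TRUE: 1.0}
_DEC = {0.0: FALSE, 0.5: NA, 1.0: TRUE}


def kleene_fold(node, assignment: dict) -> str:
    """Independent oracle: numeric min/max encoding of strong Kleene logic."""
    if isinstance(node, Atom):
        return assignment[node.key]
    vals = [_ENC[kleene_fold(c, assignment)] for c in node.children]
    return _DEC[min(vals) if isinstance(node, (And, Seq)) else max(vals)]


def brute_force_match(pv, kb) -> set:
    """Set comprehension over all pathosoms, checking the strict predicate
    directly (synonym closure via the net; cardinal attributes only, which
    is all the random KBs produce)."""
    out = set()
    for pid, p in kb.pathosoms.items():
        excluded = any(
            pp.grade == "NOT" and kb.net.same_meaning(el.term, pp.subject)
            for pp in p.pathophems
            for el in pv.elements
        )
        if excluded:
            continue
        ok = True
        for el in pv.elements:
            found = False
            for pp in p.pathophems:
                if pp.grade == "NOT" or not kb.net.same_meaning(el.term, pp.subject):
                    continue
                have = {(a.name, a.value) for a in pp.attributes}
                if all((qa.name, qa.value) in have for qa in el.attributes):
                    found = True
                    break
            if not found:
                ok = False
                break
        if ok:
            out.add(pid)
    return out
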