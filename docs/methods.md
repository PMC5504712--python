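# Methods

This note records the model, the numerical and design choices, what the
synthetic generators do and do not emulate, and the known limitations.

## Knowledge model

A knowledge base has three parts with mutual referential integrity: a
**lexicon** (term code → atomistic term), a **pathosom pool** (disease
prototypes) and a **semantic network** (typed directed graph over term
codes). Term codes follow the shape *optional uppercase letter + digits +
optional single-letter flag* (`M3094`, `O812`, `10209`, `10787Z`); the
flag (`10209 T` vs `10209`) is preserved as an opaque identity marker with
no further semantics, because none is defined anywhere we could anchor to.

Occurrence grades map to probability intervals exactly as printed in the
source vocabulary, *including the gaps between them* (nothing lies between
0.09 and 0.1, or between 0.99 and 1.0). An explicit numeric probability
may be stored alongside the grade; it then takes precedence for weighting,
and values falling inside an inter-grade gap are flagged by validation
rather than silently snapped. The `(+)` interval is taken as [0.0, 0.01)
— probability exactly 0 is admitted, the upper bound is open ("below
1%"). Grade weights are interval midpoints; any strictly increasing
scalarization would do, midpoints are simply unambiguous.

Validation is deliberately post-hoc: `validate_kb` returns typed issue
records instead of raising during construction, so malformed KBs can be
loaded, inspected and repaired. Unknown semantic-class codes and
network nodes missing from the lexicon are warnings (user KBs may extend
the taxonomy); everything else — attribute arity above 3, unresolvable
pathophem subjects, non-reciprocated or cyclic tree links, cycles in the
hierarchical subgraph — is an error. Files are written canonically
(sorted keys, sorted order-free collections), so identical KBs are
byte-identical regardless of construction order; pathophem order within a
pathosom is meaningful (it drives patient generation) and is preserved.

## The rule language

The coded expression language is small enough that the parser is written
directly as a tokenizer + recursive descent, which also gives precise
error positions. Grammar decisions that were genuinely open:

* `|` is overloaded; a `|` immediately following a code token (plus an
  optional single-letter flag) terminates the atom, any other `|` is OR.
  This is the only reading consistent with the canonical example.
* `;` is top-level conjunction. The prose equivalent of the canonical
  rule joins its clauses with AND and requires the whole term to be TRUE.
* Range constraints `a..b%` are closed below, open above: [a, b). The
  prose uses exclusive bounds (">5%", "<20%") while the WHO convention
  is the inclusive "5–19%"; [a, b) is the compromise that agrees with
  both at the upper end and with WHO at the lower. Flagged as a choice,
  not a fact.
* A constraint written after a closing parenthesis binds to the nearest
  preceding atom (the rightmost atom of the group).

Evaluation is strong Kleene three-valued logic (AND: FALSE dominates,
then NA; OR dually; `;` behaves as AND). Facts are TRUE, FALSE or a
numeric value with an optional unit; an absent code is not-available. A
boolean TRUE against a range constraint is NA (presence asserted, quantity
unknown), FALSE stays FALSE; unit disagreement between a numeric fact and
a constraint is an error naming both units. The serializer emits a
canonical spacing whose re-parse is structurally identical; it refuses
arity violations (AND/OR/SEQ need ≥ 2 children) and nested sequences.

## Semantic network

Synonymy is symmetric closure over `synonym-of` edges; label matching is
case- and diacritic-insensitive (NFKD, combining marks stripped).
Fuzzy suggestions use normalized edit similarity (difflib ratio) with a
conservative threshold of 0.8 and at most 5 suggestions, and are offered
only when no exact or synonym match exists. Generalization is
breadth-first over outgoing `is-a`, `is-part-of`, `is-class-of` edges
(increasing distance, ties by term code); `has-attribute-of` is *not*
followed — it changes meaning, not granularity. The hierarchical subgraph
must be acyclic, which guarantees termination; `check_acyclic` reports
real cycles and exempts synonym and tree-mirror edge types.

## Matching, ranking, dialogue

Match levels: **exact** (same subject after synonym closure, every query
attribute satisfied by a same-named, compatible pathophem attribute —
numeric query point/interval inside the pathophem's interval, categories
equal, ordinal at or above the pathophem's minimum on its declared scale),
**attribute-relaxed** (subject matches, some query attribute unsatisfied;
admitted only in relaxed mode or after an attribute drop), **generalized**
(the pathophem subject is a broader concept of the query term). A
pathophem may be more specific than the query (extra attributes are
fine); the reverse is not an exact match. NOT-graded pathophems exclude a
pathosom whenever their subject matches any query element; excluded
pathosoms never reach a candidate list.

The ranking formula and its constants are package design (the underlying
approach deliberately avoids a distance measure, so *some* scalarization
had to be chosen): score = Σ matched-element grade weight × level factor
(1.0 / 0.8 / 0.6), normalized by query length; ties broken by more
Lead-grade matches, then lexicographic id. All constants sit in
`QueryConfig`. One consequence, documented rather than hidden: a
prototype carrying the full query evidence at higher grades can outrank
the prototype a synthetic patient was generated from when that patient's
emitted evidence is a shared low-grade subset. The recovery property is
therefore stated as: at sensitivity 1.0 the source is always *identified*;
it ranks first unless outranked by a full exact-evidence match of at
least equal score.

Broadening is staged. Stage 1 drops query attributes one at a time —
non-cumulatively, most specific first (categorical before ordinal before
numeric, ties in element order) — re-matching strictly on the remaining
attributes after each drop and accumulating the union of admitted
candidates, so each admission is attributable to one drop. Stage 2 lets
every term also match concepts up to `max_broaden_steps` (default 2)
generalization hops away. Each stage stops as soon as the accumulated
count reaches `min_results` (default 1); a `force` flag runs a started
stage to exhaustion for scripted relaxation. The relaxed set is a superset
of the strict set by construction.

Narrowing asks about the pathophem subject whose presence count *c*
across the *n* candidates minimizes |c − n/2| (the best binary split),
ties to the higher grade weight, then term-code order. In the dialogue
loop a TRUE answer appends the finding to the patient vector (while the
5-tuple has room), FALSE excludes only candidates that carry the finding
at Lead grade — "always present" is the only grade a negative answer can
refute — and NA retires the question. The loop is deterministic given the
answer sequence and terminates because every iteration consumes a
question, shrinks the vector's remaining capacity, or ends in a single
broadening pass. Thresholds default to min 1 / max 10 proposals.
Demographic context (female, newborn, age) is handled as ordinary query
elements matching epidemiology-class pathophems, not as hard filters.

## Fixtures and synthetic data

`build_paper_cases_kb` (59 pathosoms, 27 terms) encodes four clusters:
the myelodysplasia tree (RAEB with its three subtypes, two sibling
distractors, the coded blast-fraction rule, ICD-10-GM/ICD-O references);
the breast-nodule cluster (invasive breast cancer with a firm nodule,
six named differentials carrying the nodule without the firm attribute,
one NOT-exclusion); Meckel syndrome types 1–6 under a common root, where
exactly types 1, 3 and 6 carry {polydactyly, renal cyst, encephalocele}
and type 6 carries OMIM 612284; and the renal cluster (eight named
fever+proteinuria+hematuria prototypes, the MPGN subtree and 25
deterministic two-symptom distractors whose extra findings cycle through
a fixed pool). Multilingual synonymy is exercised by four spellings of
the renal-cyst term mapping to one code.

`generate_random_kb` draws seeded KBs with defaults chosen as a plausible
desk-scale workload: 25 pathosoms, 40 terms, 4–8 pathophems each, grade
mix {Lead .15, +++ .25, ++ .30, + .20, (+) .10}, 10% of pathosoms with
one NOT finding, tree depth ≤ 2, a sparse random `is-a` DAG. Acyclicity
is guaranteed by drawing edges from higher to lower index. Subjects are
sampled without replacement within a pathosom, so no prototype contradicts
itself.

`generate_patient` emits each non-NOT pathophem independently with
probability *sensitivity × grade weight* and truncates to the five
highest-grade findings — emulating terse single-cause case reports. What
it does **not** emulate: co-morbidity, noisy or erroneous findings,
findings absent from the source prototype, free-text surface forms, or
realistic symptom correlation. Green tests on these patients therefore
show internal consistency of representation + matcher, not clinical
accuracy; the published evaluation corpus behind the original system's
headline identification rate is not public, so the evaluation harness
(`evaluate_cases`: identification rate, lower-median proposal count) runs
on these synthetic cases instead.

## Numerical and degenerate-input choices

Scores are plain double sums over ≤ 5 terms; no tolerance issues arise,
and ranking ties are broken structurally, never by float comparison
noise. Patient vectors are hard-limited to 1–5 elements and ≤ 3
attributes each (constructor errors). Zero-sensitivity generation, a
pathosom with no emittable pathophem, narrowing a single candidate and a
fully unresolvable query are errors, not empty successes. Problem sizes
in the test suite (random KBs of 12–40 terms, ≤ 25 pathosoms; 10,000
Monte-Carlo replicates for the emission check; 1,000 random expression
trees; exhaustive tri-state enumeration at ≤ 6 atoms) were chosen so each
property runs in seconds while still exercising every code path.

## Known limitations

* No probabilistic posterior over diseases; the ranking is a heuristic
  scalarization of grades, not a likelihood.
* Thesaurus cross-references are opaque strings; no external coding
  system is ingested or validated.
* The semantic network supports reachability queries only — no ontology
  reasoning, role composition or OWL semantics.
* German/English synonymy is explicit data; there is no translation.
* The rule language has no negation (exclusion lives on grades) and no
  natural-language front end.
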