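# pathosom

Prototypic-disease knowledge bases and a dialogue-driven
differential-diagnosis matcher.

`pathosom` is a compact clinical-decision-support toolkit for people who
want to *represent* medical knowledge linguistically rather than
statistically: a disease prototype (**pathosom**) is a vector of coded,
attributed findings (**pathophems**), each carrying an ordinal occurrence
grade, and diagnosis is played as a *linguistic game* — a patient vector of
up to five attributed terms is verified against a lexicon, intersected
with the prototype pool, ranked, and then iteratively **narrowed** (ask
the most discriminating missing finding) or **broadened** (drop
attributes, generalize terms over a typed semantic network) until the
candidate list is usefully small. It is aimed at researchers prototyping
knowledge-representation and query-relaxation strategies, not at clinical
deployment.

## The model

A pathosom is a vector *c(j₁ … jₙ)* of pathophems. Each pathophem is an
atomistic term (a stem-word concept with a unique internal code,
multilingual labels, a semantic class, and cross-references into external
thesauri such as ICD-10-GM, ICD-O or OMIM) plus up to three attributes
(cardinal, ordinal or numeric) and an occurrence grade:

| grade | probability interval | weight (midpoint) |
|-------|----------------------|-------------------|
| Lead  | [1.0, 1.0] — always present | 1.0 |
| +++   | [0.5, 0.99]          | 0.745 |
| ++    | [0.1, 0.49]          | 0.295 |
| +     | [0.01, 0.09]         | 0.05 |
| (+)   | [0.0, 0.01)          | 0.005 |
| NOT   | excludes the pathosom | — |

Pathosoms may additionally carry a coded Boolean rule over findings, e.g.

```
M3094|; (O812| & 10209|: 5..20%) | (10221 T| &10209 T|: 2..20%)
```

(`;` = top-level AND, `|` after a code terminates an atom, elsewhere it is
OR, `: lo..hi%` is a half-open range constraint). Rules evaluate in strong
Kleene three-valued logic: every finding is TRUE, FALSE or not-available.

Matching is conjunctive: a pathosom is a strict candidate when every query
element matches one of its pathophems (same subject after synonym closure,
all query attributes satisfied) and no NOT-graded pathophem matches any
query element. Candidates are scored by

```
score = ( Σ grade_weight(pathophem) × level_factor ) / |patient vector|
```

with level factors 1.0 (exact), 0.8 (attribute-relaxed), 0.6
(generalized), and equal-evidence tree branches are rolled up to their
most general representative.

## Worked example

Build the packaged demonstration knowledge base (59 pathosoms in four
clinical clusters) and query the myelodysplasia triad:

```
$ pathosom fixtures build-paper-cases --out kb.json
$ pathosom query --kb kb.json --term cytopenia --term anemia \
      --term "bone marrow:cellularity=hypercellular"
pathosom_id  name                                         score   matched
M3501        RAEB (refractory anemia with excess blasts)  1.0000  0:F001:exact,1:F002:exact,2:F003:exact
```

One prototype survives: all three findings match at Lead grade
(3 × 1.0 / 3 = 1.0), and the three RAEB subtypes that match with identical
evidence are rolled up into their parent. A broader renal query shows the
grade weighting — fever cluster members score
(1.0 + 0.745 + 1.0) / 3 = 0.915 because hematuria is graded `+++` there:

```
$ pathosom query --kb kb.json --term proteinuria --term hematuria --term fever
F461  cryoglobulinemia with vasculitis   0.9150  ...
F462  periarteriitis nodosa              0.9150  ...
(8 rows)
```

The same engine is scriptable from Python:

```python
from pathosom import fixtures, run_query, PatientVector, QueryElement

kb = fixtures.build_paper_cases_kb()
pv = PatientVector((QueryElement("polydactyly"),
                    QueryElement("renal cyst"),
                    QueryElement("encephalocele")))
for r in run_query(pv, kb):
    print(r.pathosom_id, round(r.score, 3))
# F311 1.0, F313 1.0, F316 1.0  (Meckel syndrome types 1, 3, 6)
```

Other subcommands: `validate`, `stats`, `dialogue` (scripted
question/answer loops), `evaluate` (identification rate and median
proposal count over labelled cases), `expr parse|eval` (the rule
language), and `fixtures random`/`fixtures patients` (seeded synthetic
knowledge bases and patients).

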