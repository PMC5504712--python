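"""Deterministic knowledge-base and synthetic-patient construction.

``build_paper_cases_kb`` assembles a small but fully validated KB holding
four clinical clusters — the myelodysplasia tree around refractory anemia
with excess blasts (RAEB), the breast-nodule cluster, Meckel syndrome
types 1-6, and the renal proteinuria/hematuria/fever cluster — so the
matcher's behaviour on realistic differential-diagnosis queries can be
exercised without any licensed thesaurus download. Internal codes follow
the published ones where they exist (M3501, M3094, O812, 10209, 10221,
10787Z, M5065); everything else uses a reserved F prefix.

``generate_random_kb`` / ``generate_patient`` produce seeded random KBs
and synthetic patient vectors for property testing and for the evaluation
harness (the published 190-report case set is not public; synthetic cases
stand in for it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .knowledge_model import (
    AtomisticTerm,
    Attribute,
    KnowledgeBase,
    Pathophem,
    Pathosom,
    ThesaurusRef,
    lookup_class,
)
from .matching_engine import PatientVector, QueryElement
from .semantic_network import SemanticNet

__all__ = [
    "FixtureSpec",
    "SyntheticPatient",
    "build_paper_cases_kb",
    "generate_random_kb",
    "generate_patient",
    "PAPER_CASE_QUERIES",
]

RAEB_RULE = "M3094|; (O812| & 10209|: 5..20%) | (10221 T| &10209 T|: 2..20%)"

BREAST_RELAXED = (
    ("F211", "angiosarcoma of breast"),
    ("F212", "secretory breast cancer"),
    ("F213", "benign breast tumor"),
    ("F214", "pseudoangiomatoid stroma hyperplasia"),
    ("F215", "fibroadenoma"),
    ("F216", "breast papilloma"),
)

FEVER_PATHOSOMS = (
    ("F461", "cryoglobulinemia with vasculitis"),
    ("F462", "periarteriitis nodosa"),
    ("F463", "microscopic polyangiitis"),
    ("F464", "hanta virus infection"),
    ("F465", "hemorrhagic fever with renal syndrome"),
    ("F466", "emphysematous pyelonephritis"),
    ("F467", "infective glomerulonephritis"),
    ("F468", "acute interstitial nephritis"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random KB: sizes, grade mix, exclusions, tree depth."""

    seed: int
    n_pathosoms: int = 25
    n_terms: int = 40
    pathophems_per_pathosom: tuple[int, int] = (4, 8)
    grade_dist: dict = field(default_factory=lambda: {
        "Lead": 0.15, "+++": 0.25, "++": 0.30, "+": 0.20, "(+)": 0.10,
    })
    not_fraction: float = 0.10
    tree_depth: int = 2

    def validate(self) -> None:
        if self.n_pathosoms < 1 or self.n_terms < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.not_fraction <= 1:
            raise ValueError("not_fraction must be a probability")
        lo, hi = self.pathophems_per_pathosom
        if not 1 <= lo <= hi:
            raise ValueError("pathophem range must satisfy 1 <= lo <= hi")
        if hi >= self.n_terms:
            raise ValueError("more pathophems per pathosom than available terms")
        total = sum(self.grade_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"grade probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class SyntheticPatient:
    source_pathosom: str
    vector: PatientVector
    sensitivity: float


def _card(name: str, value: str) -> Attribute:
    return Attribute("cardinal", name, value)


def _age_range(lo: float, hi: float) -> Attribute:
    return Attribute("numeric", "age", {"lo": lo, "hi": hi, "unit": "years"})


def _normalize(kb: KnowledgeBase) -> KnowledgeBase:
    # canonical ordering of every order-free collection, via the file codec
    from .io_cli import kb_from_dict, kb_to_dict

    return kb_from_dict(kb_to_dict(kb))


def build_paper_cases_kb() -> KnowledgeBase:
    """The fixed four-cluster KB; passes :func:`validate_kb` cleanly."""
    lex: dict[str, AtomisticTerm] = {}
    pool: dict[str, Pathosom] = {}
    net = SemanticNet()

    def term(code, cls, *labels, xrefs=()):
        lex[code] = AtomisticTerm(code, tuple(labels), lookup_class(cls),
                                  tuple(ThesaurusRef(t, c) for t, c in xrefs))
        net.nodes.add(code)

    def disease(pid, name, pathophems, rule=None, parent=None, xrefs=()):
        pool[pid] = Pathosom(pid, name, list(pathophems), rule=rule, parent=parent,
                             xrefs=[ThesaurusRef(t, c) for t, c in xrefs])
        if parent is not None:
            pool[parent].children.append(pid)

    def pp(subject, grade, *attrs, cls=5400):
        return Pathophem(subject, tuple(attrs), grade, lookup_class(cls))

    # --- myelodysplasia cluster -------------------------------------------
    term("F001", 5500, ("en", "cytopenia"), ("de", "Zytopenie"))
    term("F002", 5500, ("en", "anemia"), ("de", "Anämie"), ("la", "anaemia"))
    term("F003", 5700, ("en", "bone marrow"), ("de", "Knochenmark"))
    term("M3094", 5500, ("en", "refractory anemia"))
    term("O812", 5720, ("en", "myeloblasts"))
    term("10209", 5720, ("en", "blasts"))
    term("10221", 5720, ("en", "blast count"))

    marrow = lambda grade: pp("F003", grade, _card("cellularity", "hypercellular"),
                              cls=5700)
    disease("F200", "myelodysplasia",
            [pp("F001", "Lead", cls=5500), pp("F002", "+++", cls=5500)])
    disease("M3501", "RAEB (refractory anemia with excess blasts)",
            [pp("F001", "Lead", cls=5500), pp("F002", "Lead", cls=5500),
             marrow("Lead")],
            rule=RAEB_RULE, parent="F200",
            xrefs=(("ICD-10-GM", "D46.2"), ("ICD-O", "9983/3")))
    for pid, name in (("M35011", "RAEB-1"), ("M35012", "RAEB-2"),
                      ("M35013", "RAEB-F")):
        disease(pid, name,
                [pp("F001", "Lead", cls=5500), pp("F002", "Lead", cls=5500),
                 marrow("Lead")],
                parent="M3501")
    disease("F205", "refractory cytopenia with multilineage dysplasia",
            [pp("F001", "Lead", cls=5500), pp("F002", "++", cls=5500)],
            parent="F200")
    disease("F206", "aplastic anemia",
            [pp("F001", "Lead", cls=5500), pp("F002", "Lead", cls=5500),
             pp("F003", "Lead", _card("cellularity", "hypocellular"), cls=5700)],
            parent="F200")

    # --- breast-nodule cluster --------------------------------------------
    term("F101", 6310, ("en", "female"), ("de", "weiblich"))
    term("10787Z", 5400, ("de", "tastbarer Knoten"), ("en", "lump"),
         ("en", "palpable node"), ("en", "nodule"))
    term("F103", 5700, ("en", "metastasis"), ("de", "Metastase"))

    firm_nodule = pp("10787Z", "+++", _card("consistency", "firm"),
                     _card("site", "mamma"))
    soft_nodule = pp("10787Z", "+++", _card("site", "mamma"))
    female = pp("F101", "Lead", _age_range(20, 95), cls=6310)
    disease("F210", "invasive breast cancer", [female, firm_nodule],
            xrefs=(("ICD-10-GM", "C50.9"),))
    for pid, name in BREAST_RELAXED:
        phems = [female, soft_nodule]
        if pid == "F213":  # benign tumours exclude distant metastasis
            phems.append(pp("F103", "NOT", cls=5700))
        disease(pid, name, phems)

    # --- Meckel cluster ----------------------------------------------------
    term("F301", 5400, ("en", "polydactyly"), ("de", "Polydaktylie"))
    term("M5065", 5600, ("de", "Nierenzyste"), ("de", "Nierencyste"),
         ("en", "renal cyst"), ("en", "renal cysts"))
    term("F302", 5400, ("en", "encephalocele"), ("de", "Enzephalozele"))
    term("F303", 5400, ("en", "microcephaly"))
    term("F304", 5400, ("en", "cleft palate"))
    term("F305", 6320, ("en", "newborn"), ("de", "Neugeborenes"))

    triad = lambda: [pp("F301", "Lead"), pp("M5065", "Lead", cls=5600),
                     pp("F302", "Lead"), pp("F305", "+++", cls=6320)]
    disease("F300", "Meckel syndrome",
            [pp("M5065", "Lead", cls=5600), pp("F302", "+++"),
             pp("F305", "+++", cls=6320)])
    for i in range(1, 7):
        pid = f"F31{i}"
        if i in (1, 3, 6):
            phems = triad()
        elif i == 2:
            phems = [pp("M5065", "Lead", cls=5600), pp("F302", "Lead"),
                     pp("F304", "+++")]
        elif i == 4:
            phems = [pp("F301", "Lead"), pp("M5065", "Lead", cls=5600),
                     pp("F303", "+++")]
        else:  # type 5
            phems = [pp("F301", "Lead"), pp("F303", "+++"), pp("F304", "++")]
        xrefs = (("OMIM", "612284"),) if i == 6 else ()
        disease(pid, f"Meckel syndrome type {i}", phems, parent="F300", xrefs=xrefs)

    # --- renal / fever cluster --------------------------------------------
    term("F401", 5500, ("en", "proteinuria"), ("de", "Proteinurie"))
    term("F402", 5500, ("en", "hematuria"), ("de", "Hämaturie"))
    term("F403", 5300, ("en", "fever"), ("de", "Fieber"))
    term("F404", 5300, ("en", "pyrexia"))
    net.add_edge("F404", "synonym-of", "F403")
    extra_pool = [
        ("F405", "edema"), ("F406", "hypertension"),
        ("F407", "oliguria"), ("F408", "flank pain"),
        ("F409", "dysuria"),
    ]
    for code, label in extra_pool:
        term(code, 5400, ("en", label))

    renal_pair = lambda g1="Lead", g2="Lead": [
        pp("F401", g1, cls=5500), pp("F402", g2, cls=5500)]
    for pid, name in FEVER_PATHOSOMS:
        disease(pid, name, renal_pair("Lead", "+++") + [pp("F403", "Lead", cls=5300)])
    disease("F420", "membrano-proliferative glomerulonephritis",
            renal_pair() + [pp("F406", "++")],
            xrefs=(("ICD-10-GM", "N05.5"),))
    for i, roman in enumerate(("I", "II", "III"), start=1):
        disease(f"F42{i}", f"MPGN type {roman}",
                renal_pair() + [pp("F406", "++")], parent="F420")
    grades = ("Lead", "+++", "++")
    for i in range(1, 26):
        code, _ = extra_pool[i % len(extra_pool)]
        disease(f"F{430 + i}", f"proteinuria-hematuria distractor {i:02d}",
                renal_pair(grades[i % 3], grades[(i + 1) % 3]) + [pp(code, "++")])

    # --- semantic context ---------------------------------------------------
    net.add_edge("F002", "is-a", "F001")            # anemia is a cytopenia
    net.add_edge("O812", "is-a", "10209")           # myeloblasts are blasts
    net.add_edge("F401", "is-class-of", "F402")     # urinary findings cluster
    term("F501", 5400, ("en", "finger swelling"))
    term("F502", 5400, ("en", "hand swelling"))
    net.add_edge("F501", "is-part-of", "F502")
    disease("F510", "hand arthritis", [pp("F502", "Lead"), pp("F403", "+", cls=5300)])

    return _normalize(KnowledgeBase(lex, pool, net))


def _paper_case_queries() -> dict[str, PatientVector]:
    q = QueryElement
    return {
        "case1": PatientVector((
            q("cytopenia"), q("anemia"),
            q("bone marrow", (_card("cellularity", "hypercellular"),)),
        )),
        "case2": PatientVector((
            q("female", (Attribute("numeric", "age", {"value": 55, "unit": "years"}),)),
            q("nodule", (_card("consistency", "firm"),)),
            q("nodule", (_card("site", "mamma"),)),
        )),
        "case3": PatientVector((
            q("polydactyly"), q("renal cyst"), q("encephalocele"),
        )),
        "case4": PatientVector((
            q("proteinuria"), q("hematuria"), q("fever"),
        )),
    }


#: The four worked patient vectors, keyed case1..case4 (surface form;
#: run them through verify_vector).
PAPER_CASE_QUERIES = _paper_case_queries()


def generate_random_kb(spec: FixtureSpec) -> KnowledgeBase:
    """Seeded random KB honouring every model invariant.

    Term and pathosom identifiers are drawn from ranges disjoint from the
    worked-case fixture codes. Identical specs yield identical KBs (and,
    through the canonical writer, byte-identical files).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lex: dict[str, AtomisticTerm] = {}
    pool: dict[str, Pathosom] = {}
    net = SemanticNet()

    classes = (5100, 5300, 5400, 5500, 5700)
    term_codes = [f"{90000 + i}" for i in range(spec.n_terms)]
    for i, code in enumerate(term_codes):
        labels = ((u"en", f"finding {i:03d}"), (u"de", f"Befund {i:03d}"))
        lex[code] = AtomisticTerm(code, labels, lookup_class(classes[i % len(classes)]))
        net.nodes.add(code)

    # random DAG: edges only from higher to lower index keep it acyclic
    for i in range(1, spec.n_terms):
        if rng.random() < 0.2:
            j = int(rng.integers(0, i))
            net.add_edge(term_codes[i], "is-a", term_codes[j])

    grades = list(spec.grade_dist)
    probs = np.array([spec.grade_dist[g] for g in grades])
    lo, hi = spec.pathophems_per_pathosom
    depth: dict[str, int] = {}
    pids = [f"P{1000 + i}" for i in range(spec.n_pathosoms)]
    for i, pid in enumerate(pids):
        n_pp = int(rng.integers(lo, hi + 1))
        subjects = [term_codes[k] for k in rng.choice(spec.n_terms, n_pp, replace=False)]
        phems = []
        for s in subjects:
            grade = grades[int(rng.choice(len(grades), p=probs))]
            attrs: tuple[Attribute, ...] = ()
            if rng.random() < 0.2:
                attrs = (_card("severity", "high" if rng.random() < 0.5 else "low"),)
            phems.append(Pathophem(s, attrs, grade, lex[s].class_code))
        if rng.random() < spec.not_fraction:
            remaining = [c for c in term_codes if c not in subjects]
            s = remaining[int(rng.integers(0, len(remaining)))]
            phems.append(Pathophem(s, (), "NOT", lex[s].class_code))
        parent = None
        if spec.tree_depth > 0 and i > 0 and rng.random() < 0.3:
            cand = pids[int(rng.integers(0, i))]
            if depth.get(cand, 0) < spec.tree_depth:
                parent = cand
        depth[pid] = depth.get(parent, -1) + 1 if parent else 0
        pool[pid] = Pathosom(pid, f"random pathosom {i:03d}", phems, parent=parent)
        if parent:
            pool[parent].children.append(pid)

    return _normalize(KnowledgeBase(lex, pool, net))


def generate_patient(pathosom_id: str, kb: KnowledgeBase, sensitivity: float,
                     seed: int) -> SyntheticPatient:
    """Emit a synthetic patient vector from a disease prototype.

    Each non-excluding pathophem is emitted independently with probability
    ``sensitivity x grade weight`` (explicit probabilities override the
    grade midpoint); the emitted set is truncated to the five
    highest-grade findings. Deterministic given the seed.
    """
    if not 0 <= sensitivity <= 1:
        raise ValueError("sensitivity must lie in [0, 1]")
    p = kb.pathosoms[pathosom_id]
    rng = np.random.default_rng(seed)
    emitted = [
        pp for pp in p.pathophems
        if pp.grade != "NOT" and rng.random() < sensitivity * pp.weight()
    ]
    if not emitted:
        raise ValueError(
            f"no pathophem of {pathosom_id} was emitted "
            f"(sensitivity {sensitivity})"
        )
    emitted.sort(key=lambda pp: (-pp.weight(), pp.subject))
    elements = tuple(
        QueryElement(pp.subject, pp.attributes, resolved=True)
        for pp in emitted[:5]
    )
    return SyntheticPatient(pathosom_id, PatientVector(elements), sensitivity)


def lead_emission_frequency(kb: KnowledgeBase, pathosom_id: str, subject: str,
                            sensitivity: float, replicates: int, seed: int) -> float:
    """Fraction of replicate patients containing ``subject`` — a Monte-Carlo
    check of the emission probabilities."""
    count = 0
    for r in range(replicates):
        try:
            pat = generate_patient(pathosom_id, kb, sensitivity, seed + r)
        except ValueError:
            continue
        if any(el.term == subject for el in pat.vector.elements):
            count += 1
    return count / replicates
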