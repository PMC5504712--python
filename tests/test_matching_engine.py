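"""Verification, strict matching, ranking, roll-up, relaxation, dialogue."""

import numpy as np
import pytest

from _helpers import brute_force_match
from pathosom.fixtures import (
    PAPER_CASE_QUERIES,
    build_paper_cases_kb,
    generate_patient,
)
from pathosom.knowledge_model import Attribute, lookup_class, Pathophem, Pathosom
from pathosom.matching_engine import (
    EmptyQueryError,
    NothingToAskError,
    PatientVector,
    QueryConfig,
    QueryElement,
    VerificationIssue,
    broaden,
    dialogue,
    drop_attribute,
    evaluate_cases,
    match_strict,
    narrow_suggest,
    rank,
    roll_up,
    run_query,
    verify_vector,
)


def _resolved(kb, pv):
    out = verify_vector(pv, kb)
    assert isinstance(out, PatientVector), out
    return out


def _random_query(rng, kb, k=None):
    codes = sorted(kb.lexicon)
    k = k or int(rng.integers(1, 4))
    picks = [codes[i] for i in rng.choice(len(codes), size=k, replace=False)]
    elements = []
    for c in picks:
        attrs = ()
        if rng.random() < 0.25:
            attrs = (Attribute("cardinal", "severity",
                               "high" if rng.random() < 0.5 else "low"),)
        elements.append(QueryElement(c, attrs, resolved=True))
    return PatientVector(tuple(elements))


# --- verification ----------------------------------------------------------

def test_case1_surfaces_resolve_fully(paper_kb):
    pv = _resolved(paper_kb, PAPER_CASE_QUERIES["case1"])
    assert [e.term for e in pv.elements] == ["F001", "F002", "F003"]
    assert all(e.resolved for e in pv.elements)


def test_unresolvable_surface_reports_issue_with_suggestions(paper_kb):
    out = verify_vector(
        PatientVector((QueryElement("anemia"), QueryElement("frobnitz"))), paper_kb
    )
    assert isinstance(out, list) and isinstance(out[0], VerificationIssue)
    assert out[0].kind == "unresolvable"


def test_vector_arity_limits_enforced():
    with pytest.raises(ValueError):
        PatientVector(tuple(QueryElement(str(i)) for i in range(6)))
    with pytest.raises(ValueError):
        PatientVector(())
    with pytest.raises(ValueError):
        PatientVector((QueryElement(
            "1", tuple(Attribute("cardinal", f"a{i}", "x") for i in range(4))),))


def test_fully_unresolvable_query_raises(paper_kb):
    with pytest.raises(EmptyQueryError):
        verify_vector(PatientVector((QueryElement("qqqq"),)), paper_kb)


# --- strict matching -------------------------------------------------------

def test_strict_match_equals_brute_force_on_random_kbs(random_kb_factory):
    """match_strict agrees with a direct set comprehension over all
    pathosoms on small random KBs (<= 20 pathosoms, <= 15 terms)."""
    rng = np.random.default_rng(42)
    for seed in range(12):
        kb = random_kb_factory(seed, n_pathosoms=20, n_terms=15,
                               pathophems_per_pathosom=(2, 5))
        for _ in range(6):
            pv = _random_query(rng, kb)
            assert match_strict(pv, kb) == brute_force_match(pv, kb)


def test_not_graded_pathophem_excludes_otherwise_perfect_match(paper_kb):
    # benign breast tumor carries NOT metastasis; an explicit metastasis
    # element bars it even though the nodule evidence matches
    pv = _resolved(paper_kb, PatientVector((
        QueryElement("nodule", (Attribute("cardinal", "site", "mamma"),)),
        QueryElement("metastasis"),
    )))
    assert "F213" not in match_strict(pv, paper_kb)
    pv2 = _resolved(paper_kb, PatientVector((
        QueryElement("nodule", (Attribute("cardinal", "site", "mamma"),)),)))
    assert "F213" in match_strict(pv2, paper_kb)


def test_conjunction_monotonicity_and_not_safety(random_kb_factory):
    """Adding a query element never enlarges the strict result set, and no
    ranked result is NOT-excluded (200 random KB/query pairs)."""
    rng = np.random.default_rng(2024)
    for i in range(200):
        kb = random_kb_factory(i % 8, n_pathosoms=15, n_terms=12,
                               pathophems_per_pathosom=(2, 5))
        pv = _random_query(rng, kb, k=int(rng.integers(1, 4)))
        base = match_strict(pv, kb)
        if len(pv.elements) < 5:
            extra = _random_query(rng, kb, k=1).elements[0]
            grown = PatientVector(pv.elements + (extra,))
            assert match_strict(grown, kb) <= base
        for r in rank(base, pv, kb):
            assert r.excluded_by is None


def test_synonym_closure_matches_across_codes(paper_kb):
    pv = _resolved(paper_kb, PatientVector((
        QueryElement("proteinuria"), QueryElement("hematuria"),
        QueryElement("pyrexia"),  # resolves to F404, synonym of fever F403
    )))
    assert pv.elements[2].term == "F404"
    assert {p for p in match_strict(pv, paper_kb)} == {
        "F461", "F462", "F463", "F464", "F465", "F466", "F467", "F468"}


# --- ranking ---------------------------------------------------------------

def test_all_lead_matches_score_one(paper_kb):
    pv = _resolved(paper_kb, PAPER_CASE_QUERIES["case3"])
    results = rank(match_strict(pv, paper_kb), pv, paper_kb)
    assert results and all(r.score == pytest.approx(1.0) for r in results)
    assert [r.pathosom_id for r in results] == ["F311", "F313", "F316"]


def test_higher_grades_rank_first():
    cls = lookup_class(5400)
    term_kb = build_paper_cases_kb()
    strong = Pathosom("P9001", "strong", [Pathophem("F301", (), "+++", cls)])
    weak = Pathosom("P9002", "weak", [Pathophem("F301", (), "+", cls)])
    term_kb.pathosoms.update({"P9001": strong, "P9002": weak})
    pv = PatientVector((QueryElement("F301", (), True),))
    results = rank({"P9001", "P9002"}, pv, term_kb)
    assert [r.pathosom_id for r in results] == ["P9001", "P9002"]
    assert results[0].score > results[1].score


def test_rank_of_empty_candidate_set_is_empty(paper_kb):
    pv = _resolved(paper_kb, PAPER_CASE_QUERIES["case1"])
    assert rank(set(), pv, paper_kb) == []


def test_score_is_deterministic(paper_kb):
    pv = _resolved(paper_kb, PAPER_CASE_QUERIES["case4"])
    a = rank(match_strict(pv, paper_kb), pv, paper_kb)
    b = rank(match_strict(pv, paper_kb), pv, paper_kb)
    assert [(r.pathosom_id, r.score) for r in a] == [(r.pathosom_id, r.score) for r in b]


# --- roll-up ---------------------------------------------------------------

def test_equal_evidence_subtree_collapses_to_most_general(paper_kb):
    pv = _resolved(paper_kb, PAPER_CASE_QUERIES["case1"])
    ranked = rank(match_strict(pv, paper_kb), pv, paper_kb)
    assert {r.pathosom_id for r in ranked} == {"M3501", "M35011", "M35012", "M35013"}
    assert [r.pathosom_id for r in roll_up(ranked, paper_kb)] == ["M3501"]


def test_parent_and_child_with_different_evidence_both_retained():
    kb = build_paper_cases_kb()
    cls = lookup_class(5400)
    parent = Pathosom("P920", "broad", [Pathophem("F301", (), "Lead", cls)],
                      children=["P921"])
    child = Pathosom("P921", "narrow",
                     [Pathophem("F301", (), "Lead", cls),
                      Pathophem("F303", (), "Lead", cls)], parent="P920")
    kb.pathosoms.update({"P920": parent, "P921": child})
    pv = PatientVector((QueryElement("F301", (), True), QueryElement("F303", (), True)))
    ranked = rank({"P920", "P921"}, pv, kb)
    # parent matched {0} only, child matched {0, 1}: unequal evidence
    assert {r.pathosom_id for r in roll_up(ranked, kb)} == {"P920", "P921"}


def test_equal_evidence_branch_collapses_across_meckel_tree(paper_kb):
    # every Meckel entity matching {renal cyst, encephalocele} does so with
    # the same two-element evidence, so only the root survives roll-up
    pv = _resolved(paper_kb, PatientVector((
        QueryElement("renal cyst"), QueryElement("encephalocele"))))
    ranked = rank(match_strict(pv, paper_kb), pv, paper_kb)
    assert {r.pathosom_id for r in ranked} >= {"F300", "F312"}
    assert {r.pathosom_id for r in roll_up(ranked, paper_kb)} == {"F300"}


def test_roll_up_is_identity_without_tree_links(random_kb_factory):
    kb = random_kb_factory(5, n_pathosoms=8, n_terms=10, tree_depth=0)
    rng = np.random.default_rng(1)
    pv = _random_query(rng, kb, k=1)
    ranked = rank(match_strict(pv, kb), pv, kb)
    assert roll_up(ranked, kb) == ranked


# --- broadening ------------------------------------------------------------

def test_dropping_firm_admits_exactly_six_breast_pathosoms(paper_kb):
    pv = _resolved(paper_kb, PAPER_CASE_QUERIES["case2"])
    strict = match_strict(pv, paper_kb)
    assert strict == {"F210"}
    relaxed = match_strict(drop_attribute(pv, "firm"), paper_kb)
    assert relaxed - strict == {"F211", "F212", "F213", "F214", "F215", "F216"}


def test_forced_stage1_broadening_traces_each_drop(paper_kb):
    pv = _resolved(paper_kb, PAPER_CASE_QUERIES["case2"])
    cands, trace = broaden(pv, paper_kb, QueryConfig(), force=True)
    assert len(cands) == 7
    assert any("consistency" in t and "firm" in t for t in trace)


def test_generalization_stage_reaches_hand_level_disease(paper_kb):
    pv = _resolved(paper_kb, PatientVector((QueryElement("finger swelling"),)))
    assert match_strict(pv, paper_kb) == set()
    cands, trace = broaden(pv, paper_kb, QueryConfig())
    assert cands == {"F510"}
    assert any("generalize" in t for t in trace)


def test_broadening_skipped_when_strict_result_sufficient(paper_kb):
    pv = _resolved(paper_kb, PAPER_CASE_QUERIES["case1"])
    cands, trace = broaden(pv, paper_kb, QueryConfig())
    assert cands == match_strict(pv, paper_kb) and trace == []


def test_broadened_set_is_superset_of_strict(random_kb_factory):
    rng = np.random.default_rng(77)
    for i in range(30):
        kb = random_kb_factory(i % 6, n_pathosoms=15, n_terms=12)
        pv = _random_query(rng, kb)
        strict = match_strict(pv, kb)
        cands, _ = broaden(pv, kb, QueryConfig(), force=True)
        assert strict <= cands


# --- narrowing -------------------------------------------------------------

def _mini_kb_for_narrowing():
    kb = build_paper_cases_kb()
    cls = lookup_class(5400)
    # 4 candidates; finding F303 occurs in 2 of 4 (perfect split), F304 in 4
    for i, extra in enumerate(["F303", "F303", None, None]):
        phems = [Pathophem("F301", (), "Lead", cls), Pathophem("F304", (), "++", cls)]
        if extra:
            phems.append(Pathophem(extra, (), "+++", cls))
        kb.pathosoms[f"P91{i}"] = Pathosom(f"P91{i}", f"narrow {i}", phems)
    return kb


def test_narrow_picks_most_discriminating_split():
    kb = _mini_kb_for_narrowing()
    cands = {"P910", "P911", "P912", "P913"}
    pv = PatientVector((QueryElement("F301", (), True),))
    subject, _ = narrow_suggest(cands, pv, kb)
    assert subject == "F303"  # |2-2| beats |4-2|


def test_narrow_tie_breaks_by_grade_weight():
    kb = _mini_kb_for_narrowing()
    cls = lookup_class(5400)
    for i in range(4):  # add a second universal finding with higher grade
        kb.pathosoms[f"P91{i}"].pathophems.append(
            Pathophem("F305", (), "Lead", cls))
    cands = {"P910", "P911", "P912", "P913"}
    pv = PatientVector((QueryElement("F301", (), True),))
    subject, _ = narrow_suggest(cands, pv, kb, skip=frozenset({"F303"}))
    assert subject == "F305"  # equal split distance, Lead beats ++


def test_narrow_single_candidate_errors(paper_kb):
    pv = PatientVector((QueryElement("F001", (), True),))
    with pytest.raises(NothingToAskError):
        narrow_suggest({"M3501"}, pv, paper_kb)


# --- dialogue --------------------------------------------------------------

def test_case1_dialogue_terminates_without_questions(paper_kb):
    results, transcript = dialogue(
        PAPER_CASE_QUERIES["case1"], paper_kb, QueryConfig(),
        answer_provider=lambda s, a: pytest.fail("no question expected"))
    assert [r.pathosom_id for r in results] == ["M3501"]
    assert transcript == []


def test_always_na_dialogue_terminates_with_best_ranking(paper_kb):
    pv = PatientVector((QueryElement("proteinuria"), QueryElement("hematuria")))
    results, transcript = dialogue(pv, paper_kb, QueryConfig(),
                                   answer_provider=lambda s, a: "NA")
    assert results  # exhausted questions, still reports candidates
    assert transcript[-1] == "narrow: exhausted"


def test_dialogue_replay_equivalence_for_case4(paper_kb):
    """Answering the fever question TRUE equals the direct 3-term query."""
    pv2 = PatientVector((QueryElement("proteinuria"), QueryElement("hematuria")))
    provider = lambda code, attrs: "TRUE" if code == "F403" else "NA"
    via_dialogue, _ = dialogue(pv2, paper_kb, QueryConfig(), provider)
    direct = run_query(PAPER_CASE_QUERIES["case4"], paper_kb, QueryConfig())
    assert [r.pathosom_id for r in via_dialogue] == [r.pathosom_id for r in direct]


def test_false_answer_excludes_only_lead_bound_candidates(paper_kb):
    pv2 = PatientVector((QueryElement("proteinuria"), QueryElement("hematuria")))
    seen = []

    def provider(code, attrs):
        seen.append(code)
        return "FALSE" if code == "F403" else "NA"

    results, transcript = dialogue(pv2, paper_kb, QueryConfig(), provider)
    ids = {r.pathosom_id for r in results}
    # every fever pathosom carries fever at Lead -> all excluded
    assert "F403" in seen
    assert not ids & {"F461", "F462", "F463", "F464", "F465", "F466", "F467", "F468"}


def test_dialogue_is_deterministic(paper_kb):
    pv = PatientVector((QueryElement("proteinuria"), QueryElement("hematuria")))
    provider = lambda code, attrs: "NA"
    r1, t1 = dialogue(pv, paper_kb, QueryConfig(), provider)
    r2, t2 = dialogue(pv, paper_kb, QueryConfig(), provider)
    assert t1 == t2
    assert [(r.pathosom_id, r.score) for r in r1] == [(r.pathosom_id, r.score) for r in r2]


# --- evaluation harness ----------------------------------------------------

def test_generated_cases_at_full_sensitivity_identify_their_source(random_kb_factory):
    kb = random_kb_factory(21)
    cases = []
    for i, pid in enumerate(sorted(kb.pathosoms)):
        try:
            pat = generate_patient(pid, kb, 1.0, 1000 + i)
        except ValueError:
            continue
        cases.append((pat.vector, pid))
    assert len(cases) >= 10
    report = evaluate_cases(cases, kb)
    assert report["identification_rate"] == 1.0


def test_median_proposal_count_uses_lower_middle(paper_kb):
    cases = [
        (PAPER_CASE_QUERIES["case1"], "M3501"),   # 1 proposal
        (PAPER_CASE_QUERIES["case4"], "F461"),    # 8 proposals
    ]
    report = evaluate_cases(cases, paper_kb)
    assert report["median_proposal_count"] == 1
    assert report["identification_rate"] == 1.0


def test_unmatchable_expectation_gives_zero_rate(paper_kb):
    report = evaluate_cases(
        [(PAPER_CASE_QUERIES["case1"], "F510")], paper_kb)
    assert report["identification_rate"] == 0.0
    assert report["cases"][0]["identified"] is False
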