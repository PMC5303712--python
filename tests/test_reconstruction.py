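"""Draft extraction, GPR semantics, dead-end analysis and gap filling."""

import pytest
from hypothesis import given, settings, strategies as st

import astromet as am
from astromet.model import Metabolite, Reaction
from astromet.reconstruction import (
    ExpressionEvidence,
    GPRSyntaxError,
    ReferenceReactionDB,
    add_transport_and_exchange,
    apply_gap_fill,
    evaluate_gpr,
    extract_draft_network,
    find_dead_ends,
    suggest_gap_fills,
)
from astromet.synth import GeneratorSpec, make_deadend_fixture, make_expression_fixture, make_gapfill_db


# ---------------------------------------------------------------------------
# GPR evaluation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "gpr,present,expected",
    [
        ("(g1 and g2) or g3", {"g1", "g3"}, True),
        ("(g1 and g2) or g3", {"g1"}, False),
        ("(g1 and g2) or g3", {"g1", "g2"}, True),
        ("g1 and g2", {"g1"}, False),
        ("g1 or g2", {"g2"}, True),
        ("g1", set(), False),
        ("", {"g1"}, False),
        ("g1 and (g2 or g3) and g4", {"g1", "g3", "g4"}, True),
        ("g1 and (g2 or g3) and g4", {"g1", "g3"}, False),
    ],
)
def test_gpr_boolean_semantics(gpr, present, expected):
    assert evaluate_gpr(gpr, present) is expected


@pytest.mark.parametrize("bad", ["g1 and", "and g1", "(g1", "g1 g2", "g1 or or g2"])
def test_gpr_syntax_errors(bad):
    with pytest.raises(GPRSyntaxError):
        evaluate_gpr(bad, {"g1", "g2"})


@st.composite
def gpr_expressions(draw, depth=0):
    genes = ["gA", "gB", "gC", "gD"]
    if depth >= 3 or draw(st.booleans()):
        return draw(st.sampled_from(genes))
    left = draw(gpr_expressions(depth=depth + 1))
    right = draw(gpr_expressions(depth=depth + 1))
    op = draw(st.sampled_from(["and", "or"]))
    return f"({left} {op} {right})"


@settings(max_examples=80, deadline=None)
@given(gpr=gpr_expressions(), present=st.sets(st.sampled_from(["gA", "gB", "gC", "gD"])))
def test_gpr_evaluation_matches_cobra_oracle(gpr, present):
    """Our recursive-descent evaluator agrees with cobrapy's GPR engine."""
    from cobra.core.gene import GPR

    oracle = GPR.from_string(gpr)
    all_genes = {"gA", "gB", "gC", "gD"}
    expected = oracle.eval(knockouts=all_genes - present)
    assert evaluate_gpr(gpr, present) == expected


# ---------------------------------------------------------------------------
# Draft extraction
# ---------------------------------------------------------------------------


def test_extraction_upper_and_lower_bounds():
    evidence, db_model, _expected = make_expression_fixture()
    db = ReferenceReactionDB(db_model)
    all_genes = {g: True for g in db_model.genes}
    draft = extract_draft_network(ExpressionEvidence.from_mapping(all_genes), db)
    gpr_bearing = {r for r, rxn in db_model.reactions.items() if rxn.gpr.strip()}
    assert set(draft.reactions) == gpr_bearing
    empty = extract_draft_network(
        ExpressionEvidence.from_mapping({g: False for g in db_model.genes}), db
    )
    assert len(empty.reactions) == 0


def test_extraction_reproduces_designed_fixture():
    evidence, db_model, expected = make_expression_fixture()
    db = ReferenceReactionDB(db_model)
    draft = extract_draft_network(ExpressionEvidence.from_mapping(evidence), db)
    assert set(draft.reactions) == expected
    assert am.validate(draft) == []


def test_extraction_with_score_threshold_matches_calls():
    evidence, db_model, expected = make_expression_fixture()
    db = ReferenceReactionDB(db_model)
    # scores were drawn so that >=150 reproduces the boolean calls
    draft = extract_draft_network(
        ExpressionEvidence.from_mapping(evidence), db, threshold=150.0
    )
    assert set(draft.reactions) == expected


def test_extraction_is_monotone_in_presence_calls():
    _evidence, db_model, _expected = make_expression_fixture()
    db = ReferenceReactionDB(db_model)
    genes = sorted(db_model.genes)
    import numpy as np

    rng = np.random.default_rng(7)
    for _ in range(5):
        base = set(rng.choice(genes, size=len(genes) // 2, replace=False))
        more = base | set(rng.choice(genes, size=10, replace=False))
        small = extract_draft_network(
            ExpressionEvidence.from_mapping({g: (g in base) for g in genes}), db
        )
        large = extract_draft_network(
            ExpressionEvidence.from_mapping({g: (g in more) for g in genes}), db
        )
        assert set(small.reactions) <= set(large.reactions)


def test_complex_with_one_absent_subunit_is_excluded():
    _evidence, db_model, _expected = make_expression_fixture()
    db = ReferenceReactionDB(db_model)
    genes = {g: True for g in db_model.genes}
    genes["PDHA1"] = False  # one subunit of the pyruvate dehydrogenase complex
    draft = extract_draft_network(ExpressionEvidence.from_mapping(genes), db)
    assert "PDH" not in draft.reactions
    assert "LDH" in draft.reactions  # isozyme rule still satisfied


# ---------------------------------------------------------------------------
# Dead-end detection vs brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_dead_ends(model):
    """Independent oracle: per metabolite, scan all reactions and bounds."""
    result = {}
    has_exchange_somewhere = any(
        am.classify_reaction(model, rid) == "exchange" for rid in model.reactions
    )
    import networkx as nx

    from astromet.model import metabolite_graph

    graph = metabolite_graph(model)
    ex_mets = set()
    for rid in model.reactions:
        if am.classify_reaction(model, rid) == "exchange":
            for mid in model.reactions[rid].stoichiometry:
                met = model.metabolites.get(mid)
                if met is not None and met.compartment != "b":
                    ex_mets.add(mid)
    comp_of = {}
    for comp in nx.connected_components(graph):
        ok = bool(comp & ex_mets)
        for mid in comp:
            comp_of[mid] = ok
    for mid, met in model.metabolites.items():
        if met.compartment == "b":
            continue
        produced = consumed = False
        for rxn in model.reactions.values():
            coef = rxn.stoichiometry.get(mid, 0.0)
            if coef > 0 and rxn.upper_bound > 0:
                produced = True
            if coef < 0 and rxn.lower_bound < 0:
                produced = True
            if coef < 0 and rxn.upper_bound > 0:
                consumed = True
            if coef > 0 and rxn.lower_bound < 0:
                consumed = True
        if not produced:
            result[mid] = "never_produced"
        elif not consumed:
            result[mid] = "never_consumed"
        elif has_exchange_somewhere and not comp_of.get(mid, True):
            result[mid] = "disconnected"
    return result


def small_adversarial_models():
    models = {}

    m = am.MetabolicModel()
    for mid in ("A__c", "B__c", "C__c"):
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("EX_A", {"A__c": -1.0}, lower_bound=-10.0))
    m.add_reaction(Reaction("R1", {"A__c": -1.0, "B__c": 1.0}))
    m.add_reaction(Reaction("R2", {"B__c": -1.0, "C__c": 1.0}))
    models["linear_chain_no_C_sink"] = m

    m = am.MetabolicModel()
    for mid in ("A__c", "B__c"):
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("R", {"A__c": -1.0, "B__c": 1.0}, lower_bound=-1000.0))
    models["reversible_pair_only"] = m

    m = am.MetabolicModel()
    for mid in ("A__c", "B__c"):
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("EX_A", {"A__c": -1.0}, lower_bound=-10.0))
    m.add_reaction(Reaction("RZ", {"A__c": -1.0, "B__c": 1.0},
                            lower_bound=0.0, upper_bound=0.0))  # pinned to zero
    models["zero_bound_cannot_rescue"] = m

    m = am.MetabolicModel()
    for mid in ("A__c", "B__c", "P__c", "Q__c"):
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("EX_A", {"A__c": -1.0}, lower_bound=-10.0))
    m.add_reaction(Reaction("R1", {"A__c": -1.0, "B__c": 1.0}, lower_bound=-1000.0))
    m.add_reaction(Reaction("ISO", {"P__c": -1.0, "Q__c": 1.0}, lower_bound=-1000.0))
    models["isolated_fragment"] = m
    return models


@pytest.mark.parametrize("name", list(small_adversarial_models()))
def test_dead_end_detector_equals_brute_force_on_small_models(name):
    model = small_adversarial_models()[name]
    report = find_dead_ends(model)
    oracle = brute_force_dead_ends(model)
    assert {e.metabolite: e.kind for e in report.entries} == oracle


def test_dead_end_detector_equals_brute_force_on_fixtures(core_model):
    for model in (core_model, make_deadend_fixture(GeneratorSpec(n_deadends=4))[0]):
        report = find_dead_ends(model)
        oracle = brute_force_dead_ends(model)
        assert {e.metabolite: e.kind for e in report.entries} == oracle


def test_linear_chain_flags_terminal_metabolite():
    model = small_adversarial_models()["linear_chain_no_C_sink"]
    report = find_dead_ends(model)
    assert {e.metabolite: e.kind for e in report.entries} == {"C__c": "never_consumed"}


def test_reversible_pair_is_not_a_dead_end():
    model = small_adversarial_models()["reversible_pair_only"]
    assert len(find_dead_ends(model)) == 0


def test_report_is_sorted_and_classes_counted():
    model, truth = make_deadend_fixture(GeneratorSpec(n_deadends=3))
    report = find_dead_ends(model)
    assert report.metabolites == sorted(report.metabolites) == truth
    assert report.summary == {"never_consumed": 3}


# ---------------------------------------------------------------------------
# Gap-fill suggestions
# ---------------------------------------------------------------------------


def test_gap_fill_ranking_prefers_no_new_metabolites():
    model, truth = make_deadend_fixture(GeneratorSpec(n_deadends=1))
    db = ReferenceReactionDB(make_gapfill_db(GeneratorSpec(n_deadends=1)))
    report = find_dead_ends(model)
    suggestions = suggest_gap_fills(report, db)
    (s,) = suggestions
    assert s.metabolite == truth[0]
    assert s.candidates[0] == ("FIX1", 0)       # consumes into the existing network
    assert s.candidates[1] == ("ZFIX1", 1)      # decoy introduces a new metabolite


def test_gap_fill_tie_broken_lexicographically():
    db_model = am.MetabolicModel()
    for mid in ("C__c", "D__c"):
        db_model.add_metabolite(Metabolite(mid, compartment="c"))
    db_model.add_reaction(Reaction("B_FIX", {"C__c": -1.0, "D__c": 1.0}))
    db_model.add_reaction(Reaction("A_FIX", {"C__c": -1.0, "D__c": 1.0}))
    model = small_adversarial_models()["linear_chain_no_C_sink"]
    model.add_metabolite(Metabolite("D__c", compartment="c"))
    model.add_reaction(Reaction("EX_D", {"D__c": -1.0}))
    report = find_dead_ends(model)
    suggestions = suggest_gap_fills(report, ReferenceReactionDB(db_model))
    assert [rid for rid, _ in suggestions[0].candidates] == ["A_FIX", "B_FIX"]


def test_no_candidate_yields_reason():
    model = small_adversarial_models()["linear_chain_no_C_sink"]
    empty_db = ReferenceReactionDB(am.MetabolicModel())
    with pytest.raises(ValueError):
        extract_draft_network(ExpressionEvidence(), empty_db)
    db_model = am.MetabolicModel()
    db_model.add_metabolite(Metabolite("X__c", compartment="c"))
    db_model.add_metabolite(Metabolite("Y__c", compartment="c"))
    db_model.add_reaction(Reaction("R", {"X__c": -1.0, "Y__c": 1.0}))
    suggestions = suggest_gap_fills(find_dead_ends(model), ReferenceReactionDB(db_model))
    assert suggestions[0].candidates == []
    assert "no producing or consuming" in suggestions[0].reason


def test_iterative_top_candidate_repair_clears_designed_gaps():
    spec = GeneratorSpec(n_deadends=3)
    model, truth = make_deadend_fixture(spec)
    db = ReferenceReactionDB(make_gapfill_db(spec))
    for _ in range(spec.n_deadends):  # within k iterations
        report = find_dead_ends(model)
        if not report.entries:
            break
        suggestions = suggest_gap_fills(report, db)
        for s in suggestions:
            if s.candidates and s.candidates[0][0] not in model.reactions:
                model = apply_gap_fill(model, db, s.candidates[0][0])
    assert len(find_dead_ends(model)) == 0


# ---------------------------------------------------------------------------
# Transport/exchange completion
# ---------------------------------------------------------------------------


def completion_scenario():
    model = am.MetabolicModel()
    model.add_metabolite(Metabolite("glc__x", compartment="x"))
    model.add_metabolite(Metabolite("glc__c", compartment="c"))
    model.add_metabolite(Metabolite("g6p__c", compartment="c"))
    model.add_reaction(Reaction("HEX", {"glc__c": -1.0, "g6p__c": 1.0}))
    db_model = am.MetabolicModel()
    db_model.add_metabolite(Metabolite("glc__x", compartment="x"))
    db_model.add_metabolite(Metabolite("glc__c", compartment="c"))
    db_model.add_reaction(Reaction("GLCt", {"glc__x": -1.0, "glc__c": 1.0},
                                   lower_bound=-1000.0))
    return model, ReferenceReactionDB(db_model)


def test_completion_copies_missing_transporter_and_creates_exchange():
    model, db = completion_scenario()
    cond = am.Condition("c", {"EX_glc": (-0.16, None)})
    out, log = add_transport_and_exchange(model, db, cond)
    assert "GLCt" in out.reactions
    assert "EX_glc" in out.reactions
    assert all(entry["tag"] == "completion" for entry in log)
    actions = {entry["action"] for entry in log}
    assert actions == {"add_transport", "add_exchange"}


def test_completion_is_idempotent():
    model, db = completion_scenario()
    cond = am.Condition("c", {"EX_glc": (-0.16, None)})
    once, _ = add_transport_and_exchange(model, db, cond)
    twice, log = add_transport_and_exchange(once, db, cond)
    assert list(twice.reactions) == list(once.reactions)
    assert [e for e in log if e["action"] != "unconnectable"] == []


def test_unconnectable_species_is_logged_not_fatal():
    model, _ = completion_scenario()
    empty_db = ReferenceReactionDB(am.MetabolicModel())
    out, log = add_transport_and_exchange(model, empty_db, am.Condition("c"))
    assert any(e["action"] == "unconnectable" and "glc" in e["species"] for e in log)
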