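"""Conditions, FBA, objectives, sampling and the differential-flux Z statistic."""

import warnings

import numpy as np
import pytest

import astromet as am
from astromet.model import Metabolite, Reaction
from astromet.simulation import (
    Condition,
    InfeasibleError,
    ObjectiveFunction,
    SampleSet,
    apply_condition,
    make_ischemia_grid,
    make_astrocyte_objectives,
    run_fba,
    sample_flux_space,
    sweep_glutamate,
    zscore_compare,
)


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------


def test_condition_sets_glutamate_uptake_bound(core_model, constrained_core):
    assert constrained_core.reactions["EX_glu"].lower_bound == pytest.approx(-0.232)
    assert constrained_core.reactions["EX_o2"].lower_bound == pytest.approx(-0.530)
    assert constrained_core.reactions["EX_glc"].lower_bound == pytest.approx(-0.490)
    # only overridden bounds differ from the base model
    assert core_model.reactions["EX_glu"].lower_bound == -1000.0


def test_empty_condition_is_identity(core_model):
    out = apply_condition(core_model, Condition("noop"))
    for rid in core_model.reactions:
        assert out.reactions[rid].lower_bound == core_model.reactions[rid].lower_bound
        assert out.reactions[rid].upper_bound == core_model.reactions[rid].upper_bound


def test_non_exchange_override_warns_and_is_skipped(core_model):
    cond = Condition("bad", {"HEX1": (-1.0, 1.0)})
    with pytest.warns(UserWarning, match="not an exchange"):
        out = apply_condition(core_model, cond)
    assert out.reactions["HEX1"].lower_bound == core_model.reactions["HEX1"].lower_bound


def test_unknown_exchange_override_warns(core_model):
    with pytest.warns(UserWarning, match="no reaction"):
        apply_condition(core_model, Condition("x", {"EX_unobtainium": (-1.0, None)}))


def test_ischemia_grid_scales_uptake_magnitudes(excitatory):
    grid = make_ischemia_grid(excitatory, steps=[1.0, 0.8, 0.0])
    lo_full, _ = grid[0].overrides["EX_o2"]
    lo_08, _ = grid[1].overrides["EX_o2"]
    lo_0, _ = grid[2].overrides["EX_o2"]
    assert lo_full == pytest.approx(-0.530)
    assert lo_08 == pytest.approx(-0.424)
    assert lo_0 == 0.0
    assert grid[2].overrides["EX_glc"][0] == 0.0
    # unrelated bounds are inherited
    assert grid[1].overrides["EX_glu"] == excitatory.overrides["EX_glu"]


def test_ischemia_fraction_outside_unit_interval_is_an_error(excitatory):
    with pytest.raises(ValueError):
        make_ischemia_grid(excitatory, steps=[1.2])


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def chain_model(uptake_ub=5.0):
    m = am.MetabolicModel()
    for mid in ("A__x", "A__c", "B__c", "B__x"):
        m.add_metabolite(Metabolite(mid, compartment=mid.rsplit("__", 1)[1]))
    m.add_reaction(Reaction("EX_A", {"A__x": -1.0}, lower_bound=-uptake_ub))
    m.add_reaction(Reaction("T_A", {"A__x": -1.0, "A__c": 1.0}))
    m.add_reaction(Reaction("R", {"A__c": -1.0, "B__c": 1.0}))
    m.add_reaction(Reaction("T_B", {"B__c": -1.0, "B__x": 1.0}))
    m.add_reaction(Reaction("EX_B", {"B__x": -1.0}))
    return m


def test_hand_lp_chain_optimum_is_uptake_capacity():
    res = run_fba(chain_model(5.0), [ObjectiveFunction("export", {"EX_B": 1.0})])
    assert res.status == "optimal"
    assert res.objective_value == pytest.approx(5.0)
    assert res.fluxes["R"] == pytest.approx(5.0)


def test_all_exchanges_closed_gives_zero_atp(core_model):
    cond = Condition("closed", {
        rid: (0.0, 0.0) for rid in core_model.reactions if rid.startswith("EX_")
    })
    m = apply_condition(core_model, cond)
    res = run_fba(m, make_astrocyte_objectives(m))
    assert res.status == "optimal"
    assert res.objective_values["atp_production"] == pytest.approx(0.0, abs=1e-8)


def test_infeasible_problem_reports_status_without_fluxes():
    m = chain_model()
    # force export of B while shutting the only source of A
    m.reactions["EX_A"].lower_bound = 0.0
    m.reactions["EX_B"].lower_bound = 1.0
    res = run_fba(m, [ObjectiveFunction("export", {"EX_B": 1.0})])
    assert res.status == "infeasible"
    assert res.fluxes == {}
    assert res.objective_value is None


def test_fba_optimum_invariant_to_reaction_order(constrained_core, astrocyte_objectives):
    res = run_fba(constrained_core, astrocyte_objectives)
    shuffled = am.MetabolicModel(compartments=constrained_core.compartments)
    for met in constrained_core.metabolites.values():
        shuffled.add_metabolite(Metabolite(met.id, met.name, met.compartment, met.formula))
    rids = list(constrained_core.reactions)
    rng = np.random.default_rng(3)
    for i in rng.permutation(len(rids)):
        r = constrained_core.reactions[rids[i]]
        shuffled.add_reaction(Reaction(r.id, dict(r.stoichiometry), lower_bound=r.lower_bound,
                                       upper_bound=r.upper_bound))
    res2 = run_fba(shuffled, astrocyte_objectives)
    assert res2.objective_value == pytest.approx(res.objective_value, abs=1e-6)


def test_parsimonious_flux_vector_is_reproducible(constrained_core, astrocyte_objectives):
    a = run_fba(constrained_core, astrocyte_objectives, parsimonious=True)
    b = run_fba(constrained_core, astrocyte_objectives, parsimonious=True)
    for rid in a.fluxes:
        assert a.fluxes[rid] == pytest.approx(b.fluxes[rid], abs=1e-6)


def test_fba_matches_cobra_oracle(core_model, excitatory, tmp_path):
    """Independent cross-check: cobrapy solves the same LP on our SBML export."""
    import cobra
    from astromet.io import ModelDocument, write_model

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = apply_condition(core_model, excitatory)
        objectives = make_astrocyte_objectives(m)
        ours = run_fba(m, objectives[:1], parsimonious=False)

        path = write_model(ModelDocument(m, "sbml"), tmp_path / "core.xml", "sbml")
        cm = cobra.io.read_sbml_model(str(path))
        cm.objective = cm.reactions.get_by_id("DM_atp")
        sol = cm.optimize()
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(ours.objective_value, rel=1e-6)


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------


def test_atp_synthase_carries_published_proton_stoichiometry(core_model):
    rxn = core_model.reactions["ATPS"]
    assert rxn.stoichiometry["h__c"] == -4.0   # 4 H+[c] consumed
    assert rxn.stoichiometry["h__m"] == 3.0    # 3 H+[m] produced
    assert rxn.stoichiometry["adp__m"] == -1.0
    assert rxn.stoichiometry["atp__m"] == 1.0
    assert rxn.stoichiometry["h2o__m"] == 1.0
    assert rxn.stoichiometry["pi__m"] == -1.0


def test_objective_reactions_classify_as_specified(core_model):
    m = core_model.copy()
    make_astrocyte_objectives(m)
    assert am.classify_reaction(m, "DM_atp") == "internal"
    assert am.classify_reaction(m, "GLUGLN_CYCLE") == "transport"


def test_missing_cycle_species_error_names_them(core_model):
    m = core_model.copy()
    # remove extracellular glutamine and every reaction touching it
    for rid in [r for r, x in m.reactions.items() if "gln__x" in x.stoichiometry]:
        del m.reactions[rid]
    del m.metabolites["gln__x"]
    with pytest.raises(KeyError, match="gln__x"):
        make_astrocyte_objectives(m)


def test_objective_requires_nonzero_coefficient():
    with pytest.raises(ValueError):
        ObjectiveFunction("null", {"R": 0.0})


def test_glutamine_cycle_capability_alone(constrained_core):
    """Maximising the cycle alone drives glutamine export at the glutamate rate."""
    m = constrained_core.copy()
    objectives = make_astrocyte_objectives(m)
    res = run_fba(m, [objectives[1]], parsimonious=True)
    assert res.status == "optimal"
    assert res.objective_value == pytest.approx(0.232, rel=1e-6)
    assert res.fluxes["EX_gln"] == pytest.approx(0.232, rel=1e-6)


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------


def test_sweep_zero_uptake_releases_no_glutamine(core_model, excitatory):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sweep_glutamate(core_model, excitatory, [0.0])
    assert table.loc[0, "status"] == "optimal"
    assert table.loc[0, "glutamine_release"] == pytest.approx(0.0, abs=1e-8)
    assert table.loc[0, "akg_production"] == pytest.approx(0.0, abs=1e-6)


def test_sweep_rejects_negative_uptake(core_model, excitatory):
    with pytest.raises(ValueError):
        sweep_glutamate(core_model, excitatory, [-0.1])


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def test_fully_pinned_polytope_yields_identical_samples():
    m = chain_model()
    for rxn in m.reactions.values():
        rxn.lower_bound = rxn.upper_bound = 2.0 * (-1.0 if rxn.id == "EX_A" else 1.0)
    m.reactions["EX_A"].lower_bound = m.reactions["EX_A"].upper_bound = -2.0
    ss = sample_flux_space(m, None, n_samples=5, seed=0)
    assert np.allclose(ss.samples, ss.samples[0])
    assert np.allclose(ss.var, 0.0)


def test_chain_samples_conserve_mass_and_stay_interior():
    m = chain_model(uptake_ub=1.0)
    ss = sample_flux_space(m, None, n_samples=200, seed=4)
    # conservation forces all chain fluxes equal within each sample
    for rid in ("T_A", "R", "T_B", "EX_B"):
        j = ss.reaction_ids.index(rid)
        i = ss.reaction_ids.index("EX_A")
        assert np.allclose(ss.samples[:, j], -ss.samples[:, i], atol=1e-6)
    uptake_mean = -ss.mean[ss.reaction_ids.index("EX_A")]
    assert 0.0 < uptake_mean < 1.0


def test_sampling_is_reproducible_given_seed(core_model, excitatory):
    a = sample_flux_space(core_model, excitatory, 20, seed=42)
    b = sample_flux_space(core_model, excitatory, 20, seed=42)
    assert np.array_equal(a.samples, b.samples)


def test_sampling_infeasible_condition_raises():
    m = chain_model()
    m.reactions["EX_B"].lower_bound = 10.0  # must export more than can be taken up
    with pytest.raises(InfeasibleError):
        sample_flux_space(m, None, 10, seed=0,
                          objective=ObjectiveFunction("e", {"EX_B": 1.0}))


def test_sampling_requires_two_samples(core_model, excitatory):
    with pytest.raises(ValueError):
        sample_flux_space(core_model, excitatory, 1, seed=0)


@pytest.mark.parametrize("method", ["achr", "corners"])
def test_samples_satisfy_balance_and_bounds(core_model, excitatory, method):
    ss = sample_flux_space(core_model, excitatory, 50, seed=9, method=method)
    mat = am.build_stoichiometric_matrix(apply_condition(core_model, excitatory))
    rid_order = [ss.reaction_ids.index(r) for r in mat.col_index]
    lb = np.array([apply_condition(core_model, excitatory).reactions[r].lower_bound
                   for r in ss.reaction_ids])
    ub = np.array([apply_condition(core_model, excitatory).reactions[r].upper_bound
                   for r in ss.reaction_ids])
    S = mat.S.toarray()
    for row in ss.samples:
        assert np.max(np.abs(S @ row[rid_order])) < 1e-6
        assert np.all(row >= lb - 1e-9) and np.all(row <= ub + 1e-9)


# ---------------------------------------------------------------------------
# Z score
# ---------------------------------------------------------------------------


def manual_sample_set(name, means, variances, n=100):
    rids = [f"R{i}" for i in range(len(means))]
    return SampleSet(
        condition=name, n_samples=n, reaction_ids=rids,
        samples=np.zeros((n, len(means))),
        mean=np.array(means, dtype=float), var=np.array(variances, dtype=float),
        seed=0, method="manual",
    )


def test_zscore_hand_arithmetic():
    a = manual_sample_set("a", [1.0], [0.5])
    b = manual_sample_set("b", [2.0], [0.5])
    z = zscore_compare(a, b)
    assert z.z["R0"] == pytest.approx(1.0)


def test_identical_sample_sets_give_zero_z(core_model, excitatory):
    a = sample_flux_space(core_model, excitatory, 30, seed=7)
    z = zscore_compare(a, a)
    assert all(v == 0.0 for v in z.z.values())
    assert set(z.calls.values()) == {"unchanged"}


def test_zero_variance_mean_shift_gives_signed_infinity():
    a = manual_sample_set("a", [1.0, 1.0], [0.0, 0.0])
    b = manual_sample_set("b", [2.0, 1.0], [0.0, 0.0])
    z = zscore_compare(a, b)
    assert z.z["R0"] == np.inf and z.calls["R0"] == "up"
    assert z.z["R1"] == 0.0 and z.calls["R1"] == "unchanged"


def test_default_threshold_is_three_sigma_of_sampling_null():
    a = manual_sample_set("a", [0.0], [1.0], n=400)
    b = manual_sample_set("b", [0.0], [1.0], n=400)
    z = zscore_compare(a, b)
    assert z.threshold == pytest.approx(3.0 / np.sqrt(400))


def test_mismatched_reaction_index_is_an_error():
    a = manual_sample_set("a", [0.0], [1.0])
    b = manual_sample_set("b", [0.0, 1.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        zscore_compare(a, b)
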