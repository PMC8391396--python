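"""TFA MILP: FBA/pFBA/pTFVA correctness, direction coupling, loop exclusion."""

import cobra
import numpy as np
import pandas as pd
import pytest

from conftest import MICRO_ID_MAP, OptlangTFAOracle
from thermoflux.exceptions import ConfigurationError
from thermoflux.tfa import FluxRangeSet, TFAProblem
from thermoflux.thermo import CompartmentSpec, ThermoTable


def simple_model(reactions, mets):
    m = cobra.Model("simple")
    objs = {mid: cobra.Metabolite(mid, compartment=mid.rsplit("_", 1)[1])
            for mid in mets}
    for v in objs.values():
        v.charge = 0
    m.add_metabolites(list(objs.values()))
    for rid, stoich, lb, ub in reactions:
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        m.add_reactions([r])
        r.add_metabolites({objs[k]: c for k, c in stoich.items()})
        r.subsystem = "core"
    return m


def chain_model(u=4.0):
    return simple_model([
        ("EX_s_e", {"s_e": -1}, -u, 0.0),
        ("T_s", {"s_e": -1, "s_c": 1}, 0.0, 1000.0),
        ("CONV", {"s_c": -1, "p_c": 2}, 0.0, 1000.0),
        ("BIOMASS_chain", {"p_c": -1}, 0.0, 1000.0),
    ], ["s_e", "s_c", "p_c"])


def test_fba_chain_yield_is_analytic():
    u = 4.0
    prob = TFAProblem(chain_model(u), thermo=None, include_thermo=False,
                      biomass_id="BIOMASS_chain")
    res = prob.solve_fba()
    assert res.objective == pytest.approx(2.0 * u, rel=1e-9)


def test_fba_all_exchanges_closed_gives_zero():
    m = chain_model()
    m.reactions.EX_s_e.bounds = (0.0, 0.0)
    prob = TFAProblem(m, thermo=None, include_thermo=False,
                      biomass_id="BIOMASS_chain")
    assert prob.solve_fba().objective == pytest.approx(0.0, abs=1e-9)


def parallel_model():
    """Two routes a -> b with equal yield: direct (1 reaction) vs 2 reactions."""
    return simple_model([
        ("EX_a_e", {"a_e": -1}, -3.0, 0.0),
        ("T_a", {"a_e": -1, "a_c": 1}, 0.0, 1000.0),
        ("DIRECT", {"a_c": -1, "b_c": 1}, 0.0, 1000.0),
        ("LONG1", {"a_c": -1, "x_c": 1}, 0.0, 1000.0),
        ("LONG2", {"x_c": -1, "b_c": 1}, 0.0, 1000.0),
        ("BIOMASS_par", {"b_c": -1}, 0.0, 1000.0),
    ], ["a_e", "a_c", "x_c", "b_c"])


def test_pfba_prefers_shorter_route():
    prob = TFAProblem(parallel_model(), thermo=None, include_thermo=False,
                      biomass_id="BIOMASS_par")
    prob.solve_pfba()
    sol = prob.pfba_solution
    assert sol["DIRECT"] == pytest.approx(3.0, rel=1e-6)
    assert sol["LONG1"] == pytest.approx(0.0, abs=1e-8)


def test_pfba_zero_demand_means_zero_total_flux():
    m = chain_model()
    m.reactions.EX_s_e.bounds = (0.0, 0.0)
    prob = TFAProblem(m, thermo=None, include_thermo=False,
                      biomass_id="BIOMASS_chain")
    res = prob.solve_pfba()
    assert res.objective == pytest.approx(0.0, abs=1e-8)


def test_ptfva_fully_determined_chain():
    u = 4.0
    m = chain_model(u)
    m.reactions.EX_s_e.bounds = (-u, -u)
    prob = TFAProblem(m, thermo=None, include_thermo=False,
                      biomass_id="BIOMASS_chain")
    prob.solve_pfba()
    ranges = prob.solve_ptfva().ranges
    for rid, expect in [("T_s", u), ("CONV", u), ("BIOMASS_chain", 2 * u),
                        ("EX_s_e", -u)]:
        assert ranges.loc[rid, "minimum"] == pytest.approx(expect, rel=1e-6)
        assert ranges.loc[rid, "maximum"] == pytest.approx(expect, rel=1e-6)


def test_ptfva_subset_of_tfva(micro_model, micro_thermo):
    prob = TFAProblem(micro_model.copy(), micro_thermo, id_map=MICRO_ID_MAP,
                      biomass_id="BIOMASS_micro")
    prob.solve_pfba()
    ptfva = prob.solve_ptfva().ranges
    tfva = prob.solve_ptfva(parsimonious=False).ranges
    tol = 1e-6
    assert (ptfva["minimum"] >= tfva["minimum"] - tol).all()
    assert (ptfva["maximum"] <= tfva["maximum"] + tol).all()


def test_tfva_subset_of_fva_cobra_oracle(micro_model, micro_thermo):
    """Thermodynamic constraints never enlarge ranges (vs cobra's FVA)."""
    from cobra.flux_analysis import flux_variability_analysis

    prob = TFAProblem(micro_model.copy(), micro_thermo, id_map=MICRO_ID_MAP,
                      biomass_id="BIOMASS_micro")
    tfva = prob.solve_ptfva(parsimonious=False).ranges
    fva = flux_variability_analysis(micro_model.copy(), fraction_of_optimum=0.0)
    tol = 1e-6
    for rid in tfva.index:
        assert tfva.loc[rid, "minimum"] >= fva.loc[rid, "minimum"] - tol
        assert tfva.loc[rid, "maximum"] <= fva.loc[rid, "maximum"] + tol


def test_ptfva_matches_optlang_oracle(micro_model, micro_thermo):
    prob = TFAProblem(micro_model.copy(), micro_thermo, id_map=MICRO_ID_MAP,
                      biomass_id="BIOMASS_micro")
    prob.solve_pfba()
    mine = prob.solve_ptfva().ranges
    oracle = OptlangTFAOracle(micro_model.copy(), micro_thermo, MICRO_ID_MAP,
                              "BIOMASS_micro").ptfva()
    for rid, (lo, hi) in oracle.items():
        assert mine.loc[rid, "minimum"] == pytest.approx(lo, rel=1e-6, abs=1e-6)
        assert mine.loc[rid, "maximum"] == pytest.approx(hi, rel=1e-6, abs=1e-6)


def test_positive_drg_forces_zero_forward_flux():
    """drG'0 = +50 with capped concentration ratios shuts the reaction off."""
    m = simple_model([
        ("EX_a_e", {"a_c": -1}, -5.0, 0.0),
        ("R_up", {"a_c": -1, "b_c": 1}, 0.0, 1000.0),
        ("BIOMASS_up", {"b_c": -1}, 0.0, 1000.0),
    ], ["a_c", "b_c"])
    rows = pd.DataFrame([("a", "c", -100.0, 0.0), ("b", "c", -50.0, 0.0)],
                        columns=["compound_id", "compartment", "dfG0_prime",
                                 "dfG0_error"])
    thermo = ThermoTable(compounds=rows,
                         compartments={"c": CompartmentSpec(ph=7.0)})
    conc = {"a_c": (1e-3, 1.001e-3), "b_c": (1e-3, 1.001e-3)}
    prob = TFAProblem(m, thermo, conc_bounds=conc,
                      id_map={"a_c": "a", "b_c": "b"}, biomass_id="BIOMASS_up")
    res = prob.solve_fba()
    assert res.objective == pytest.approx(0.0, abs=1e-8)
    # sanity: the same reaction runs when drG'0 is negative
    rows2 = rows.copy()
    rows2.loc[rows2.compound_id == "b", "dfG0_prime"] = -160.0
    thermo2 = ThermoTable(compounds=rows2,
                          compartments={"c": CompartmentSpec(ph=7.0)})
    prob2 = TFAProblem(m.copy(), thermo2, conc_bounds=conc,
                       id_map={"a_c": "a", "b_c": "b"}, biomass_id="BIOMASS_up")
    assert prob2.solve_fba().objective == pytest.approx(5.0, rel=1e-6)


def test_loop_cannot_circulate_in_any_direction_pattern(bundle):
    """Mass balance ties the three loop legs into one circulation mode, and
    the telescoping Gibbs energies forbid it: every pattern that forces any
    leg to carry flux is infeasible; the all-zero pattern is feasible."""
    import itertools

    loop = ["LOOP1", "LOOP2", "LOOP3"]
    for pattern in itertools.product([False, True], repeat=3):
        prob = TFAProblem(bundle.model.copy(), bundle.thermo,
                          id_map=bundle.id_map, biomass_id="BIOMASS")
        for rid, forced in zip(loop, pattern):
            if forced:
                prob.lp.set_variable_bounds(prob.vf[rid], 1e-3, 1000.0)
        prob.lp.set_objective({}, sense="min")
        res = prob.lp.solve()
        if any(pattern):
            assert res.status == "infeasible", pattern
        else:
            assert res.ok


def test_second_law_holds_in_solutions(micro_model, micro_thermo):
    prob = TFAProblem(micro_model.copy(), micro_thermo, id_map=MICRO_ID_MAP,
                      biomass_id="BIOMASS_micro")
    prob.solve_pfba()
    _, sols = prob.solve_ptfva(collect_solutions=True)
    assert sols
    for x in sols:
        assert prob.check_second_law(x) == []


def test_ptfva_determinism_and_partition_equivalence(micro_model, micro_thermo):
    def full_run(reactions=None):
        prob = TFAProblem(micro_model.copy(), micro_thermo, id_map=MICRO_ID_MAP,
                          biomass_id="BIOMASS_micro")
        prob.solve_pfba()
        if reactions is None:
            return prob.solve_ptfva().ranges
        parts = [prob.solve_ptfva(reactions=list(chunk)).ranges
                 for chunk in reactions]
        return pd.concat(parts)

    r1 = full_run()
    r2 = full_run()
    assert np.allclose(r1.to_numpy(), r2.loc[r1.index].to_numpy(),
                       rtol=1e-6, atol=1e-9)
    rids = list(r1.index)
    r3 = full_run(reactions=[rids[:3], rids[3:]])
    assert np.allclose(r1.to_numpy(), r3.loc[r1.index].to_numpy(),
                       rtol=1e-6, atol=1e-9)


def test_ptfva_requires_pfba(micro_model, micro_thermo):
    prob = TFAProblem(micro_model.copy(), micro_thermo, id_map=MICRO_ID_MAP,
                      biomass_id="BIOMASS_micro")
    with pytest.raises(ConfigurationError):
        prob._activate_sum_constraint(True)


def test_conc_bounds_outside_default_are_clipped(micro_model, micro_thermo, caplog):
    prob = TFAProblem(micro_model.copy(), micro_thermo, id_map=MICRO_ID_MAP,
                      biomass_id="BIOMASS_micro",
                      conc_bounds={"A_c": (1e-15, 1.0)})
    lo, hi = prob.lp.variable_bounds(prob.lnc["A_c"])
    assert lo == pytest.approx(np.log(1e-12))
    assert hi == pytest.approx(np.log(0.1))


def test_flux_range_set_tsv_roundtrip(tmp_path, micro_model, micro_thermo):
    prob = TFAProblem(micro_model.copy(), micro_thermo, id_map=MICRO_ID_MAP,
                      biomass_id="BIOMASS_micro")
    prob.solve_pfba()
    rset = prob.solve_ptfva(instance="micro")
    rset.to_tsv(tmp_path / "r.tsv")
    back = FluxRangeSet.from_tsv(tmp_path / "r.tsv", instance="micro")
    assert np.allclose(back.ranges.to_numpy(), rset.ranges.to_numpy())
    assert back.subsystems == rset.subsystems


def test_infeasibility_diagnosis_names_the_culprit():
    m = chain_model()
    m.reactions.EX_s_e.bounds = (0.0, 0.0)
    m.reactions.BIOMASS_chain.bounds = (1.0, 10.0)  # demand with no supply
    prob = TFAProblem(m, thermo=None, include_thermo=False,
                      biomass_id="BIOMASS_chain")
    diag = prob.diagnose_infeasibility()
    assert diag  # some bound must move
    assert any(r in diag for r in ("EX_s_e", "BIOMASS_chain"))
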