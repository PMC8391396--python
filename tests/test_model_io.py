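"""SBML round trips, exchange augmentation, blocked removal, thermo joins."""

import cobra
import numpy as np
import pytest

from thermoflux import model_io
from thermoflux.exceptions import ConfigurationError, DataError, InfeasibleModelError
from thermoflux.solver import LinearProblem


def stoich_matrix(model):
    mets = sorted(m.id for m in model.metabolites)
    rxns = sorted(r.id for r in model.reactions)
    S = np.zeros((len(mets), len(rxns)))
    mi = {m: i for i, m in enumerate(mets)}
    ri = {r: j for j, r in enumerate(rxns)}
    for rxn in model.reactions:
        for met, coef in rxn.metabolites.items():
            S[mi[met.id], ri[rxn.id]] = coef
    return S, mets, rxns


def test_sbml_round_trip_preserves_everything(tmp_path, bundle):
    path = tmp_path / "m.xml"
    model_io.write_model(bundle.model, path)
    back = model_io.read_model(path)
    S1, m1, r1 = stoich_matrix(bundle.model)
    S2, m2, r2 = stoich_matrix(back)
    assert m1 == m2 and r1 == r2
    assert np.array_equal(S1, S2)
    for rxn in bundle.model.reactions:
        again = back.reactions.get_by_id(rxn.id)
        assert again.bounds == rxn.bounds
        assert again.subsystem == rxn.subsystem


def test_read_without_groups_defaults_to_unassigned(tmp_path):
    m = cobra.Model("plain")
    a = cobra.Metabolite("a_e", compartment="e")
    m.add_metabolites([a])
    ex = cobra.Reaction("EX_a_e", lower_bound=-1, upper_bound=1)
    m.add_reactions([ex])
    ex.add_metabolites({a: -1})
    bio = cobra.Reaction("biomass_plain", lower_bound=0, upper_bound=1)
    m.add_reactions([bio])
    bio.add_metabolites({a: -1})
    cobra.io.write_sbml_model(m, str(tmp_path / "plain.xml"))
    back = model_io.read_model(tmp_path / "plain.xml")
    assert all(r.subsystem == model_io.UNASSIGNED for r in back.reactions)


def test_read_model_errors(tmp_path):
    with pytest.raises(DataError):
        model_io.read_model(tmp_path / "absent.xml")
    bad = tmp_path / "bad.xml"
    bad.write_text("<sbml this is not valid")
    with pytest.raises(DataError):
        model_io.read_model(bad)


def test_missing_biomass_is_configuration_error(tmp_path):
    m = cobra.Model("nobio")
    a = cobra.Metabolite("a_e", compartment="e")
    m.add_metabolites([a])
    r = cobra.Reaction("EX_a_e", lower_bound=-1, upper_bound=1)
    m.add_reactions([r])
    r.add_metabolites({a: -1})
    cobra.io.write_sbml_model(m, str(tmp_path / "m.xml"))
    with pytest.raises(ConfigurationError):
        model_io.read_model(tmp_path / "m.xml")
    assert model_io.read_model(tmp_path / "m.xml", require_biomass=False)


def test_add_exchanges_counts_and_idempotence(bundle):
    model = bundle.model.copy()
    n0 = len(model.reactions)
    new_ids = [f"x{i}_e" for i in range(7)]
    model_io.add_exchanges(model, new_ids)
    assert len(model.reactions) == n0 + 7
    model_io.add_exchanges(model, new_ids)      # idempotent
    assert len(model.reactions) == n0 + 7
    model_io.add_exchanges(model, [])           # empty list is a no-op
    assert len(model.reactions) == n0 + 7
    with pytest.raises(DataError):
        model_io.add_exchanges(model, ["nonexistent_c"])


def test_replace_pooled_supply(bundle):
    model = bundle.model.copy()
    pool = cobra.Reaction("POOL_fa", lower_bound=0, upper_bound=1)
    model.add_reactions([pool])
    pool.add_metabolites({model.metabolites.fa1_c: 1})
    model_io.replace_pooled_supply(model, ["POOL_fa"], ["fa1_e", "fa2_e"])
    assert "POOL_fa" not in [r.id for r in model.reactions]
    for mid in ("fa1_e", "fa2_e"):
        ex = [r for r in model.metabolites.get_by_id(mid).reactions if r.boundary]
        assert ex and ex[0].lower_bound == -model_io.DEFAULT_BOUND


def closed_chain_model():
    m = cobra.Model("chain")
    a_e = cobra.Metabolite("a_e", compartment="e")
    a = cobra.Metabolite("a_c", compartment="c")
    b = cobra.Metabolite("b_c", compartment="c")
    m.add_metabolites([a_e, a, b])

    def add(rid, stoich, lb, ub):
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        m.add_reactions([r])
        r.add_metabolites(stoich)
        return r

    add("EX_a_e", {a_e: -1}, 0.0, 0.0)          # closed
    add("T_a", {a_e: -1, a: 1}, -10, 10)
    add("R_ab", {a: -1, b: 1}, -10, 10)
    add("SINK_b", {b: -1}, 0, 10)
    add("biomass_chain", {b: -0.1}, 0, 10)
    return m


def test_closed_exchange_blocks_whole_chain():
    model = closed_chain_model()
    reduced, removed = model_io.remove_blocked(model)
    # the closed exchange blocks everything downstream (and itself)
    assert {"T_a", "R_ab", "SINK_b", "biomass_chain"} <= set(removed)
    assert len(reduced.reactions) == 0 or not any(
        r.bounds != (0.0, 0.0) for r in reduced.reactions)


def test_open_toy_has_no_blocked_reactions(bundle):
    reduced, removed = model_io.remove_blocked(bundle.model.copy())
    assert removed == []


def brute_force_fva(model):
    """Independent per-reaction LP min/max via the scipy wrapper."""
    lp = LinearProblem()
    idx = {}
    for rxn in model.reactions:
        idx[rxn.id] = lp.add_variable(rxn.id, *rxn.bounds)
    for met in model.metabolites:
        lp.add_constraint({idx[r.id]: r.metabolites[met] for r in met.reactions},
                          0.0, 0.0)
    out = {}
    for rid in idx:
        lo_hi = []
        for sense in ("min", "max"):
            lp.set_objective({idx[rid]: 1.0}, sense=sense)
            lo_hi.append(lp.solve().objective)
        out[rid] = tuple(lo_hi)
    return out


def test_dead_end_branch_removed_matches_fva_oracle():
    model = closed_chain_model()
    model.reactions.EX_a_e.bounds = (-5, 0)   # reopen uptake
    dead = cobra.Metabolite("d_c", compartment="c")
    model.add_metabolites([dead])
    r = cobra.Reaction("R_dead", lower_bound=0, upper_bound=10)
    model.add_reactions([r])
    r.add_metabolites({model.metabolites.a_c: -1, dead: 1})  # d_c has no sink
    reduced, removed = model_io.remove_blocked(model)
    oracle = brute_force_fva(model)
    expected = sorted(rid for rid, (lo, hi) in oracle.items()
                      if abs(lo) <= 1e-9 and abs(hi) <= 1e-9)
    assert sorted(removed) == expected == ["R_dead"]
    # idempotence
    again, removed2 = model_io.remove_blocked(reduced)
    assert removed2 == []


def test_remove_blocked_surfaces_infeasibility():
    model = closed_chain_model()
    model.reactions.SINK_b.bounds = (5, 10)   # demands flux through closed chain
    with pytest.raises(InfeasibleModelError) as err:
        model_io.remove_blocked(model, {"EX_a_e": (0.0, 0.0)})
    assert err.value.diagnostics is not None


def test_join_thermo_coverage(bundle):
    cov = model_io.join_thermo(bundle.model, bundle.thermo, bundle.id_map)
    assert cov.compound_fraction == 1.0
    assert cov.reaction_fraction == 1.0

    import pandas as pd
    from thermoflux.thermo import ThermoTable
    empty = ThermoTable(
        compounds=pd.DataFrame(columns=list(ThermoTable.REQUIRED)),
        compartments=bundle.thermo.compartments)
    cov0 = model_io.join_thermo(bundle.model, empty, bundle.id_map)
    assert cov0.compound_fraction == 0.0 and cov0.reaction_fraction == 0.0


def test_join_thermo_missing_hub_compound(bundle):
    """Removing one hub compound drops exactly the reactions touching it."""
    table = bundle.thermo
    hub = "pyr"   # participates in several internal reactions
    reduced = table.compounds[table.compounds.compound_id != hub]
    from thermoflux.thermo import ThermoTable
    t2 = ThermoTable(compounds=reduced, compartments=table.compartments)
    full = model_io.join_thermo(bundle.model, table, bundle.id_map)
    part = model_io.join_thermo(bundle.model, t2, bundle.id_map)
    touching = {r.id for r in bundle.model.reactions if not r.boundary
                and any(bundle.id_map[m.id] == hub for m in r.metabolites)}
    lost = set(full.estimable_reactions) - set(part.estimable_reactions)
    assert lost == touching


def test_thermo_table_tsv_roundtrip(tmp_path, bundle):
    model_io.write_thermo_table(bundle.thermo, tmp_path / "c.tsv", tmp_path / "k.tsv")
    back = model_io.read_thermo_table(tmp_path / "c.tsv", tmp_path / "k.tsv")
    assert back.compartments == bundle.thermo.compartments
    for met in bundle.model.metabolites:
        cid = bundle.id_map[met.id]
        assert back.lookup(cid, met.compartment) == pytest.approx(
            bundle.thermo.lookup(cid, met.compartment))
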