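"""Oxygen / fatty-acid envelope sweeps and key-flux extraction."""

import numpy as np
import pandas as pd
import pytest

from conftest import OptlangTFAOracle
from thermoflux import envelopes as env
from thermoflux.exceptions import ConfigurationError
from thermoflux.pipeline import apply_instance_bounds, fit_condition
from thermoflux.tfa import GROWTH_NORMALIZED, FluxRangeSet, TFAProblem

FA = ["EX_fa1_e", "EX_fa2_e"]
RELAX = ["EX_ktb_e", "EX_co2_e", "EX_lac_e"]
ROLES = {"oxygen_uptake": "EX_o2_e", "atp_synthase": "OXPHOS",
         "lactate_secretion": "EX_lac_e", "fatty_acid_exchanges": FA}


def pinned_instance(bundle, cond="sensitive-A"):
    fits = fit_condition(bundle.conditions[cond], bundle.model)
    return apply_instance_bounds(bundle.model, fits, "BIOMASS")


@pytest.fixture(scope="module")
def instance_problem(bundle):
    inst = pinned_instance(bundle)
    prob = TFAProblem(inst, bundle.thermo,
                      conc_bounds=bundle.conditions["sensitive-A"].conc_bounds,
                      id_map=bundle.id_map, biomass_id="BIOMASS")
    prob.solve_pfba()
    return prob


def manual_ranges(values, instance="i", state=GROWTH_NORMALIZED):
    df = pd.DataFrame.from_dict(values, orient="index",
                                columns=["minimum", "maximum"])
    return FluxRangeSet(ranges=df, instance=instance, state=state,
                        biomass_id="BIO", biomass_flux=1.0)


def test_key_fluxes_singleton_sum_and_additivity():
    values = {"EX_o2_e": (-2.0, -1.5), "OXPHOS": (0.5, 0.9),
              "EX_lac_e": (1.0, 1.2), "EX_fa1_e": (-0.1, -0.1),
              "EX_fa2_e": (0.0, 0.0)}
    table = env.key_fluxes(manual_ranges(values), ROLES)
    total = table[table.role == "fatty_acid_influx_total"].iloc[0]
    per_fa = table[table.role == "fatty_acid_exchange"]
    assert total["minimum"] == pytest.approx(per_fa["minimum"].sum())
    assert total["maximum"] == pytest.approx(per_fa["maximum"].sum())
    assert total["minimum"] == pytest.approx(-0.1)


def test_key_fluxes_anaerobic_instance_reports_zero_oxygen():
    values = {"EX_o2_e": (0.0, 0.0), "OXPHOS": (0.0, 0.0),
              "EX_lac_e": (2.0, 2.0), "EX_fa1_e": (0.0, 0.0),
              "EX_fa2_e": (0.0, 0.0)}
    table = env.key_fluxes(manual_ranges(values), ROLES)
    o2 = table[table.role == "oxygen_uptake"].iloc[0]
    assert o2["minimum"] == o2["maximum"] == 0.0


def test_key_fluxes_unmapped_role_is_error():
    with pytest.raises(ConfigurationError):
        env.key_fluxes(manual_ranges({"EX_o2_e": (0, 0)}),
                       {"oxygen_uptake": "EX_o2_e"})


def relaxed_instance_problem(bundle, cond="sensitive-A"):
    """Instance with fatty-acid and oxygen influx unconstrained (the sweeps'
    own frame of reference), all other exchanges pinned from the data."""
    inst = pinned_instance(bundle, cond)
    for rid in FA + ["EX_o2_e"]:
        inst.reactions.get_by_id(rid).bounds = (-1000.0, 0.0)
    prob = TFAProblem(inst, bundle.thermo,
                      conc_bounds=bundle.conditions[cond].conc_bounds,
                      id_map=bundle.id_map, biomass_id="BIOMASS")
    prob.solve_pfba()
    return prob


def test_consistency_at_operating_point(bundle):
    """The sweep reproduces the instance's own parsimonious fatty-acid
    minimum when oxygen is pinned at the instance's operating influx."""
    prob = relaxed_instance_problem(bundle)
    prob.solve_ptfva(instance="sensitive-A")
    fa_min, solution = env.parsimonious_min_influx(prob, FA)
    o2_op = -float(solution["EX_o2_e"])
    curve = env.sweep_min_fa(prob, "EX_o2_e", FA, o2_grid=[o2_op])
    assert curve.feasible[0]
    assert curve.minima[0] == pytest.approx(fa_min, abs=1e-6)


def test_zero_biomass_demand_needs_no_fatty_acid(bundle):
    inst = pinned_instance(bundle)
    inst.reactions.BIOMASS.bounds = (0.0, 1e-9)
    for rid in RELAX:   # products respond when growth is switched off
        inst.reactions.get_by_id(rid).bounds = (-1000.0, 1000.0)
    prob = TFAProblem(inst, bundle.thermo,
                      conc_bounds=bundle.conditions["sensitive-A"].conc_bounds,
                      id_map=bundle.id_map, biomass_id="BIOMASS")
    prob.solve_pfba()
    curve = env.sweep_min_fa(prob, "EX_o2_e", FA, n_points=4, also_relax=RELAX)
    assert curve.feasible.all()
    assert np.all(curve.minima <= 1e-6)


def test_upper_bound_mode_is_monotone_non_increasing(instance_problem):
    curve = env.sweep_min_fa(instance_problem, "EX_o2_e", FA, n_points=6,
                             mode="upper", also_relax=RELAX)
    vals = curve.minima[curve.feasible]
    assert np.all(np.diff(vals) <= 1e-8)


def test_equality_sweep_decreases_then_allows_zero(instance_problem):
    curve = env.sweep_min_fa(instance_problem, "EX_o2_e", FA, n_points=6,
                             also_relax=RELAX)
    assert curve.feasible.all()
    assert curve.minima[0] > 0.0          # oxygen-starved: fat is required
    assert curve.minima[-1] == pytest.approx(0.0, abs=1e-8)
    assert not curve.breakdown.isna().any().any()
    assert np.allclose(curve.breakdown.sum(axis=1), curve.minima, atol=5e-5)


def test_forced_fat_oxidation_creates_interior_oxygen_minimum(instance_problem):
    fa_grid = np.linspace(0.0, 0.08, 9)
    curve = env.sweep_min_o2(instance_problem, "EX_o2_e", FA, fa_grid,
                             also_relax=RELAX)[0]
    assert curve.feasible.all()
    i = int(np.argmin(curve.minima))
    assert 0 < i < len(fa_grid) - 1, "expected an interior minimum"
    assert curve.minima[0] > curve.minima[i]
    assert curve.minima[-1] > curve.minima[i]


def test_doubling_biomass_never_decreases_min_oxygen(instance_problem, bundle):
    mu = bundle.truth.growth_rates["sensitive-A"]
    fa_grid = np.linspace(0.0, 0.04, 4)
    lo, hi = env.sweep_min_o2(instance_problem, "EX_o2_e", FA, fa_grid,
                              biomass_levels=[mu, 2 * mu],
                              also_relax=RELAX + ["EX_glc_e", "EX_gln_e",
                                                  "EX_sol_e"])
    assert np.all(hi.minima[hi.feasible] >=
                  lo.minima[lo.feasible][:hi.feasible.sum()] - 1e-8)


def test_argmin_is_growth_invariant_on_homogeneous_instance(instance_problem, bundle):
    """With all substrate pins relaxed the LP is homogeneous in biomass, so
    the growth-normalized location of the oxygen minimum is the same at every
    biomass level."""
    mu = bundle.truth.growth_rates["sensitive-A"]
    relax = RELAX + ["EX_glc_e", "EX_gln_e", "EX_sol_e"]
    curves = {}
    for level in (mu, 2 * mu):
        grid = np.linspace(0.005, 0.08, 9) * (level / mu)
        curves[level] = env.sweep_min_o2(instance_problem, "EX_o2_e", FA, grid,
                                         biomass_levels=[level],
                                         also_relax=relax)[0]
    a, b = curves[mu], curves[2 * mu]
    assert a.feasible.all() and b.feasible.all()
    ia, ib = int(np.argmin(a.minima)), int(np.argmin(b.minima))
    assert a.grid_normalized[ia] == pytest.approx(b.grid_normalized[ib], rel=1e-3)
    assert a.minima_normalized[ia] == pytest.approx(b.minima_normalized[ib],
                                                    rel=1e-3)


def test_sweep_points_match_bruteforce_two_stage_oracle(bundle, instance_problem):
    """Each envelope point equals an independently built parsimonious MILP."""
    prob = instance_problem
    curve = env.sweep_min_fa(prob, "EX_o2_e", FA, n_points=3, also_relax=RELAX)
    for g, val, ok in zip(curve.grid, curve.minima, curve.feasible):
        assert ok
        inst = pinned_instance(bundle)
        hw = 1e-9 + 1e-6 * g
        inst.reactions.EX_o2_e.bounds = (-g - hw, -g + hw)
        for rid in FA:
            inst.reactions.get_by_id(rid).bounds = (-1000.0, 0.0)
        for rid in RELAX:
            inst.reactions.get_by_id(rid).bounds = (-1000.0, 1000.0)
        oracle = OptlangTFAOracle(inst, bundle.thermo, bundle.id_map, "BIOMASS",
                                  conc_bounds=bundle.conditions["sensitive-A"].conc_bounds)
        expect = oracle.min_influx_two_stage(FA)
        assert val == pytest.approx(expect, abs=5e-6)


def test_sweep_restores_problem_state(instance_problem):
    before = {rid: instance_problem.reaction_bounds(rid)
              for rid in ["EX_o2_e"] + FA + RELAX}
    env.sweep_min_fa(instance_problem, "EX_o2_e", FA, n_points=3,
                     also_relax=RELAX)
    after = {rid: instance_problem.reaction_bounds(rid) for rid in before}
    assert before == after


def test_envelope_curve_validation_and_tsv(tmp_path):
    with pytest.raises(ValueError):
        env.EnvelopeCurve(swept="x", minimized="y",
                          grid=np.array([1.0, 1.0]),
                          minima=np.array([0.0, 0.0]),
                          feasible=np.array([True, True]),
                          biomass=np.array([1.0, 1.0]))
    c = env.EnvelopeCurve(swept="x", minimized="y",
                          grid=np.array([1.0, 2.0]),
                          minima=np.array([0.5, 0.25]),
                          feasible=np.array([True, True]),
                          biomass=np.array([0.5, 0.5]))
    assert np.allclose(c.minima_normalized, [1.0, 0.5])
    c.to_tsv(tmp_path / "c.tsv")
    back = pd.read_csv(tmp_path / "c.tsv", sep="\t")
    assert list(back["grid_value"]) == [1.0, 2.0]
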