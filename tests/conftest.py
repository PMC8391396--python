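"""Shared fixtures: micro networks, synthetic bundles, pipeline runs, and an
independent optlang/GLPK MILP oracle for variability analysis."""

from __future__ import annotations

import math

import cobra
import numpy as np
import pytest

from thermoflux import pipeline, synth
from thermoflux.thermo import CompartmentSpec, ThermoTable

import pandas as pd

PAIRING = {"resistant-A": "sensitive-A", "resistant-B": "sensitive-B"}


def build_micro_model():
    """Branched 8-reaction network with parallel routes and a reversible step.

    A is taken up, converted to B and C (directly or via B), and biomass
    consumes both.  C can also be secreted.  Small enough for brute-force
    oracles, rich enough for nondegenerate flux ranges.
    """
    m = cobra.Model("micro")
    mets = {}
    for mid, comp in [("A_e", "e"), ("A_c", "c"), ("B_c", "c"), ("C_c", "c"),
                      ("D_e", "e")]:
        mets[mid] = cobra.Metabolite(mid, compartment=comp)
        mets[mid].charge = 0
    m.add_metabolites(list(mets.values()))

    def rxn(rid, stoich, lb, ub, subsystem="core"):
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        m.add_reactions([r])
        r.add_metabolites({mets[k]: v for k, v in stoich.items()})
        r.subsystem = subsystem
        return r

    rxn("EX_A_e", {"A_e": -1}, -5.0, 0.0, "transport")
    rxn("T_A", {"A_e": -1, "A_c": 1}, 0.0, 1000.0, "transport")
    rxn("R1", {"A_c": -1, "B_c": 1}, -1000.0, 1000.0)   # reversible
    rxn("R2", {"B_c": -1, "C_c": 1}, 0.0, 1000.0)
    rxn("R3", {"A_c": -1, "C_c": 1}, 0.0, 1000.0)       # parallel shortcut
    rxn("BIOMASS_micro", {"B_c": -0.5, "C_c": -0.5}, 0.0, 1000.0, "biomass")
    rxn("T_D", {"C_c": -1, "D_e": 1}, 0.0, 1000.0, "transport")
    rxn("EX_D_e", {"D_e": -1}, 0.0, 1000.0, "transport")
    m.objective = "BIOMASS_micro"
    return m


def build_micro_thermo():
    rows = []
    energies = {"A": -100.0, "B": -120.0, "C": -145.0, "D": -160.0}
    for comp in ("e", "c"):
        for cid, g in energies.items():
            rows.append({"compound_id": cid, "compartment": comp,
                         "dfG0_prime": g, "dfG0_error": 1.0})
    specs = {"e": CompartmentSpec(ph=7.4), "c": CompartmentSpec(ph=7.2)}
    return ThermoTable(compounds=pd.DataFrame(rows), compartments=specs)


MICRO_ID_MAP = {"A_e": "A", "A_c": "A", "B_c": "B", "C_c": "C", "D_e": "D"}


@pytest.fixture(scope="session")
def micro_model():
    return build_micro_model()


@pytest.fixture(scope="session")
def micro_thermo():
    return build_micro_thermo()


@pytest.fixture(scope="session")
def bundle():
    return synth.make_bundle(seed=1)


def make_config(data_dir, out_dir) -> pipeline.RunConfig:
    return pipeline.RunConfig(
        data_dir=data_dir, output_dir=out_dir, pairing=dict(PAIRING),
        roles={"oxygen_uptake": "EX_o2_e", "atp_synthase": "OXPHOS",
               "lactate_secretion": "EX_lac_e",
               "fatty_acid_exchanges": ["EX_fa1_e", "EX_fa2_e"],
               "envelope_relax": ["EX_ktb_e", "EX_co2_e", "EX_lac_e"]})


def run_bundle(bundle_obj, tmp_root):
    data = tmp_root / "data"
    out = tmp_root / "out"
    bundle_obj.save(data)
    cfg = make_config(data, out)
    return pipeline.run_pipeline(cfg)


@pytest.fixture(scope="session")
def pipeline_baseline(bundle, tmp_path_factory):
    return run_bundle(bundle, tmp_path_factory.mktemp("baseline"))


@pytest.fixture(scope="session")
def solvent_pair(tmp_path_factory):
    """(baseline result, solvent-spiked result) on a common seed."""
    plain = synth.make_bundle(seed=11)
    spiked = synth.make_bundle(seed=11, solvent_scale=1.4)
    r0 = run_bundle(plain, tmp_path_factory.mktemp("plain"))
    r1 = run_bundle(spiked, tmp_path_factory.mktemp("spiked"))
    return plain, r0, spiked, r1


@pytest.fixture(scope="session")
def growth_only_result(tmp_path_factory):
    b = synth.make_bundle(seed=11, fa_scale=1.0, gln_scale=1.0)
    return b, run_bundle(b, tmp_path_factory.mktemp("growth_only"))


# ---------------------------------------------------------------------------
# independent optlang/GLPK oracle
# ---------------------------------------------------------------------------

class OptlangTFAOracle:
    """Independent TFA MILP (optlang + GLPK) for cross-checking pTFVA.

    Re-derives the formulation from first principles: split fluxes, log
    concentrations, a reaction Gibbs-energy variable with a bounded slack,
    and big-M direction coupling.  Only uncharged, single-temperature models
    are supported (sufficient for the micro fixtures).
    """

    RT = 8.314462618e-3 * 310.15
    EPS = 1e-3   # must match the implementation's strict-inequality surrogate
    M = 1000.0

    def __init__(self, model, thermo, id_map, biomass_id,
                 conc_bounds=None, conc_default=(1e-12, 0.1)):
        from optlang.glpk_interface import Constraint, Model, Variable

        self.model = model
        self.biomass_id = biomass_id
        conc_bounds = conc_bounds or {}
        om = Model(name="oracle")
        self.vf, self.vb = {}, {}
        cons = []
        for rxn in model.reactions:
            lb, ub = rxn.bounds
            vf = Variable(f"vf_{rxn.id}", lb=0, ub=min(self.M, max(ub, 0.0)))
            vb = Variable(f"vb_{rxn.id}", lb=0, ub=min(self.M, max(-lb, 0.0)))
            self.vf[rxn.id], self.vb[rxn.id] = vf, vb
            cons.append(Constraint(vf - vb, lb=lb, ub=ub, name=f"net_{rxn.id}"))
        for met in model.metabolites:
            expr = 0
            for rxn in met.reactions:
                s = rxn.metabolites[met]
                expr = expr + s * self.vf[rxn.id] - s * self.vb[rxn.id]
            cons.append(Constraint(expr, lb=0, ub=0, name=f"mass_{met.id}"))

        lnc = {}

        def lnc_var(met):
            if met.id not in lnc:
                lo, hi = conc_bounds.get(met.id, conc_default)
                lnc[met.id] = Variable(f"lnc_{met.id}", lb=math.log(lo),
                                       ub=math.log(hi))
            return lnc[met.id]

        for rxn in model.reactions:
            if rxn.boundary or rxn.id == biomass_id:
                continue
            total, var = 0.0, 0.0
            covered = True
            for met, coef in rxn.metabolites.items():
                hit = thermo.lookup(id_map.get(met.id, met.id), met.compartment)
                if hit is None:
                    covered = False
                    break
                total += coef * hit[0]
                var += coef**2 * hit[1]**2
            if not covered:
                continue
            err = math.sqrt(var)
            drg = Variable(f"drg_{rxn.id}", lb=-1e6, ub=1e6)
            slack = Variable(f"sl_{rxn.id}", lb=-err, ub=err)
            expr = drg - slack
            span = 0.0
            for met, coef in rxn.metabolites.items():
                v = lnc_var(met)
                expr = expr - self.RT * coef * v
                span += abs(coef) * max(abs(v.lb), abs(v.ub))
            cons.append(Constraint(expr, lb=total, ub=total, name=f"dg_{rxn.id}"))
            big_k = abs(total) + err + self.RT * span + self.EPS + 1.0
            yf = Variable(f"yf_{rxn.id}", type="binary")
            yb = Variable(f"yb_{rxn.id}", type="binary")
            cons.append(Constraint(self.vf[rxn.id] - self.M * yf, ub=0))
            cons.append(Constraint(self.vb[rxn.id] - self.M * yb, ub=0))
            cons.append(Constraint(yf + yb, ub=1))
            cons.append(Constraint(drg + big_k * yf, ub=big_k - self.EPS))
            cons.append(Constraint(-drg + big_k * yb, ub=big_k - self.EPS))
        om.add(cons)
        self.om = om

    def _net(self, rid):
        return self.vf[rid] - self.vb[rid]

    def _optimize(self, expr, direction):
        from optlang.glpk_interface import Objective
        self.om.objective = Objective(expr, direction=direction)
        status = self.om.optimize()
        if status != "optimal":
            raise RuntimeError(f"oracle status {status}")
        return self.om.objective.value

    def _prepare_parsimonious(self, sum_tol_rel=1e-6):
        from optlang.glpk_interface import Constraint
        opt = self._optimize(self._net(self.biomass_id), "max")
        self.om.add([Constraint(self._net(self.biomass_id), lb=opt, ub=opt,
                                name="biomass_fix")])
        total = 0
        for rid in self.vf:
            total = total + self.vf[rid] + self.vb[rid]
        min_sum = self._optimize(total, "min")
        cap = min_sum + sum_tol_rel * abs(min_sum) + 1e-9
        self.om.add([Constraint(total, ub=cap, name="sum_cap")])

    def ptfva(self, sum_tol_rel=1e-6):
        self._prepare_parsimonious(sum_tol_rel)
        out = {}
        for rid in self.vf:
            lo = self._optimize(self._net(rid), "min")
            hi = self._optimize(self._net(rid), "max")
            out[rid] = (lo, hi)
        return out

    def min_influx_two_stage(self, rids, sum_tol_rel=1e-6):
        """Parsimonious minimum summed influx over ``rids`` (fresh problem)."""
        self._prepare_parsimonious(sum_tol_rel)
        expr = 0
        for rid in rids:
            expr = expr + self.vb[rid] - self.vf[rid]
        return self._optimize(expr, "min")
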