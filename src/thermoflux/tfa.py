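"""Thermodynamically constrained flux analysis (TFA) as a MILP.

Each reaction's net flux is split into forward/backward parts.  For every
reaction whose standard Gibbs energy is estimable from the thermodynamic
table, the problem carries a transformed reaction energy variable

    drG' = drG'0 + slack + RT * sum_j s_j ln(c_j),   slack in [-err, +err],

metabolite log-concentration variables ln(c_j) bounded by measurements or
the default range, and direction-use binaries coupling flux sign to the sign
of drG': forward flux forces drG' <= -eps, backward flux forces
drG' >= +eps.  This is the second law at the reaction level and, because
drG' sums to zero around any closed cycle, it excludes thermodynamically
infeasible loop flux by construction.

On top of the MILP the module provides FBA, parsimonious FBA (pFBA: biomass
fixed at its optimum, total |flux| minimized) and parsimonious thermodynamic
flux variability analysis (pTFVA: per-reaction min/max with the pFBA total
flux as an additional constraint).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InfeasibleModelError
from .solver import INFEASIBLE, OPTIMAL, LinearProblem, SolveResult, SolverError
from .thermo import PROTON_IDS, ReactionThermo, ThermoTable, reaction_delta_g0_detailed

logger = logging.getLogger(__name__)

#: default metabolite concentration range, mol per total protein
DEFAULT_CONC_RANGE = (1e-12, 0.1)
#: conventional flux cap, mmol/(gDW*h)
BIG_M = 1000.0
#: strict-inequality surrogate on drG', kJ/mol; must sit well above the MILP
#: feasibility tolerance (~1e-6) or closed thermodynamic cycles could
#: circulate within solver slack, yet is negligible against RT ~ 2.6 kJ/mol
EPSILON_DG = 1e-3
#: relative numerical cushion used where the total-flux minimum is re-imposed;
#: no modelling slack is intended, but the MILP needs a closed neighbourhood
SUM_TOL_REL = 1e-6

RAW = "raw"
GROWTH_NORMALIZED = "growth_normalized"
FEATURE_SCALED = "feature_scaled"
CONTROL_RATIO = "control_ratio"


@dataclass
class FluxRangeSet:
    """Per-reaction [min, max] net-flux intervals for one model instance.

    Exchange convention: flux > 0 is secretion, < 0 is uptake.
    """

    ranges: pd.DataFrame  # index: reaction id; columns: minimum, maximum
    instance: str
    state: str = RAW
    biomass_id: str | None = None
    biomass_flux: float | None = None
    subsystems: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = self.ranges["minimum"] > self.ranges["maximum"] + 1e-9
        if bad.any():
            raise ValueError(
                f"min > max for reactions: {list(self.ranges.index[bad])[:5]}")

    @property
    def reactions(self) -> list[str]:
        return list(self.ranges.index)

    def copy_with(self, ranges: pd.DataFrame, state: str) -> "FluxRangeSet":
        return FluxRangeSet(ranges=ranges, instance=self.instance, state=state,
                            biomass_id=self.biomass_id,
                            biomass_flux=self.biomass_flux,
                            subsystems=dict(self.subsystems))

    def to_tsv(self, path: str | Path) -> None:
        out = self.ranges.copy()
        out.insert(0, "subsystem", [self.subsystems.get(r, "") for r in out.index])
        out["state"] = self.state
        out.index.name = "reaction"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, instance: str,
                 biomass_id: str | None = None,
                 biomass_flux: float | None = None) -> "FluxRangeSet":
        df = pd.read_csv(path, sep="\t", index_col="reaction")
        state = df["state"].iloc[0] if len(df) else RAW
        subsystems = df["subsystem"].fillna("").to_dict()
        return cls(ranges=df[["minimum", "maximum"]], instance=instance,
                   state=state, biomass_id=biomass_id, biomass_flux=biomass_flux,
                   subsystems=subsystems)


class TFAProblem:
    """MILP for one condition-specific model instance.

    Parameters
    ----------
    model:
        cobra model with bounds already set for the condition.
    thermo:
        thermodynamic table; ``None`` (or ``include_thermo=False``) builds the
        plain FBA/FVA relaxation with the same flux variables.
    conc_bounds:
        measured metabolite concentration intervals, ``id -> (lb, ub)`` in
        mol per total protein; intervals outside the default range are
        clipped with a warning.  Unmeasured metabolites get the default.
    """

    def __init__(self, model: cobra.Model, thermo: ThermoTable | None = None,
                 conc_bounds: dict[str, tuple[float, float]] | None = None,
                 id_map: dict[str, str] | None = None,
                 biomass_id: str | None = None,
                 include_thermo: bool = True,
                 big_m: float = BIG_M,
                 epsilon: float = EPSILON_DG,
                 conc_default: tuple[float, float] = DEFAULT_CONC_RANGE):
        self.model = model
        self.thermo = thermo if include_thermo else None
        self.id_map = id_map or {}
        self.big_m = big_m
        self.epsilon = epsilon
        self.conc_default = conc_default
        if biomass_id is None:
            from .model_io import find_biomass_reaction
            rxn = find_biomass_reaction(model)
            biomass_id = rxn.id if rxn is not None else None
        if biomass_id is None:
            raise ConfigurationError("a biomass reaction id is required")
        self.biomass_id = biomass_id
        self.rt = self.thermo.rt if self.thermo is not None else 2.5789

        self.lp = LinearProblem()
        self.vf: dict[str, int] = {}
        self.vb: dict[str, int] = {}
        self.net_rows: dict[str, int] = {}
        self.lnc: dict[str, int] = {}
        self.drg: dict[str, int] = {}
        self.yf: dict[str, int] = {}
        self.yb: dict[str, int] = {}
        self.reaction_thermo: dict[str, ReactionThermo] = {}
        self.min_total_flux: float | None = None
        self.pfba_solution: pd.Series | None = None
        self._pfba_x: np.ndarray | None = None
        self._sum_row: int | None = None
        self._biomass_row: int | None = None
        self._build(conc_bounds or {})

    # -- construction --------------------------------------------------
    def _build(self, conc_bounds) -> None:
        lp = self.lp
        for rxn in self.model.reactions:
            lb, ub = rxn.bounds
            fcap = min(self.big_m, max(ub, 0.0))
            bcap = min(self.big_m, max(-lb, 0.0))
            self.vf[rxn.id] = lp.add_variable(f"vf_{rxn.id}", 0.0, fcap)
            self.vb[rxn.id] = lp.add_variable(f"vb_{rxn.id}", 0.0, bcap)
            self.net_rows[rxn.id] = lp.add_constraint(
                {self.vf[rxn.id]: 1.0, self.vb[rxn.id]: -1.0}, lb, ub,
                name=f"net_{rxn.id}")

        for met in self.model.metabolites:
            coeffs: dict[int, float] = {}
            for rxn in met.reactions:
                s = rxn.metabolites[met]
                coeffs[self.vf[rxn.id]] = coeffs.get(self.vf[rxn.id], 0.0) + s
                coeffs[self.vb[rxn.id]] = coeffs.get(self.vb[rxn.id], 0.0) - s
            lp.add_constraint(coeffs, 0.0, 0.0, name=f"mass_{met.id}")

        if self.thermo is not None:
            self._add_thermo_constraints(conc_bounds)

    def _thermo_eligible(self, rxn: cobra.Reaction) -> bool:
        return not rxn.boundary and rxn.id != self.biomass_id

    def _lnc_var(self, met: cobra.Metabolite, conc_bounds) -> int:
        if met.id in self.lnc:
            return self.lnc[met.id]
        lo, hi = self.conc_default
        if met.id in conc_bounds:
            mlo, mhi = conc_bounds[met.id]
            if mlo < lo or mhi > hi:
                logger.warning("concentration bounds for %s clipped into default range",
                               met.id)
            lo, hi = max(mlo, lo), min(mhi, hi)
        idx = self.lp.add_variable(f"lnc_{met.id}", math.log(lo), math.log(hi))
        self.lnc[met.id] = idx
        return idx

    def _add_thermo_constraints(self, conc_bounds) -> None:
        lp = self.lp
        specs = self.thermo.compartments
        for rxn in self.model.reactions:
            if not self._thermo_eligible(rxn):
                continue
            participants = [
                (m.id, m.compartment, coef, float(m.charge or 0.0))
                for m, coef in rxn.metabolites.items()]
            rt_info = reaction_delta_g0_detailed(participants, self.thermo, self.id_map)
            self.reaction_thermo[rxn.id] = rt_info
            if not rt_info.estimable:
                continue

            # drG' = drG0 + slack + RT * sum s_j ln c_j
            drg = lp.add_variable(f"drg_{rxn.id}", -np.inf, np.inf)
            slack = lp.add_variable(f"dgerr_{rxn.id}",
                                    -rt_info.drG0_error, rt_info.drG0_error)
            row = {drg: 1.0, slack: -1.0}
            span = 0.0
            for m, coef in rxn.metabolites.items():
                cid = self.id_map.get(m.id, m.id)
                if cid.lower() in PROTON_IDS:
                    continue  # proton activity folded into drG0 via pH
                j = self._lnc_var(m, conc_bounds)
                row[j] = row.get(j, 0.0) - self.rt * coef
                lo, hi = lp.variable_bounds(j)
                span += abs(coef) * max(abs(lo), abs(hi))
            lp.add_constraint(row, rt_info.drG0_prime, rt_info.drG0_prime,
                              name=f"dg_{rxn.id}")

            big_k = (abs(rt_info.drG0_prime) + rt_info.drG0_error
                     + self.rt * span + self.epsilon + 1.0)
            yf = lp.add_variable(f"yf_{rxn.id}", 0.0, 1.0, integer=True)
            yb = lp.add_variable(f"yb_{rxn.id}", 0.0, 1.0, integer=True)
            self.drg[rxn.id], self.yf[rxn.id], self.yb[rxn.id] = drg, yf, yb
            lp.add_constraint({self.vf[rxn.id]: 1.0, yf: -self.big_m}, -np.inf, 0.0,
                              name=f"use_f_{rxn.id}")
            lp.add_constraint({self.vb[rxn.id]: 1.0, yb: -self.big_m}, -np.inf, 0.0,
                              name=f"use_b_{rxn.id}")
            lp.add_constraint({yf: 1.0, yb: 1.0}, 0.0, 1.0, name=f"use_xor_{rxn.id}")
            # yf = 1  =>  drG' <= -eps ;  yb = 1  =>  drG' >= +eps
            lp.add_constraint({drg: 1.0, yf: big_k}, -np.inf, big_k - self.epsilon,
                              name=f"couple_f_{rxn.id}")
            lp.add_constraint({drg: -1.0, yb: big_k}, -np.inf, big_k - self.epsilon,
                              name=f"couple_b_{rxn.id}")

    # -- bound handling -------------------------------------------------
    def set_reaction_bounds(self, rid: str, lb: float, ub: float) -> None:
        if lb > ub:
            raise ValueError(f"lb > ub for {rid}")
        self.lp.set_variable_bounds(self.vf[rid], 0.0, min(self.big_m, max(ub, 0.0)))
        self.lp.set_variable_bounds(self.vb[rid], 0.0, min(self.big_m, max(-lb, 0.0)))
        self.lp.set_constraint_bounds(self.net_rows[rid], lb, ub)

    def reaction_bounds(self, rid: str) -> tuple[float, float]:
        return self.lp.constraint_bounds(self.net_rows[rid])

    def _net_coeffs(self, rid: str) -> dict[int, float]:
        return {self.vf[rid]: 1.0, self.vb[rid]: -1.0}

    def net_flux(self, x: np.ndarray, rid: str) -> float:
        return float(x[self.vf[rid]] - x[self.vb[rid]])

    def flux_vector(self, x: np.ndarray) -> pd.Series:
        return pd.Series({rid: self.net_flux(x, rid) for rid in self.vf},
                         name="flux")

    # -- solves ----------------------------------------------------------
    def solve_fba(self, objective_reaction: str | None = None,
                  direction: str = "max") -> SolveResult:
        rid = objective_reaction or self.biomass_id
        self.lp.set_objective(self._net_coeffs(rid), sense=direction)
        res = self.lp.solve()
        if res.status == INFEASIBLE:
            raise InfeasibleModelError(
                f"FBA infeasible for objective {rid}",
                diagnostics=self.diagnose_infeasibility())
        if not res.ok:
            raise SolverError(res.status, f"FBA on {rid}")
        return res

    def solve_pfba(self) -> SolveResult:
        """Fix biomass at its optimum, then minimize total flux sum."""
        if self._sum_row is not None:  # drop any stale parsimony cap
            self.lp.set_constraint_bounds(self._sum_row, -np.inf, np.inf)
        if self._biomass_row is not None:
            self.lp.set_constraint_bounds(self._biomass_row, -np.inf, np.inf)
        fba = self.solve_fba(self.biomass_id, "max")
        opt = fba.objective
        if self._biomass_row is None:
            self._biomass_row = self.lp.add_constraint(
                self._net_coeffs(self.biomass_id), opt, opt, name="biomass_fix")
        else:
            self.lp.set_constraint_bounds(self._biomass_row, opt, opt)
        total = {}
        for rid in self.vf:
            total[self.vf[rid]] = 1.0
            total[self.vb[rid]] = 1.0
        self.lp.set_objective(total, sense="min")
        res = self.lp.solve()
        if not res.ok:
            raise SolverError(res.status, "pFBA flux-sum minimization")
        self.min_total_flux = res.objective
        self._pfba_x = res.x
        self.pfba_solution = self.flux_vector(res.x)
        return res

    def _activate_sum_constraint(self, active: bool = True) -> None:
        if self.min_total_flux is None:
            raise ConfigurationError("run solve_pfba() before pTFVA")
        ub = self.min_total_flux + SUM_TOL_REL * abs(self.min_total_flux) + 1e-9
        total = {}
        for rid in self.vf:
            total[self.vf[rid]] = 1.0
            total[self.vb[rid]] = 1.0
        if self._sum_row is None:
            self._sum_row = self.lp.add_constraint(total, -np.inf, ub, name="pfba_sum")
        self.lp.set_constraint_bounds(self._sum_row, -np.inf,
                                      ub if active else np.inf)

    def solve_ptfva(self, reactions: list[str] | None = None,
                    parsimonious: bool = True,
                    instance: str = "instance",
                    collect_solutions: bool = False,
                    ) -> FluxRangeSet | tuple[FluxRangeSet, list[np.ndarray]]:
        """Per-reaction net-flux minima/maxima (pTFVA, or plain TFVA).

        With ``parsimonious=True`` the pFBA total-flux minimum is imposed as
        an additional constraint; the returned ranges then contain the pFBA
        solution.  Work is independent per reaction, so any partition over
        reactions yields identical results.
        """
        if parsimonious:
            if self.min_total_flux is None:
                self.solve_pfba()
            self._activate_sum_constraint(True)
        elif self._sum_row is not None:
            self._activate_sum_constraint(False)
        rids = reactions if reactions is not None else list(self.vf)
        mins, maxs = {}, {}
        solutions: list[np.ndarray] = []
        for rid in rids:
            lohi = []
            for sense in ("min", "max"):
                self.lp.set_objective(self._net_coeffs(rid), sense=sense)
                res = self.lp.solve()
                if not res.ok:
                    logger.warning("pTFVA %s of %s failed: %s", sense, rid, res.status)
                    lohi.append(math.nan)
                else:
                    lohi.append(res.objective)
                    if collect_solutions:
                        solutions.append(res.x)
            mins[rid], maxs[rid] = lohi
        # clamp solver noise so minimum <= maximum always holds
        df = pd.DataFrame({"minimum": mins, "maximum": maxs}).loc[rids]
        swap = df["minimum"] > df["maximum"]
        df.loc[swap, ["minimum", "maximum"]] = df.loc[
            swap, ["maximum", "minimum"]].to_numpy()
        biomass_flux = (float(self.pfba_solution[self.biomass_id])
                        if self.pfba_solution is not None else None)
        out = FluxRangeSet(
            ranges=df, instance=instance, state=RAW, biomass_id=self.biomass_id,
            biomass_flux=biomass_flux,
            subsystems={r.id: r.subsystem for r in self.model.reactions})
        if collect_solutions:
            return out, solutions
        return out

    # -- diagnostics ------------------------------------------------------
    def check_second_law(self, x: np.ndarray, flux_tol: float = 1e-6) -> list[str]:
        """Ids of reactions violating sign(flux) vs sign(drG') in solution x."""
        bad = []
        for rid, j in self.drg.items():
            v = self.net_flux(x, rid)
            g = x[j]
            if v > flux_tol and g >= 0.0:
                bad.append(rid)
            elif v < -flux_tol and g <= 0.0:
                bad.append(rid)
        return bad

    def assert_feasible(self) -> None:
        self.lp.set_objective({}, sense="min")
        res = self.lp.solve()
        if res.status == INFEASIBLE:
            raise InfeasibleModelError(
                "TFA problem infeasible", diagnostics=self.diagnose_infeasibility())

    def diagnose_infeasibility(self) -> dict[str, float]:
        """Minimal L1 relaxation of reaction bounds restoring feasibility.

        Returns the reactions whose bounds must move, with the violation
        magnitude; empty when the problem is feasible as stated.
        """
        relaxed = LinearProblem()
        relaxed._names = list(self.lp._names)
        relaxed._lb = list(self.lp._lb)
        relaxed._ub = list(self.lp._ub)
        relaxed._integer = list(self.lp._integer)
        relaxed._rows = [dict(r) for r in self.lp._rows]
        relaxed._row_lb = list(self.lp._row_lb)
        relaxed._row_ub = list(self.lp._row_ub)
        relaxed._row_names = list(self.lp._row_names)
        obj = {}
        slack_of = {}
        for rid in self.net_rows:
            # lift the split-variable caps so only the net rows bind
            relaxed._ub[self.vf[rid]] = self.big_m
            relaxed._ub[self.vb[rid]] = self.big_m
        for rid, row in self.net_rows.items():
            up = relaxed.add_variable(f"relax_up_{rid}", 0.0, np.inf)
            dn = relaxed.add_variable(f"relax_dn_{rid}", 0.0, np.inf)
            relaxed._rows[row][up] = 1.0
            relaxed._rows[row][dn] = -1.0
            relaxed._A = None
            obj[up] = 1.0
            obj[dn] = 1.0
            slack_of[rid] = (up, dn)
        relaxed.set_objective(obj, sense="min")
        res = relaxed.solve()
        if not res.ok:
            return {}
        out = {}
        for rid, (up, dn) in slack_of.items():
            v = float(res.x[up] + res.x[dn])
            if v > 1e-9:
                out[rid] = v
        return out
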