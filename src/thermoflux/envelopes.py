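"""Oxygen / fatty-acid production envelopes and key-flux extraction.

Hypoxia counterfactuals for a constrained instance: the oxygen exchange is
pinned to a grid of influx values and the minimum total fatty-acid influx is
computed at each point (or vice versa, at several biomass levels).  Each
grid point is solved as a fresh parsimonious problem -- biomass maximized
within its measured band, total flux sum minimized and re-imposed -- before
the target influx is minimized, so the curves are consistent with the
instance's own parsimonious variability analysis at its operating point.

Influx means uptake magnitude, i.e. minus the exchange flux (exchange flux
> 0 is secretion).  Pinning uses equality by default; an upper-bound mode
(influx <= grid value) is available and makes the minimum-fatty-acid curve
monotone non-increasing.  The total-minimizing fatty-acid solution is
usually degenerate across substrates; the per-substrate breakdown is made
unique by lexicographic secondary minimization in the configured substrate
order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .tfa import BIG_M, TFAProblem

logger = logging.getLogger(__name__)

#: relative half-width used when pinning a flux to a value (closed MILP sets)
PIN_TOL_REL = 1e-6
PIN_TOL_ABS = 1e-9
#: looser window for the secondary (per-substrate) pins: these stack on top
#: of the grid pin and the parsimony cap, and only the reported split -- not
#: the envelope minima -- depends on them
BREAKDOWN_TOL_ABS = 1e-6

REQUIRED_ROLES = ("oxygen_uptake", "atp_synthase", "lactate_secretion",
                  "fatty_acid_exchanges")


@dataclass
class EnvelopeCurve:
    """One sweep: grid of pinned influxes and minimized target values."""

    swept: str
    minimized: str
    grid: np.ndarray                 # pinned influx, mmol/(gDW h)
    minima: np.ndarray               # minimized influx per grid point
    feasible: np.ndarray
    biomass: np.ndarray              # biomass flux at each solved point
    breakdown: pd.DataFrame | None = None   # per-substrate influx columns
    label: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def grid_normalized(self) -> np.ndarray:
        """Grid in growth-normalized units (per unit biomass flux)."""
        return self.grid / self.biomass

    @property
    def minima_normalized(self) -> np.ndarray:
        return self.minima / self.biomass

    def argmin(self) -> float:
        """Grid value minimizing the target (feasible points only)."""
        vals = np.where(self.feasible, self.minima, np.inf)
        return float(self.grid[int(np.argmin(vals))])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"grid_value": self.grid, "min_value": self.minima,
                           "feasible": self.feasible,
                           "biomass_flux": self.biomass,
                           "grid_value_per_biomass": self.grid_normalized,
                           "min_value_per_biomass": self.minima_normalized})
        if self.breakdown is not None:
            df = pd.concat([df, self.breakdown.reset_index(drop=True)], axis=1)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def key_fluxes(ranges, config: dict) -> pd.DataFrame:
    """Oxygen uptake, ATP synthase, lactate secretion and fatty-acid influx.

    ``config`` maps the roles {oxygen_uptake, atp_synthase,
    lactate_secretion, fatty_acid_exchanges} to reaction ids; fatty-acid
    influx is the (additive) sum of the configured exchange ranges.  Values
    are reported in the normalization state of ``ranges``.
    """
    for role in REQUIRED_ROLES:
        if role not in config:
            raise ConfigurationError(f"role {role!r} not mapped to a reaction id")
    rows = []
    for role in ("oxygen_uptake", "atp_synthase", "lactate_secretion"):
        rid = config[role]
        if rid not in ranges.ranges.index:
            raise ConfigurationError(f"reaction {rid!r} for role {role!r} missing")
        lo, hi = ranges.ranges.loc[rid, ["minimum", "maximum"]]
        rows.append({"role": role, "reaction": rid, "minimum": lo, "maximum": hi})
    total_lo = total_hi = 0.0
    for rid in config["fatty_acid_exchanges"]:
        if rid not in ranges.ranges.index:
            raise ConfigurationError(f"fatty-acid exchange {rid!r} missing")
        lo, hi = ranges.ranges.loc[rid, ["minimum", "maximum"]]
        rows.append({"role": "fatty_acid_exchange", "reaction": rid,
                     "minimum": lo, "maximum": hi})
        total_lo += lo
        total_hi += hi
    rows.append({"role": "fatty_acid_influx_total", "reaction": "(sum)",
                 "minimum": total_lo, "maximum": total_hi})
    df = pd.DataFrame(rows)
    df["instance"] = ranges.instance
    df["state"] = ranges.state
    return df


# ---------------------------------------------------------------------------
# sweep machinery
# ---------------------------------------------------------------------------

def parsimonious_min_influx(problem: TFAProblem, rids: list[str]):
    """The instance's own minimum total influx over ``rids``.

    Solved under the instance's parsimony cap (pFBA must have run); returns
    the minimum summed influx and the full flux solution at the optimum --
    the operating point any sweep passing through it must reproduce.
    """
    problem._activate_sum_constraint(True)
    val, x = _min_influx(problem, rids)
    if val is None:
        raise ConfigurationError("no feasible influx under the parsimony cap")
    return val, problem.flux_vector(x)


def _pin_window(value: float, loose: bool = False) -> tuple[float, float]:
    hw = (BREAKDOWN_TOL_ABS if loose else PIN_TOL_ABS) + PIN_TOL_REL * abs(value)
    return value - hw, value + hw


class _Sweeper:
    """Pins/restores exchange bounds on a TFAProblem during a sweep."""

    def __init__(self, problem: TFAProblem):
        self.problem = problem
        self._saved: dict[str, tuple[float, float]] = {}
        self._fa_row: int | None = None

    def save(self, rid: str) -> None:
        if rid not in self._saved:
            self._saved[rid] = self.problem.reaction_bounds(rid)

    def relax(self, rid: str, lb: float = -BIG_M, ub: float = BIG_M) -> None:
        self.save(rid)
        self.problem.set_reaction_bounds(rid, lb, ub)

    def pin_influx(self, rid: str, influx: float, mode: str = "equality") -> None:
        self.save(rid)
        lo, hi = _pin_window(-influx)
        if mode == "equality":
            self.problem.set_reaction_bounds(rid, lo, hi)
        elif mode == "upper":  # influx <= grid value
            self.problem.set_reaction_bounds(rid, lo, 0.0)
        else:
            raise ConfigurationError(f"unknown pin mode {mode!r}")

    def pin_total_influx(self, rids: list[str], influx: float | None,
                         loose: bool = False) -> None:
        coeffs = {}
        for rid in rids:
            coeffs[self.problem.vf[rid]] = -1.0
            coeffs[self.problem.vb[rid]] = 1.0
        if self._fa_row is None:
            self._fa_row = self.problem.lp.add_constraint(
                coeffs, -np.inf, np.inf, name="total_influx_pin")
        if influx is None:
            self.problem.lp.set_constraint_bounds(self._fa_row, -np.inf, np.inf)
        else:
            lo, hi = _pin_window(influx, loose=loose)
            self.problem.lp.set_constraint_bounds(self._fa_row, lo, hi)

    def restore(self) -> None:
        for rid, (lb, ub) in self._saved.items():
            self.problem.set_reaction_bounds(rid, lb, ub)
        self._saved.clear()
        if self._fa_row is not None:
            self.problem.lp.set_constraint_bounds(self._fa_row, -np.inf, np.inf)


def _influx_objective(problem: TFAProblem, rids: list[str]) -> dict[int, float]:
    obj: dict[int, float] = {}
    for rid in rids:
        obj[problem.vf[rid]] = obj.get(problem.vf[rid], 0.0) - 1.0
        obj[problem.vb[rid]] = obj.get(problem.vb[rid], 0.0) + 1.0
    return obj


def _min_influx(problem: TFAProblem, rids: list[str]):
    """Minimize total influx over ``rids``; returns (value, solution) or (None, None)."""
    problem.lp.set_objective(_influx_objective(problem, rids), sense="min")
    res = problem.lp.solve()
    if not res.ok:
        return None, None
    return res.objective, res.x


def _parsimonious_point(problem: TFAProblem) -> bool:
    """Re-run pFBA at the current bounds and re-impose the flux-sum minimum."""
    try:
        problem.solve_pfba()
    except Exception:
        return False
    problem._activate_sum_constraint(True)
    return True


def _lexicographic_breakdown(problem: TFAProblem, fa_ids: list[str],
                             sweeper: _Sweeper,
                             fallback: np.ndarray | None) -> dict[str, float]:
    """Unique per-substrate influxes at the current optimum, in config order.

    Substrates are minimized one after another, each pinned at its optimum
    before the next solve.  Where a refinement solve fails numerically (the
    feasible set can be a knife edge at the grid boundary) the split observed
    in the total-minimization solution is reported instead.
    """
    out = {}
    for rid in fa_ids:
        val, _ = _min_influx(problem, [rid])
        if val is None:
            out[rid] = (-problem.net_flux(fallback, rid)
                        if fallback is not None else math.nan)
            continue
        out[rid] = val
        sweeper.save(rid)
        lo, hi = _pin_window(-val, loose=True)
        problem.set_reaction_bounds(rid, min(lo, hi), max(lo, hi))
    return out


def sweep_min_fa(problem: TFAProblem, oxygen_exchange: str,
                 fatty_acid_exchanges: list[str],
                 o2_grid=None, n_points: int = 10,
                 mode: str = "equality",
                 also_relax: list[str] | None = None,
                 label: str = "") -> EnvelopeCurve:
    """Minimum fatty-acid influx as the oxygen influx is swept.

    The oxygen exchange is relaxed, the grid (if not given) starts at the
    minimum feasible oxygen influx, and at each point the exchange is pinned
    and the summed fatty-acid influx minimized under that point's own
    parsimonious constraint.  Fatty-acid exchanges are opened for the sweep;
    ``also_relax`` lists further exchanges (typically the oxidation products)
    to open so that off-operating-point states are reachable.
    """
    sw = _Sweeper(problem)
    try:
        sw.relax(oxygen_exchange, -BIG_M, 0.0)
        for rid in fatty_acid_exchanges:
            sw.relax(rid, -BIG_M, 0.0)
        for rid in also_relax or []:
            sw.relax(rid, -BIG_M, BIG_M)
        if o2_grid is None:
            o2_min, _ = _min_influx(problem, [oxygen_exchange])
            if o2_min is None:
                raise ConfigurationError("no feasible oxygen influx")
            lo = max(o2_min, 0.0)
            hi = 2.0 * max(lo, 1e-3)
            o2_grid = np.linspace(lo, hi, n_points)
        o2_grid = np.asarray(o2_grid, dtype=float)

        minima, feas, biomass = [], [], []
        breakdown_rows = []
        for g in o2_grid:
            sw.pin_influx(oxygen_exchange, g, mode=mode)
            ok = _parsimonious_point(problem)
            val, xsol = _min_influx(problem, fatty_acid_exchanges) if ok else (None, None)
            if val is None:
                minima.append(math.nan)
                feas.append(False)
                biomass.append(math.nan)
                breakdown_rows.append({rid: math.nan for rid in fatty_acid_exchanges})
                logger.warning("envelope point O2=%.4g infeasible", g)
                continue
            # hold the total at its optimum while splitting by substrate
            sw.pin_total_influx(fatty_acid_exchanges, val, loose=True)
            breakdown_rows.append(
                _lexicographic_breakdown(problem, fatty_acid_exchanges, sw, xsol))
            sw.pin_total_influx(fatty_acid_exchanges, None)
            for rid in fatty_acid_exchanges:
                problem.set_reaction_bounds(rid, -BIG_M, 0.0)
            minima.append(val)
            feas.append(True)
            biomass.append(float(problem.pfba_solution[problem.biomass_id]))
        return EnvelopeCurve(
            swept="oxygen_influx", minimized="fatty_acid_influx",
            grid=o2_grid, minima=np.asarray(minima),
            feasible=np.asarray(feas, dtype=bool),
            biomass=np.asarray(biomass),
            breakdown=pd.DataFrame(breakdown_rows), label=label)
    finally:
        sw.restore()
        _parsimonious_point(problem)


def sweep_min_o2(problem: TFAProblem, oxygen_exchange: str,
                 fatty_acid_exchanges: list[str], fa_grid,
                 biomass_levels=None,
                 also_relax: list[str] | None = None,
                 label: str = "") -> list[EnvelopeCurve]:
    """Minimum oxygen influx as total fatty-acid influx is swept.

    One curve per biomass level (biomass flux values in model units); with
    ``biomass_levels=None`` the instance's own biomass bounds are kept.
    """
    fa_grid = np.asarray(fa_grid, dtype=float)
    levels = biomass_levels if biomass_levels is not None else [None]
    curves = []
    for level in levels:
        sw = _Sweeper(problem)
        try:
            sw.relax(oxygen_exchange, -BIG_M, 0.0)
            for rid in fatty_acid_exchanges:
                sw.relax(rid, -BIG_M, 0.0)
            for rid in also_relax or []:
                sw.relax(rid, -BIG_M, BIG_M)
            if level is not None:
                sw.save(problem.biomass_id)
                lo, hi = _pin_window(level)
                problem.set_reaction_bounds(problem.biomass_id, lo, hi)
            minima, feas, biomass = [], [], []
            for g in fa_grid:
                sw.pin_total_influx(fatty_acid_exchanges, g)
                ok = _parsimonious_point(problem)
                val, _ = _min_influx(problem, [oxygen_exchange]) if ok else (None, None)
                if val is None:
                    minima.append(math.nan)
                    feas.append(False)
                    biomass.append(math.nan)
                    logger.warning("envelope point FA=%.4g infeasible", g)
                else:
                    minima.append(val)
                    feas.append(True)
                    biomass.append(float(problem.pfba_solution[problem.biomass_id]))
            sw.pin_total_influx(fatty_acid_exchanges, None)
            curves.append(EnvelopeCurve(
                swept="fatty_acid_influx", minimized="oxygen_influx",
                grid=fa_grid, minima=np.asarray(minima),
                feasible=np.asarray(feas, dtype=bool),
                biomass=np.asarray(biomass),
                label=label or (f"biomass={level:g}" if level is not None else "")))
        finally:
            sw.restore()
            _parsimonious_point(problem)
    return curves
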