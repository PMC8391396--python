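"""Thin LP/MILP layer over scipy's HiGHS interface.

All flux, thermodynamic and envelope problems in this package are expressed
as one :class:`LinearProblem` each: continuous or binary variables, sparse
row constraints, and a linear objective.  Variable and row bounds are
mutable so that variability analyses and envelope sweeps can re-solve the
same problem with pinned values instead of rebuilding it.

Statuses follow the convention {optimal, infeasible, unbounded, limit}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

#: scipy.optimize.milp status codes -> package statuses
_STATUS = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded", 4: "limit"}

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """Raised when a subproblem does not solve to optimality."""

    def __init__(self, status: str, context: str = ""):
        self.status = status
        super().__init__(f"solver returned status '{status}'" + (f" ({context})" if context else ""))


@dataclass
class SolveResult:
    status: str
    objective: float | None = None
    x: np.ndarray | None = None

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class LinearProblem:
    """A mutable mixed-integer linear program ``min c'x  s.t.  lb <= Ax <= ub``."""

    mip_rel_gap: float = 0.0
    feasibility_tol: float = 1e-9

    _names: list[str] = field(default_factory=list)
    _lb: list[float] = field(default_factory=list)
    _ub: list[float] = field(default_factory=list)
    _integer: list[bool] = field(default_factory=list)
    _rows: list[dict[int, float]] = field(default_factory=list)
    _row_lb: list[float] = field(default_factory=list)
    _row_ub: list[float] = field(default_factory=list)
    _row_names: list[str] = field(default_factory=list)
    _obj: dict[int, float] = field(default_factory=dict)
    _sense: int = 1  # 1 = minimize, -1 = maximize
    _A: sparse.csr_matrix | None = None

    # -- construction -------------------------------------------------
    def add_variable(self, name: str, lb: float = 0.0, ub: float = np.inf,
                     integer: bool = False) -> int:
        self._names.append(name)
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(integer)
        return len(self._names) - 1

    def add_constraint(self, coeffs: dict[int, float], lb: float, ub: float,
                       name: str = "") -> int:
        self._rows.append(dict(coeffs))
        self._row_lb.append(lb)
        self._row_ub.append(ub)
        self._row_names.append(name)
        self._A = None
        return len(self._rows) - 1

    # -- mutation ------------------------------------------------------
    def set_variable_bounds(self, idx: int, lb: float, ub: float) -> None:
        self._lb[idx] = lb
        self._ub[idx] = ub

    def variable_bounds(self, idx: int) -> tuple[float, float]:
        return self._lb[idx], self._ub[idx]

    def set_constraint_bounds(self, row: int, lb: float, ub: float) -> None:
        self._row_lb[row] = lb
        self._row_ub[row] = ub

    def constraint_bounds(self, row: int) -> tuple[float, float]:
        return self._row_lb[row], self._row_ub[row]

    def set_objective(self, coeffs: dict[int, float], sense: str = "min") -> None:
        if sense not in ("min", "max"):
            raise ValueError(f"unknown objective sense {sense!r}")
        self._obj = dict(coeffs)
        self._sense = 1 if sense == "min" else -1

    # -- solving -------------------------------------------------------
    @property
    def n_variables(self) -> int:
        return len(self._names)

    def _matrix(self) -> sparse.csr_matrix:
        if self._A is None or self._A.shape != (len(self._rows), self.n_variables):
            data, ri, ci = [], [], []
            for i, row in enumerate(self._rows):
                for j, v in row.items():
                    ri.append(i)
                    ci.append(j)
                    data.append(v)
            self._A = sparse.csr_matrix(
                (data, (ri, ci)), shape=(len(self._rows), self.n_variables))
        return self._A

    def solve(self) -> SolveResult:
        n = self.n_variables
        c = np.zeros(n)
        for j, v in self._obj.items():
            c[j] = self._sense * v
        constraints = None
        if self._rows:
            constraints = LinearConstraint(
                self._matrix(), np.asarray(self._row_lb), np.asarray(self._row_ub))
        res = milp(
            c,
            constraints=constraints,
            integrality=np.asarray(self._integer, dtype=int),
            bounds=Bounds(np.asarray(self._lb), np.asarray(self._ub)),
            options={"mip_rel_gap": self.mip_rel_gap},
        )
        status = _STATUS.get(res.status, "limit")
        if status != OPTIMAL:
            return SolveResult(status=status)
        return SolveResult(status=OPTIMAL, objective=self._sense * res.fun, x=res.x)

    def value(self, x: np.ndarray, coeffs: dict[int, float]) -> float:
        return float(sum(v * x[j] for j, v in coeffs.items()))
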