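"""Growth-rate and specific exchange-rate fitting with error propagation.

Growth: X(t) = X0 exp(mu t), fitted with a soft-L1 robust loss (rho(z) =
2(sqrt(1+z^2)-1), f_scale = 0.3) on *relative* residuals
(X0 exp(mu t_i) - y_i) / y_i.  Cell counts carry multiplicative noise
(assays report CVs, not SDs), so relative residuals give every time point
equal leverage -- with absolute residuals a late-time outlier dominates the
exponential's gradient and the robust loss loses its purpose -- and
f_scale = 0.3 acquires a meaning: deviations beyond ~30% are outliers.
Standard errors come from the Jacobian at the optimum.

Exchange: with mu and B0 = X0 * m_dw fixed from the growth fit, the medium
concentration of a metabolite with specific exchange rate q (mmol/(gDW h),
secretion positive) and first-order abiotic decay constant k obeys
dC/dt = q B(t)/V - k C, whose exact solution

    C(t) = C0 exp(-k t) + (q B0 / V) * (exp(mu t) - exp(-k t)) / (mu + k)

is linear in (C0, q); for k = 0 it reduces to the familiar
C(t) = C0 + q (B0/(mu V)) (exp(mu t) - 1).  k is fitted on a cell-free
control series and held fixed.  V is the medium volume in litres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DataError

logger = logging.getLogger(__name__)

F_SCALE = 0.3


@dataclass
class GrowthFit:
    x0: float
    mu: float          # 1/h
    se_x0: float
    se_mu: float
    loss: float

    def __post_init__(self):
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if self.se_mu < 0:
            raise ValueError("se_mu must be >= 0")


@dataclass
class BiomassCalibration:
    dry_mass_per_cell: float  # g/cell
    se_dry_mass: float = 0.0

    def __post_init__(self):
        if self.dry_mass_per_cell <= 0:
            raise ValueError("dry mass per cell must be positive")

    def b0(self, growth: GrowthFit) -> float:
        """Initial biomass, gDW."""
        return growth.x0 * self.dry_mass_per_cell


@dataclass
class ExchangeRate:
    metabolite: str
    q: float            # mmol/(gDW h), + secretion
    se_q: float
    lower_bound: float
    upper_bound: float

    def __post_init__(self):
        if not (self.lower_bound <= self.q <= self.upper_bound):
            raise ValueError(f"bounds do not bracket q for {self.metabolite}")


def fit_growth(times, counts, robust: bool = True) -> GrowthFit:
    """Fit X(t) = X0 exp(mu t) to cell counts.

    ``times`` and ``counts`` are flat arrays (replicates simply repeat time
    points).  At least three points are required and counts must be positive.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    if t.shape != y.shape:
        raise DataError("times and counts must have the same length")
    if t.size < 3:
        raise DataError("growth fit needs at least 3 points")
    if np.any(y <= 0):
        raise DataError("counts must be positive")

    # log-linear start values; a few deterministic restarts around the
    # log-linear slope guard against local optima of the robust objective
    slope, intercept = np.polyfit(t, np.log(y), 1)
    x0_init = math.exp(intercept)
    starts = [(x0_init, slope)]
    if robust:
        starts += [(x0_init, 0.5 * slope), (x0_init, 2.0 * slope),
                   (float(y[np.argmin(t)]), slope)]

    def residuals(p):
        return (p[0] * np.exp(p[1] * t) - y) / y

    res = None
    for p0 in starts:
        trial = least_squares(residuals, np.asarray(p0, dtype=float),
                              loss="soft_l1" if robust else "linear",
                              f_scale=F_SCALE, x_scale="jac")
        if trial.success and (res is None or trial.cost < res.cost):
            res = trial
    if res is None:
        raise DataError("growth fit did not converge from any start point")
    x0_hat, mu_hat = res.x

    se_x0, se_mu = _jacobian_se(res.jac, res.fun)
    return GrowthFit(x0=float(x0_hat), mu=float(mu_hat),
                     se_x0=se_x0, se_mu=se_mu, loss=float(res.cost))


def _jacobian_se(jac, fun):
    """Standard errors from the Jacobian at the optimum, (J'J)^-1 s^2."""
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = float(fun @ fun) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.array([np.inf, np.inf])
    return float(se[0]), float(se[1])


def fit_decay(times, concentrations) -> float:
    """First-order decay constant k (1/h) from a cell-free control series."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    keep = c > 0
    if keep.sum() < 2:
        raise DataError("decay fit needs at least 2 positive points")
    slope, _ = np.polyfit(t[keep], np.log(c[keep]), 1)
    return float(-slope)


def fit_exchange(times, concentrations, growth: GrowthFit,
                 calib: BiomassCalibration, metabolite: str = "",
                 abiotic_times=None, abiotic_concentrations=None,
                 volume_l: float = 1.0,
                 fix_c0: float | None = None) -> ExchangeRate:
    """Specific exchange rate from a medium time course.

    ``times``/``concentrations`` are flat arrays over replicates and time
    points (0 must be included).  If a cell-free series is supplied the decay
    constant is fitted first and held fixed.  ``fix_c0`` pins the intercept
    instead of fitting it jointly.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.min() > 0:
        raise DataError("exchange fit requires a t=0 measurement")
    mu, b0 = growth.mu, calib.b0(growth)

    k = 0.0
    if abiotic_times is not None and abiotic_concentrations is not None:
        k = fit_decay(abiotic_times, abiotic_concentrations)

    a = biomass_integral(t, mu, b0, volume_l, k)
    if mu <= 1e-12:
        logger.info("mu <= 0 for %s; biomass integral is linear in t",
                    metabolite)
    c0_basis = np.exp(-k * t)

    # replicated time points: errors are reported at single-replicate level
    # (pooled-fit SE times sqrt(replicates)), a deliberately conservative
    # convention for flux-bound setting
    n_unique = np.unique(t).size
    replicate_factor = math.sqrt(t.size / n_unique) if n_unique else 1.0

    if fix_c0 is None:
        design = np.column_stack([c0_basis, a])
        coef, *_ = np.linalg.lstsq(design, c, rcond=None)
        c0_hat, q_hat = coef
        fitted = design @ coef
        dof = max(t.size - 2, 1)
        resid = c - fitted
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
        se_fit = math.sqrt(max(cov[1, 1], 0.0))
    else:
        y2 = c - fix_c0 * c0_basis
        denom = float(a @ a)
        if denom == 0.0:
            raise DataError("no biomass signal; q is unidentifiable")
        q_hat = float(a @ y2) / denom
        resid = y2 - q_hat * a
        dof = max(t.size - 1, 1)
        s2 = float(resid @ resid) / dof
        se_fit = math.sqrt(s2 / denom)

    # propagate growth and dry-mass uncertainty into the rate (first order)
    rel_parts = []
    if growth.mu != 0 and growth.se_mu > 0:
        rel_parts.append(growth.se_mu / abs(growth.mu))
    if calib.se_dry_mass > 0:
        rel_parts.append(calib.se_dry_mass / calib.dry_mass_per_cell)
    rel = combine_relative_errors(rel_parts)
    se_q = math.sqrt((se_fit * replicate_factor)**2 + (q_hat * rel)**2)
    lo, hi = propagate_bounds(float(q_hat), se_q, mode="propagated")
    return ExchangeRate(metabolite=metabolite, q=float(q_hat), se_q=se_q,
                        lower_bound=lo, upper_bound=hi)


def biomass_integral(t, mu: float, b0: float, volume_l: float,
                     k: float = 0.0) -> np.ndarray:
    """Coefficient of q in the medium-concentration model.

    Exact solution of dC/dt = q B0 exp(mu t)/V - k C for the q-dependent
    part; handles the mu + k -> 0 limit.
    """
    t = np.asarray(t, dtype=float)
    if abs(mu + k) < 1e-12:
        core = t * np.exp(mu * t)
    else:
        core = (np.exp(mu * t) - np.exp(-k * t)) / (mu + k)
    return (b0 / volume_l) * core


def combine_relative_errors(relative_errors) -> float:
    """Relative error of a product of independent factors, in quadrature."""
    return math.sqrt(sum(r * r for r in relative_errors))


def propagate_bounds(estimate: float, se: float, mode: str = "propagated",
                     ) -> tuple[float, float]:
    """Flux bounds from an estimate and its error.

    ``propagated``: estimate -+ se (se absolute).  ``relative``:
    estimate * (1 -+ se) with se a relative error; ordering is enforced after
    sign handling.
    """
    if se < 0:
        raise ValueError("se must be >= 0")
    if mode == "propagated":
        lo, hi = estimate - se, estimate + se
    elif mode == "relative":
        lo, hi = estimate * (1.0 - se), estimate * (1.0 + se)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (lo, hi) if lo <= hi else (hi, lo)
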