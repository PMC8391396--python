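"""Thermodynamic data containers and standard reaction Gibbs energies.

The thermodynamic table carries one standard transformed formation energy
(dfG'0, kJ/mol) with an error estimate per compound (optionally per
compartment), plus the physicochemical state of each compartment (pH, ionic
strength, membrane potential relative to the external medium, temperature).
Formation energies are taken as already transformed to compartment
conditions; no Debye-Hueckel or pseudoisomer corrections are applied here.

For a reaction with stoichiometric coefficients ``s_j`` the standard
transformed reaction energy is

    drG'0 = sum_j s_j dfG'0_j  +  F * sum_j s_j z_j psi(comp_j)
            -  RT ln(10) * sum_{j in protons} s_j pH(comp_j)

i.e. the chemical term plus, for transport reactions, the electrical work of
moving charge across the membrane potential and the proton-gradient term
(RT ln10 * delta-pH per translocated proton).  Protons are excluded from the
chemical sum and from concentration variables: their activity is fixed by
the compartment pH.  The error is propagated in quadrature,
``err = sqrt(sum_j s_j^2 err_j^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

#: Faraday constant, kJ / (V * mol)
FARADAY = 96.485
#: gas constant, kJ / (mol * K)
GAS_CONSTANT = 8.314462618e-3

#: compound ids interpreted as the proton
PROTON_IDS = frozenset({"h", "h+", "proton"})


@dataclass(frozen=True)
class CompartmentSpec:
    """Physicochemical conditions of one compartment."""

    ph: float
    ionic_strength: float = 0.15      # mol/L
    membrane_potential: float = 0.0   # V, relative to the external medium
    temperature: float = 310.15       # K

    def __post_init__(self):
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"pH {self.ph} outside [0, 14]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ThermoTable:
    """Per-compound formation energies plus per-compartment conditions.

    ``compounds`` columns: compound_id, compartment, dfG0_prime, dfG0_error.
    A compartment value of ``"*"`` matches any compartment.
    """

    compounds: pd.DataFrame
    compartments: dict[str, CompartmentSpec] = field(default_factory=dict)

    REQUIRED = ("compound_id", "compartment", "dfG0_prime", "dfG0_error")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.compounds.columns]
        if missing:
            raise ValueError(f"thermo table missing columns: {missing}")
        if (self.compounds["dfG0_error"] < 0).any():
            raise ValueError("dfG0_error must be non-negative")
        self._index: dict[tuple[str, str], tuple[float, float]] = {}
        for row in self.compounds.itertuples(index=False):
            self._index[(row.compound_id, row.compartment)] = (
                float(row.dfG0_prime), float(row.dfG0_error))

    def lookup(self, compound_id: str, compartment: str) -> tuple[float, float] | None:
        """Formation energy and error, preferring an exact compartment match."""
        hit = self._index.get((compound_id, compartment))
        if hit is None:
            hit = self._index.get((compound_id, "*"))
        return hit

    def covers(self, compound_id: str, compartment: str) -> bool:
        return self.lookup(compound_id, compartment) is not None

    def temperature(self) -> float:
        """Single model temperature (K); compartments must agree to 0.1 K."""
        temps = sorted({spec.temperature for spec in self.compartments.values()})
        if not temps:
            return 310.15
        if temps[-1] - temps[0] > 0.1:
            raise ValueError(f"inconsistent compartment temperatures: {temps}")
        return temps[0]

    @property
    def rt(self) -> float:
        """RT in kJ/mol at the model temperature."""
        return GAS_CONSTANT * self.temperature()


@dataclass
class ReactionThermo:
    """drG'0 estimate for one reaction."""

    drG0_prime: float
    drG0_error: float
    estimable: bool

    def __post_init__(self):
        if self.estimable and self.drG0_error < 0:
            raise ValueError("drG0_error must be non-negative")


def reaction_delta_g0(
    stoichiometry: dict[tuple[str, str], float],
    table: ThermoTable,
    id_map: dict[str, str] | None = None,
) -> ReactionThermo:
    """drG'0 for uncharged participants ``(metabolite_id, compartment) -> coefficient``.

    Convenience wrapper around :func:`reaction_delta_g0_detailed` with all
    charges zero; use the detailed form when the electrical term matters.
    """
    return reaction_delta_g0_detailed(
        [(mid, comp, coef, 0.0) for (mid, comp), coef in stoichiometry.items()],
        table, id_map)


def reaction_delta_g0_detailed(
    participants: list[tuple[str, str, float, float]],
    table: ThermoTable,
    id_map: dict[str, str] | None = None,
) -> ReactionThermo:
    """drG'0 from explicit participants ``(metabolite_id, compartment, coefficient, charge)``.

    Not estimable when any non-proton participant lacks a table entry or a
    participant's compartment lacks a :class:`CompartmentSpec` while being
    needed for an electrical/proton term.
    """
    id_map = id_map or {}
    rt = table.rt
    total = 0.0
    var = 0.0
    electrical = 0.0
    proton_term = 0.0
    for mid, comp, coef, charge in participants:
        cid = id_map.get(mid, mid)
        spec = table.compartments.get(comp)
        if cid.lower() in PROTON_IDS:
            if spec is None:
                return ReactionThermo(math.nan, math.nan, estimable=False)
            # proton activity fixed by compartment pH
            proton_term += -rt * math.log(10.0) * coef * spec.ph
            if spec.membrane_potential != 0.0:
                electrical += FARADAY * coef * 1.0 * spec.membrane_potential
            continue
        hit = table.lookup(cid, comp)
        if hit is None:
            return ReactionThermo(math.nan, math.nan, estimable=False)
        dfg, err = hit
        total += coef * dfg
        var += coef * coef * err * err
        if charge != 0.0:
            psi = spec.membrane_potential if spec is not None else 0.0
            electrical += FARADAY * coef * charge * psi
    return ReactionThermo(total + electrical + proton_term, math.sqrt(var), estimable=True)
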