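"""Synthetic toy networks, thermodynamic tables and four-condition datasets.

The generator emulates the structure of a drug-resistance exometabolomics
study: four instances of one network ("resistant-A"/"sensitive-A" grown in
plain medium, "resistant-B"/"sensitive-B" in a solvent-spiked medium),
exponential growth with condition-specific rates, medium
depletion/accumulation curves consistent with those rates, one abiotically
decaying medium compound (a glutamine analog) with a matching cell-free
series, and known pathway-level flux reprogramming injected into the
resistant conditions.

The toy metabolism has cytosol (c), mitochondrion (m) and medium (e):

* glucose -> glycolysis -> pyruvate -> lactate (fermentation) or
  mitochondrial oxidation (PDH -> acetyl-CoA -> lumped OXPHOS);
* a solvent-responsive side branch importing a dedicated medium compound and
  exporting a polyol (deliberately decoupled from energy metabolism, so a
  solvent background shifts only this branch);
* glutamine oxidised in the mitochondrion (TCA label) -- decoupled from ATP;
* two fatty-acid-like substrates beta-oxidised to an exported ketone body,
  with ATP coupling that makes fat the oxygen-efficient fuel;
* a maintenance ATPase, a biomass reaction consuming three precursors plus
  ATP, and a three-reaction thermodynamic loop that can never circulate.

Every reaction carries a closed-form reference flux derived from mass
balance, so each condition dataset is feasible for the model by
construction, and formation energies are assigned by a small LP so every
reference-direction reaction has attainable drG' < 0 at the planned
concentration midpoints.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import cobra
import numpy as np
import pandas as pd

from . import model_io, rates
from .exceptions import DataError
from .solver import LinearProblem
from .thermo import GAS_CONSTANT, CompartmentSpec, ThermoTable

CONDITIONS = ("resistant-A", "sensitive-A", "resistant-B", "sensitive-B")
#: resistant -> matched sensitive control
PAIRING = {"resistant-A": "sensitive-A", "resistant-B": "sensitive-B"}

SUBSYSTEMS = ("glycolysis", "TCA", "oxidative phosphorylation",
              "fatty acid oxidation", "transport", "biomass")

BIOMASS_ID = "BIOMASS"
DECAYING_METABOLITE = "gln_e"

#: baseline growth rates, 1/h (resistant grows slower; A-resistant slowest)
MU_BASE = {"sensitive-A": 0.032, "resistant-A": 0.024,
           "sensitive-B": 0.031, "resistant-B": 0.025}

#: default experiment geometry
X0_CELLS = 2.0e5            # cells seeded per well
DRY_MASS_PER_CELL = 4.0e-10  # g/cell (400 pg)
#: relative dry-mass error at the reference noise level (3% at 5% CV); the
#: synthetic world's calibration uncertainty scales with its assay noise, so
#: noiseless bundles have exactly known dry mass
SE_DRY_MASS_FRACTION = 0.03
REFERENCE_NOISE_CV = 0.05
MEDIUM_VOLUME_L = 2.0e-3    # 2 mL wells
ABIOTIC_DECAY_RATE = 3.0e-3  # 1/h, first-order glutamine-analog decay

#: initial medium concentrations, mM
INITIAL_CONC = {"glc_e": 16.7, "gln_e": 4.0, "o2_e": 30.0,
                "fa1_e": 0.15, "fa2_e": 0.10, "sol_e": 2.0,
                "lac_e": 0.0, "co2_e": 0.0, "ktb_e": 0.0, "poly_e": 0.0}

#: intracellular metabolites reported with measured concentration bounds
MEASURED_METABOLITES = ("glc_c", "pyr_c", "lac_c", "atp_c", "adp_c",
                        "accoa_m", "gln_c", "o2_c")

_CORE_INTERNAL_COUNT = 24  # internal species in the core network

TEMPERATURE = 310.15
RT = GAS_CONSTANT * TEMPERATURE

COMPARTMENT_SPECS = {
    "e": CompartmentSpec(ph=7.4, ionic_strength=0.15, membrane_potential=0.0,
                         temperature=TEMPERATURE),
    "c": CompartmentSpec(ph=7.2, ionic_strength=0.15, membrane_potential=0.0,
                         temperature=TEMPERATURE),
    "m": CompartmentSpec(ph=7.8, ionic_strength=0.15, membrane_potential=-0.15,
                         temperature=TEMPERATURE),
}

_CHARGES = {"atp": -4, "adp": -3, "pyr": -1, "lac": -1}


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator injected, for downstream recovery checks."""

    seed: int
    growth_rates: dict[str, float]                  # 1/h per condition
    exchange_rates: dict[str, dict[str, float]]     # cond -> met_e -> mmol/(gDW h)
    reprogrammed_subsystems: dict[str, float]       # subsystem -> scale factor
    abiotic_decay_rate: float                       # 1/h
    decaying_metabolite: str
    solvent_scale: float
    x0: float
    dry_mass_per_cell: float
    reference_fluxes: dict[str, dict[str, float]]   # cond -> reaction -> flux

    def __post_init__(self):
        for cond, mu in self.growth_rates.items():
            if mu <= 0:
                raise ValueError(f"growth rate for {cond} must be positive")
        for sub, scale in self.reprogrammed_subsystems.items():
            if scale <= 0:
                raise ValueError(f"scale factor for {sub} must be positive")

    def changed_reactions(self, resistant: str, sensitive: str,
                          threshold: float = 0.15,
                          delta: float = 1e-8) -> set[str]:
        """Reactions whose growth-normalized reference flux differs > threshold."""
        mu_r = self.growth_rates[resistant]
        mu_s = self.growth_rates[sensitive]
        out = set()
        for rid, v_r in self.reference_fluxes[resistant].items():
            a = v_r / mu_r
            b = self.reference_fluxes[sensitive][rid] / mu_s
            rel = abs(a - b) / max(abs(a), abs(b), delta)
            if rel > threshold:
                out.add(rid)
        return out


@dataclass
class ConditionDataset:
    """Time-course cell counts and medium concentrations for one condition."""

    condition_id: str
    counts: pd.DataFrame      # time_h, replicate, count
    medium: pd.DataFrame      # metabolite, time_h, replicate, concentration
    cellfree: pd.DataFrame    # metabolite, time_h, replicate, concentration
    conc_bounds: dict[str, tuple[float, float]]  # mol per total protein
    x0: float
    dry_mass_per_cell: float
    se_dry_mass: float
    volume_l: float
    initial_concentrations: dict[str, float]


@dataclass
class SyntheticBundle:
    model: cobra.Model
    thermo: ThermoTable
    conditions: dict[str, ConditionDataset]
    truth: GroundTruth
    id_map: dict[str, str]

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        model_io.write_model(self.model, d / "model.xml")
        model_io.write_thermo_table(self.thermo, d / "thermo_compounds.tsv",
                                    d / "thermo_compartments.tsv")
        model_io.write_id_map(self.id_map, d / "id_map.tsv")
        counts, medium, cellfree = [], [], []
        meta = {}
        for cond in CONDITIONS:
            ds = self.conditions[cond]
            counts.append(ds.counts.assign(condition=cond))
            medium.append(ds.medium.assign(condition=cond))
            cellfree.append(ds.cellfree.assign(condition=cond))
            meta[cond] = {
                "x0": ds.x0, "dry_mass_per_cell": ds.dry_mass_per_cell,
                "se_dry_mass": ds.se_dry_mass, "volume_l": ds.volume_l,
                "conc_bounds": {k: list(v) for k, v in ds.conc_bounds.items()},
                "initial_concentrations": ds.initial_concentrations,
            }
        pd.concat(counts).to_csv(d / "counts.tsv", sep="\t", index=False,
                                 float_format="%.10g")
        pd.concat(medium).to_csv(d / "medium.tsv", sep="\t", index=False,
                                 float_format="%.10g")
        pd.concat(cellfree).to_csv(d / "cellfree.tsv", sep="\t", index=False,
                                   float_format="%.10g")
        (d / "conditions.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        (d / "ground_truth.json").write_text(
            json.dumps(asdict(self.truth), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _base_compound(met_id: str) -> str:
    return met_id.rsplit("_", 1)[0]


def _core_reactions(n_fillers: int):
    """(id, subsystem, stoichiometry, reversible) for the core + fillers."""
    rxns = [
        # exchanges (secretion positive)
        ("EX_glc_e", "transport", {"glc_e": -1}, True),
        ("EX_gln_e", "transport", {"gln_e": -1}, True),
        ("EX_o2_e", "transport", {"o2_e": -1}, True),
        ("EX_lac_e", "transport", {"lac_e": -1}, True),
        ("EX_co2_e", "transport", {"co2_e": -1}, True),
        ("EX_ktb_e", "transport", {"ktb_e": -1}, True),
        ("EX_poly_e", "transport", {"poly_e": -1}, True),
        ("EX_sol_e", "transport", {"sol_e": -1}, True),
        ("EX_fa1_e", "transport", {"fa1_e": -1}, True),
        ("EX_fa2_e", "transport", {"fa2_e": -1}, True),
        # transport
        ("T_glc", "transport", {"glc_e": -1, "glc_c": 1}, False),
        ("T_gln", "transport", {"gln_e": -1, "gln_c": 1}, False),
        ("T_gln_m", "transport", {"gln_c": -1, "gln_m": 1}, False),
        ("T_o2", "transport", {"o2_e": -1, "o2_c": 1}, False),
        ("T_o2_m", "transport", {"o2_c": -1, "o2_m": 1}, False),
        ("T_lac", "transport", {"lac_c": -1, "lac_e": 1}, False),
        ("T_co2", "transport", {"co2_m": -1, "co2_c": 1}, False),
        ("T_co2_e", "transport", {"co2_c": -1, "co2_e": 1}, False),
        ("T_ktb", "transport", {"ktb_m": -1, "ktb_c": 1}, False),
        ("T_ktb_e", "transport", {"ktb_c": -1, "ktb_e": 1}, False),
        ("T_poly", "transport", {"poly_c": -1, "poly_e": 1}, False),
        ("T_sol", "transport", {"sol_e": -1, "sol_c": 1}, False),
        ("T_fa1", "transport", {"fa1_e": -1, "fa1_c": 1}, False),
        ("T_fa1_m", "transport", {"fa1_c": -1, "fa1_m": 1}, False),
        ("T_fa2", "transport", {"fa2_e": -1, "fa2_c": 1}, False),
        ("T_fa2_m", "transport", {"fa2_c": -1, "fa2_m": 1}, False),
        ("T_pyr", "transport", {"pyr_c": -1, "pyr_m": 1}, False),
        # glycolysis + fermentation + solvent-responsive polyol branch
        ("GLY", "glycolysis",
         {"glc_c": -1, "adp_c": -2, "pyr_c": 2, "atp_c": 2}, False),
        ("LDH", "glycolysis", {"pyr_c": -1, "lac_c": 1}, False),
        ("POLY", "glycolysis", {"sol_c": -1, "poly_c": 1}, False),
        # mitochondrial oxidation
        ("PDH", "TCA", {"pyr_m": -1, "accoa_m": 1, "co2_m": 1}, False),
        ("GLNOX", "TCA", {"gln_m": -1, "o2_m": -2, "co2_m": 3}, False),
        ("OXPHOS", "oxidative phosphorylation",
         {"accoa_m": -1, "o2_m": -2, "adp_c": -14, "atp_c": 14, "co2_m": 2},
         False),
        # ketogenic beta-oxidation (oxygen-efficient ATP source)
        ("FAOX1", "fatty acid oxidation",
         {"fa1_m": -1, "o2_m": -0.5, "adp_c": -10, "ktb_m": 2, "atp_c": 10},
         False),
        ("FAOX2", "fatty acid oxidation",
         {"fa2_m": -1, "o2_m": -0.8, "adp_c": -12, "ktb_m": 2.5, "atp_c": 12},
         False),
        # energy sinks
        ("MAINT", "biomass", {"atp_c": -1, "adp_c": 1}, False),
        (BIOMASS_ID, "biomass",
         {"glc_c": -0.3, "pyr_c": -0.4, "accoa_m": -0.2,
          "atp_c": -30, "adp_c": 30}, False),
        # thermodynamically closed 3-cycle: can never circulate
        ("LOOP1", "TCA", {"l1_c": -1, "l2_c": 1}, False),
        ("LOOP2", "TCA", {"l2_c": -1, "l3_c": 1}, False),
        ("LOOP3", "TCA", {"l3_c": -1, "l1_c": 1}, False),
    ]
    for i in range(n_fillers):
        rxns.append((f"FILL{i}a", "TCA", {"pyr_c": -1, f"f{i}_c": 1}, False))
        rxns.append((f"FILL{i}b", "TCA", {f"f{i}_c": -1, "lac_c": 1}, False))
    return rxns


def _reference_profile(fa_scale: float = 1.0, gln_scale: float = 1.0,
                       solvent_scale: float = 1.0) -> dict[str, float]:
    """Reference flux per unit biomass flux (growth-normalized), closed form."""
    u = 10.0                    # glucose uptake
    p = 0.5 * solvent_scale     # solvent-responsive polyol branch
    g = 0.5 * gln_scale         # glutamine-analog oxidation
    f1 = 0.06 * fa_scale        # fatty-acid 1 uptake
    f2 = 0.04 * fa_scale        # fatty-acid 2 uptake
    m0 = 1.0                    # maintenance ATPase

    gly = u - 0.3
    oxphos = (30.0 + m0 - 2.0 * gly - 10.0 * f1 - 12.0 * f2) / 14.0
    pdh = oxphos + 0.2
    ldh = 2.0 * gly - pdh - 0.4
    o2 = 2.0 * oxphos + 2.0 * g + 0.5 * f1 + 0.8 * f2
    co2 = pdh + 3.0 * g + 2.0 * oxphos
    ktb = 2.0 * f1 + 2.5 * f2
    for name, v in [("GLY", gly), ("OXPHOS", oxphos), ("PDH", pdh),
                    ("LDH", ldh)]:
        if v <= 0:
            raise DataError(f"reference profile infeasible: {name} = {v:.3f}")
    prof = {
        "EX_glc_e": -u, "T_glc": u, "GLY": gly,
        "EX_sol_e": -p, "T_sol": p,
        "POLY": p, "T_poly": p, "EX_poly_e": p,
        "LDH": ldh, "T_lac": ldh, "EX_lac_e": ldh,
        "T_pyr": pdh, "PDH": pdh,
        "EX_gln_e": -g, "T_gln": g, "T_gln_m": g, "GLNOX": g,
        "EX_o2_e": -o2, "T_o2": o2, "T_o2_m": o2,
        "OXPHOS": oxphos,
        "EX_co2_e": co2, "T_co2": co2, "T_co2_e": co2,
        "EX_fa1_e": -f1, "T_fa1": f1, "T_fa1_m": f1, "FAOX1": f1,
        "EX_fa2_e": -f2, "T_fa2": f2, "T_fa2_m": f2, "FAOX2": f2,
        "EX_ktb_e": ktb, "T_ktb": ktb, "T_ktb_e": ktb,
        "MAINT": m0, BIOMASS_ID: 1.0,
        "LOOP1": 0.0, "LOOP2": 0.0, "LOOP3": 0.0,
    }
    return prof


def _concentration_midpoints(seed: int, met_ids: list[str]) -> dict[str, float]:
    """Seeded per-species concentration midpoints (mol per total protein)."""
    rng = np.random.default_rng([17, seed % (2**31)])
    out = {}
    for mid in sorted(met_ids):
        out[mid] = float(1e-3 * math.exp(rng.uniform(-1.2, 1.2)))
    return out


def _assign_formation_energies(seed: int, reactions, met_ids: list[str],
                               cstar: dict[str, float]) -> dict[str, float]:
    """Species formation energies making every reference-direction reaction
    exergonic (drG' <= -margin) at the planned concentration midpoints."""
    rng = np.random.default_rng([23, seed % (2**31)])
    lp = LinearProblem()
    g_idx = {mid: lp.add_variable(f"G_{mid}", -2000.0, 500.0)
             for mid in sorted(met_ids)}
    loop_mets = {"l1_c", "l2_c", "l3_c"}
    for rid, _sub, stoich, _rev in reactions:
        if rid.startswith(("EX_", "LOOP")) or rid == BIOMASS_ID:
            continue
        margin = 15.0 + rng.uniform(0.0, 5.0)
        row = {g_idx[m]: s for m, s in stoich.items()}
        rhs = -margin - RT * sum(s * math.log(cstar[m]) for m, s in stoich.items())
        lp.add_constraint(row, -np.inf, rhs, name=rid)
    lp.set_objective({j: 1.0 for j in g_idx.values()}, sense="max")
    res = lp.solve()
    if not res.ok:
        raise DataError(f"formation-energy assignment failed: {res.status}")
    out = {mid: float(res.x[j]) for mid, j in g_idx.items()}
    for mid in loop_mets:
        out[mid] = -50.0  # closed cycle: energies must telescope exactly
    return out


def make_toy_model(seed: int, n_internal: int = _CORE_INTERNAL_COUNT,
                   ) -> tuple[cobra.Model, ThermoTable]:
    """Deterministic toy network plus matching thermodynamic table.

    ``n_internal`` is the minimum number of internal (non-medium) species;
    the core network provides 23, larger values add inert two-step detour
    pathways.  Values below 10 are rejected; between 10 and 23 the core is
    returned unchanged.
    """
    if n_internal < 10:
        raise ValueError("n_internal must be at least 10")
    n_fillers = max(0, n_internal - _CORE_INTERNAL_COUNT)
    reactions = _core_reactions(n_fillers)

    model = cobra.Model(f"toy_s{seed}")
    met_objs: dict[str, cobra.Metabolite] = {}
    for rid, sub, stoich, rev in reactions:
        for mid in stoich:
            if mid not in met_objs:
                comp = mid.rsplit("_", 1)[1]
                met = cobra.Metabolite(mid, compartment=comp)
                met.charge = _CHARGES.get(_base_compound(mid), 0)
                met_objs[mid] = met
    model.add_metabolites(list(met_objs.values()))
    for rid, sub, stoich, rev in reactions:
        rxn = cobra.Reaction(rid)
        rxn.bounds = (-model_io.DEFAULT_BOUND if rev else 0.0,
                      model_io.DEFAULT_BOUND)
        model.add_reactions([rxn])
        rxn.add_metabolites({met_objs[m]: s for m, s in stoich.items()})
        rxn.subsystem = sub
    model.objective = BIOMASS_ID

    met_ids = list(met_objs)
    cstar = _concentration_midpoints(seed, met_ids)
    energies = _assign_formation_energies(seed, reactions, met_ids, cstar)
    err_rng = np.random.default_rng([29, seed % (2**31)])
    rows = []
    loop_mets = {"l1_c", "l2_c", "l3_c"}
    for mid in sorted(met_ids):
        err = 0.0 if mid in loop_mets else float(err_rng.uniform(0.2, 1.5))
        rows.append({"compound_id": _base_compound(mid),
                     "compartment": mid.rsplit("_", 1)[1],
                     "dfG0_prime": round(energies[mid], 6),
                     "dfG0_error": round(err, 6)})
    table = ThermoTable(compounds=pd.DataFrame(rows),
                        compartments=dict(COMPARTMENT_SPECS))
    return model, table


def default_id_map(model: cobra.Model) -> dict[str, str]:
    return {m.id: _base_compound(m.id) for m in model.metabolites}


# ---------------------------------------------------------------------------
# Condition simulation
# ---------------------------------------------------------------------------

def _condition_profile(condition_id: str, fa_scale: float, gln_scale: float,
                       solvent_scale: float) -> dict[str, float]:
    resistant = condition_id.startswith("resistant")
    pair_b = condition_id.endswith("-B")
    return _reference_profile(
        fa_scale=fa_scale if resistant else 1.0,
        gln_scale=gln_scale if resistant else 1.0,
        solvent_scale=solvent_scale if pair_b else 1.0)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size) - 0.5 * sigma * sigma)


def simulate_condition(model: cobra.Model, truth: GroundTruth, condition_id: str,
                       times: list[float] | tuple[float, ...] = (0.0, 24.0, 48.0, 72.0),
                       noise_cv: float = 0.0, replicates: int = 4,
                       volume_l: float = MEDIUM_VOLUME_L) -> ConditionDataset:
    """Time-course dataset for one condition, consistent with the ground truth.

    Cell counts follow X(t) = X0 exp(mu t); medium concentrations follow
    C(t) = C0 + q (B0 / (mu V)) (exp(mu t) - 1), the decaying compound is
    additionally multiplied by exp(-k t) and gets a matching cell-free
    series.  Noise is multiplicative lognormal with the stated CV.
    """
    if condition_id not in truth.growth_rates:
        raise DataError(f"unknown condition id {condition_id!r}")
    times = np.asarray(sorted(times), dtype=float)
    if times[0] != 0.0:
        raise DataError("times must include 0")
    if noise_cv < 0:
        raise DataError("noise_cv must be >= 0")
    cond_index = CONDITIONS.index(condition_id)
    rng = np.random.default_rng([truth.seed % (2**31), 101 + cond_index])

    mu = truth.growth_rates[condition_id]
    x0 = truth.x0
    b0 = x0 * truth.dry_mass_per_cell
    q_map = truth.exchange_rates[condition_id]

    count_rows = []
    for t in times:
        mean = x0 * math.exp(mu * t)
        noise = _lognormal_factor(rng, noise_cv, replicates)
        for rep in range(replicates):
            count_rows.append({"time_h": t, "replicate": rep,
                               "count": mean * noise[rep]})
    counts = pd.DataFrame(count_rows)

    medium_rows = []
    k = truth.abiotic_decay_rate
    for met_e in sorted(q_map):
        q = q_map[met_e]
        c0 = truth_initial_concentration(met_e)
        k_i = k if met_e == truth.decaying_metabolite else 0.0
        for t in times:
            # exact solution of dC/dt = q B(t)/V - k C
            mean = (c0 * math.exp(-k_i * t)
                    + q * float(rates.biomass_integral(t, mu, b0, volume_l, k_i)))
            mean = max(mean, 0.0)
            noise = _lognormal_factor(rng, noise_cv, replicates)
            for rep in range(replicates):
                medium_rows.append({"metabolite": met_e, "time_h": t,
                                    "replicate": rep,
                                    "concentration": mean * noise[rep]})
    medium = pd.DataFrame(medium_rows)

    cellfree_rows = []
    c0 = truth_initial_concentration(truth.decaying_metabolite)
    for t in times:
        mean = c0 * math.exp(-k * t)
        noise = _lognormal_factor(rng, noise_cv, replicates)
        for rep in range(replicates):
            cellfree_rows.append({"metabolite": truth.decaying_metabolite,
                                  "time_h": t, "replicate": rep,
                                  "concentration": mean * noise[rep]})
    cellfree = pd.DataFrame(cellfree_rows)

    cstar = _concentration_midpoints(truth.seed, [m.id for m in model.metabolites])
    conc_bounds = {mid: (cstar[mid] / 2.0, cstar[mid] * 2.0)
                   for mid in MEASURED_METABOLITES if mid in cstar}

    se_mdw = (truth.dry_mass_per_cell * SE_DRY_MASS_FRACTION
              * (noise_cv / REFERENCE_NOISE_CV))
    return ConditionDataset(
        condition_id=condition_id, counts=counts, medium=medium,
        cellfree=cellfree, conc_bounds=conc_bounds, x0=x0,
        dry_mass_per_cell=truth.dry_mass_per_cell,
        se_dry_mass=se_mdw,
        volume_l=volume_l,
        initial_concentrations={m: truth_initial_concentration(m)
                                for m in sorted(q_map)})


def truth_initial_concentration(met_e: str) -> float:
    return INITIAL_CONC.get(met_e, 1.0)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def make_ground_truth(seed: int, model: cobra.Model, fa_scale: float = 2.0,
                      gln_scale: float = 1.6, solvent_scale: float = 1.0,
                      mu_jitter: float = 0.02) -> GroundTruth:
    """Condition-specific growth rates, exchange rates and reference fluxes."""
    rng = np.random.default_rng([11, seed % (2**31)])
    growth_rates = {}
    for cond in CONDITIONS:
        growth_rates[cond] = MU_BASE[cond] * (1.0 + mu_jitter * rng.uniform(-1, 1))

    reference_fluxes = {}
    exchange_rates = {}
    for cond in CONDITIONS:
        prof = _condition_profile(cond, fa_scale, gln_scale, solvent_scale)
        mu = growth_rates[cond]
        flux = {rid: v * mu for rid, v in prof.items()}
        for rxn in model.reactions:
            flux.setdefault(rxn.id, 0.0)
        reference_fluxes[cond] = flux
        exchange_rates[cond] = {
            next(iter(rxn.metabolites)).id: flux[rxn.id]
            for rxn in model.reactions if rxn.boundary}

    reprogrammed = {}
    if fa_scale != 1.0:
        reprogrammed["fatty acid oxidation"] = fa_scale
    if gln_scale != 1.0:
        reprogrammed["TCA"] = gln_scale

    return GroundTruth(
        seed=seed, growth_rates=growth_rates, exchange_rates=exchange_rates,
        reprogrammed_subsystems=reprogrammed,
        abiotic_decay_rate=ABIOTIC_DECAY_RATE,
        decaying_metabolite=DECAYING_METABOLITE,
        solvent_scale=solvent_scale, x0=X0_CELLS,
        dry_mass_per_cell=DRY_MASS_PER_CELL,
        reference_fluxes=reference_fluxes)


def make_bundle(seed: int, n_internal: int = _CORE_INTERNAL_COUNT,
                noise_cv: float = 0.0, replicates: int = 4,
                times: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0),
                fa_scale: float = 2.0, gln_scale: float = 1.6,
                solvent_scale: float = 1.0,
                mu_jitter: float = 0.02) -> SyntheticBundle:
    """Model + thermodynamics + four condition datasets with known truth.

    Reprogramming (applied in the resistant conditions): fatty-acid
    oxidation scaled by ``fa_scale`` and the glutamine-oxidation branch
    (TCA label) by ``gln_scale``.  ``solvent_scale`` scales the polyol
    branch in *both* pair-B conditions, emulating a pure solvent effect.
    """
    model, table = make_toy_model(seed, n_internal)
    truth = make_ground_truth(seed, model, fa_scale=fa_scale,
                              gln_scale=gln_scale, solvent_scale=solvent_scale,
                              mu_jitter=mu_jitter)
    _assert_balanced(model, truth.reference_fluxes)

    conditions = {cond: simulate_condition(model, truth, cond, times=times,
                                           noise_cv=noise_cv,
                                           replicates=replicates)
                  for cond in CONDITIONS}
    return SyntheticBundle(model=model, thermo=table, conditions=conditions,
                           truth=truth, id_map=default_id_map(model))


def _assert_balanced(model: cobra.Model, reference_fluxes) -> None:
    """Every condition's reference flux must satisfy S v = 0 exactly."""
    for cond, flux in reference_fluxes.items():
        resid = {}
        for met in model.metabolites:
            tot = sum(rxn.metabolites[met] * flux[rxn.id] for rxn in met.reactions)
            if abs(tot) > 1e-9:
                resid[met.id] = tot
        if resid:
            raise DataError(f"reference flux unbalanced for {cond}: {resid}")


def load_bundle_inputs(directory: str | Path):
    """Read back the on-disk artifacts written by :meth:`SyntheticBundle.save`.

    Returns (model, thermo, id_map, conditions) where conditions is a dict of
    :class:`ConditionDataset`; the ground truth file is deliberately not read
    (the analysis pipeline must not see it).
    """
    d = Path(directory)
    model = model_io.read_model(d / "model.xml")
    table = model_io.read_thermo_table(d / "thermo_compounds.tsv",
                                       d / "thermo_compartments.tsv")
    id_map = model_io.read_id_map(d / "id_map.tsv")
    counts = pd.read_csv(d / "counts.tsv", sep="\t")
    medium = pd.read_csv(d / "medium.tsv", sep="\t")
    cellfree = pd.read_csv(d / "cellfree.tsv", sep="\t")
    meta = json.loads((d / "conditions.json").read_text())
    conditions = {}
    for cond, info in meta.items():
        conditions[cond] = ConditionDataset(
            condition_id=cond,
            counts=counts[counts.condition == cond].drop(columns="condition"),
            medium=medium[medium.condition == cond].drop(columns="condition"),
            cellfree=cellfree[cellfree.condition == cond].drop(columns="condition"),
            conc_bounds={k: tuple(v) for k, v in info["conc_bounds"].items()},
            x0=info["x0"], dry_mass_per_cell=info["dry_mass_per_cell"],
            se_dry_mass=info["se_dry_mass"], volume_l=info["volume_l"],
            initial_concentrations=info["initial_concentrations"])
    return model, table, id_map, conditions
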