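"""Network and thermodynamic-table I/O plus model surgery.

Networks are cobra models read from / written to SBML Level 3.  Subsystem
labels travel as SBML ``groups``; reading a file without groups yields
subsystem ``"unassigned"`` with a warning.  Exchange fluxes follow the
half-reaction convention ``internal species -> (nothing)``: positive flux is
secretion, negative flux is uptake, and uptake limits are lower bounds.

Thermodynamic tables are two TSV files: per-compound formation energies
(compound_id, compartment, dfG0_prime, dfG0_error) and per-compartment
conditions (compartment, ph, ionic_strength, membrane_potential,
temperature).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import cobra
import pandas as pd
from cobra.core import Group
from cobra.flux_analysis import find_blocked_reactions

from .exceptions import ConfigurationError, DataError, InfeasibleModelError
from .thermo import PROTON_IDS, CompartmentSpec, ThermoTable

logger = logging.getLogger(__name__)

#: |flux| below this is treated as zero when classifying blocked reactions;
#: far below any measured exchange magnitude, above LP solver noise.
BLOCKED_TOLERANCE = 1e-9

#: conventional open bound for genome-scale models, mmol/(gDW*h)
DEFAULT_BOUND = 1000.0

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# SBML round trip with subsystem groups
# ---------------------------------------------------------------------------

def write_model(model: cobra.Model, path: str | Path) -> None:
    """Write SBML L3, encoding each reaction's subsystem as a group.

    Group members are re-sorted in the emitted XML (cobra stores them in a
    set) so that identical models serialize byte-identically.
    """
    model = model.copy()
    model.groups.clear()
    by_subsystem: dict[str, list] = {}
    for rxn in model.reactions:
        sub = rxn.subsystem or UNASSIGNED
        by_subsystem.setdefault(sub, []).append(rxn)
    groups = []
    for sub in sorted(by_subsystem):
        g = Group(_group_id(sub), name=sub, members=by_subsystem[sub], kind="partonomy")
        groups.append(g)
    model.add_groups(groups)
    cobra.io.write_sbml_model(model, str(path))
    _canonicalize_group_members(Path(path))


def _canonicalize_group_members(path: Path) -> None:
    import re

    text = path.read_text()

    def sort_block(match: "re.Match") -> str:
        head, body, tail = match.group(1), match.group(2), match.group(3)
        members = sorted(line for line in body.splitlines() if line.strip())
        return head + "\n".join(members) + tail

    out = re.sub(
        r"(<groups:listOfMembers>\n)(.*?)(\n\s*</groups:listOfMembers>)",
        sort_block, text, flags=re.DOTALL)
    path.write_text(out)


def _group_id(subsystem: str) -> str:
    safe = "".join(ch if ch.isalnum() else "_" for ch in subsystem)
    return f"g_{safe}"


def read_model(path: str | Path, biomass_reaction: str | None = None,
               require_biomass: bool = True) -> cobra.Model:
    """Read an SBML L3 model, restoring subsystems from groups.

    Extra "enzyme"/"coupling" pseudo-species (ids starting with ``prot_`` or
    ``pmet_``, as left behind by enzyme-constrained exports) are dropped and
    logged.  A missing biomass reaction is a configuration error unless
    ``require_biomass`` is false.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"model file not found: {path}")
    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises many types
        raise DataError(f"malformed SBML in {path}: {exc}") from exc

    pseudo = [m for m in model.metabolites
              if m.id.startswith(("prot_", "pmet_", "enzyme_"))]
    if pseudo:
        logger.warning("dropping %d enzyme/coupling pseudo-species", len(pseudo))
        model.remove_metabolites(pseudo, destructive=False)

    labelled = set()
    for group in model.groups:
        sub = group.name or group.id
        for member in group.members:
            if isinstance(member, cobra.Reaction):
                member.subsystem = sub
                labelled.add(member.id)
    unlabelled = [r for r in model.reactions if r.id not in labelled]
    if unlabelled:
        logger.warning("%d reactions lack a subsystem group; set to %r",
                       len(unlabelled), UNASSIGNED)
        for r in unlabelled:
            if not r.subsystem:
                r.subsystem = UNASSIGNED

    biomass = find_biomass_reaction(model, biomass_reaction)
    if biomass is None and require_biomass:
        raise ConfigurationError(
            f"no biomass reaction found in {path.name}; pass biomass_reaction=")
    if biomass is not None:
        model.objective = biomass
    return model


def find_biomass_reaction(model: cobra.Model, biomass_reaction: str | None = None):
    """The named reaction, or the first whose id/subsystem mentions biomass."""
    if biomass_reaction is not None:
        if biomass_reaction not in model.reactions:
            raise ConfigurationError(
                f"biomass reaction {biomass_reaction!r} not in model")
        return model.reactions.get_by_id(biomass_reaction)
    for rxn in model.reactions:
        if "biomass" in rxn.id.lower():
            return rxn
    candidates = [r for r in model.reactions if r.subsystem.lower() == "biomass"]
    if len(candidates) == 1:
        return candidates[0]
    return None


# ---------------------------------------------------------------------------
# Exchange augmentation / pooled-supply replacement
# ---------------------------------------------------------------------------

def add_exchanges(model: cobra.Model, metabolite_ids: list[str],
                  external_compartment: str = "e",
                  bounds: tuple[float, float] = (-DEFAULT_BOUND, DEFAULT_BOUND),
                  ) -> cobra.Model:
    """Add one reversible exchange per listed external metabolite (in place).

    Missing external species are created (and logged) when their id carries
    the external-compartment suffix; anything else is an unknown metabolite.
    Re-adding an existing exchange is a no-op.
    """
    for mid in metabolite_ids:
        if mid in model.metabolites:
            met = model.metabolites.get_by_id(mid)
        elif mid.endswith(f"_{external_compartment}"):
            met = cobra.Metabolite(mid, compartment=external_compartment)
            model.add_metabolites([met])
            logger.warning("created missing external species %s", mid)
        else:
            raise DataError(f"unknown metabolite id {mid!r}")
        ex_id = f"EX_{mid}"
        if ex_id in model.reactions:
            continue
        existing = [r for r in met.reactions if r.boundary]
        if existing:
            continue
        rxn = cobra.Reaction(ex_id, lower_bound=bounds[0], upper_bound=bounds[1])
        rxn.add_metabolites({met: -1.0})
        rxn.subsystem = "transport"
        model.add_reactions([rxn])
    return model


def replace_pooled_supply(model: cobra.Model, pooled_reaction_ids: list[str],
                          fatty_acid_ids: list[str],
                          external_compartment: str = "e") -> cobra.Model:
    """Remove pooled-supply artifact reactions; open direct fatty-acid influx.

    The listed reactions are deleted and each fatty acid receives a
    reversible exchange with fully open bounds, so its influx is
    unconstrained.
    """
    to_remove = []
    for rid in pooled_reaction_ids:
        if rid in model.reactions:
            to_remove.append(model.reactions.get_by_id(rid))
        else:
            logger.warning("pooled-supply reaction %s absent, skipping", rid)
    if to_remove:
        model.remove_reactions(to_remove, remove_orphans=True)
    add_exchanges(model, fatty_acid_ids, external_compartment)
    for mid in fatty_acid_ids:
        met = model.metabolites.get_by_id(mid)
        for rxn in met.reactions:
            if rxn.boundary:
                rxn.bounds = (-DEFAULT_BOUND, DEFAULT_BOUND)
    return model


# ---------------------------------------------------------------------------
# Blocked reactions
# ---------------------------------------------------------------------------

def remove_blocked(model: cobra.Model,
                   condition_bounds: dict[str, tuple[float, float]] | None = None,
                   ) -> tuple[cobra.Model, list[str]]:
    """Drop reactions that cannot carry flux under the stated bounds.

    A reaction is blocked iff its plain FVA minimum and maximum are both zero
    within :data:`BLOCKED_TOLERANCE` (no thermodynamic constraints).  Returns
    a new model and the sorted removed ids.
    """
    work = model.copy()
    condition_bounds = condition_bounds or {}
    for rid, (lb, ub) in condition_bounds.items():
        if rid not in work.reactions:
            raise DataError(f"condition bound for unknown reaction {rid!r}")
        work.reactions.get_by_id(rid).bounds = (lb, ub)

    if math.isnan(work.slim_optimize(error_value=float("nan"))):
        logged = {rid: tuple(b) for rid, b in condition_bounds.items()}
        raise InfeasibleModelError(
            "model infeasible under condition bounds", diagnostics=logged)

    try:
        work.tolerance = BLOCKED_TOLERANCE
        cutoff = BLOCKED_TOLERANCE
    except Exception:  # solver rejects tighter tolerance; keep its default
        cutoff = max(BLOCKED_TOLERANCE, work.tolerance)
    blocked = sorted(find_blocked_reactions(work, zero_cutoff=cutoff))
    if blocked:
        work.remove_reactions([work.reactions.get_by_id(r) for r in blocked],
                              remove_orphans=True)
        logger.info("removed %d blocked reactions", len(blocked))
    return work, blocked


def write_removed_report(removed_ids: list[str], model: cobra.Model,
                         path: str | Path) -> None:
    rows = [{"reaction": rid,
             "subsystem": (model.reactions.get_by_id(rid).subsystem
                           if rid in model.reactions else "")}
            for rid in removed_ids]
    pd.DataFrame(rows, columns=["reaction", "subsystem"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Thermodynamic identifier join
# ---------------------------------------------------------------------------

@dataclass
class ThermoCoverage:
    compound_fraction: float
    reaction_fraction: float
    unmatched_compounds: list[str]
    estimable_reactions: list[str]


def join_thermo(model: cobra.Model, table: ThermoTable,
                id_map: dict[str, str] | None = None) -> ThermoCoverage:
    """Set-theoretic thermodynamic coverage of a model.

    A compound is covered when its mapped id has a table entry for its
    compartment; a (non-boundary) reaction is estimable when every non-proton
    participant is covered.  Independent of bounds and solver.
    """
    id_map = id_map or {}
    covered = {}
    for met in model.metabolites:
        cid = id_map.get(met.id, met.id)
        covered[met.id] = cid.lower() in PROTON_IDS or table.covers(cid, met.compartment)
    unmatched = sorted(mid for mid, ok in covered.items() if not ok)

    internal = [r for r in model.reactions if not r.boundary]
    estimable = [r.id for r in internal
                 if all(covered[m.id] for m in r.metabolites)]
    n_mets = len(model.metabolites)
    return ThermoCoverage(
        compound_fraction=(n_mets - len(unmatched)) / n_mets if n_mets else 0.0,
        reaction_fraction=len(estimable) / len(internal) if internal else 0.0,
        unmatched_compounds=unmatched,
        estimable_reactions=estimable,
    )


# ---------------------------------------------------------------------------
# Thermo table and id-map TSV I/O
# ---------------------------------------------------------------------------

def write_thermo_table(table: ThermoTable, compounds_path: str | Path,
                       compartments_path: str | Path) -> None:
    table.compounds.to_csv(compounds_path, sep="\t", index=False,
                           float_format="%.10g")
    rows = [{"compartment": cid, "ph": s.ph, "ionic_strength": s.ionic_strength,
             "membrane_potential": s.membrane_potential,
             "temperature": s.temperature}
            for cid, s in sorted(table.compartments.items())]
    pd.DataFrame(rows).to_csv(compartments_path, sep="\t", index=False,
                              float_format="%.10g")


def read_thermo_table(compounds_path: str | Path,
                      compartments_path: str | Path | None = None) -> ThermoTable:
    compounds = pd.read_csv(compounds_path, sep="\t",
                            dtype={"compound_id": str, "compartment": str})
    compartments = {}
    if compartments_path is not None:
        cdf = pd.read_csv(compartments_path, sep="\t")
        for row in cdf.itertuples(index=False):
            compartments[str(row.compartment)] = CompartmentSpec(
                ph=float(row.ph), ionic_strength=float(row.ionic_strength),
                membrane_potential=float(row.membrane_potential),
                temperature=float(row.temperature))
    return ThermoTable(compounds=compounds, compartments=compartments)


def read_id_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"model_id", "thermo_id"} <= set(df.columns):
        raise DataError("id map must have columns model_id, thermo_id")
    return dict(zip(df["model_id"], df["thermo_id"]))


def write_id_map(id_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(id_map.items()), columns=["model_id", "thermo_id"]).to_csv(
        path, sep="\t", index=False)
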