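"""End-to-end orchestration: fit -> constrain -> pTFVA -> normalization cascade.

A run consumes a data directory (SBML model, thermodynamic table TSVs, id
map, time-course TSVs, per-condition metadata JSON) plus a YAML/dict
configuration, and produces per-instance flux ranges, pairwise comparison
reports at each cascade stage, subsystem summaries and a JSON run summary.
Re-running with an identical configuration reproduces all reports (the
solver is deterministic).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, model_io, rates, synth
from .exceptions import ConfigurationError, DataError
from .tfa import DEFAULT_CONC_RANGE, FluxRangeSet, TFAProblem

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration.

    ``pairing`` maps each resistant condition to exactly one sensitive
    control.  ``roles`` maps {oxygen_uptake, atp_synthase, lactate_secretion,
    fatty_acid_exchanges, (optional) envelope_relax} to reaction ids for the
    energy-flux and envelope analyses.
    """

    data_dir: Path
    output_dir: Path
    pairing: dict[str, str]
    threshold: float = compare.DEFAULT_THRESHOLD
    delta: float = compare.DELTA
    seed: int = 0
    bound_mode: str = "propagated"
    min_bound_halfwidth: float = 1e-6
    conc_default: tuple[float, float] = DEFAULT_CONC_RANGE
    excluded_subsystems: list[str] = field(default_factory=lambda: ["transport"])
    roles: dict = field(default_factory=dict)
    pooled_supply_reactions: list[str] = field(default_factory=list)
    pooled_supply_fatty_acids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data_dir = Path(self.data_dir)
        self.output_dir = Path(self.output_dir)
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must lie in (0, 1)")
        if not self.pairing:
            raise ConfigurationError("pairing must map resistant -> control")
        controls = list(self.pairing.values())
        if len(set(controls)) != len(controls):
            raise ConfigurationError("each resistant condition needs its own control")
        lo, hi = self.conc_default
        if not 0 < lo < hi:
            raise ConfigurationError("invalid default concentration range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {
            "data_dir", "output_dir", "pairing", "threshold", "delta", "seed",
            "bound_mode", "min_bound_halfwidth", "conc_default",
            "excluded_subsystems", "roles", "pooled_supply_reactions",
            "pooled_supply_fatty_acids"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("data_dir", "output_dir", "pairing"):
            if key not in raw:
                raise ConfigurationError(f"config key {key!r} is required")
        if "conc_default" in raw:
            raw = dict(raw)
            raw["conc_default"] = tuple(float(v) for v in raw["conc_default"])
        return cls(**raw)


@dataclass
class InstanceFits:
    growth: rates.GrowthFit
    calibration: rates.BiomassCalibration
    exchanges: dict[str, rates.ExchangeRate]     # metabolite -> rate
    biomass_bounds: tuple[float, float]
    exchange_bounds: dict[str, tuple[float, float]]  # reaction id -> bounds


@dataclass
class PipelineResult:
    config: RunConfig
    fits: dict[str, InstanceFits]
    removed_reactions: list[str]
    raw_ranges: dict[str, FluxRangeSet]
    normalized_ranges: dict[str, FluxRangeSet]
    reports_raw: dict[str, compare.ComparisonReport]
    reports_normalized: dict[str, compare.ComparisonReport]
    cross_report: compare.ComparisonReport | None
    summary: dict
    problems: dict[str, TFAProblem] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage 1: rate fitting
# ---------------------------------------------------------------------------

def fit_condition(dataset: synth.ConditionDataset, model,
                  bound_mode: str = "propagated",
                  min_halfwidth: float = 1e-6) -> InstanceFits:
    """Growth + exchange fits and the flux bounds they imply."""
    counts = dataset.counts
    growth = rates.fit_growth(counts["time_h"].to_numpy(),
                              counts["count"].to_numpy())
    calib = rates.BiomassCalibration(dataset.dry_mass_per_cell,
                                     dataset.se_dry_mass)

    decaying = None
    if len(dataset.cellfree):
        decaying = dataset.cellfree["metabolite"].iloc[0]

    exchanges: dict[str, rates.ExchangeRate] = {}
    exchange_bounds: dict[str, tuple[float, float]] = {}
    met_to_exchange = {}
    for rxn in model.reactions:
        if rxn.boundary:
            met_to_exchange[next(iter(rxn.metabolites)).id] = rxn.id
    for met, sub in dataset.medium.groupby("metabolite"):
        kwargs = {}
        if met == decaying:
            kwargs = {"abiotic_times": dataset.cellfree["time_h"].to_numpy(),
                      "abiotic_concentrations":
                          dataset.cellfree["concentration"].to_numpy()}
        ex = rates.fit_exchange(sub["time_h"].to_numpy(),
                                sub["concentration"].to_numpy(),
                                growth, calib, metabolite=met,
                                volume_l=dataset.volume_l, **kwargs)
        exchanges[met] = ex
        if met not in met_to_exchange:
            logger.warning("no exchange reaction for measured metabolite %s", met)
            continue
        se = (ex.se_q / abs(ex.q) if (bound_mode == "relative" and ex.q != 0)
              else ex.se_q)
        lo, hi = rates.propagate_bounds(ex.q, se, mode=bound_mode)
        lo, hi = _widen((lo, hi), ex.q, min_halfwidth)
        exchange_bounds[met_to_exchange[met]] = (lo, hi)

    mu = growth.mu
    rel = rates.combine_relative_errors([
        growth.se_mu / abs(mu) if mu else 0.0,
        calib.se_dry_mass / calib.dry_mass_per_cell])
    bm = rates.propagate_bounds(mu, mu * rel, mode="propagated")
    biomass_bounds = _widen(bm, mu, min_halfwidth)
    return InstanceFits(growth=growth, calibration=calib, exchanges=exchanges,
                        biomass_bounds=biomass_bounds,
                        exchange_bounds=exchange_bounds)


def _widen(bounds: tuple[float, float], center: float,
           min_halfwidth: float) -> tuple[float, float]:
    lo, hi = bounds
    if hi - lo < 2 * min_halfwidth:
        lo = min(lo, center - min_halfwidth)
        hi = max(hi, center + min_halfwidth)
    return lo, hi


# ---------------------------------------------------------------------------
# stage 2-3: constrain, reduce, solve
# ---------------------------------------------------------------------------

def apply_instance_bounds(model, fits: InstanceFits, biomass_id: str):
    """Copy of the model with the condition's measured bounds applied."""
    inst = model.copy()
    for rid, (lo, hi) in fits.exchange_bounds.items():
        inst.reactions.get_by_id(rid).bounds = (lo, hi)
    inst.reactions.get_by_id(biomass_id).bounds = fits.biomass_bounds
    return inst


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute fit -> constrain -> pTFVA -> cascade and write all reports."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        model, thermo, id_map, conditions = synth.load_bundle_inputs(config.data_dir)
        biomass_id = model_io.find_biomass_reaction(model).id
        if config.pooled_supply_reactions:
            model_io.replace_pooled_supply(model, config.pooled_supply_reactions,
                                           config.pooled_supply_fatty_acids)
        _validate_pairing(config.pairing, conditions)

        stage = "fit"
        fits = {}
        for cond, ds in conditions.items():
            fits[cond] = fit_condition(ds, model, config.bound_mode,
                                       config.min_bound_halfwidth)
            _write_fit_outputs(out, cond, fits[cond])

        stage = "reduce"
        blocked_union: set[str] = set()
        for cond, f in fits.items():
            inst = apply_instance_bounds(model, f, biomass_id)
            _, blocked = model_io.remove_blocked(inst)
            blocked_union |= set(blocked)
        if blocked_union:
            model.remove_reactions(
                [model.reactions.get_by_id(r) for r in sorted(blocked_union)],
                remove_orphans=True)
        model_io.write_removed_report(sorted(blocked_union), model,
                                      out / "removed_reactions.tsv")

        stage = "solve"
        coverage = model_io.join_thermo(model, thermo, id_map)
        raw_ranges: dict[str, FluxRangeSet] = {}
        problems: dict[str, TFAProblem] = {}
        for cond, f in fits.items():
            inst = apply_instance_bounds(model, f, biomass_id)
            prob = TFAProblem(inst, thermo,
                              conc_bounds=conditions[cond].conc_bounds,
                              id_map=id_map, biomass_id=biomass_id,
                              conc_default=config.conc_default)
            prob.solve_pfba()
            rset = prob.solve_ptfva(instance=cond)
            rset.to_tsv(out / f"ranges_raw_{cond}.tsv")
            raw_ranges[cond] = rset
            problems[cond] = prob
            logger.info("instance %s: pFBA total %.4g, biomass %.4g",
                        cond, prob.min_total_flux, rset.biomass_flux)

        stage = "compare"
        reports_raw = {}
        reports_norm = {}
        normalized = {}
        for cond, rset in raw_ranges.items():
            normalized[cond] = compare.growth_normalize(rset)
            normalized[cond].to_tsv(out / f"ranges_growth_normalized_{cond}.tsv")
        for res, ctl in config.pairing.items():
            key = f"{res}_vs_{ctl}"
            reports_raw[key] = compare.flag_differences(
                raw_ranges[res], raw_ranges[ctl],
                config.threshold, config.delta)
            reports_norm[key] = compare.flag_differences(
                normalized[res], normalized[ctl],
                config.threshold, config.delta)
            reports_raw[key].to_tsv(out / f"report_raw_{key}.tsv")
            reports_norm[key].to_tsv(out / f"report_growth_normalized_{key}.tsv")
            summ = compare.subsystem_summary(
                reports_norm[key], normalized[res].subsystems,
                exclude=config.excluded_subsystems)
            summ.to_tsv(out / f"subsystems_{key}.tsv")

        cross_report = None
        if len(config.pairing) == 2:
            scaled = compare.feature_scale(
                [normalized[c] for c in _cascade_order(config.pairing)])
            by_cond = {s.instance: s for s in scaled}
            ratios = [compare.control_ratio(by_cond[res], by_cond[ctl])
                      for res, ctl in config.pairing.items()]
            cross_report = compare.flag_differences(
                ratios[0], ratios[1], config.threshold, config.delta)
            cross_report.to_tsv(out / "report_cross_resistance.tsv")
            cross_summary = compare.subsystem_summary(
                cross_report, raw_ranges[_first(config.pairing)].subsystems,
                exclude=config.excluded_subsystems)
            cross_summary.to_tsv(out / "subsystems_cross_resistance.tsv")

        summary = {
            "reactions": len(model.reactions),
            "removed_blocked": len(blocked_union),
            "thermo_compound_coverage": coverage.compound_fraction,
            "thermo_reaction_coverage": coverage.reaction_fraction,
            "growth_rates": {c: f.growth.mu for c, f in fits.items()},
            "flags_raw": {k: r.n_flagged for k, r in reports_raw.items()},
            "flags_growth_normalized": {k: r.n_flagged
                                        for k, r in reports_norm.items()},
            "flags_cross_resistance": (cross_report.n_flagged
                                       if cross_report else None),
            "exchange_convention": "flux > 0 = secretion, < 0 = uptake",
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                     sort_keys=True))
        return PipelineResult(
            config=config, fits=fits, removed_reactions=sorted(blocked_union),
            raw_ranges=raw_ranges, normalized_ranges=normalized,
            reports_raw=reports_raw, reports_normalized=reports_norm,
            cross_report=cross_report, summary=summary, problems=problems)
    except Exception as exc:
        logger.error("pipeline aborted in stage %r (completed artifacts in %s): %s",
                     stage, out, exc)
        exc.pipeline_stage = stage
        raise


def _validate_pairing(pairing, conditions) -> None:
    for res, ctl in pairing.items():
        for cond in (res, ctl):
            if cond not in conditions:
                raise ConfigurationError(
                    f"pairing references unknown condition {cond!r}")


def _cascade_order(pairing) -> list[str]:
    order = []
    for res, ctl in pairing.items():
        order.extend([res, ctl])
    return order


def _first(pairing) -> str:
    return next(iter(pairing))


def _write_fit_outputs(out: Path, cond: str, fits: InstanceFits) -> None:
    rows = [{"metabolite": m, "q": e.q, "se": e.se_q,
             "lower": e.lower_bound, "upper": e.upper_bound}
            for m, e in sorted(fits.exchanges.items())]
    pd.DataFrame(rows).to_csv(out / f"exchange_rates_{cond}.tsv", sep="\t",
                              index=False, float_format="%.10g")
    g = fits.growth
    (out / f"growth_{cond}.json").write_text(json.dumps(
        {"x0": g.x0, "mu": g.mu, "se_x0": g.se_x0, "se_mu": g.se_mu,
         "loss": g.loss, "biomass_bounds": list(fits.biomass_bounds)},
        indent=1))
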