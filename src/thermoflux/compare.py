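"""Normalization cascade and the dual-bound 15% difference statistic.

Flux ranges from variability analysis are compared between a resistant and
a sensitive model instance through a cascade of normalizations:

1. growth normalization -- every range endpoint is divided by the instance's
   biomass flux, removing growth-magnitude effects;
2. feature scaling -- per reaction, all endpoints across the four instances
   are min-max mapped onto [0, 1];
3. control ratio -- scaled resistant values are divided by the paired
   sensitive control values, cancelling effects (e.g. a solvent background)
   shared by a resistant/control pair.

At any stage two instances can be compared with the dual-bound rule: a
reaction differs when BOTH its lower-bound and upper-bound relative
differences reach the threshold (default 15%).  The relative difference per
bound is |x_a - x_b| / max(|x_a|, |x_b|, delta), a symmetric, zero-safe
baseline.  Exchange convention (flux > 0 secretion) is stated in every
report header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .tfa import (CONTROL_RATIO, FEATURE_SCALED, GROWTH_NORMALIZED, RAW,
                  FluxRangeSet)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.15
#: zero-safe floor for relative-difference denominators
DELTA = 1e-8
#: feature-scaled values below this fraction of the per-reaction range are
#: numerically indistinguishable from zero (solver tolerances and
#: measurement-window widths propagate through the scaling); such values are
#: treated as exact zeros, and ratios against such controls are meaningless
#: (the reaction is marked incomparable)
INCOMPARABLE_FLOOR = 5e-3
#: across-instance spans below this fraction of the value magnitude carry no
#: information (they are solver/measurement-window noise); min-max scaling
#: would amplify them to the full [0, 1] range, so they map to 0.5 instead
SPAN_FLOOR_REL = 1e-3

REPORT_HEADER = "# exchange convention: flux > 0 = secretion, flux < 0 = uptake"


@dataclass
class ComparisonReport:
    """Per-reaction difference flags for a pair of instances."""

    per_reaction: pd.DataFrame
    #: instance labels (a, b)
    instances: tuple[str, str]
    threshold: float
    state: str

    @property
    def flagged(self) -> list[str]:
        return list(self.per_reaction.index[self.per_reaction["flagged"]])

    @property
    def n_flagged(self) -> int:
        return int(self.per_reaction["flagged"].sum())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(REPORT_HEADER + "\n")
            self.per_reaction.to_csv(fh, sep="\t", float_format="%.10g")


def growth_normalize(ranges: FluxRangeSet, tolerance: float = 1e-9) -> FluxRangeSet:
    """Divide every endpoint by the instance's (pFBA) biomass flux."""
    if ranges.state != RAW:
        raise DataError(f"growth_normalize expects raw ranges, got {ranges.state}")
    if ranges.biomass_flux is None:
        raise DataError("biomass flux unknown; solve pFBA first")
    if ranges.biomass_flux <= tolerance:
        raise DataError("biomass flux is ~0; growth normalization undefined")
    out = ranges.ranges / ranges.biomass_flux
    if ranges.biomass_id in out.index:
        out.loc[ranges.biomass_id] = [1.0, 1.0]
    return ranges.copy_with(out, GROWTH_NORMALIZED)


def _relative_difference(a: np.ndarray, b: np.ndarray, delta: float) -> np.ndarray:
    return np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), delta)


def flag_differences(a: FluxRangeSet, b: FluxRangeSet,
                     threshold: float = DEFAULT_THRESHOLD,
                     delta: float = DELTA) -> ComparisonReport:
    """Dual-bound difference flags between two instances.

    A reaction is flagged iff both the lower-bound and the upper-bound
    relative differences are >= threshold.  Direction compares interval
    midpoints (which instance carries the higher flux).  Reactions marked
    incomparable (by :func:`control_ratio`) are never flagged.
    """
    if a.state != b.state:
        raise DataError(f"normalization states differ: {a.state} vs {b.state}")
    if set(a.ranges.index) != set(b.ranges.index):
        diff = set(a.ranges.index) ^ set(b.ranges.index)
        raise DataError(f"reaction universes differ: {sorted(diff)[:10]}")
    ra = a.ranges
    rb = b.ranges.loc[ra.index]
    rel_lb = _relative_difference(ra["minimum"].to_numpy(),
                                  rb["minimum"].to_numpy(), delta)
    rel_ub = _relative_difference(ra["maximum"].to_numpy(),
                                  rb["maximum"].to_numpy(), delta)
    flagged = (rel_lb >= threshold) & (rel_ub >= threshold)
    incomparable = np.zeros(len(ra), dtype=bool)
    for rs in (a, b):
        if "incomparable" in rs.ranges.columns:
            incomparable |= rs.ranges["incomparable"].to_numpy(dtype=bool)
    flagged &= ~incomparable
    mid_a = (ra["minimum"] + ra["maximum"]).to_numpy() / 2.0
    mid_b = (rb["minimum"] + rb["maximum"]).to_numpy() / 2.0
    direction = np.where(mid_a > mid_b, a.instance,
                         np.where(mid_b > mid_a, b.instance, "equal"))
    df = pd.DataFrame({
        "subsystem": [a.subsystems.get(r, "") for r in ra.index],
        "lb_a": ra["minimum"].to_numpy(), "ub_a": ra["maximum"].to_numpy(),
        "lb_b": rb["minimum"].to_numpy(), "ub_b": rb["maximum"].to_numpy(),
        "rel_lb": rel_lb, "rel_ub": rel_ub,
        "flagged": flagged, "incomparable": incomparable,
        "direction": direction,
    }, index=ra.index)
    df.index.name = "reaction"
    return ComparisonReport(per_reaction=df, instances=(a.instance, b.instance),
                            threshold=threshold, state=a.state)


def feature_scale(sets: list[FluxRangeSet],
                  span_floor_rel: float = SPAN_FLOOR_REL) -> list[FluxRangeSet]:
    """Min-max scale each reaction onto [0, 1] across all instances jointly.

    The scaling uses the minimum and maximum over all 2 * len(sets) endpoint
    values of that reaction; degenerate reactions -- those whose
    across-instance span is zero or below ``span_floor_rel`` of the value
    magnitude -- map to 0.5 everywhere, which keeps downstream ratios defined
    and never spuriously flagged.
    """
    if not sets:
        return []
    for s in sets:
        if s.state != GROWTH_NORMALIZED:
            raise DataError(f"feature_scale expects growth-normalized sets, got {s.state}")
    index = sets[0].ranges.index
    for s in sets[1:]:
        if set(s.ranges.index) != set(index):
            raise DataError("feature_scale requires a common reaction universe")
    los = np.min([s.ranges.loc[index, "minimum"].to_numpy() for s in sets], axis=0)
    his = np.max([s.ranges.loc[index, "maximum"].to_numpy() for s in sets], axis=0)
    span = his - los
    magnitude = np.maximum(np.abs(los), np.abs(his))
    degenerate = span <= span_floor_rel * magnitude
    span_safe = np.where(degenerate, 1.0, span)
    out = []
    for s in sets:
        r = s.ranges.loc[index]
        lo = (r["minimum"].to_numpy() - los) / span_safe
        hi = (r["maximum"].to_numpy() - los) / span_safe
        lo[degenerate] = 0.5
        hi[degenerate] = 0.5
        df = pd.DataFrame({"minimum": lo, "maximum": hi}, index=index)
        out.append(s.copy_with(df, FEATURE_SCALED))
    return out


def control_ratio(resistant: FluxRangeSet, sensitive: FluxRangeSet,
                  delta: float = INCOMPARABLE_FLOOR) -> FluxRangeSet:
    """Per-bound ratio resistant/sensitive of feature-scaled values.

    Scaled values below ``delta`` (a fraction of the per-reaction feature
    range) are numerically zero and treated as such: a zero numerator gives
    ratio 0, while reactions whose sensitive value is below ``delta`` in
    either bound are marked incomparable (excluded from downstream flagging)
    and counted in the log.  Endpoints are re-ordered where the division
    inverts them.
    """
    for s in (resistant, sensitive):
        if s.state != FEATURE_SCALED:
            raise DataError(f"control_ratio expects feature-scaled sets, got {s.state}")
    index = resistant.ranges.index
    rs = resistant.ranges
    ss = sensitive.ranges.loc[index]
    res_lo = np.where(np.abs(rs["minimum"].to_numpy()) < delta, 0.0,
                      rs["minimum"].to_numpy())
    res_hi = np.where(np.abs(rs["maximum"].to_numpy()) < delta, 0.0,
                      rs["maximum"].to_numpy())
    sen_lo = ss["minimum"].to_numpy()
    sen_hi = ss["maximum"].to_numpy()
    incomparable = (np.abs(sen_lo) < delta) | (np.abs(sen_hi) < delta)
    lo = res_lo / np.where(np.abs(sen_lo) < delta, delta, sen_lo)
    hi = res_hi / np.where(np.abs(sen_hi) < delta, delta, sen_hi)
    lo2 = np.minimum(lo, hi)
    hi2 = np.maximum(lo, hi)
    n_inc = int(incomparable.sum())
    if n_inc:
        logger.info("control_ratio: %d reactions incomparable (control < delta)",
                    n_inc)
    df = pd.DataFrame({"minimum": lo2, "maximum": hi2,
                       "incomparable": incomparable}, index=index)
    out = resistant.copy_with(df[["minimum", "maximum"]], CONTROL_RATIO)
    out.ranges["incomparable"] = incomparable
    out.instance = f"{resistant.instance}/{sensitive.instance}"
    return out


@dataclass
class SubsystemSummary:
    proportions: pd.DataFrame  # subsystem, n, n_flagged, proportion
    shares: pd.DataFrame       # subsystem, share (over non-excluded flags)
    excluded: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        merged = self.proportions.merge(self.shares, on="subsystem", how="left")
        merged["share"] = merged["share"].fillna(0.0)
        with open(path, "w") as fh:
            fh.write(REPORT_HEADER + "\n")
            merged.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def subsystem_summary(report: ComparisonReport, subsystems: dict[str, str],
                      exclude: list[str] | None = None) -> SubsystemSummary:
    """Per-subsystem flag proportions and shares of all flagged reactions.

    ``exclude`` lists subsystems (typically transport) removed before the
    share computation; subsystems with zero flags are omitted from the
    output.  Shares sum to one whenever any non-excluded reaction is flagged.
    """
    exclude = list(exclude or [])
    known = set(subsystems.values())
    for sub in exclude:
        if sub not in known:
            logger.warning("excluded subsystem %r not present in model", sub)
    df = report.per_reaction
    sub_series = pd.Series({rid: subsystems.get(rid, "") for rid in df.index})
    members = sub_series.groupby(sub_series).size()
    flagged = df["flagged"].groupby(sub_series).sum()
    prop = pd.DataFrame({
        "subsystem": members.index, "n": members.to_numpy(),
        "n_flagged": flagged.reindex(members.index).fillna(0).astype(int).to_numpy(),
    })
    prop["proportion"] = prop["n_flagged"] / prop["n"]
    prop = prop[prop["n_flagged"] > 0].reset_index(drop=True)

    keep = prop[~prop["subsystem"].isin(exclude)]
    total = keep["n_flagged"].sum()
    if total > 0:
        shares = keep[["subsystem", "n_flagged"]].copy()
        shares["share"] = shares["n_flagged"] / total
        shares = shares[["subsystem", "share"]].reset_index(drop=True)
    else:
        shares = pd.DataFrame(columns=["subsystem", "share"])
    return SubsystemSummary(proportions=prop, shares=shares, excluded=exclude)


def cascade_summary_json(stage_flags: dict[str, int], path: str | Path) -> None:
    """Flag counts at each cascade stage, for the run summary."""
    Path(path).write_text(json.dumps(stage_flags, indent=1, sort_keys=True))
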