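"""Campaign-level aggregation: descriptor summaries, zone occupancy
trajectories, and rule-based phenological stage labels.

The stage rules operationalize the qualitative occupancy narrative for a
maize season (seedling/leaf development -> elongation -> big trumpet ->
tasseling -> maturity) as an ordered, first-match-wins rule list over the
six-zone occupancy vector. The thresholds are configurable; the defaults
encode "about 80% of pixels in the low-to-moderate entropy zones" for leaf
development and "over 60% in the high-entropy distributed zone" for
maturity, with modal-zone rules for the middle stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorField
from .zoning import N_ZONES, ZoneMap, zone_occupancy

__all__ = [
    "STAGE_ORDER",
    "STAGE_ALIASES",
    "ViolinStats",
    "OccupancyEntry",
    "OccupancySeries",
    "StageRules",
    "summarize_descriptors",
    "build_time_series",
    "classify_stage",
    "detect_transitions",
]

# Canonical stage order for a maize season, with the field-guide names they
# alias (seedling, elongation/jointing, big flare/bell mouth, tasseling,
# full ripe).
STAGE_ORDER = ("leaf_development", "elongation", "big_trumpet", "tasseling", "maturity")
STAGE_ALIASES = {
    "leaf_development": "seedling",
    "elongation": "elongation",
    "big_trumpet": "big_flare",
    "tasseling": "tasseling",
    "maturity": "full_ripe",
}

_DESCRIPTORS = ("q", "m_c", "theta_c", "H_c")


@dataclass(frozen=True)
class ViolinStats:
    """Box-plot statistics (mean, std, median, quartiles) per descriptor.

    ``stats`` maps descriptor name (q, m_c, theta_c, H_c) to a dict with
    keys mean, std, median, q1, q3 — the quantities a violin/box summary
    displays. All statistics are computed over the same valid-pixel set.
    """

    stats: dict
    count: int
    scene_id: str = ""
    doy: int = 0
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("ViolinStats needs at least one pixel")
        for name, s in self.stats.items():
            if not s["q1"] <= s["median"] <= s["q3"]:
                raise ValueError(f"{name}: quartiles out of order: {s}")

    def to_row(self) -> dict:
        row = {"scene_id": self.scene_id, "doy": self.doy, "region_id": self.region_id, "count": self.count}
        for name in _DESCRIPTORS:
            for stat, val in self.stats[name].items():
                row[f"{name}_{stat}"] = val
        return row


@dataclass
class OccupancyEntry:
    doy: int
    region_id: str
    occupancy: np.ndarray  # six fractions summing to 1
    stats: ViolinStats
    stage: str | None = None


@dataclass
class OccupancySeries:
    """Per-date, per-region zone fractions and descriptor summaries."""

    entries: list[OccupancyEntry] = dc_field(default_factory=list)

    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.region_id, None)
        return list(seen)

    def for_region(self, region_id: str) -> list[OccupancyEntry]:
        return [e for e in self.entries if e.region_id == region_id]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = e.stats.to_row()
            row.update({f"z{k + 1}": e.occupancy[k] for k in range(N_ZONES)})
            row["stage"] = e.stage if e.stage is not None else ""
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StageRules:
    """Ordered occupancy rules, first match wins; every vector gets a label.

    Default order: leaf development when the low-to-moderate entropy zones
    Z1+Z2 hold >= 80% of pixels; maturity when the high-entropy distributed
    zone Z6 holds >= 60%; tasseling when the high-entropy vegetation zone Z5
    is modal; big trumpet when Z4+Z5 hold >= 50% with Z5 not modal;
    elongation when the medium-entropy zone Z3 is modal; otherwise
    "transitional".
    """

    leaf_threshold: float = 0.8
    maturity_threshold: float = 0.6
    big_trumpet_threshold: float = 0.5
    fallback: str = "transitional"

    def classify(self, occupancy: Sequence[float]) -> str:
        z = _check_occupancy(occupancy)
        modal = int(np.argmax(z))
        if z[0] + z[1] >= self.leaf_threshold:
            return "leaf_development"
        if z[5] >= self.maturity_threshold:
            return "maturity"
        if modal == 4:
            return "tasseling"
        if z[3] + z[4] >= self.big_trumpet_threshold:
            return "big_trumpet"
        if modal == 2:
            return "elongation"
        return self.fallback


def _check_occupancy(occupancy: Sequence[float]) -> np.ndarray:
    z = np.asarray(occupancy, np.float64)
    if z.shape != (N_ZONES,) or not np.isfinite(z).all() or (z < 0).any():
        raise ValueError(f"occupancy must be six non-negative finite fractions, got {occupancy}")
    if abs(z.sum() - 1.0) > 1e-9:
        raise ValueError(f"occupancy sums to {z.sum():.12f}, expected 1")
    return z


def summarize_descriptors(
    field: DescriptorField, region: np.ndarray | None = None, region_id: str = ""
) -> ViolinStats:
    """Mean/std/median/quartiles of q, m_c, theta_c, H_c over a region."""
    sel = field.mask if region is None else (np.asarray(region, bool) & field.mask)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"empty region {region_id!r}: no valid pixels")
    stats = {}
    for name in _DESCRIPTORS:
        vals = getattr(field, name)[sel]
        q1, med, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
        stats[name] = {
            "mean": float(vals.mean()),
            "std": float(vals.std(ddof=0)),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
        }
    return ViolinStats(stats=stats, count=n, scene_id=field.scene_id, doy=field.doy, region_id=region_id)


def build_time_series(
    scenes: Sequence[tuple[int, DescriptorField, ZoneMap]],
    regions: dict[str, np.ndarray] | None = None,
    rules: StageRules | None = None,
) -> OccupancySeries:
    """Per-region occupancy vectors and descriptor summaries for each date.

    ``regions`` maps region_id to a boolean grid; None summarizes the whole
    valid footprint under region_id "all". DOYs must be strictly increasing
    and all scenes must share grid geometry. When ``rules`` is given each
    entry is stage-labeled.
    """
    if not scenes:
        raise ValueError("no scenes supplied")
    doys = [doy for doy, _, _ in scenes]
    if len(set(doys)) != len(doys):
        raise ValueError(f"duplicate DOY in campaign: {doys}")
    if any(b <= a for a, b in zip(doys, doys[1:])):
        raise ValueError(f"DOYs must be strictly increasing, got {doys}")
    shape = scenes[0][1].shape
    series = OccupancySeries()
    for doy, dfield, zmap in scenes:
        if dfield.shape != shape or zmap.labels.shape != shape:
            raise ValueError(
                f"scene at DOY {doy}: geometry {dfield.shape} does not match campaign {shape}"
            )
        region_items = regions.items() if regions is not None else [("all", None)]
        for region_id, rmask in region_items:
            occ = zone_occupancy(zmap, rmask)
            stats = summarize_descriptors(dfield, rmask, region_id=str(region_id))
            stage = rules.classify(occ) if rules is not None else None
            series.entries.append(
                OccupancyEntry(doy=doy, region_id=str(region_id), occupancy=occ, stats=stats, stage=stage)
            )
    return series


def classify_stage(occupancy: Sequence[float], rules: StageRules = StageRules()) -> str:
    """Label one occupancy vector by the ordered stage rules."""
    return rules.classify(occupancy)


def detect_transitions(series: OccupancySeries) -> list[tuple[int, int, str, str]]:
    """Consecutive-date stage changes per region: (doy_from, doy_to, from, to)."""
    out = []
    for region_id in series.regions():
        entries = series.for_region(region_id)
        if any(e.stage is None for e in entries):
            raise ValueError(f"region {region_id!r}: series is not stage-labeled")
        for prev, cur in zip(entries, entries[1:]):
            if prev.stage != cur.stage:
                out.append((prev.doy, cur.doy, prev.stage, cur.stage))
    return out
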