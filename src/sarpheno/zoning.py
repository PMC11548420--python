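"""Feasible H_c/theta_c scattering zones Z1-Z6 and per-pixel zone assignment.

On dual-pol GRD data every pixel's (H_c, theta_c) pair lies on a single
one-dimensional feasibility curve parameterized by the cross-pol ratio q,
because both descriptors are functions of q alone. Partitioning H_c into
four subclasses (0-0.3, 0.3-0.5, 0.5-0.7, 0.7-1.0) and theta_c into three
(0-15deg, 15-30deg, 30-45deg) yields a 4x3 cell grid of which the curve
visits exactly six cells — the six feasible scattering zones, numbered
Z1..Z6 by increasing q (low-entropy pure surface-like scattering through
high-entropy distributed scattering).

Zone boundaries are the q values where the curve crosses a bin edge; pixel
assignment uses those q cut-points directly (not rounded descriptor
rasters), which makes the q-interval and the (H_c, theta_c) cell-membership
definitions exactly equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .descriptors import DescriptorField, pseudo_entropy, pseudo_scattering_type

__all__ = [
    "H_BIN_EDGES",
    "THETA_BIN_EDGES",
    "ZoneThresholds",
    "ZoneMap",
    "feasibility_curve",
    "derive_zone_thresholds",
    "assign_zones",
    "zone_occupancy",
    "region_mask_from_polygon",
]

H_BIN_EDGES = (0.0, 0.3, 0.5, 0.7, 1.0)
THETA_BIN_EDGES = (0.0, 15.0, 30.0, 45.0)
N_ZONES = 6


@dataclass(frozen=True)
class ZoneThresholds:
    """Five strictly increasing q cut-points delimiting Z1..Z6.

    The cuts are where the feasibility curve crosses H_c = 0.3, 0.5, 0.7 and
    theta_c = 30deg, 15deg (in increasing-q order: H 0.3, H 0.5, H 0.7,
    theta 30, theta 15).
    """

    q_cuts: tuple[float, float, float, float, float]
    tolerance: float = 1e-10
    h_bins: tuple = tuple(zip(H_BIN_EDGES[:-1], H_BIN_EDGES[1:]))
    theta_bins: tuple = tuple(zip(THETA_BIN_EDGES[:-1], THETA_BIN_EDGES[1:]))

    def __post_init__(self) -> None:
        cuts = np.asarray(self.q_cuts, np.float64)
        if cuts.shape != (5,) or not (np.diff(cuts) > 0).all():
            raise ValueError(f"q_cuts must be five strictly increasing values, got {self.q_cuts}")
        if not ((cuts > 0) & (cuts < 1)).all():
            raise ValueError("q_cuts must lie strictly inside (0, 1)")


@dataclass
class ZoneMap:
    """Integer zone labels 1..6 per pixel, 0 = nodata."""

    labels: np.ndarray
    doy: int
    thresholds: ZoneThresholds
    scene_id: str = ""

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def feasibility_curve(n: int = 10_001) -> np.ndarray:
    """Sample the (q, H_c, theta_c) feasibility curve at n uniform q values.

    Returns a structured array with fields q, H_c, theta_c; H_c is weakly
    increasing and theta_c weakly decreasing along the sequence.
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    q = np.linspace(0.0, 1.0, n)
    out = np.empty(n, dtype=[("q", float), ("H_c", float), ("theta_c", float)])
    out["q"] = q
    out["H_c"] = pseudo_entropy(q)
    out["theta_c"] = pseudo_scattering_type(q)
    return out


def _scalar_H(q: float) -> float:
    return float(pseudo_entropy(np.asarray([q]))[0])


def _scalar_theta(q: float) -> float:
    return float(pseudo_scattering_type(np.asarray([q]))[0])


def _visited_cells(n: int = 100_001) -> set[tuple[int, int]]:
    """Cells of the 4x3 H_c x theta_c bin grid visited by the curve."""
    curve = feasibility_curve(n)
    hi = np.clip(np.searchsorted(H_BIN_EDGES, curve["H_c"], side="right") - 1, 0, 3)
    ti = np.clip(np.searchsorted(THETA_BIN_EDGES, curve["theta_c"], side="right") - 1, 0, 2)
    return set(zip(hi.tolist(), ti.tolist()))


def derive_zone_thresholds(tolerance: float = 1e-10) -> ZoneThresholds:
    """Solve for the five q cut-points by bracketed root finding on [0, 1].

    Asserts that the feasibility curve visits exactly six cells of the
    4x3 bin grid (the defining property of the six-zone framework).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    cuts = []
    for level in (0.3, 0.5, 0.7):
        cuts.append(brentq(lambda q: _scalar_H(q) - level, 1e-15, 1.0, xtol=tolerance))
    for level in (30.0, 15.0):
        cuts.append(brentq(lambda q: _scalar_theta(q) - level, 1e-15, 1.0, xtol=tolerance))
    cuts = tuple(cuts)
    n_cells = len(_visited_cells())
    if n_cells != N_ZONES:
        raise RuntimeError(
            f"feasibility curve visits {n_cells} bin cells, expected {N_ZONES}"
        )
    return ZoneThresholds(q_cuts=cuts, tolerance=tolerance)


def assign_zones(field: DescriptorField, thr: ZoneThresholds) -> ZoneMap:
    """Label every valid pixel Z1..Z6 from its q via the threshold cuts.

    Intervals are half-open [q_{k-1}, q_k) with the last closed at q = 1, so
    each pixel gets exactly one label; labels are monotone in q.
    """
    cuts = np.asarray(thr.q_cuts, np.float64)
    labels = np.zeros(field.shape, np.uint8)
    valid = field.mask & np.isfinite(field.q)
    labels[valid] = np.searchsorted(cuts, field.q[valid], side="right").astype(np.uint8) + 1
    return ZoneMap(labels=labels, doy=field.doy, thresholds=thr, scene_id=field.scene_id)


def zone_occupancy(zmap: ZoneMap, region: np.ndarray | None = None) -> np.ndarray:
    """Fractions of valid in-region pixels per zone; a six-vector summing to 1."""
    sel = zmap.mask if region is None else (np.asarray(region, bool) & zmap.mask)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty region: no valid pixels selected")
    counts = np.bincount(zmap.labels[sel].astype(int), minlength=N_ZONES + 1)[1:]
    return counts / n


def region_mask_from_polygon(polygon, shape: tuple[int, int], geo) -> np.ndarray:
    """Rasterize a shapely polygon (or GeoJSON-like mapping) onto the grid.

    A pixel belongs to the region when its center falls inside the polygon.
    Requires a georeference to place pixel centers in world coordinates.
    """
    import shapely
    from shapely.geometry import shape as shapely_shape

    if geo is None:
        raise ValueError("polygon regions require a georeferenced grid")
    if isinstance(polygon, dict):
        polygon = shapely_shape(polygon.get("geometry", polygon))
    x, y = geo.pixel_centers(shape)
    return shapely.contains_xy(polygon, x.ravel(), y.ravel()).reshape(shape)
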