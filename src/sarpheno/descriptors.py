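"""Dual-polarization pseudo-scattering descriptors from the cross-pol ratio.

All three descriptors are pointwise functions of the cross-pol ratio
q = sigma0_VH / sigma0_VV in [0, 1]:

* co-polar purity            m_c    = (1 - q) / (1 + q)            in [0, 1]
* pseudo-scattering type     theta_c = atan[(1 - q)^2 / (1 + q^2 - q)]  in [0deg, 45deg]
* pseudo-scattering entropy  H_c    = -p1 log2 p1 - p2 log2 p2     in [0, 1]

with pseudo-probabilities p1 = 1/(1+q), p2 = q/(1+q). m_c and theta_c fall
and H_c rises as canopy randomness (volume scattering) grows. theta_c also
equals the difference zeta1 - zeta2 of the auxiliary angles
tan(zeta_i) = sigma0_i / (m_c * I), I = sigma0_VV + sigma0_VH, wherever
q < 1; the closed form covers the q = 1 singularity. Because every
descriptor depends on the channels only through q, all of them are
invariant to a common multiplicative calibration factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import entr

from .raster_io import RadarScene

__all__ = [
    "DescriptorField",
    "cross_pol_ratio",
    "copolar_purity",
    "auxiliary_angles",
    "pseudo_scattering_type",
    "pseudo_entropy",
    "compute_descriptor_field",
]

_LN2 = np.log(2.0)


@dataclass
class DescriptorField:
    """Per-pixel q, m_c, theta_c (degrees), H_c grids with a shared mask."""

    q: np.ndarray
    m_c: np.ndarray
    theta_c: np.ndarray
    H_c: np.ndarray
    clip_fraction: float
    mask: np.ndarray
    doy: int
    scene_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.q.shape

    def __post_init__(self) -> None:
        shapes = {self.q.shape, self.m_c.shape, self.theta_c.shape, self.H_c.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"descriptor grids disagree in shape: {shapes}")


def _check_domain(q: np.ndarray, name: str = "q") -> np.ndarray:
    q = np.asarray(q, np.float64)
    finite = np.isfinite(q)
    if finite.any() and ((q[finite] < 0).any() or (q[finite] > 1).any()):
        bad = q[finite]
        raise ValueError(
            f"{name} outside [0, 1]: min {bad.min():.6g}, max {bad.max():.6g}"
        )
    return q


def cross_pol_ratio(
    vv: np.ndarray, vh: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    """q = vh/vv clipped to [0, 1]; returns (q, clip_fraction, out_mask).

    Pixels with vv <= 0 are demoted to mask-false. clip_fraction is the share
    of valid pixels whose raw ratio exceeded 1 (cross-pol above co-pol occurs
    in noise; the descriptor framework assumes q <= 1).
    """
    vv = np.asarray(vv, np.float64)
    vh = np.asarray(vh, np.float64)
    out_mask = np.asarray(mask, bool) & np.isfinite(vv) & np.isfinite(vh) & (vv > 0) & (vh >= 0)
    n_valid = int(out_mask.sum())
    if n_valid == 0:
        raise ValueError("empty valid set: no pixel has finite vv > 0 and vh >= 0")
    q = np.full(vv.shape, np.nan)
    np.divide(vh, vv, out=q, where=out_mask)
    clipped = out_mask & (q > 1.0)
    q[out_mask] = np.clip(q[out_mask], 0.0, 1.0)
    return q, int(clipped.sum()) / n_valid, out_mask


def copolar_purity(q: np.ndarray) -> np.ndarray:
    """m_c = (1 - q)/(1 + q); 1 at pure co-pol, 0 at fully depolarized."""
    q = _check_domain(q)
    return (1.0 - q) / (1.0 + q)


def auxiliary_angles(
    vv: np.ndarray, vh: np.ndarray, m_c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """zeta1 = atan(vv/(m_c I)), zeta2 = atan(vh/(m_c I)) in degrees.

    Returns (zeta1, zeta2, singular) where ``singular`` flags q = 1 pixels
    (m_c = 0); those are NaN in both angle grids — the closed-form theta_c
    covers them.
    """
    vv = np.asarray(vv, np.float64)
    vh = np.asarray(vh, np.float64)
    m_c = np.asarray(m_c, np.float64)
    I = vv + vh
    singular = ~(m_c > 0) | ~np.isfinite(m_c)
    denom = np.where(singular, np.nan, m_c * I)
    with np.errstate(invalid="ignore", divide="ignore"):
        zeta1 = np.degrees(np.arctan(vv / denom))
        zeta2 = np.degrees(np.arctan(vh / denom))
    return zeta1, zeta2, singular


def pseudo_scattering_type(q: np.ndarray) -> np.ndarray:
    """theta_c = atan[(1-q)^2 / (1 + q^2 - q)] in degrees, in [0, 45]."""
    q = _check_domain(q)
    return np.degrees(np.arctan((1.0 - q) ** 2 / (1.0 + q * q - q)))


def pseudo_entropy(q: np.ndarray) -> np.ndarray:
    """Binary Shannon entropy (base 2) of p1 = 1/(1+q), p2 = q/(1+q).

    0*log 0 := 0, so H_c(0) = 0 exactly; H_c(1) = 1 exactly.
    """
    q = _check_domain(q)
    p1 = 1.0 / (1.0 + q)
    p2 = q / (1.0 + q)
    # scipy entr(p) = -p ln p with entr(0) = 0
    return (entr(p1) + entr(p2)) / _LN2


def compute_descriptor_field(scene: RadarScene) -> DescriptorField:
    """Assemble q, m_c, theta_c, H_c from a preprocessed (linear, filtered)
    scene, on a shared mask, recording the q-clipping fraction."""
    q, clip_fraction, mask = cross_pol_ratio(scene.vv, scene.vh, scene.mask)
    qv = np.where(mask, q, np.nan)
    return DescriptorField(
        q=qv,
        m_c=copolar_purity(qv),
        theta_c=pseudo_scattering_type(qv),
        H_c=pseudo_entropy(qv),
        clip_fraction=clip_fraction,
        mask=mask,
        doy=scene.doy,
        scene_id=scene.scene_id,
    )
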