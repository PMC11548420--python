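"""Valid-pixel masking and boxcar speckle filtering.

Filtering happens on channel intensities in linear power, before the
cross-pol ratio is formed (ratio of means, not mean of ratios), which is
the physical multilook estimator and bounds ratio bias under multiplicative
speckle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .raster_io import RadarScene

__all__ = ["PreprocessConfig", "build_valid_mask", "boxcar_filter", "preprocess_scene"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Boxcar filter configuration.

    window: odd box side in pixels (5 is a common choice for Sentinel-1 GRD
    speckle suppression). min_valid_fraction: fraction of valid neighbors a
    window must contain for the output pixel to stay valid; prevents
    single-pixel "means" at mask boundaries.
    """

    window: int = 5
    edge_mode: str = "reflect"
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if not 0.0 <= self.min_valid_fraction <= 1.0:
            raise ValueError(f"min_valid_fraction {self.min_valid_fraction} outside [0, 1]")
        if self.edge_mode != "reflect":
            raise ValueError(f"unsupported edge_mode {self.edge_mode!r}")


def build_valid_mask(scene: RadarScene) -> np.ndarray:
    """True exactly where both channels are finite, vv > 0 and vh >= 0,
    AND-combined with the scene's incoming mask."""
    ok = np.isfinite(scene.vv) & np.isfinite(scene.vh)
    ok &= (scene.vv > 0) & (scene.vh >= 0)
    return ok & scene.mask


def boxcar_filter(
    grid: np.ndarray, mask: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Masked moving-window mean with reflect padding.

    Each output pixel is the arithmetic mean of the mask-valid neighbors in
    its window x window box. Pixels whose valid-neighbor fraction falls below
    ``cfg.min_valid_fraction`` are mask-false on output. Returns
    ``(filtered, out_mask)``.
    """
    grid = np.asarray(grid, np.float64)
    mask = np.asarray(mask, bool)
    if grid.shape != mask.shape:
        raise ValueError(f"grid {grid.shape} and mask {mask.shape} differ in shape")
    if cfg.window == 1:
        out = np.where(mask, grid, np.nan)
        return out, mask.copy()
    filled = np.where(mask, grid, 0.0)
    num = ndimage.uniform_filter(filled, size=cfg.window, mode=cfg.edge_mode)
    frac = ndimage.uniform_filter(mask.astype(np.float64), size=cfg.window, mode=cfg.edge_mode)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / frac
    # small epsilon guards float round-off at exactly-threshold fractions
    out_mask = frac >= cfg.min_valid_fraction - 1e-9
    out_mask &= frac > 0
    out[~out_mask] = np.nan
    return out, out_mask


def preprocess_scene(scene: RadarScene, cfg: PreprocessConfig = PreprocessConfig()) -> RadarScene:
    """Mask then boxcar-filter both channels with a shared validity mask.

    Returns a new RadarScene in linear power; doy, scene_id and geo are
    preserved.
    """
    shared = build_valid_mask(scene)
    vv_f, mask_vv = boxcar_filter(scene.vv, shared, cfg)
    vh_f, mask_vh = boxcar_filter(scene.vh, shared, cfg)
    out_mask = mask_vv & mask_vh
    return RadarScene(
        vv=np.where(out_mask, vv_f, np.nan),
        vh=np.where(out_mask, vh_f, np.nan),
        mask=out_mask,
        doy=scene.doy,
        scene_id=scene.scene_id,
        geo=scene.geo,
    )
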