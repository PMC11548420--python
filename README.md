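# sarpheno

Crop-phenology monitoring from dual-polarization SAR backscatter.

Optical crop monitoring fails under cloud; C-band SAR does not. Sentinel-1
GRD products carry only two detected intensities per pixel — co-polarized
σ°_VV and cross-polarized σ°_VH — so the full polarimetric H/α machinery is
unavailable. `sarpheno` implements the pseudo-scattering descriptor
framework that works from GRD intensities alone, and uses it to track the
phenological stages of a maize season (seedling → elongation → big trumpet
→ tasseling → maturity) from a time stack of acquisitions. It is written
for agricultural remote-sensing practitioners who have analysis-ready
dual-pol backscatter rasters and want per-field growth-stage trajectories
without training data.

## The descriptors

Everything derives from the cross-pol ratio `q = σ°_VH / σ°_VV ∈ [0, 1]`,
which grows with canopy randomness (volume scattering):

- **co-polar purity**  `m_c = (1 − q) / (1 + q)` — 1 for pure surface-like
  scattering, 0 for fully depolarized returns;
- **pseudo-scattering type**  `θ_c = arctan[(1 − q)² / (1 + q² − q)]`
  ∈ [0°, 45°] — equivalently the difference ζ₁ − ζ₂ of the auxiliary angles
  tan ζᵢ = σ°ᵢ / (m_c·I), I = σ°_VV + σ°_VH;
- **pseudo-scattering entropy**  `H_c = −p₁ log₂ p₁ − p₂ log₂ p₂` with
  pseudo-probabilities p₁ = 1/(1+q), p₂ = q/(1+q).

Because all three are functions of q alone, every pixel lies on a single
feasibility curve in the H_c/θ_c plane. Intersecting that curve with the
standard entropy subclasses (0.3, 0.5, 0.7) and scattering-type subclasses
(15°, 30°) yields exactly **six feasible scattering zones Z1–Z6**, delimited
by five q cut-points (≈ 0.0562, 0.1236, 0.2335, 0.3293, 0.5509). Zone
occupancy per field and date, run through an ordered rule list (e.g. ≥ 80 %
of pixels in Z1+Z2 ⇒ leaf development; ≥ 60 % in Z6 ⇒ maturity), gives the
stage label.

The processing chain per scene is: ingest (dB → linear power) → validity
mask → 5×5 boxcar speckle filter on intensities → descriptors → zone map →
per-region occupancy and violin statistics → stage labels and transitions.

A synthetic-campaign generator (stage-dependent cross-pol ratios on a
12-plot layout, multilook Gamma speckle, 13-date schedule) provides
ground-truthed inputs for testing and calibration.

## Worked example

```python
import numpy as np
from sarpheno import (copolar_purity, pseudo_scattering_type, pseudo_entropy,
                      derive_zone_thresholds, classify_stage)
from sarpheno.synthetic import make_plot_layout, simulate_campaign
from sarpheno.preprocess import preprocess_scene, PreprocessConfig
from sarpheno.descriptors import compute_descriptor_field
from sarpheno.zoning import assign_zones, zone_occupancy

# one pixel with cross-pol ratio q = 0.2195 (late-May maize)
q = np.array([0.2195])
print(copolar_purity(q), pseudo_scattering_type(q), pseudo_entropy(q))
# -> m_c = 0.64, theta_c = 36.32 deg, H_c = 0.6801

# a simulated season, scored on its last acquisition
layout = make_plot_layout(shape=(250, 400))
scenes, truth = simulate_campaign(layout=layout, looks=9, seed=1)
thr = derive_zone_thresholds()
doy, scene = scenes[-1]                       # DOY 270
field = compute_descriptor_field(preprocess_scene(scene, PreprocessConfig()))
occ = zone_occupancy(assign_zones(field, thr), layout.plot_mask(1))
print(doy, np.round(occ, 3), classify_stage(occ))
# -> 270 [0. 0. 0. 0. 0.005 0.995] maturity
```

The first block shows the three descriptors agreeing at a single ratio: a
purity of 0.64 implies a scattering type of 36.32° and an entropy of 0.68 —
soil-dominated, low-to-medium-entropy scattering typical of early canopy.
The second block pushes a speckled end-of-season scene through the full
chain: 99.5 % of the plot's pixels land in Z6, the high-entropy distributed
scattering zone, so the rule list labels the plot `maturity`.

There is also a CLI (`sarpheno thresholds | descriptors | classify |
simulate | campaign`) for running the same chain on rasters from a shell;
`sarpheno simulate --out-dir d` followed by
`sarpheno campaign --manifest d/manifest.csv --regions d/plots.geojson
--out-dir out` reproduces the example end to end.

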