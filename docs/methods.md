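# Methods

## Model

`sarpheno` works entirely from detected dual-pol intensities. The cross-pol
ratio q = σ°_VH/σ°_VV is the single degree of freedom; the three
descriptors are deterministic transforms of it:

- m_c = (1 − q)/(1 + q), strictly decreasing, m_c(0) = 1, m_c(1) = 0;
- θ_c = arctan[(1 − q)²/(1 + q² − q)] in degrees, strictly decreasing,
  θ_c(0) = 45°, θ_c(1) = 0°;
- H_c = −p₁log₂p₁ − p₂log₂p₂ with p₁ = 1/(1+q), p₂ = q/(1+q), strictly
  increasing, H_c(0) = 0 (0·log 0 := 0), H_c(1) = 1.

θ_c can equivalently be computed as ζ₁ − ζ₂ with tan ζᵢ = σ°ᵢ/(m_c·I),
I = σ°_VV + σ°_VH. That rendering is ambiguous as printed in the
literature (σ°·m_c/I vs σ°/(m_c·I)); the package adopts σ°/(m_c·I), the
unique parse under which the closed form above is exact, satisfies the
printed bounds, and is monotone. The two routes agree to < 1e−13 degrees on
a dense grid (the auxiliary route is singular at q = 1, where the closed
form applies). Because every descriptor depends on the channels only
through q, a common multiplicative calibration factor cancels: descriptors
are invariant to the absolute radiometric scale (σ° vs γ° calibration only
matters through incidence-angle dependence, which this framework does not
model).

### Zones

Partitioning H_c into (0, 0.3), (0.3, 0.5), (0.5, 0.7), (0.7, 1) and θ_c
into (0°, 15°), (15°, 30°), (30°, 45°) gives 12 cells; the feasibility
curve (H_c(q), θ_c(q)) visits exactly 6 of them. The zone boundaries in q
are found by Brent root-finding to 1e−10 (H_c = 0.3, 0.5, 0.7 then
θ_c = 30°, 15°):

| cut | q | crossing |
|---|---|---|
| Z1/Z2 | 0.05623 | H_c = 0.3 |
| Z2/Z3 | 0.12363 | H_c = 0.5 |
| Z3/Z4 | 0.23350 | H_c = 0.7 |
| Z4/Z5 | 0.32930 | θ_c = 30° |
| Z5/Z6 | 0.55094 | θ_c = 15° |

Pixels are labeled from q directly with half-open intervals [q_{k−1}, q_k)
(last closed at 1), which is exactly equivalent to cell membership of
(H_c, θ_c) but immune to rounding at bin edges. Zone numbering follows
increasing q: Z1/Z2 low-to-medium-entropy pure (surface-dominated)
scattering, Z3 medium entropy, Z4 high-entropy vegetation, Z5 high-entropy
vegetation dispersion, Z6 high-entropy distributed scattering.

## Processing chain

Per scene: ingest (dB inputs converted to linear power; declared nodata and
non-finite pixels mask-false) → validity mask (finite, VV > 0, VH ≥ 0) →
boxcar mean filter → descriptors → zones. Filtering happens on channel
intensities in linear power *before* the ratio is formed (ratio of means):
the mean of power is the physical multilook estimator, and it bounds the
ratio bias under multiplicative speckle (relative bias ≈ 2/(L·w²) ≈ 0.9 %
at L = 9, w = 5, well inside the speckle noise floor).

Tunable parameters:

| parameter | default | meaning |
|---|---|---|
| `window` | 5 px | boxcar side; odd; 5×5 is the conventional choice for Sentinel-1 GRD speckle suppression |
| `edge_mode` | reflect | padding; avoids darkening field borders |
| `min_valid_fraction` | 0.5 | valid-neighbor fraction below which a filtered pixel is masked out; prevents single-pixel means at mask edges |
| `zoning_tolerance` | 1e−10 | root-finder tolerance on the q cuts |

q > 1 (cross-pol above co-pol, possible in noise) is clipped to 1 and the
clipped fraction is logged per scene; θ_c is stored in degrees and H_c uses
log base 2 throughout.

### Stage rules

The literature reports occupancy percentages narratively, not a classifier.
The package operationalizes them as an ordered, first-match-wins rule list
over the occupancy six-vector (all thresholds configurable):

1. `leaf_development` if z1 + z2 ≥ 0.8 (the "~80 % in low-to-moderate
   entropy zones" observation);
2. `maturity` if z6 ≥ 0.6 ("over 60 % in the high-entropy distributed
   zone");
3. `tasseling` if Z5 is the modal zone;
4. `big_trumpet` if z4 + z5 ≥ 0.5 with Z5 not modal;
5. `elongation` if Z3 is the modal zone;
6. otherwise `transitional`.

Rule 5 is the package's addition: without it no occupancy pattern maps to
the elongation stage and a five-stage calendar cannot be recovered. The
stage names alias the field-guide terms seedling, elongation/jointing, big
flare/bell mouth, tasseling, full ripe.

A worked consistency check: a reported late-May mean purity m_c = 0.64
inverts to q = 0.2195, which implies θ_c = 36.32° and H_c = 0.680 —
within 0.4 % and 1.5 % of the companion reported values (36.18°, 0.67).
The analogous reported mid-season triple (0.51, 36.96°, 0.65) is mutually
inconsistent under these formulas (0.51 implies θ_c = 30.3°, H_c = 0.80)
and is not used as a check.

## Synthetic campaigns

The generator emulates the study conditions: a 4 km × 6 km area tiled by 12
rectangular plots (default 400×600 px at 10 m spacing) observed on 13 dates
(DOY 126–270, 12-day revisit). Each plot on each date draws a true q from a
truncated normal on [0, 1] around its stage's center, and a true VV level
with mild lognormal field-to-field variation (σ = 0.1 in log space);
observed intensity is truth × Gamma(L, mean 1) speckle, independent across
pixels and channels — the standard multilook GRD intensity model, with
L = 9 by default. All randomness flows from explicit seeds;
scenes are bitwise reproducible from the truth record.

Stage profiles (q center ± spread, VV center in linear power) are a stated
fixture anchored to the derived zone cuts, not field measurements:

| stage | q center | spread | VV | target zone |
|---|---|---|---|---|
| leaf_development | 0.08 | 0.010 | 0.080 | Z2 (Z1/Z2 band) |
| elongation | 0.17 | 0.020 | 0.100 | Z3 |
| big_trumpet | 0.28 | 0.020 | 0.130 | Z4 |
| tasseling | 0.42 | 0.040 | 0.140 | Z5 |
| maturity | 0.65 | 0.040 | 0.110 | Z6 |

The spreads are plot-to-plot variability chosen to keep ±2σ inside the
target zone; the VV levels follow the usual maize backscatter season
(≈ −11 dB emerging, ≈ −8.5 dB at peak canopy, falling at senescence). The
calendar maps the five stages onto the schedule by season fraction with
weights (0.25, 0.20, 0.15, 0.20, 0.20), placing DOY 198–210 in big trumpet,
222–234 in tasseling and 246–270 in maturity, consistent with the
mid-season narrative for this region.

The generator deliberately omits spatially correlated speckle,
incidence-angle gradients across the swath, and temporally correlated
soil-moisture effects — no quantitative model of these is available for
the target site. Passing recovery tests therefore demonstrate statistical
correctness of the chain under idealized multilook speckle, not robustness
to those real-data effects.

### Recovery scoring

`recovery_report` compares, per (plot, date): the plot-mean filtered q
against the true draw (relative error); the occupancy of the truth zone
(the zone containing the true q); and the predicted vs true stage. A
plot-date whose true q lies within 0.5 post-filter standard errors
(q·√(2/(L·w²))) of a zone cut is flagged *transitional*: there the
per-pixel zone decision is a near coin flip and a truth-zone occupancy
bound is not meaningful, so the occupancy aggregate excludes those pairs
(they remain in the q-error and stage-accuracy aggregates). At the scoring
scale used by `scripts/acceptance.py` — 250×400 px (12 plots of ~8,300 px,
the per-plot size at which speckle standard errors make the 2 % recovery
bound meaningful), L = 9, 5×5 boxcar, three seeded campaigns — typical
results are mean relative q error ≈ 0.6 %, minimum non-transitional
truth-zone occupancy ≈ 0.65–0.70, stage accuracy ≈ 99 %.

## Numerical choices and degenerate inputs

- H_c and θ_c hit their bounds exactly at q ∈ {0, 1}: `scipy.special.entr`
  handles 0·log 0, and the closed-form θ_c needs no special-casing at the
  q = 1 singularity of the auxiliary-angle route.
- Zone assignment uses `searchsorted` on the q cuts; a pixel exactly at a
  cut belongs to the upper zone (half-open intervals), so labels are a
  monotone step function of q.
- The boxcar divides a windowed sum by the windowed valid-count; an epsilon
  (1e−9) guards the min-valid-fraction comparison against float round-off
  at exactly-threshold fractions.
- Calibration invariance of q holds bitwise for power-of-two scale factors
  and to ≤ a few ulp for arbitrary factors (three IEEE roundings).
- Campaign CSVs are written with a fixed float format (`%.10g`) and line
  terminator, so identical configs reproduce byte-identical outputs.
- Empty regions, all-invalid scenes, duplicate or non-increasing DOYs, and
  geometry mismatches raise structured errors naming the offender.

## Limitations

- GRD intensities only: no interchannel phase, so covariance-based H/α or
  DpRVI descriptors are out of reach by design.
- Descriptor trajectories respond to anything that moves q — soil moisture
  after rain, lodging, residue — not only phenology; stage labels inherit
  that ambiguity.
- The rule thresholds were set from reported season-level percentages for
  maize in one irrigation district; other crops or regions will need
  re-tuning (they are plain dataclass fields).
- Incidence angle can vary by ~20° across a real campaign's acquisitions;
  no incidence normalization is applied, and the simulator correspondingly
  omits incidence effects rather than invent a model for them.
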