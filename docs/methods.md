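# Methods

This note records the models behind `canopyscan`, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the platform firmware leaves the method
open.

## Coordinate frame and calibration

All internal geometry is in millimetres, right-handed, z up from the
platform ground plane, y along scanner travel; areas are reported in
cm² and heights in cm. The scanner measures distances, not heights: a
calibration frame carries the sensor-to-ground distance `D_G`, the
sensor-to-barcode-target distance `D_T` and the physical target height
`T_H`. The frame is accepted only if `|D_G − D_T − T_H| ≤ 5 mm`
(configurable); each return then gets `z = D_G − D_P`, and returns that
would land below the ground plane are dropped as spurious. Returns at
or below the pot-height cutoff (default 200 mm; strictly-above points
are kept, ties discarded) are excluded from all trait computation, which
removes pot rims, soil and mulch. Sector binning along a scan lane uses
half-open `[y_start, y_end)` intervals; physical barcode markers
(nominally every 5 m) re-zero the local y of each returned sector cloud,
mirroring the scanner's position reset.

## Surface reconstruction and traits

A single-viewpoint nadir scan is single-valued in xy, so the canopy
surface is reconstructed by Delaunay triangulation of the xy-projection
(scipy's Qhull). Pruning every triangle with a 3D edge longer than
`max_edge_mm` (default 3.2 mm = 4× the 0.8 mm pitch) is the step that
gives the triangulation its "nearest-neighbour" character: a contiguous
surface tilted below ~75° never produces such edges, whereas gaps
between leaves and occlusion cliffs always do, so the mesh cannot
bridge them. Zero-area triangles are discarded.

- **3D leaf area** is the sum of retained triangle areas. Its only bias
  on clean scans is the boundary strip: the outermost sampled point of a
  leaf sits up to one pitch inside the physical edge, losing on average
  `perimeter × pitch/2` of area (≈1% for a 150 cm² leaf, ~3% for a
  25 cm² seedling leaf). Height quantisation (0.2 mm) adds a small
  opposite (inflating) roughness term. Reference recovery studies
  therefore use well-developed leaves (nominal 150 cm²), where the
  measured recovery error is below 1%.
- **Projected area** rasterises the union of triangle xy-footprints on
  a grid at the scan pitch (cell centres; one vectorised point-location
  query against the source triangulation, or an STRtree query for
  hand-built meshes). Union, not sum: stacked layers must not count
  twice, since the quantity stands in for ground cover / LAI.
- **Plant height** is the 99.5th percentile of z above the pot rim
  (configurable; 1.0 = maximum). The quantile guards against stray high
  returns on real scans; for noise-free synthetic scans the studies use
  the maximum. Two sampling bounds apply: ±0.5 z-quantum everywhere,
  plus up to `pitch × tan(tilt)` when the apex lies on a tilted leaf
  rim between two rays. Arched leaves crest horizontally, so their
  heights are exact to the quantum.
- **Leaf angle** is the area-weighted mean angle between triangle
  normals and the vertical, folded to [0°, 90°] because a surface
  normal's sign is arbitrary. 0° is a flat leaf. An empty mesh yields
  NaN — undefined, deliberately distinct from a flat canopy.

Sectors with fewer than `min_points` (50) canopy points yield all-zero
traits with a `low_points` flag instead of raising, so batch runs over
thousands of sectors never abort.

## Virtual scanner

Scenes are lists of parametric leaf patches with exact ground truth:
planar rectangles, elliptical leaflets (legume archetype; the truth is
the area of the rendered polygon fan, so truth and rendering agree by
construction), and arched cereal strap leaves — circular-arc ribbons
rising from the anchor at a base inclination and flattening to
horizontal at the tip, whose area is exactly arc length × width and
whose area-weighted mean surface angle is exactly half the base
inclination. Plants are placed at field-like density (default
16 m⁻², i.e. 4 plants per 0.26 m² sector, a typical cereal sowing);
`arrangement="spaced"` confines each leaf to its own grid cell
(guaranteed single layer, for recovery studies), `"natural"` lets
leaves radiate and overlap (occlusion studies).

Rendering casts one vertical ray per grid node (0.8 mm pitch, endpoints
inclusive: `floor(L/pitch)+1` samples per axis) and keeps only the
highest intersection — strict nadir occlusion; the real sensor's small
triangulation baseline is ignored as the conservative simplification.
Leaves are opaque with single returns (the sensor works in NIR, where
leaves reflect strongly). z is quantised to 0.2 mm. Wind adds seeded
per-point Gaussian xy displacement with sd = 0.5 mm × wind (m s⁻¹) — a
deliberately simple monotone blur model; the true noise structure of
wind-blown canopies (correlated leaf motion, z error) is not
characterised and not claimed. Identical (scene, config, seed) gives a
bit-identical cloud.

The trace generators emulate the platform's other streams: 30-min
weather records with a sinusoidal temperature day (default 22–38 °C,
peak 14:00), inverse RH, calm nights and gusty afternoons; and
second-to-minute cadence load-cell readings combining a daylight-bell
diurnal loss profile (default 150 g day⁻¹ per sector), irrigation /
drainage steps, and iid Gaussian scale noise (10 g per 1 s reading,
which hourly averaging brings to the platform's ~0.1 g regime). What
passing these studies does **not** show: fidelity to real canopy
architecture, soil evaporation, correlated scale drift, or rain.

## Lysimetry

Hour bins are half-open `[t, t+1h)`, clock-aligned UTC; empty hours are
flagged missing and never interpolated. Event detection runs on the
hourly series: an hour-to-hour increase above 50 g is irrigation, a
decrease faster than 200 g h⁻¹ is drainage (both configurable; the
defaults sit far above plausible hourly transpiration of pot-grown
canopies and far below a typical 1 l watering). Consecutive offending
hours merge into one event. Because events are resolved at hour scale,
a daytime event's magnitude absorbs that hour's own transpiration
(≤ ~25 g for a 150 g day⁻¹ canopy); night-time irrigation — standard
platform practice — makes daily totals recoverable to better than 1%.

Hourly transpiration is the weight drop outside event hours. Weight
*gains* outside events are censored to missing (not clipped), keeping
the mass-balance audit exact:
`Σ transpiration − Σ event magnitudes + total weight change = censored
mass`. Gains within 0.5 g (~5× the hourly-integrated scale precision)
are retained with a `noise_gain` flag instead: they are scale noise
around a near-zero night flux, and censoring them would bias daily
sums upward by ~1 g. Rates divide by piecewise-linearly interpolated
leaf area (missing outside the observed span) and are flagged undefined
when leaf area is not positive. Treatment contrasts report per-group
hourly means ± SE and post/pre mean-rate ratios per sector (SE over
replicates; undefined and flagged at n = 1).

## Weather derivations

VPD uses the Tetens saturation vapour pressure over water
(0.6108 / 17.27 / 237.3 — the standard agronomic form); inputs outside
0–100% RH are errors, not clamped. Thermal time accrues per 30-min
record at 0 below 10 °C, `T − 10` up to 25 °C, a 15 °C-plateau across
25–35 °C, and a linear decline to zero at 45 °C (ceiling configurable;
the supra-optimal limb is a modelling choice, the plateau is standard
for warm-season cereals). Each record's rate applies until the next
record; gaps over 2 h accrue at the mean of the flanking rates and are
logged. The axis is re-zeroed at sowing. Wind filtering matches each
observation to the nearest weather record within 30 min (the station's
integration cadence) and keeps it iff wind ≤ 2 m s⁻¹ (inclusive);
unmatched observations are dropped with a warning and a `reason` column
keeps counts conserving. The filter is applied per scan, not per day.

## Validation harness and reference studies

Estimated leaf area is regressed on true (or destructively observed)
area by OLS, per group and pooled; degenerate fits (n < 3 or zero x
variance) raise. On sparse single-layer panels the slope is ~1 with
R² > 0.98; on dense panels the slope falls (measured ~0.8 at 16 m⁻²
with five 30–70 cm² leaves per plant) because one perspective cannot
see overlapped tissue — underestimation, never inflation, and ranking
is preserved.

The reference studies (in `canopyscan.studies`, rerun by
`scripts/acceptance.py`) use these problem sizes, chosen to exercise
each property at full platform resolution while staying desk-scale:
50 single-layer sectors for trait recovery; 5 deterministic plate tilts
(a 51.2 × 195.3 mm, 100 cm² plate with grid-aligned short edges);
20 dense scenes for the occlusion slope; 20 noisy one-day traces
(1 s cadence) for lysimetry; 100 jitter replicates per wind level on
two-leaf sectors (320 × 330 mm, the platform's prototype scan window)
plus one 12-scan mixed-wind day; and a 20-day two-archetype
conductance study (VPD-sensitive genotype capped at
0.055 mg cm⁻² min⁻¹ above the VPD breakpoint, insensitive uncapped,
three sectors each) from which the cap is re-estimated as the median
midday rate on high-VPD hours of the joined table.

## Known limitations

- The meshing chain is a principled stand-in: the firmware's actual
  nearest-neighbour meshing algorithm and thresholds are unpublished.
- Nadir-only occlusion slightly overstates what a real scanner with a
  triangulation baseline misses near vertical edges.
- The boundary-strip bias makes small (< 50 cm²) isolated leaves read
  2–3% low at 0.8 mm pitch; this is a resolution limit, not a bug.
- Event magnitudes estimated from hourly bins absorb within-hour
  transpiration; sub-hourly event detection is not implemented.
- Synthetic weather and canopies are caricatures adequate for testing
  the computation chain, not for agronomic simulation.
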