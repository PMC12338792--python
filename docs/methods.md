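# Methods

## Signal model and the attenuation fit

The analysis treats each OCT A-scan as samples of a depth-decaying signal
under the single-scattering approximation: the mean detected signal in a
homogeneous layer is `I(z) = I0 · exp(−μ z)` with μ the attenuation
coefficient (scattering plus absorption) in mm⁻¹. On the stored logarithmic
scale this is a straight line, so μ is estimated by ordinary least squares
of log intensity against physical depth over the dermal region of interest
(DEJ peak to detected dermis–muscle boundary) of every valid averaged
A-scan, then averaged per volume.

Two log conventions are supported, declared in the volume sidecar's
`scale` field rather than guessed: `"log"` (natural log; μ = −slope) and
`"db"` (10·log₁₀; μ = −slope·ln10/10). Synthetic volumes use `"log"`. The
reported μ is the single-pass decay rate; no factor-of-two round-trip
correction is applied (a `round_trip` flag divides by 2 for comparison
with literature that uses the round-trip convention). Group contrasts are
unaffected by either convention.

The fit excludes two pixels at the shallow end of the ROI and one at the
deep end (`roi_trim_start=2`, `roi_trim_end=1`). The shallow guard keeps
the specular DEJ reflection — which is not part of the Lambert–Beer decay —
out of the line; the deep guard drops the partial-volume pixel at the
detected boundary. Fits shorter than `min_fit_points` (default 5; a
two-point fit is exact but meaningless) are marked invalid and excluded,
never imputed. Weighted or heteroscedasticity-aware fitting is deliberately
not used; plain OLS on block-averaged columns is the estimator the rest of
the pipeline assumes.

## Preprocessing and calibration

Each B-scan's raw A-scan columns are block-averaged in sets of 10 **on the
log scale**, keeping the trailing partial block — the only convention under
which a 1355-column B-scan yields 136 averaged columns and, after removing
15 low-intensity columns at each edge, 106 usable columns (12,720 per
120-B-scan volume). Averaging logs rather than linear amplitudes also has a
convenient exactness property: the block mean of log profiles from
laterally shifted exponential decays is still exactly linear in depth with
the same slope, so lateral jitter does not bias the attenuation fit. A
config switch allows averaging linearized amplitude instead for sensitivity
analysis of that choice.

Calibration pools annotated air and muscle voxels over a set of reference
volumes (by default one per group at baseline):

* `air_mean` — noise floor for peak detection;
* `muscle_mean` — the dermis–muscle boundary threshold;
* `prominence_threshold` — by default 3× the pooled air-region standard
  deviation. The original manual procedure set this "experimentally"; the
  3σ rule is the package's reproducible surrogate, sized so that speckle
  bumps (prominence ≈ one noise SD on averaged columns) are rejected by a
  wide margin while the DEJ reflection (worst-case prominence ≈ 1.5 log
  units under the default phantom) is kept.

## Layer detection

Per averaged column: local maxima are found with a topographic-prominence
criterion (plateau ties resolve to the shallowest index — deterministic and
biased identically across groups); peaks at or below the noise floor are
discarded. The first surviving peak is the surface, the second the DEJ.
The muscle boundary is the first index where intensity drops below
`muscle_mean`, with the search starting only after the profile has fallen
at least one prominence-threshold below the surface-peak value: applied
naively, the threshold rule would fire in the dark trough just under a
bright surface peak; the descent condition skips the peak's own flank while
keeping the global-threshold spirit. Columns missing any landmark, or with
landmarks out of order, are flagged invalid, excluded from volume means,
and reported through `n_valid`/`n_total`.

Thickness is reported as optical path (index difference × axial pitch). An
optional refractive-index division exists but defaults to 1.0 (off).

## The synthetic phantom

`phantom.py` generates four-layer (air / epidermis / dermis / muscle)
volumes in the instrument's raster (default 1355 A-scans × 120 B-scans,
4.4 μm lateral spacing; axial window 256 pixels at 4.0 μm — the axial pitch
is a free simulator parameter, not a claim about any device). Within each
layer the noiseless linear signal is `A0·exp(−μ·(z − z_top))`; defaults:

| layer     | thickness | reflectivity | attenuation |
|-----------|-----------|--------------|-------------|
| air       | 100 μm    | 1e-10 (noise floor) | 0    |
| epidermis | 20 μm     | 1.0          | 40 mm⁻¹     |
| dermis    | 400 μm    | 1.0          | 40 (baseline) / 25 (UVR-like) mm⁻¹ |
| muscle    | fills window | e⁻²⁰      | 0           |

The surface and DEJ carry specular reflections: additive amplitude spikes
of 2× the underlying layer reflectivity, distributed over the two pixels
bracketing the interface by sub-pixel weight. Anti-aliasing matters: a
spike painted into a single rounded pixel gets split between adjacent
pixels once lateral jitter moves the interface across a rounding boundary
inside a 10-column averaging block, which halves its log-scale height and
cost ~27% of DEJ detections in early experiments. The dermis–muscle
interface is a plain step (that boundary is found by thresholding, not
peak detection).

Speckle is multiplicative gamma noise with unit mean (default shape 10,
suggesting partially developed speckle after multi-beam compounding),
applied to linear amplitude before the log transform — so the mean linear
signal equals the noiseless signal and the fit is unbiased. Lateral
geometry variation is a single smooth corrugation field (Gaussian-filtered
white noise, correlation ≈ 20 A-scans × 4 B-scans) shifting all three
interfaces together, with standard deviation `thickness_jitter` (default
6 μm) and hard clipping at ±3.5σ so interface ordering is preserved
exactly and realized depths stay within 4σ of nominal. Between-animal
variation in thickness and attenuation is modelled at study level, not
inside a volume.

Amplitude levels are chosen so every detection rule is self-consistent
across the simulated μ range: a 400 μm dermis at 45 mm⁻¹ loses ~18 nepers,
so the muscle plateau (−20) and air floor (−23) must sit below the dermis
bottom for the boundary rule to fire at the true interface. This implies
an idealized dynamic range with no detector noise-floor clipping — a
deliberate simplification (see Limitations). The synthetic muscle
annotation for calibration references starts one pixel above the nominal
boundary, as an annotator outlining from the visible bright interface
would; this lifts `muscle_mean` slightly above the muscle plateau, which
is what makes the "first drop below the muscle mean" rule fire *at* the
boundary even on noiseless data. Calibration reference phantoms are
generated flat (jitter 0) so rectangular annotation boxes never leak
dermis voxels into the muscle region.

## Study-level generator

`study.py` draws per-mouse metric trajectories: value = group baseline +
mouse random intercept + linear drift toward a month-7 target + per-visit
noise. Defaults (the simulated study conditions): attenuation baseline
40 mm⁻¹ with back-site month-7 targets 23 / 31 / 26 mm⁻¹ for UVR control /
UVR+NMN / UVR+PL (σ_mouse 2.0, σ_visit 1.2 mm⁻¹); thickness baseline
420 μm with back-site targets 560 / 525 / 540 μm (σ_mouse 25, σ_visit
12 μm); side and stomach sites flat for every group. The default design is
4 groups × 6 mice × 3 sites × 8 monthly visits. `generate_metric_series`
samples metric values directly (the fast path used for replicated
plan-level simulation); `generate_study` renders each record as a phantom
volume whose dermis attenuation and thickness follow the same
trajectories.

## Statistics

* IQR filter: quartiles by linear interpolation between order statistics
  (no convention was inherited, so one is fixed and documented); fences at
  Q1 − k·IQR / Q3 + k·IQR, k = 3; fewer than 4 values pass through with a
  warning. Applied per group/site/month cell before Mann–Whitney tests
  only.
* One-way ANOVA: classic F; the degenerate all-constant case uses F = 0,
  p = 1 for equal means (F = ∞, p = 0 otherwise).
* Mann–Whitney U: two-sided, unpaired; exact null by enumeration when the
  samples are tie-free and n_a·n_b ≤ 400, otherwise the normal
  approximation with tie and continuity correction (worst-case deviation
  from the exact null at n = 7,7 is 0.0125 over the whole U range). A U at
  the null center reports p = 1.
* Plan: per site, ANOVA at months 0 and 7; follow-ups gated on the month-7
  ANOVA at α = 0.05: within-group month 0 vs 7 (×4), control vs each UVR
  group at month 7 (×3), UVR control vs each treated group (×2). Raw
  p-values, no multiple-testing correction, matching per-comparison
  reporting.
* Longitudinal summary: group×site×month means plus an OLS slope per
  group×site fitted on the individual records.

## Problem sizes used in the checks

The validation suite and `scripts/acceptance.py` use full lateral counts
(1355×120, i.e. 12,720 averaged A-scans) for the speckled attenuation
sweep, 1355×20 for the speckled thickness check, 200–300×4–6 rasters for
noiseless exactness checks (noiseless phantoms are also jitter-free, since
per-column ground truth is only well defined without lateral jitter once
columns are block-averaged), 200 replicates for the null
type-I-calibration of the ANOVA gate, and 100 replicates for the
planted-effect power check — sizes chosen as the package's own validation
scale.

## Limitations

* The phantom has unlimited dynamic range: real detectors clip deep-dermis
  signal at the noise floor, which truncates the usable fit range and
  biases μ low in strongly attenuating skin. Passing tests on the phantom
  therefore validate the estimator, not detector effects.
* No confocal/focal-plane PSF, multi-beam focus merging, sensor roll-off,
  or multiple scattering is simulated; absolute μ values from real data
  carry the single-scattering and scale-convention caveats even though
  group contrasts do not.
* The boundary rule is a global threshold. When total dermal attenuation
  approaches the margin between the dermis bottom and the muscle
  threshold (very thick, strongly attenuating skin), the crossing can fire
  early inside the dermis — the same failure mode reported for heavily
  photodamaged skin in practice. The per-volume `n_valid` counts and
  logged calibration constants exist to make such regimes auditable.
* Segmentation-failure handling (invalid columns excluded, failed volumes
  recorded as missing) is a package convention; no inherited convention
  existed for these cases.
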