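# skinoct

Quantifying UV-induced skin photodamage from optical coherence tomography
(OCT) volumes. The package implements the full analysis chain used in
longitudinal murine photodamage studies — per-A-scan skin-layer
segmentation, skin-thickness measurement, dermal attenuation-coefficient
estimation, and the group-level statistical comparison plan — together with
a synthetic layered-skin OCT simulator that provides ground truth for every
stage.

It is aimed at researchers analyzing volumetric OCT of skin (real exports
or simulated phantoms) who need reproducible, threshold-auditable
measurements of skin thickness and tissue attenuation over time and across
treatment groups.

## The measurements

An OCT **A-scan** is a depth profile of backscattered intensity, stored on a
logarithmic scale. Per averaged A-scan the pipeline finds:

* the **skin surface** — the first intensity peak above the noise floor
  (mean log intensity of annotated air regions) whose topographic
  prominence clears a calibration threshold;
* the **dermal–epidermal junction (DEJ)** — the second such peak;
* the **dermis–muscle boundary** — the first depth past the surface peak's
  falling edge where intensity drops below the mean log intensity of
  annotated muscle regions.

**Skin thickness** is the surface-to-muscle distance (axial pixels ×
pitch). The **attenuation coefficient** μ (mm⁻¹) comes from the
single-scattering model

```
I(z) = I0 · exp(−μ z)
```

so on a log scale the dermis is a straight line: an ordinary least-squares
fit of log intensity against depth over the DEJ-to-muscle region of
interest gives μ = −slope (natural-log scale; a dB convention is also
supported). Per-volume values are means over all valid averaged A-scans
(12,720 per full volume: 106 usable averaged A-scans × 120 B-scans).

Group-level inference mirrors a gate-then-follow-up plan: per imaging site,
one-way ANOVA across the four groups (control, UVR control, UVR + NMN,
UVR + PL) at baseline and month 7; where the month-7 ANOVA is significant,
two-sided unpaired Mann–Whitney U follow-ups with 3×IQR outlier removal
per group/site/month cell.

## Worked example

```python
import skinoct as sk

# 1. a flat reference phantom (dermal mu = 40 mm^-1) gives the calibration
ref = sk.default_phantom(40.0, thickness_jitter=0.0, seed=0,
                         n_ascans_per_bscan=300, n_bscans=6)
ref_vol, _ = sk.generate_volume(ref)
cal = sk.calibrate([(ref_vol, sk.reference_annotations(ref, "ref"))])
print(f"noise floor (air mean)     : {cal.air_mean:.2f} log units")
print(f"muscle boundary threshold  : {cal.muscle_mean:.2f} log units")
print(f"peak prominence threshold  : {cal.prominence_threshold:.2f} log units")

# 2. a UVR-like phantom (mu = 25 mm^-1, 420 um skin) under default speckle
spec = sk.default_phantom(25.0, seed=1, n_ascans_per_bscan=300, n_bscans=6)
vol, truth = sk.generate_volume(spec)

# 3. average in blocks of 10, trim the scan edges, segment, measure
averaged = sk.average_volume(vol, window=10, n_trim=2)
columns, profiles = sk.segment_volume(averaged, cal)
thickness = sk.measure_thickness(profiles, vol.axial_pitch)
atten = sk.measure_attenuation(columns, profiles, vol.axial_pitch, vol.scale)
print(f"valid A-scans              : {atten.n_valid}/{atten.n_total}")
print(f"mean skin thickness        : {thickness.volume_mean:.1f} um "
      f"(truth {truth.skin_thickness.mean():.1f})")
print(f"mean attenuation coeff     : {atten.volume_mean:.2f} mm^-1 "
      f"(truth {truth.dermal_attenuation:.1f})")
```

prints

```
noise floor (air mean)     : -23.07 log units
muscle boundary threshold  : -19.22 log units
peak prominence threshold  : 0.98 log units
valid A-scans              : 134/156
mean skin thickness        : 422.0 um (truth 420.0)
mean attenuation coeff     : 25.00 mm^-1 (truth 25.0)
```

The calibration constants are the three detection thresholds derived from
the annotated reference volume; the phantom's 420 μm skin and 25 mm⁻¹
dermal attenuation are recovered to within half an axial pixel and 0.01
mm⁻¹ respectively, with the invalid-column count reported for QC.

The same workflow is available from the shell:

```sh
skinoct simulate --out study/           # volumes + references + study table
skinoct calibrate study/references/annotations.json
skinoct analyze study/study_table.csv   # metrics.csv, comparisons, report
skinoct report study/analysis/metrics.csv --metric mu_mm_inv
```

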