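# dermquant

Quantitative dermoscopy of basal cell carcinoma (BCC): calibrated lesion and
pigment areas, the Pigmentation Coverage Ratio, size/depth stratification,
and exact small-sample statistics — with a synthetic-data layer that makes
every step testable against known ground truth.

## The problem

BCC is the most common skin cancer. Dermoscopy (surface microscopy at ~10x)
reveals pigmented and vascular structures whose prevalence shifts with tumor
size and histological subtype, and pigmentation appears to fade as tumors
invade deeper. Quantifying this requires three things that are easy to get
subtly wrong:

1. **Physical units.** A dermoscopic photograph carries an embedded
   millimetre scale; two annotated pixel positions on it a known distance
   apart give `mm_per_px`, and any binary mask then measures
   `area = (foreground pixels) × mm_per_px²`.
2. **Pigmentation Coverage Ratio.** The headline statistic of a lesion:

   ```
   PCR (%) = 100 × pigmented area (mm²) / total lesion area (mm²)
   ```

   with the pigment annotation optionally refined by inclusive per-channel
   colour bounds (blue-gray structures occupy a narrow RGB band).
3. **Exact categorical tests.** A cohort of ~40 lesions split over three
   size classes (small ≤ 15 mm², medium (15, 50] mm², large > 50 mm²) or six
   subtypes produces r×c tables far too sparse for chi-square. The
   Freeman–Halton test — Fisher's exact test generalised to r×c — conditions
   on both margins and sums the multivariate hypergeometric probabilities

   ```
   P(T) = (∏ᵢ Rᵢ!)(∏ⱼ Cⱼ!) / (N! ∏ᵢⱼ nᵢⱼ!)
   ```

   of every margin-consistent table no more probable than the observed one.
   `dermquant` implements it by full enumeration (with a Monte Carlo
   fallback for large tables), plus Pearson/Spearman correlations for the
   depth–pigmentation trend.

Because per-patient images of the reference cohort are not publicly
deposited, the package also ships:

- a **synthetic image generator** (lesion blob + pigment blobs + scale bar,
  masks emitted as exact ground truth),
- a **cohort simulator** whose defaults reproduce the published 42-lesion
  summary statistics (depth-layer mix 23/12/7, per-layer pigmentation
  means/SDs, lognormal areas, per-size feature prevalences), and
- a **printed-percentage inverter** that recovers the original integer
  contingency tables from two-decimal published percentages — group sizes
  (24, 13, 5) are the *unique* composition of 42 consistent with all 14
  printed feature rows.

## Worked example

```python
from dermquant import (
    ChannelBounds, SynthImageParams, generate_lesion_image, pigmentation_coverage,
    fh_exact_test, infer_group_sizes, printed_rows_from_reference, reconstruct_contingency,
)

params = SynthImageParams(
    image_width_px=1024, image_height_px=1024, mm_per_px=0.05,
    lesion_area_target_mm2=30.0, pigment_coverage_target=0.25, seed=7,
)
annotated, truth = generate_lesion_image(params)
bounds = ChannelBounds((90, 110), (100, 120), (120, 140))
m = pigmentation_coverage(annotated, bounds)
print(f"lesion area = {m.lesion_area_mm2:.2f} mm^2")
print(f"pigment area = {m.pigment_area_mm2:.2f} mm^2")
print(f"PCR = {m.pcr_percent:.2f}%  (generator target 25%)")

rows = printed_rows_from_reference()
sizes = infer_group_sizes(rows, total=42)
print(f"inferred size-group sizes: {sizes}")
hem = next(r for r in rows if r.feature_name == "hemorrhage")
table = reconstruct_contingency(hem, sizes)
print(f"hemorrhage (present, absent) by size group: {table.counts}")
res = fh_exact_test(table)
print(f"Freeman-Halton exact p = {res.p_value:.4f} ({res.tables_enumerated} tables enumerated)")
```

prints

```
lesion area = 30.47 mm^2
pigment area = 7.63 mm^2
PCR = 25.02%  (generator target 25%)
inferred size-group sizes: (24, 13, 5)
hemorrhage (present, absent) by size group: ((5, 19), (4, 9), (4, 1))
Freeman-Halton exact p = 0.0301 (69 tables enumerated)
```

The 30 mm² lesion rasterised to 30.47 mm² (within the generator's 5%
contract) and the measured PCR recovers the 25% coverage target to within
0.03 percentage points. The hemorrhage-by-size table reconstructed from the
printed percentages (20.83%, 30.77%, 80.00% of groups 24/13/5) gives an
exact two-sided p of 0.0301 — hemorrhage is significantly more prevalent in
larger tumors.

## Command line

```sh
dermquant simulate --config scenario.yaml --out data/        # images + cohort + manifest
dermquant quantify --images data/ --out measurements.csv     # calibrated areas + PCR
dermquant classify --cohort data/cohort.csv --out classified.csv
dermquant stats    --cohort data/cohort.csv --out tables/    # prevalence + exact p + depth summary
dermquant report   --tables tables/ --out report.md
```

The scenario file is a YAML mapping with optional `seed`, `n_images`,
`image` (SynthImageParams fields), `cohort` (CohortSimParams fields) and
`channel_bounds` sections; every run is deterministic under its seed and
`simulate` writes SHA-256 checksums of all artifacts to `manifest.json`.

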