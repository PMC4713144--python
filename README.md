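# thrombodens

Automated *entire-thrombus* density measurement for acute ischemic stroke CT,
with a simulated manual 3-ROI measurement and the full observer-agreement
analysis, exercised on synthetic paired CTA/NCCT phantoms.

The automated measurement follows the three-step segmentation design:

1. **Contralateral vessel segmentation** on CTA from two seed points
   (threshold-constrained region growing inside a geodesic tube).
2. **Mirror mapping**: the midsagittal symmetry plane is estimated by
   maximizing reflective self-similarity, and the contralateral segmentation
   is mirrored onto the occluded side as a search region.
3. **Thrombus segmentation** by intensity-bounded region growing inside the
   mapped region (with leak control).

The CTA-based thrombus mask is projected onto NCCT through a rigid
mutual-information registration, and the density distribution of the entire
thrombus is sampled and summarized (mean, median, SD, min, max, IQR,
skewness, excess kurtosis, volume, Shapiro-Wilk normality). A configurable
observer model places three small spherical ROIs (uniform-random through
hyperdense-seeking placement) to reproduce manual measurements, and an
agreement module provides OLS with CIs, Pearson, paired t, Bland-Altman and
two-way ICC, plus Kruskal-Wallis for kernel-group comparisons.

A fully parameterized phantom generator produces paired CTA/NCCT volumes
with a bilaterally symmetric arterial tree, an occluding thrombus whose
voxel densities follow a configurable spatially-coherent Gaussian-mixture
model, CT noise, partial-volume blur, and a known rigid misalignment — with
complete ground truth for every stage.

## CLI

```bash
thrombodens generate --spec spec.yaml --out phantom/ --seed 1
thrombodens segment-vessel --cta cta.nii.gz --seeds "41,38,25;20,59,56" --out vessel.nii.gz
thrombodens map-symmetry --cta cta.nii.gz --vessel-mask vessel.nii.gz --out mapped.nii.gz
thrombodens segment-thrombus --cta cta.nii.gz --mapped mapped.nii.gz --out thrombus.nii.gz
thrombodens register --moving cta.nii.gz --fixed ncct.nii.gz --out tfm.txt
thrombodens measure --ncct ncct.nii.gz --mask thrombus.nii.gz --out summary.json --histogram hist.csv
thrombodens simulate-observers --ncct ncct.nii.gz --mask thrombus.nii.gz --observers 3 --beta 0.8 --out manual.csv
thrombodens run-case --cta cta.nii.gz --ncct ncct.nii.gz --seeds seeds.json --out record.json
thrombodens agree --measurements measurements.csv --out report.json
thrombodens replicate --s1 s1.csv --out replication.json [--reference ref.json]
```

Volumes are NIfTI (`.nii`/`.nii.gz`) or MetaImage (`.mha`/`.mhd`); rigid
transforms are plain-text key/value files (rotation deg, translation mm,
center mm).

## Layout

| module | role |
| --- | --- |
| `thrombodens.image_core` | volumes, masks, rigid transforms, NIfTI/MetaImage I/O, resampling |
| `thrombodens.phantom` | synthetic paired CTA/NCCT generator + ground truth, cohort spec sampling |
| `thrombodens.vessel` | contralateral artery segmentation from seed points |
| `thrombodens.symmetry` | midsagittal plane estimation, mirror mapping |
| `thrombodens.registration` | rigid MI registration, manual-correction hook |
| `thrombodens.thrombus` | intensity-bounded thrombus growing |
| `thrombodens.density` | density sampling and distribution descriptors |
| `thrombodens.observers` | simulated 3-ROI manual measurement, bias curves |
| `thrombodens.stats` | OLS/Pearson/paired-t/Bland-Altman/ICC/Kruskal-Wallis |
| `thrombodens.cohort` | per-case orchestration, exclusion filters, cohort tables, replication |
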